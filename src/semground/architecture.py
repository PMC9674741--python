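"""Network architecture: the 12-area graph and its sparse wiring.

Twelve model areas mimic four cortical processing streams (auditory,
articulatory, visual, dorsal-motor), each consisting of a primary, a
secondary and a central multimodal "connector hub" area.  Between-area
links come in three classes: next-neighbour links between adjacent areas of
a stream, "jumping" links that skip the intermediate area of a stream, and
long-distance links between all pairs of the four hub areas.

Each area is a square sheet of excitatory cells (25 x 25 by default), with
one inhibitory cell underlying each excitatory cell.  Excitatory links are
sparse and random, restricted to a local window (19 x 19 by default) with a
Gaussian neighbourhood bias, and initially weak.  The grid is treated as a
torus so every cell has a full neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from semground.config import SimConfig


@dataclass(frozen=True)
class Area:
    """One model cortical area and its place in the architecture."""

    name: str
    stream: str        # auditory | articulatory | visual | dorsal-motor
    centrality: str    # primary | secondary | central
    system: str        # peri-sylvian | extra-sylvian
    lobe: str          # temporal | frontal


#: The 12 areas in canonical order (peri-sylvian first, streams
#: primary -> secondary -> central).
AREAS: tuple[Area, ...] = (
    Area("A1", "auditory", "primary", "peri-sylvian", "temporal"),
    Area("AB", "auditory", "secondary", "peri-sylvian", "temporal"),
    Area("PB", "auditory", "central", "peri-sylvian", "temporal"),
    Area("M1i", "articulatory", "primary", "peri-sylvian", "frontal"),
    Area("PMi", "articulatory", "secondary", "peri-sylvian", "frontal"),
    Area("PFi", "articulatory", "central", "peri-sylvian", "frontal"),
    Area("V1", "visual", "primary", "extra-sylvian", "temporal"),
    Area("TO", "visual", "secondary", "extra-sylvian", "temporal"),
    Area("AT", "visual", "central", "extra-sylvian", "temporal"),
    Area("M1L", "dorsal-motor", "primary", "extra-sylvian", "frontal"),
    Area("PML", "dorsal-motor", "secondary", "extra-sylvian", "frontal"),
    Area("PFL", "dorsal-motor", "central", "extra-sylvian", "frontal"),
)

AREA_NAMES: tuple[str, ...] = tuple(a.name for a in AREAS)
AREA_INDEX: dict[str, int] = {a.name: i for i, a in enumerate(AREAS)}

#: The four multimodal connector hubs linked all-to-all.
HUB_AREAS: tuple[str, ...] = ("PB", "PFi", "AT", "PFL")

STREAMS: dict[str, tuple[str, str, str]] = {
    "auditory": ("A1", "AB", "PB"),
    "articulatory": ("M1i", "PMi", "PFi"),
    "visual": ("V1", "TO", "AT"),
    "dorsal-motor": ("M1L", "PML", "PFL"),
}


def area(name: str) -> Area:
    try:
        return AREAS[AREA_INDEX[name]]
    except KeyError:
        raise KeyError(f"unknown area name: {name!r}") from None


def areas_by(**criteria: str) -> list[str]:
    """Names of areas matching all given attribute=value criteria.

    >>> areas_by(centrality="central", system="extra-sylvian")
    ['AT', 'PFL']
    """
    out = []
    for a in AREAS:
        if all(getattr(a, k) == v for k, v in criteria.items()):
            out.append(a.name)
    return out


@dataclass(frozen=True)
class AreaGeometry:
    """Grid geometry shared by all areas."""

    n_e_cells: int = 625
    excitatory_kernel: int = 19
    inhibitory_kernel: int = 5

    def __post_init__(self) -> None:
        edge = int(round(self.n_e_cells ** 0.5))
        if edge * edge != self.n_e_cells:
            raise ValueError(f"n_e_cells={self.n_e_cells} is not a square grid")

    @property
    def edge(self) -> int:
        return int(round(self.n_e_cells ** 0.5))

    @classmethod
    def from_config(cls, config: SimConfig) -> "AreaGeometry":
        return cls(
            n_e_cells=config.n_cells,
            excitatory_kernel=config.excitatory_kernel,
            inhibitory_kernel=config.inhibitory_kernel,
        )


@dataclass
class Projection:
    """A sparse excitatory projection between (or within) areas.

    ``weights`` is CSR with shape (n_source_cells, n_target_cells);
    row = presynaptic cell, column = postsynaptic cell.
    """

    source: str
    target: str
    weights: sp.csr_matrix
    link_class: str  # within | next-neighbour | jumping | long-distance

    def __post_init__(self) -> None:
        if self.weights.nnz and self.weights.data.min() < 0:
            raise ValueError("projection contains negative weights")


@dataclass
class AreaGraph:
    """The fixed 12-node area graph with classed, unordered links."""

    areas: tuple[str, ...]
    links: dict[frozenset, str] = field(default_factory=dict)

    def link_class(self, a: str, b: str) -> str | None:
        return self.links.get(frozenset((a, b)))

    def has_link(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.links

    @property
    def n_links(self) -> int:
        return len(self.links)

    def to_edge_list(self) -> list[tuple[str, str, str]]:
        """Sorted (source, target, link_class) triples, one per link."""
        rows = []
        for pair, cls in self.links.items():
            a, b = sorted(pair, key=AREA_INDEX.__getitem__)
            rows.append((a, b, cls))
        return sorted(rows, key=lambda r: (AREA_INDEX[r[0]], AREA_INDEX[r[1]]))

    def save_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tlink_class\n")
            for a, b, cls in self.to_edge_list():
                fh.write(f"{a}\t{b}\t{cls}\n")


def build_area_graph() -> AreaGraph:
    """Construct the fixed 12-area connectivity graph.

    8 next-neighbour links (2 per stream), 4 jumping links (1 per stream)
    and 6 long-distance links (all hub pairs): 18 links in total.
    """
    graph = AreaGraph(areas=AREA_NAMES)
    for chain in STREAMS.values():
        graph.links[frozenset(chain[0:2])] = "next-neighbour"
        graph.links[frozenset(chain[1:3])] = "next-neighbour"
        graph.links[frozenset((chain[0], chain[2]))] = "jumping"
    for i, a in enumerate(HUB_AREAS):
        for b in HUB_AREAS[i + 1:]:
            graph.links[frozenset((a, b))] = "long-distance"
    return graph


def _kernel_offsets(kernel: int, sigma: float, density: float,
                    exclude_self: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window offsets and their Gaussian link probabilities."""
    half = kernel // 2
    dr, dc = np.meshgrid(np.arange(-half, half + 1),
                         np.arange(-half, half + 1), indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()
    if exclude_self:
        keep = (dr != 0) | (dc != 0)
        dr, dc = dr[keep], dc[keep]
    prob = density * np.exp(-(dr ** 2 + dc ** 2) / (2.0 * sigma ** 2))
    return dr, dc, prob


def _wire(geometry: AreaGeometry, density: float, sigma: float,
          w_init_max: float, rng: np.random.Generator,
          exclude_self: bool) -> sp.csr_matrix:
    """Sparse random wiring with a truncated-Gaussian neighbourhood bias.

    Toroidal wrap-around keeps every cell's window complete.  Weights are
    drawn uniformly from (0, w_init_max].
    """
    edge = geometry.edge
    n = geometry.n_e_cells
    rows = np.arange(n) // edge
    cols = np.arange(n) % edge
    dr, dc, prob = _kernel_offsets(geometry.excitatory_kernel, sigma,
                                   density, exclude_self)
    pre_idx: list[np.ndarray] = []
    post_idx: list[np.ndarray] = []
    for k in range(dr.size):
        hit = np.nonzero(rng.random(n) < prob[k])[0]
        if hit.size == 0:
            continue
        tr = (rows[hit] + dr[k]) % edge
        tc = (cols[hit] + dc[k]) % edge
        pre_idx.append(hit)
        post_idx.append(tr * edge + tc)
    if pre_idx:
        pre = np.concatenate(pre_idx)
        post = np.concatenate(post_idx)
    else:
        pre = post = np.empty(0, dtype=np.int64)
    # (0, w_init_max]: flip the half-open unit interval
    w = (1.0 - rng.random(pre.size)) * w_init_max
    mat = sp.coo_matrix((w, (pre, post)), shape=(n, n)).tocsr()
    return mat


def build_within_area_wiring(geometry: AreaGeometry, density: float,
                             rng: np.random.Generator, *,
                             sigma: float = 5.0,
                             w_init_max: float = 0.1) -> Projection:
    """Within-area excitatory wiring: sparse, random, initially weak.

    Links stay inside each cell's excitatory window; link probability
    decays as a Gaussian of grid distance; self-connections are excluded.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    mat = _wire(geometry, density, sigma, w_init_max, rng, exclude_self=True)
    return Projection("within", "within", mat, "within")


def build_between_area_wiring(graph: AreaGraph, geometry: AreaGeometry,
                              density: float, rng: np.random.Generator, *,
                              sigma: float = 5.0,
                              w_init_max: float = 0.1) -> list[Projection]:
    """One reciprocal pair of sparse topographic projections per graph link.

    Each projection is centred on the corresponding (row, col) position in
    the target area with the same truncated-Gaussian profile as the
    within-area wiring (the straight-through offset is allowed here).
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    for name in graph.areas:
        if name not in AREA_INDEX:
            raise KeyError(f"unknown area name: {name!r}")
    projections = []
    for src, dst, cls in graph.to_edge_list():
        for a, b in ((src, dst), (dst, src)):
            mat = _wire(geometry, density, sigma, w_init_max, rng,
                        exclude_self=False)
            projections.append(Projection(a, b, mat, cls))
    return projections
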