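"""Grounding patterns: the synthetic stimulation inputs.

A *grounding pattern* is one perceptuo-motor experience of a concept: a
fixed set of 12 active cells in each stimulated primary area (V1 and M1L).
A *grounding set* holds the three instance patterns of one concept.

Concrete concepts implement full semantic-feature overlap: per area, 6
cells are shared by all three instances and each instance adds 6 unique
cells (6 + 3*6 = 24 distinct cells).  Abstract concepts implement family
resemblance: per area, each of the three instance pairs shares 4 cells
(the three pairwise overlaps are disjoint, so the triple intersection is
empty) and each instance adds 4 unique cells (3*4 + 3*4 = 24 distinct
cells).  Both types are thereby matched on cells per pattern (12) and
distinct cells per set (24).

An inventory holds 10 concepts (30 patterns); cells of different concepts
never overlap.  Cell placement is uniformly random over the remaining free
pool of each area's 625 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STIMULATED_AREAS: tuple[str, ...] = ("V1", "M1L")

CELLS_PER_PATTERN = 12
DISTINCT_CELLS_PER_SET = 24
CONCEPTS_PER_INVENTORY = 10
INSTANCES_PER_CONCEPT = 3


@dataclass(frozen=True)
class GroundingPattern:
    """One instance pattern: 12 active cells in each stimulated area."""

    concept_id: int
    instance_index: int  # 1..3
    cells_per_area: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        if not 1 <= self.instance_index <= INSTANCES_PER_CONCEPT:
            raise ValueError("instance_index must be 1..3")
        for area, cells in self.cells_per_area.items():
            if len(cells) != CELLS_PER_PATTERN:
                raise ValueError(
                    f"{area}: expected {CELLS_PER_PATTERN} cells, got {len(cells)}")
            if any(c < 0 or c > 624 for c in cells):
                raise ValueError(f"{area}: cell index out of [0, 624]")


@dataclass(frozen=True)
class GroundingSet:
    """The three related instance patterns of one concept."""

    concept_id: int
    semantic_type: str  # concrete | abstract
    patterns: tuple[GroundingPattern, GroundingPattern, GroundingPattern]

    def cells(self, area: str) -> list[frozenset[int]]:
        return [p.cells_per_area[area] for p in self.patterns]

    def union(self, area: str) -> frozenset[int]:
        a, b, c = self.cells(area)
        return a | b | c

    def shared_cells(self, area: str) -> frozenset[int]:
        """Cells occurring in at least two instance patterns."""
        a, b, c = self.cells(area)
        return (a & b) | (a & c) | (b & c)


@dataclass
class GroundingInventory:
    """All grounding sets of one semantic type (10 concepts, 30 patterns)."""

    semantic_type: str
    sets: list[GroundingSet] = field(default_factory=list)

    @property
    def patterns(self) -> list[GroundingPattern]:
        return [p for s in self.sets for p in s.patterns]

    @property
    def total_patterns(self) -> int:
        return len(self.patterns)

    # --- plain-text serialization (one record per pattern x area) ------
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# semantic_type: {self.semantic_type}\n")
            fh.write("concept_id\tinstance\tarea\tcells\n")
            for s in self.sets:
                for p in s.patterns:
                    for area_name in sorted(p.cells_per_area):
                        cells = ",".join(map(str, sorted(p.cells_per_area[area_name])))
                        fh.write(f"{s.concept_id}\t{p.instance_index}\t"
                                 f"{area_name}\t{cells}\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundingInventory":
        lines = Path(path).read_text().splitlines()
        semantic_type = lines[0].split(":", 1)[1].strip()
        records: dict[tuple[int, int], dict[str, frozenset[int]]] = {}
        for line in lines[2:]:
            if not line.strip():
                continue
            cid, inst, area_name, cells = line.split("\t")
            key = (int(cid), int(inst))
            records.setdefault(key, {})[area_name] = frozenset(
                int(c) for c in cells.split(","))
        by_concept: dict[int, dict[int, dict]] = {}
        for (cid, inst), per_area in records.items():
            by_concept.setdefault(cid, {})[inst] = per_area
        inv = cls(semantic_type=semantic_type)
        for cid in sorted(by_concept):
            patterns = tuple(
                GroundingPattern(cid, inst, by_concept[cid][inst])
                for inst in sorted(by_concept[cid]))
            inv.sets.append(GroundingSet(cid, semantic_type, patterns))
        return inv


class PoolExhaustedError(RuntimeError):
    """Raised when an area's free-cell pool cannot supply a grounding set."""


def _draw(pool: list[int], k: int, rng: np.random.Generator) -> list[int]:
    if len(pool) < k:
        raise PoolExhaustedError(
            f"need {k} free cells, pool holds {len(pool)}")
    chosen = rng.choice(len(pool), size=k, replace=False)
    cells = [pool[i] for i in chosen]
    for c in sorted(chosen, reverse=True):
        del pool[c]
    return cells


def _concrete_instances(pool: list[int],
                        rng: np.random.Generator) -> list[frozenset[int]]:
    shared = _draw(pool, 6, rng)
    return [frozenset(shared + _draw(pool, 6, rng)) for _ in range(3)]


def _abstract_instances(pool: list[int],
                        rng: np.random.Generator) -> list[frozenset[int]]:
    # disjoint pairwise overlaps for pairs (1,2), (1,3), (2,3)
    s12, s13, s23 = (_draw(pool, 4, rng) for _ in range(3))
    uniq = [_draw(pool, 4, rng) for _ in range(3)]
    return [frozenset(s12 + s13 + uniq[0]),
            frozenset(s12 + s23 + uniq[1]),
            frozenset(s13 + s23 + uniq[2])]


def generate_set(semantic_type: str, concept_id: int,
                 available_cells: dict[str, list[int]],
                 rng: np.random.Generator) -> GroundingSet:
    """Generate one grounding set, drawing without replacement per area.

    ``available_cells`` maps each stimulated area to its free-cell pool;
    drawn cells are removed from the pools in place.  The overlap structure
    is instantiated independently per area.
    """
    if semantic_type not in ("concrete", "abstract"):
        raise ValueError(f"unknown semantic_type: {semantic_type!r}")
    make = (_concrete_instances if semantic_type == "concrete"
            else _abstract_instances)
    per_area: dict[str, list[frozenset[int]]] = {}
    for area_name in STIMULATED_AREAS:
        per_area[area_name] = make(available_cells[area_name], rng)
    patterns = tuple(
        GroundingPattern(concept_id, i + 1,
                         {a: per_area[a][i] for a in STIMULATED_AREAS})
        for i in range(3))
    return GroundingSet(concept_id, semantic_type, patterns)


def generate_inventory(semantic_type: str, rng: np.random.Generator, *,
                       n_concepts: int = CONCEPTS_PER_INVENTORY,
                       n_cells: int = 625) -> GroundingInventory:
    """Generate a full inventory of disjoint grounding sets."""
    if n_concepts * DISTINCT_CELLS_PER_SET > n_cells:
        raise ValueError("free pool too small for the requested inventory")
    pools = {a: list(range(n_cells)) for a in STIMULATED_AREAS}
    inv = GroundingInventory(semantic_type=semantic_type)
    for cid in range(n_concepts):
        inv.sets.append(generate_set(semantic_type, cid, pools, rng))
    return inv


def activation_counts(gset: GroundingSet) -> dict[str, dict]:
    """Per-cell activation counts over one full cycle (each instance once).

    Returns, per area, the per-cell counts plus the summed activations of
    shared and unique cells.  A concrete set yields 18 shared-cell
    activations per area (6 cells x 3), an abstract one 24 (12 cells x 2).
    """
    out: dict[str, dict] = {}
    for area_name in STIMULATED_AREAS:
        counts: dict[int, int] = {}
        for cells in gset.cells(area_name):
            for c in cells:
                counts[c] = counts.get(c, 0) + 1
        shared_total = sum(v for v in counts.values() if v >= 2)
        unique_total = sum(v for v in counts.values() if v == 1)
        out[area_name] = {
            "counts": counts,
            "shared_activations": shared_total,
            "unique_activations": unique_total,
        }
    return out
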