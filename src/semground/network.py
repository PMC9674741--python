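"""The multi-area network: state, time-stepped dynamics and checkpoints.

Every area is a 25 x 25 sheet of excitatory cells, each underlain by one
inhibitory cell.  Per time step (synchronous update, all inputs taken from
the previous step's outputs):

* e-cell potential: leaky integration of within- and between-area
  excitation, external input and white noise, minus local (5x5-pooled)
  and slow area-global inhibition;
* e-cell output: piecewise-linear rate ``clip(V - adaptation - theta, 0, 1)``,
  with subtractive adaptation tracking recent output;
* i-cell potential: leaky integration of the summed e-output in its 5x5
  neighbourhood; it inhibits the e-cell above it in proportion;
* area-global inhibition: low-pass of the summed e-output of the area;
* optional Hebbian LTP/LTD on all e->e synapses, clamped to [0, w_max].
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from semground import _kernels
from semground.architecture import (
    AREA_INDEX,
    AREA_NAMES,
    AreaGeometry,
    Projection,
    build_area_graph,
    build_between_area_wiring,
    build_within_area_wiring,
)
from semground.config import SimConfig

N_AREAS = 12


class SimulationError(RuntimeError):
    """Raised when the state becomes non-finite (fail fast)."""


@dataclass
class SimulationTrace:
    """Recorded per-cell output of one test presentation.

    ``output`` has shape (steps, areas, cells); areas follow ``AREA_NAMES``.
    """

    concept_id: int
    instance_index: int
    output: np.ndarray

    def area_output(self, area: str) -> np.ndarray:
        return self.output[:, AREA_INDEX[area], :]


def _pool_indices(edge: int, kernel: int) -> np.ndarray:
    """(n_cells, kernel**2) toroidal gather indices for the 5x5 pooling."""
    half = kernel // 2
    n = edge * edge
    rows = np.arange(n) // edge
    cols = np.arange(n) % edge
    offs = [(dr, dc) for dr in range(-half, half + 1)
            for dc in range(-half, half + 1)]
    idx = np.empty((n, len(offs)), dtype=np.int64)
    for k, (dr, dc) in enumerate(offs):
        idx[:, k] = ((rows + dr) % edge) * edge + (cols + dc) % edge
    return idx


class Network:
    """A 12-area network with sparse e->e synapses in flat arrays."""

    def __init__(self, config: SimConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 _empty: bool = False):
        self.config = config or SimConfig.default()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.rng = rng
        self.graph = build_area_graph()
        self.n_cells = self.config.n_cells
        self.n_total = N_AREAS * self.n_cells
        self._pool_idx = _pool_indices(self.config.grid_edge,
                                       self.config.inhibitory_kernel)
        self._alloc_state()
        if not _empty:
            self._build_wiring()

    # ------------------------------------------------------------------
    def _alloc_state(self) -> None:
        n = self.n_total
        self.potential = np.zeros(n)
        self.adaptation = np.zeros(n)
        self.output = np.zeros(n)
        self.i_potential = np.zeros(n)
        self.global_inhibition = np.zeros(N_AREAS)
        self.step_count = 0

    def _alloc_buffers(self) -> None:
        n = self.n_total
        self._exc = np.zeros(n)
        self._out_buf = np.zeros(n)
        self._noise_e = np.zeros(n)
        self._noise_i = np.zeros(n)
        self._zeros = np.zeros(n)

    def _build_wiring(self) -> None:
        cfg = self.config
        geom = AreaGeometry.from_config(cfg)
        projections: list[Projection] = []
        for _ in AREA_NAMES:
            projections.append(build_within_area_wiring(
                geom, cfg.within_density, self.rng,
                sigma=cfg.within_sigma, w_init_max=cfg.w_init_max_within))
        for i, name in enumerate(AREA_NAMES):
            projections[i].source = name
            projections[i].target = name
        projections += build_between_area_wiring(
            self.graph, geom, cfg.between_density, self.rng,
            sigma=cfg.between_sigma, w_init_max=cfg.w_init_max_between)
        self._flatten(projections)

    def _flatten(self, projections: list[Projection]) -> None:
        """Pack all projections into one pre-sorted synapse array."""
        pres, posts, ws, pids = [], [], [], []
        meta = []
        for pid, proj in enumerate(projections):
            coo = proj.weights.tocoo()
            src_off = AREA_INDEX[proj.source] * self.n_cells
            dst_off = AREA_INDEX[proj.target] * self.n_cells
            pres.append(coo.row.astype(np.int64) + src_off)
            posts.append(coo.col.astype(np.int64) + dst_off)
            ws.append(coo.data.astype(np.float64))
            pids.append(np.full(coo.nnz, pid, dtype=np.int16))
            meta.append((proj.source, proj.target, proj.link_class))
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
        w = np.concatenate(ws)
        pid_arr = np.concatenate(pids)
        order = np.argsort(pre, kind="stable")
        self.syn_pre = np.ascontiguousarray(pre[order], dtype=np.int32)
        self.syn_post = np.ascontiguousarray(post[order], dtype=np.int32)
        self.syn_w = np.ascontiguousarray(w[order])
        self.syn_proj = np.ascontiguousarray(pid_arr[order])
        counts = np.bincount(self.syn_pre, minlength=self.n_total)
        self.indptr_pre = np.concatenate(
            ([0], np.cumsum(counts))).astype(np.int64)
        self.syn_order = np.argsort(self.syn_post, kind="stable").astype(np.int64)
        counts_post = np.bincount(self.syn_post, minlength=self.n_total)
        self.indptr_post = np.concatenate(
            ([0], np.cumsum(counts_post))).astype(np.int64)
        self.projection_meta = meta
        self._alloc_buffers()

    # ------------------------------------------------------------------
    @property
    def n_synapses(self) -> int:
        return self.syn_w.size

    def weights_of(self, source: str, target: str) -> np.ndarray:
        """Copy of the weights of one directed projection."""
        for pid, (s, t, _) in enumerate(self.projection_meta):
            if s == source and t == target:
                return self.syn_w[self.syn_proj == pid].copy()
        raise KeyError(f"no projection {source}->{target}")

    def weight_checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(self.syn_pre.tobytes())
        h.update(self.syn_post.tobytes())
        h.update(self.syn_w.tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------------
    def reset(self) -> None:
        """Global reset: clear all potentials, adaptation, outputs and
        inhibition.  Weights are untouched."""
        self.potential[:] = 0.0
        self.adaptation[:] = 0.0
        self.output[:] = 0.0
        self.i_potential[:] = 0.0
        self.global_inhibition[:] = 0.0

    def step(self, external: np.ndarray | None = None, *,
             baseline_noise: bool = True,
             input_noise_std: np.ndarray | None = None,
             learning: bool = False) -> None:
        """Advance the network one time step (synchronous update).

        Parameters
        ----------
        external : optional (12, n_cells) array of external input currents.
        baseline_noise : add white noise of std ``noise_baseline`` to every
            cell's input (e- and i-cells).
        input_noise_std : optional per-area std of extra white input noise
            delivered to e-cells (shape (12,)).
        learning : apply the Hebbian LTP/LTD rule after the state update.
        """
        cfg = self.config
        if external is not None:
            ext = np.asarray(external, dtype=np.float64)
            if ext.shape == (N_AREAS, self.n_cells):
                ext = ext.ravel()
            elif ext.shape != (self.n_total,):
                raise ValueError(
                    f"external input shape {ext.shape} != "
                    f"{(N_AREAS, self.n_cells)}")
        else:
            ext = self._zeros
        if baseline_noise and cfg.noise_baseline > 0:
            self.rng.standard_normal(out=self._noise_e)
            self._noise_e *= cfg.noise_baseline
            self.rng.standard_normal(out=self._noise_i)
            self._noise_i *= cfg.noise_baseline
        else:
            self._noise_e[:] = 0.0
            self._noise_i[:] = 0.0
        if input_noise_std is not None:
            stds = np.asarray(input_noise_std, dtype=float)
            for a in np.nonzero(stds > 0)[0]:
                sl = slice(a * self.n_cells, (a + 1) * self.n_cells)
                self._noise_e[sl] += self.rng.normal(
                    0.0, stds[a], self.n_cells)
        bad = _kernels.step_core(
            self.indptr_pre, self.syn_post, self.syn_w,
            self.output, self._out_buf, self._exc,
            self.potential, self.adaptation, self.i_potential,
            self.global_inhibition, self._pool_idx,
            self._noise_e, self._noise_i, ext,
            cfg.tau_e, cfg.tau_i, cfg.tau_adapt, cfg.tau_global,
            cfg.adapt_strength, cfg.output_threshold,
            cfg.k_local, cfg.k_global, self.n_cells, N_AREAS)
        self.output, self._out_buf = self._out_buf, self.output
        self.step_count += 1
        self._maybe_log()
        if bad >= 0:
            raise SimulationError(
                f"non-finite potential in area "
                f"{AREA_NAMES[bad // self.n_cells]} at step {self.step_count}")
        if learning:
            _kernels.hebbian(self.indptr_pre, self.syn_post, self.syn_w,
                             self.indptr_post, self.syn_order, self.syn_pre,
                             self.output, cfg.pre_threshold,
                             cfg.post_threshold, cfg.ltp, cfg.ltd, cfg.ltd_hetero,
                             cfg.w_max)

    # ------------------------------------------------------------------
    def enable_logging(self, every: int = 100) -> None:
        """Record (step, per-area mean output, global inhibition) every
        ``every`` steps; rows accumulate until :meth:`run_log` is read."""
        if every < 1:
            raise ValueError("logging cadence must be >= 1")
        self._log_every = every
        self._log_rows: list[tuple] = []

    def run_log(self):
        """The accumulated run log as a pandas DataFrame."""
        import pandas as pd
        cols = (["step"] + [f"mean_out_{a}" for a in AREA_NAMES]
                + [f"global_inh_{a}" for a in AREA_NAMES])
        return pd.DataFrame(getattr(self, "_log_rows", []), columns=cols)

    def _maybe_log(self) -> None:
        every = getattr(self, "_log_every", 0)
        if every and self.step_count % every == 0:
            self._log_rows.append(
                (self.step_count, *self.mean_area_output(),
                 *self.global_inhibition))

    def area_output(self, area: str) -> np.ndarray:
        i = AREA_INDEX[area]
        return self.output[i * self.n_cells:(i + 1) * self.n_cells]

    def mean_area_output(self) -> np.ndarray:
        return self.output.reshape(N_AREAS, self.n_cells).mean(axis=1)

    def clone(self) -> "Network":
        """Deep copy sharing nothing; RNG state is copied bit-for-bit."""
        new = Network(self.config, np.random.default_rng(), _empty=True)
        new.rng.bit_generator.state = self.rng.bit_generator.state
        for name in ("syn_pre", "syn_post", "syn_w", "syn_proj",
                     "indptr_pre", "syn_order", "indptr_post",
                     "potential", "adaptation", "output", "i_potential",
                     "global_inhibition"):
            setattr(new, name, getattr(self, name).copy())
        new._alloc_buffers()
        new.projection_meta = list(self.projection_meta)
        new.step_count = self.step_count
        return new

    # --- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        """Bit-stable checkpoint: synapses, state, config and RNG state."""
        meta = json.dumps({
            "projection_meta": self.projection_meta,
            "rng_state": self.rng.bit_generator.state,
            "step_count": self.step_count,
        })
        np.savez_compressed(
            path,
            config_yaml=np.frombuffer(
                io.BytesIO(_cfg_bytes(self.config)).getvalue(), dtype=np.uint8),
            meta=np.frombuffer(meta.encode(), dtype=np.uint8),
            syn_pre=self.syn_pre, syn_post=self.syn_post,
            syn_w=self.syn_w, syn_proj=self.syn_proj,
            potential=self.potential, adaptation=self.adaptation,
            output=self.output, i_potential=self.i_potential,
            global_inhibition=self.global_inhibition)

    @classmethod
    def load(cls, path) -> "Network":
        import yaml
        with np.load(path) as data:
            cfg = SimConfig.from_dict(
                yaml.safe_load(bytes(data["config_yaml"]).decode()))
            meta = json.loads(bytes(data["meta"]).decode())
            net = cls(cfg, np.random.default_rng(), _empty=True)
            net.rng.bit_generator.state = meta["rng_state"]
            net.step_count = meta["step_count"]
            net.projection_meta = [tuple(m) for m in meta["projection_meta"]]
            for name in ("syn_pre", "syn_post", "syn_w", "syn_proj",
                         "potential", "adaptation", "output", "i_potential",
                         "global_inhibition"):
                setattr(net, name, data[name].copy())
        counts = np.bincount(net.syn_pre, minlength=net.n_total)
        net.indptr_pre = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        net.syn_order = np.argsort(net.syn_post, kind="stable").astype(np.int64)
        counts_post = np.bincount(net.syn_post, minlength=net.n_total)
        net.indptr_post = np.concatenate(
            ([0], np.cumsum(counts_post))).astype(np.int64)
        net._alloc_buffers()
        return net


def _cfg_bytes(cfg: SimConfig) -> bytes:
    import yaml
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False).encode()
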