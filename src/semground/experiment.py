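"""Training and testing protocol: the paired "simulated subjects" design.

One *subject* is one random network initialization.  Its wiring is cloned
into two model instances, one trained on a concrete and one on an abstract
grounding-pattern inventory, so semantic type is a within-subject factor.

Training trial: one of the 30 patterns (chosen uniformly at random among
those not yet fully presented) is clamped as input to V1 and M1L for 16
steps with learning on; the non-stimulated peri-sylvian primary areas (A1,
M1i) receive uncorrelated white input noise throughout.  Each trial is
followed by a noise-only inter-stimulus interval (input noise to all four
primary areas) that ends only once global inhibition in A1 and PB has
fallen below a threshold.  Training runs until every pattern has been
presented ``reps_per_pattern`` times.

Testing: per pattern, a global reset, 2 noise-free stimulation steps, then
28 steps with baseline noise only; the full per-cell output of all 12
areas is recorded (30 steps total) with learning off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from semground.architecture import AREA_INDEX, AREA_NAMES
from semground.config import SimConfig
from semground.network import N_AREAS, Network, SimulationTrace
from semground.patterns import (
    GroundingInventory,
    GroundingPattern,
    generate_inventory,
)

PRIMARY_AREAS = ("A1", "M1i", "V1", "M1L")
NOISE_ONLY_AREAS = ("A1", "M1i")  # extra input noise during stimulation
ISI_MONITOR_AREAS = ("A1", "PB")


class RunawayDynamicsError(RuntimeError):
    """ISI failed to terminate within the configured step cap."""


@dataclass
class TrainingSchedule:
    reps_per_pattern: int = 4000
    stim_steps: int = 16
    isi_threshold: float | None = None  # None: take from config
    isi_max_steps: int | None = None


@dataclass
class TestProtocol:
    stim_steps: int = 2
    record_steps: int = 30
    noise_off_during_stim: bool = True
    reset_before_each: bool = True


@dataclass
class ModelInstance:
    subject_id: int
    master_seed: int
    semantic_type: str
    network: Network
    trained: bool = False
    training_log: dict = field(default_factory=dict)


def _pattern_input(pattern: GroundingPattern, amplitude: float,
                   n_cells: int) -> np.ndarray:
    ext = np.zeros((N_AREAS, n_cells))
    for area_name, cells in pattern.cells_per_area.items():
        ext[AREA_INDEX[area_name], sorted(cells)] = amplitude
    return ext


def _noise_std(areas: tuple[str, ...], std: float) -> np.ndarray:
    out = np.zeros(N_AREAS)
    for a in areas:
        out[AREA_INDEX[a]] = std
    return out


def train_model(instance: ModelInstance, inventory: GroundingInventory,
                schedule: TrainingSchedule,
                order_rng: np.random.Generator) -> ModelInstance:
    """Train one model instance in place and return it."""
    net = instance.network
    cfg = net.config
    isi_thr = (cfg.isi_threshold if schedule.isi_threshold is None
               else schedule.isi_threshold)
    isi_cap = (cfg.isi_max_steps if schedule.isi_max_steps is None
               else schedule.isi_max_steps)
    patterns = inventory.patterns
    n_pat = len(patterns)
    ext_inputs = [_pattern_input(p, cfg.stim_amplitude, net.n_cells)
                  for p in patterns]
    stim_noise = _noise_std(NOISE_ONLY_AREAS, cfg.noise_input)
    isi_noise = _noise_std(PRIMARY_AREAS, cfg.noise_input)
    mon = [AREA_INDEX[a] for a in ISI_MONITOR_AREAS]

    remaining = np.full(n_pat, schedule.reps_per_pattern, dtype=np.int64)
    counts = np.zeros(n_pat, dtype=np.int64)
    isi_lengths: list[int] = []
    n_trials = 0
    while remaining.any():
        open_idx = np.nonzero(remaining > 0)[0]
        k = open_idx[order_rng.integers(open_idx.size)]
        for _ in range(schedule.stim_steps):
            net.step(ext_inputs[k], input_noise_std=stim_noise, learning=True)
        counts[k] += 1
        remaining[k] -= 1
        n_trials += 1
        isi_len = 0
        while True:
            net.step(None, input_noise_std=isi_noise, learning=True)
            isi_len += 1
            if np.all(net.global_inhibition[mon] < isi_thr):
                break
            if isi_len >= isi_cap:
                raise RunawayDynamicsError(
                    f"ISI did not terminate within {isi_cap} steps "
                    f"(subject {instance.subject_id}, trial {n_trials})")
        isi_lengths.append(isi_len)
    instance.trained = True
    instance.training_log = {
        "n_trials": n_trials,
        "presentations": counts.tolist(),
        "mean_isi_steps": float(np.mean(isi_lengths)) if isi_lengths else 0.0,
        "total_steps": net.step_count,
    }
    return instance


def test_model(instance: ModelInstance, inventory: GroundingInventory,
               protocol: TestProtocol | None = None) -> list[SimulationTrace]:
    """Record the network response to each pattern with learning off."""
    protocol = protocol or TestProtocol()
    net = instance.network
    cfg = net.config
    traces = []
    for pattern in inventory.patterns:
        if protocol.reset_before_each:
            net.reset()
        ext = _pattern_input(pattern, cfg.stim_amplitude, net.n_cells)
        rec = np.empty((protocol.record_steps, N_AREAS, net.n_cells),
                       dtype=np.float32)
        for t in range(protocol.record_steps):
            if t < protocol.stim_steps:
                net.step(ext,
                         baseline_noise=not protocol.noise_off_during_stim,
                         learning=False)
            else:
                net.step(None, baseline_noise=True, learning=False)
            rec[t] = net.output.reshape(N_AREAS, net.n_cells)
        traces.append(SimulationTrace(pattern.concept_id,
                                      pattern.instance_index, rec))
    return traces


# ----------------------------------------------------------------------
@dataclass
class SubjectCondition:
    """Everything recorded for one subject under one training condition."""

    subject_id: int
    condition: str       # concrete | abstract | concrete_control
    semantic_type: str   # concrete | abstract
    inventory: GroundingInventory
    traces: list[SimulationTrace]
    initial_checksum: str
    trained_checksum: str
    training_log: dict


@dataclass
class ExperimentResult:
    config: SimConfig
    conditions: tuple[str, ...]
    subjects: tuple[int, ...]
    data: dict[tuple[int, str], SubjectCondition]

    def save(self, out_dir: str | Path) -> None:
        """Archive to disk: traces (compressed arrays), inventories
        (plain text), config snapshot and logs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.save(out / "config.yaml")
        meta = {"conditions": list(self.conditions),
                "subjects": list(self.subjects)}
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        for (sid, cond), sc in self.data.items():
            d = out / f"subject{sid:02d}" / cond
            d.mkdir(parents=True, exist_ok=True)
            sc.inventory.save(d / "inventory.txt")
            np.savez_compressed(
                d / "traces.npz",
                output=np.stack([t.output for t in sc.traces]),
                concept_id=np.array([t.concept_id for t in sc.traces]),
                instance_index=np.array(
                    [t.instance_index for t in sc.traces]))
            (d / "log.json").write_text(json.dumps({
                "semantic_type": sc.semantic_type,
                "initial_checksum": sc.initial_checksum,
                "trained_checksum": sc.trained_checksum,
                "training_log": sc.training_log}, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "ExperimentResult":
        out = Path(out_dir)
        config = SimConfig.load(out / "config.yaml")
        meta = json.loads((out / "meta.json").read_text())
        data = {}
        for sid in meta["subjects"]:
            for cond in meta["conditions"]:
                d = out / f"subject{sid:02d}" / cond
                inv = GroundingInventory.load(d / "inventory.txt")
                log = json.loads((d / "log.json").read_text())
                with np.load(d / "traces.npz") as z:
                    traces = [SimulationTrace(int(c), int(i), o) for c, i, o
                              in zip(z["concept_id"], z["instance_index"],
                                     z["output"])]
                data[(sid, cond)] = SubjectCondition(
                    sid, cond, log["semantic_type"], inv, traces,
                    log["initial_checksum"], log["trained_checksum"],
                    log["training_log"])
        return cls(config, tuple(meta["conditions"]),
                   tuple(meta["subjects"]), data)


#: Scaled-down presets.  "full" reproduces the complete study design;
#: "desk" finishes on one CPU within minutes; "smoke" only checks plumbing.
PRESETS: dict[str, dict] = {
    "full": {"n_subjects": 12, "n_concepts": 10, "reps_per_pattern": 4000,
             "control_reps": 2000},
    "desk": {"n_subjects": 2, "n_concepts": 4, "reps_per_pattern": 400,
             "control_reps": 200},
    "smoke": {"n_subjects": 2, "n_concepts": 2, "reps_per_pattern": 2,
              "control_reps": 1},
}


def run_paired_experiment(n_subjects: int = 12,
                          config: SimConfig | None = None, *,
                          n_concepts: int = 10,
                          reps_per_pattern: int = 4000,
                          control_reps: int | None = None,
                          seed: int = 0,
                          out_dir: str | Path | None = None,
                          progress: bool = False) -> ExperimentResult:
    """Run the full paired design: per subject, one initial network is
    cloned and trained separately on concrete and abstract inventories
    (plus, optionally, a halved-training concrete control condition)."""
    config = config or SimConfig.default()
    conditions = ["concrete", "abstract"]
    if control_reps is not None:
        conditions.append("concrete_control")
    data: dict[tuple[int, str], SubjectCondition] = {}
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)
    for sid, seq in enumerate(subject_seqs, start=1):
        streams = seq.spawn(2 + 3 * len(conditions))
        wiring_rng = np.random.default_rng(streams[0])
        pattern_rng = np.random.default_rng(streams[1])
        base = Network(config, wiring_rng)
        initial_checksum = base.weight_checksum()
        inventories = {
            "concrete": generate_inventory("concrete", pattern_rng,
                                           n_concepts=n_concepts,
                                           n_cells=config.n_cells),
            "abstract": generate_inventory("abstract", pattern_rng,
                                           n_concepts=n_concepts,
                                           n_cells=config.n_cells),
        }
        for ci, cond in enumerate(conditions):
            semantic_type = "concrete" if cond.startswith("concrete") else "abstract"
            reps = (control_reps if cond == "concrete_control"
                    else reps_per_pattern)
            noise_rng = np.random.default_rng(streams[2 + 3 * ci])
            order_rng = np.random.default_rng(streams[3 + 3 * ci])
            net = base.clone()
            net.rng = noise_rng
            inst = ModelInstance(sid, seed, semantic_type, net)
            try:
                train_model(inst, inventories[semantic_type],
                            TrainingSchedule(reps_per_pattern=reps),
                            order_rng)
                traces = test_model(inst, inventories[semantic_type])
            except Exception as exc:
                raise RuntimeError(
                    f"subject {sid}, condition {cond} failed") from exc
            data[(sid, cond)] = SubjectCondition(
                sid, cond, semantic_type, inventories[semantic_type], traces,
                initial_checksum, net.weight_checksum(), inst.training_log)
            if progress:
                print(f"subject {sid}/{n_subjects} {cond}: "
                      f"{inst.training_log['total_steps']} steps")
    result = ExperimentResult(config, tuple(conditions),
                              tuple(range(1, n_subjects + 1)), data)
    if out_dir is not None:
        result.save(out_dir)
    return result
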