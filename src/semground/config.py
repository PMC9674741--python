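"""Simulation configuration.

All tunable constants of the model live here: grid geometry, connection
kernels and densities, cell time constants, inhibition gains, Hebbian
learning parameters, noise amplitudes and the training/testing protocol.
A shipped YAML file (``semground/data/default_config.yaml``) mirrors the
dataclass defaults so runs can be reproduced and inspected without reading
code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    # --- geometry -----------------------------------------------------
    grid_edge: int = 25              # excitatory cells per area: grid_edge**2
    excitatory_kernel: int = 19      # odd; within/between links stay inside it
    inhibitory_kernel: int = 5       # odd; pooling window of the i-cell under e

    # --- wiring -------------------------------------------------------
    within_density: float = 0.35     # peak link probability at zero grid distance
    within_sigma: float = 5.0        # grid cells; Gaussian fall-off of link prob.
    between_density: float = 0.08
    between_sigma: float = 3.0
    w_init_max_within: float = 0.01   # within-area initial weights ~ U(0, max]
    w_init_max_between: float = 0.45  # between-area initial weights ~ U(0, max]
    w_max: float = 1.0                # hard upper bound on any synaptic weight

    # --- cell and area dynamics (time constants in simulation steps) --
    tau_e: float = 2.5               # e-cell membrane time constant
    tau_i: float = 5.0               # i-cell membrane time constant
    tau_adapt: float = 15.0          # adaptation low-pass time constant
    adapt_strength: float = 4.0      # gain of subtractive adaptation
    output_threshold: float = 0.10   # offset of the piecewise-linear rate fn
    k_local: float = 0.60            # gain of local (5x5-pooled) inhibition
    k_global: float = 0.07           # gain of slow area-level inhibition
    tau_global: float = 8.0          # time constant of global inhibition

    # --- Hebbian learning (LTP/LTD on e->e synapses) -------------------
    ltp: float = 0.004               # weight increment, pre & post both active
    ltd: float = 0.0002              # decrement, pre active & post silent
    ltd_hetero: float = 0.0006       # decrement, post active & pre silent
    pre_threshold: float = 0.15     # "active" criterion on presynaptic output
    post_threshold: float = 0.15    # "active" criterion on postsynaptic output

    # --- noise ----------------------------------------------------------
    noise_baseline: float = 0.30     # std of white noise into every cell
    noise_input: float = 2.0         # std of extra input noise (see experiment)

    # --- stimulation and protocol ---------------------------------------
    stim_amplitude: float = 6.0      # external drive onto a pattern cell
    train_stim_steps: int = 16
    isi_threshold: float = 18.0       # global-inhibition cut-off ending an ISI
    isi_max_steps: int = 1000        # runaway guard
    test_stim_steps: int = 2
    test_record_steps: int = 30

    def __post_init__(self) -> None:
        if self.grid_edge <= 0:
            raise ValueError("grid_edge must be positive")
        for name in ("excitatory_kernel", "inhibitory_kernel"):
            k = getattr(self, name)
            if k % 2 != 1 or k < 1:
                raise ValueError(f"{name} must be a positive odd integer")
        if not (0.0 < self.within_density <= 1.0):
            raise ValueError("within_density must be in (0, 1]")
        if not (0.0 < self.between_density <= 1.0):
            raise ValueError("between_density must be in (0, 1]")
        if min(self.w_max, self.w_init_max_within, self.w_init_max_between) <= 0:
            raise ValueError("weight bounds must be positive")

    @property
    def n_cells(self) -> int:
        return self.grid_edge * self.grid_edge

    # --- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "SimConfig":
        """The shipped default configuration."""
        ref = resources.files("semground").joinpath("data/default_config.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
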