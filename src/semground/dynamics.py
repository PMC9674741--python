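"""Elementary dynamics operations as pure functions.

These are the reference forms of the update rules; the fused numba kernel
in :mod:`semground._kernels` applies the same arithmetic across the whole
synapse and cell arrays per step (a consistency test ties the two
together).
"""

from __future__ import annotations

from dataclasses import dataclass

from semground.config import SimConfig


@dataclass(frozen=True)
class LearningRule:
    """Threshold Hebbian LTP/LTD rule on excitatory synapses."""

    ltp_increment: float
    ltd_decrement: float          # homosynaptic: pre active, post silent
    pre_threshold: float
    post_threshold: float
    w_max: float
    ltd_hetero_decrement: float | None = None  # post active, pre silent

    def __post_init__(self) -> None:
        if self.ltd_hetero_decrement is None:
            object.__setattr__(self, "ltd_hetero_decrement",
                               self.ltd_decrement)
        if (self.ltp_increment <= 0 or self.ltd_decrement <= 0
                or self.ltd_hetero_decrement <= 0):
            raise ValueError("learning increments must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")

    @classmethod
    def from_config(cls, config: SimConfig) -> "LearningRule":
        return cls(config.ltp, config.ltd, config.pre_threshold,
                   config.post_threshold, config.w_max,
                   ltd_hetero_decrement=config.ltd_hetero)


def hebbian_update(pre_output: float, post_output: float, weight: float,
                   rule: LearningRule) -> float:
    """One Hebbian weight update.

    LTP when both outputs exceed their thresholds; LTD when exactly one
    does (with separate magnitudes for the pre-only/homosynaptic and the
    post-only/heterosynaptic case); no change otherwise.  The result is
    clamped to [0, w_max].
    """
    pre_on = pre_output > rule.pre_threshold
    post_on = post_output > rule.post_threshold
    if pre_on and post_on:
        weight += rule.ltp_increment
    elif pre_on:
        weight -= rule.ltd_decrement
    elif post_on:
        weight -= rule.ltd_hetero_decrement
    return min(max(weight, 0.0), rule.w_max)


def leaky_integrate(value: float, drive: float, time_constant: float) -> float:
    """One step of the discrete leaky integrator used by all cells."""
    return value + (drive - value) / time_constant


def leaky_fixed_point(drive: float) -> float:
    """The fixed point of the leaky integrator under constant drive."""
    return drive


def global_inhibition_update(value: float, summed_output: float,
                             gain: float, time_constant: float) -> float:
    """Slow area-level inhibition: low-pass of gain x total e-output.

    With a silent area the signal decays geometrically by
    (1 - 1/time_constant) per step; under sustained activity it converges
    to gain x summed_output.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    if time_constant <= 0:
        raise ValueError("time_constant must be positive")
    return leaky_integrate(value, gain * summed_output, time_constant)
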