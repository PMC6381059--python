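"""Model constants: field geometry, dynamics, trial timeline, latency windows.

All defaults reproduce the baseline simulation; every value can be overridden
through :class:`~scfield.config.RunConfig` for exploratory runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class FieldParams:
    """Scalar constants of the 1-D periodic neural field.

    The field discretizes 10 mm of intermediate superior colliculus (SCi)
    tissue, representing horizontal visual space from -5 mm (far left) to
    +5 mm (far right), into ``n_nodes`` nodes on a torus.

    Attributes
    ----------
    n_nodes : number of field nodes (N).
    dt : integration time step, ms.
    tau : membrane time constant of the field dynamics, ms.
    beta : steepness of the sigmoidal output nonlinearity.
    threshold : output activity level at which a saccade is triggered.
    resting_potential : initial internal state of every node.
    lateral_sigma : width (mm) of the Gaussian intra-field interaction kernel.
    lateral_scale : amplitude (sf) of the interaction kernel before shifting.
    shift_fraction : m as a fraction of max(G); the kernel is shifted down by
        ``shift_fraction * lateral_scale`` to produce distal inhibition.
    input_gamma : width (mm) of the Gaussian spatial profile of the inputs.
    input_amp : peak amplitude of the input spatial profile.
    fixation_exclusion_radius : half-width (mm) of the central zone whose
        threshold crossings do not trigger saccades ("non-central" rule).
    """

    n_nodes: int = 100
    dt: float = 1.0
    tau: float = 4.0
    beta: float = 0.09
    threshold: float = 0.7
    resting_potential: float = -30.0
    lateral_sigma: float = 0.85
    lateral_scale: float = 74.7
    shift_fraction: float = 0.8
    input_gamma: float = 0.6
    input_amp: float = 1.05
    fixation_exclusion_radius: float = 1.0

    # torus geometry
    @property
    def circumference(self) -> float:
        """Torus circumference L = 10 mm of SCi tissue."""
        return 10.0

    @property
    def dx(self) -> float:
        """Node spacing in mm (10 / N)."""
        return self.circumference / self.n_nodes

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.dt <= 0 or self.tau <= 0 or self.beta <= 0:
            raise ValueError("dt, tau and beta must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrialTimeline:
    """Event times of one trial, in ms relative to stimulus onset.

    The gap paradigm: the fixation point disappears 200 ms before the
    peripheral stimulus appears.  The pre-gap fixation duration is not a
    behavioural constraint of the task; 800 ms of stable fixation before
    the gap is assumed (it only sets the voluntary-preparation ramp slope).
    """

    fixation_acquired_t: float = -1000.0
    fixation_off_t: float = -200.0
    stimulus_on_t: float = 0.0
    max_sim_t: float = 600.0

    def __post_init__(self) -> None:
        if not (self.fixation_acquired_t < self.fixation_off_t
                < self.stimulus_on_t < self.max_sim_t):
            raise ValueError("timeline events must be strictly ordered")

    @property
    def gap(self) -> float:
        return self.stimulus_on_t - self.fixation_off_t

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ClassificationWindows:
    """Latency windows for the five-type saccade taxonomy (ms).

    Saccades before 90 ms are anticipatory; the express window is the
    closed interval [express_lo, express_hi]; later saccades are regular.
    """

    anticipatory_max: float = 90.0
    express_lo: float = 90.0
    express_hi: float = 138.0
    regular_hi: float = 600.0

    def __post_init__(self) -> None:
        if not (self.anticipatory_max == self.express_lo < self.express_hi
                < self.regular_hi):
            raise ValueError("invalid latency windows")

    def to_dict(self) -> dict:
        return asdict(self)


__all__ = ["FieldParams", "TrialTimeline", "ClassificationWindows"]
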