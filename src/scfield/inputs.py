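"""The eight component-based inputs to the SCi field.

Each input is a Gaussian spatial profile (width ``input_gamma``, peak
``input_amp``) times a piecewise-linear scalar amplitude in time.  Amplitudes
change linearly at a rate-of-response (RoR, fraction of the profile per ms)
after an onset delay keyed to a trial event (fixation acquisition, fixation
offset, or stimulus onset):

1. visual_transient      -- brief sensory burst at the stimulus site; rises
                            from 50 ms after stimulus onset until it reaches
                            its MaxVal (~51 ms of rise), then fades at half
                            its RoR back to zero.
2. automated_motor       -- stimulus-triggered, self-propagating motor drive;
                            rises to its MaxVal and holds until the saccade.
3. automated_fixation    -- foveal-stimulus hold; at MaxVal from trial start,
                            fades after fixation offset + delay.
4. voluntary_motor       -- internally initiated motor drive at the task goal
                            (stimulus site for pro, mirror for anti); uncapped.
5. voluntary_fixation    -- internal fixation hold; decays from voluntary
                            onset.
6. voluntary_preparation -- two-peaked anticipatory build-up at both possible
                            stimulus sites, reaching MaxVal exactly at the
                            expected stimulus onset (dependent RoR).
7. inhibitory_gate       -- uniform inhibitory wall of depth MaxVal with a
                            Gaussian opening carved out at the goal (SNr-like
                            location-specific dis-inhibition).
8. peripheral_inhibition -- inhibition of the whole periphery sparing the
                            fovea, released uniformly ("universal pauser").

All amplitude functions are closed-form evaluations of the per-step linear
update ``input(t+dt) = input(t) + k * RoR * dt`` and accept numpy arrays, so
the batched trial engine evaluates them directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .field import gaussian_profile, mirror_permutation
from .params import FieldParams, TrialTimeline

INPUT_NAMES = (
    "visual_transient",
    "automated_motor",
    "automated_fixation",
    "voluntary_motor",
    "voluntary_fixation",
    "voluntary_preparation",
    "inhibitory_gate",
    "peripheral_inhibition",
)

EXCITATORY = INPUT_NAMES[:6]
INHIBITORY = INPUT_NAMES[6:]

#: ms between the visual transient's response onset and its fade onset
VISUAL_BURST_MS = 50.0


@dataclass(frozen=True)
class InputAttributes:
    """Resolved attributes of one input for one trial.

    ``ror`` is a fraction per ms; ``max_val`` the cap on the absolute peak
    value (None for the uncapped voluntary motor input); ``mu`` the profile
    centre(s) in mm; ``onset_delay`` in ms relative to the input's reference
    event.
    """

    onset_delay: float
    ror: float
    max_val: Optional[float]
    mu: Tuple[float, ...]
    polarity: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if self.ror < 0:
            raise ValueError("ror must be >= 0")
        if self.max_val is not None and self.max_val < 0:
            raise ValueError("max_val must be >= 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError("polarity must be excitatory or inhibitory")


@dataclass
class EventClock:
    """Reference event times of the current trial (ms, stimulus onset = 0)."""

    fixation_acquired_t: float
    fixation_off_t: float
    stimulus_on_t: float
    saccade_t: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.fixation_acquired_t < self.fixation_off_t
                < self.stimulus_on_t):
            raise ValueError("clock events must be ordered")


# ---------------------------------------------------------------------------
# closed-form amplitude laws (multiples of the spatial profile k)
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def amp_transient(t, onset, ror, cap, burst_ms=VISUAL_BURST_MS, dt=1.0):
    """Brief sensory burst: rise at ``ror`` from ``onset`` until the cap is
    reached, then fade at ``ror/2`` back to zero.

    The fade begins on the first time step at which the transient has risen
    to its ceiling (the per-step rise is clamped at the cap), and no earlier
    than ``burst_ms`` after response onset.  With the baseline attributes
    (RoR 15 %/ms, MaxVal 8) the cap is reached on the 51st step after
    response onset, so the burst lasts just over 50 ms before fading.
    """
    safe_ror = np.where(np.asarray(ror) > 0, ror, np.inf)
    rise_ms = np.maximum(burst_ms, np.ceil(cap / safe_ror / dt) * dt)
    rise = np.minimum(ror * _relu(t - onset), cap)
    fade_start = onset + rise_ms
    peak = np.minimum(ror * rise_ms, cap)
    fade = _relu(peak - 0.5 * ror * _relu(t - fade_start))
    return np.where(t <= fade_start, rise, fade)


def amp_rise_hold(t, onset, ror, cap):
    """Rise at ``ror`` from ``onset``, saturate at ``cap`` and hold."""
    return np.minimum(ror * _relu(t - onset), cap)


def amp_hold_decay(t, decay_onset, ror, cap):
    """Hold at ``cap`` until ``decay_onset``, then decay at ``ror`` to zero."""
    return _relu(cap - ror * _relu(t - decay_onset))


def amp_ramp(t, onset, ror, ramp_ms):
    """Linear ramp from ``onset`` that saturates after ``ramp_ms``."""
    return ror * np.clip(t - onset, 0.0, ramp_ms)


def amp_unbounded(t, onset, ror):
    """Rise at ``ror`` from ``onset`` without bound."""
    return ror * _relu(t - onset)


def gate_field(t, onset, ror, max_val, k_goal):
    """Inhibitory-gate vector: a ``-max_val`` wall with a Gaussian opening
    growing at ``ror`` at the goal, clamped at zero."""
    opening = np.multiply.outer(ror * _relu(t - onset), k_goal)
    return np.minimum(0.0, opening - np.asarray(max_val)[..., None])


def peripheral_field(t, onset, ror, max_val, notch, amp):
    """Peripheral-inhibition vector: ``-max_val`` times the fovea-sparing
    notch shape, released uniformly at ``amp * ror`` per ms, clamped at
    zero per node."""
    release = np.asarray(amp * ror * _relu(t - onset))[..., None]
    base = -np.multiply.outer(np.asarray(max_val, float), notch)
    return np.minimum(0.0, base + release)


def apply_crosstalk(voluntary_motor_vec: np.ndarray,
                    automated_motor_vec: np.ndarray,
                    fraction: float,
                    mirror: np.ndarray) -> np.ndarray:
    """Voluntary-to-automated inhibitory crosstalk.

    Subtracts ``fraction`` of the horizontally flipped voluntary-motor vector
    from the automated-motor vector, clamping at zero (the automated motor
    input is never inhibitory).  The voluntary input is unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("crosstalk fraction must lie in [0, 1]")
    flipped = voluntary_motor_vec[..., mirror]
    return np.maximum(0.0, automated_motor_vec - fraction * flipped)


class InputBank:
    """The eight input vectors of one trial, evaluated at any time point.

    Parameters
    ----------
    attrs : mapping from input name to its resolved :class:`InputAttributes`.
    clock : the trial's event clock.
    params : field constants (profile width/amplitude, node grid).
    timeline : trial timeline (start time, used for the preparation ramp).
    """

    def __init__(self, attrs: Dict[str, InputAttributes], clock: EventClock,
                 params: FieldParams,
                 timeline: Optional[TrialTimeline] = None) -> None:
        missing = set(INPUT_NAMES) - set(attrs)
        if missing:
            raise ValueError(f"missing input attributes: {sorted(missing)}")
        self.attrs = dict(attrs)
        self.clock = clock
        self.params = params
        self.mirror = mirror_permutation(params)
        amp = params.input_amp

        self._prof = {name: gaussian_profile(attrs[name].mu[0], params)
                      for name in INPUT_NAMES
                      if name != "voluntary_preparation"}
        vp = attrs["voluntary_preparation"]
        self._prof["voluntary_preparation"] = np.maximum.reduce(
            [gaussian_profile(mu, params) for mu in vp.mu])
        center = gaussian_profile(0.0, params)
        self._notch = 1.0 - center / amp

        # preparation ramp: both peaks reach MaxVal exactly at stimulus onset
        self._vp_onset = clock.fixation_acquired_t + vp.onset_delay
        self._vp_ramp = clock.stimulus_on_t - self._vp_onset
        if self._vp_ramp <= 0:
            raise ValueError("voluntary-preparation ramp duration must be > 0")
        self._vp_ror = vp.ror  # dependent RoR, already resolved (0 = ablated)

    def _cap(self, name: str) -> float:
        mv = self.attrs[name].max_val
        return np.inf if mv is None else mv / self.params.input_amp

    def amplitude(self, name: str, t) -> np.ndarray:
        """Scalar amplitude A(t) of a Gaussian-profiled input (value at node
        i is ``A(t) * k_i``).  Not defined for the two inhibitory inputs,
        whose clamping is per node."""
        a = self.attrs[name]
        c = self.clock
        t = np.asarray(t, dtype=float)
        if name == "visual_transient":
            return amp_transient(t, c.stimulus_on_t + a.onset_delay, a.ror,
                                 self._cap(name))
        if name == "automated_motor":
            return amp_rise_hold(t, c.stimulus_on_t + a.onset_delay, a.ror,
                                 self._cap(name))
        if name == "automated_fixation":
            return amp_hold_decay(t, c.fixation_off_t + a.onset_delay, a.ror,
                                  self._cap(name))
        if name == "voluntary_motor":
            return amp_unbounded(t, c.stimulus_on_t + a.onset_delay, a.ror)
        if name == "voluntary_fixation":
            return amp_hold_decay(t, c.stimulus_on_t + a.onset_delay, a.ror,
                                  self._cap(name))
        if name == "voluntary_preparation":
            return amp_ramp(t, self._vp_onset, self._vp_ror, self._vp_ramp)
        raise KeyError(name)

    def vector(self, name: str, t: float) -> np.ndarray:
        """The input's spatial vector at time ``t``."""
        c = self.clock
        if c.saccade_t is not None and t >= c.saccade_t and name in (
                "visual_transient", "automated_motor", "voluntary_motor",
                "voluntary_preparation"):
            return np.zeros(self.params.n_nodes)
        a = self.attrs[name]
        if name == "inhibitory_gate":
            return gate_field(np.asarray(float(t)), c.stimulus_on_t
                              + a.onset_delay, a.ror, a.max_val,
                              self._prof[name])
        if name == "peripheral_inhibition":
            return peripheral_field(np.asarray(float(t)), c.stimulus_on_t
                                    + a.onset_delay, a.ror, a.max_val,
                                    self._notch, self.params.input_amp)
        return float(self.amplitude(name, t)) * self._prof[name]

    def vectors(self, t: float) -> Dict[str, np.ndarray]:
        return {name: self.vector(name, t) for name in INPUT_NAMES}

    def phase(self, name: str, t: float) -> str:
        """Coarse phase label of an input at time ``t``."""
        a = self.attrs[name]
        c = self.clock
        if name in ("inhibitory_gate", "peripheral_inhibition"):
            onset = c.stimulus_on_t + a.onset_delay
            return "holding" if t <= onset else "open"
        if name in ("automated_fixation", "voluntary_fixation"):
            amp_now = float(self.amplitude(name, t))
            if amp_now == 0.0:
                return "idle"
            ref = (c.fixation_off_t if name == "automated_fixation"
                   else c.stimulus_on_t)
            return "holding" if t <= ref + a.onset_delay else "fading"
        amp_now = float(self.amplitude(name, t))
        if amp_now == 0.0:
            return "idle"
        eps = 1e-12
        later = float(self.amplitude(name, t + self.params.dt))
        if later > amp_now + eps:
            return "rising"
        if later < amp_now - eps:
            return "fading"
        return "holding"

    def c_ext(self, t: float, crosstalk_enabled: bool = False,
              fraction: float = 0.25) -> np.ndarray:
        """Sum the eight vectors into the external contribution."""
        return sum_inputs(self.vectors(t), crosstalk_enabled=crosstalk_enabled,
                          fraction=fraction, mirror=self.mirror)


def sum_inputs(vectors: Dict[str, np.ndarray], crosstalk_enabled: bool = False,
               fraction: float = 0.25,
               mirror: Optional[np.ndarray] = None) -> np.ndarray:
    """Element-wise sum of the eight input vectors; with crosstalk enabled the
    automated-motor vector is replaced by its crosstalk-adjusted version."""
    am = vectors["automated_motor"]
    if crosstalk_enabled:
        if mirror is None:
            raise ValueError("crosstalk requires the mirror permutation")
        am = apply_crosstalk(vectors["voluntary_motor"], am, fraction, mirror)
    total = am.astype(float, copy=True)
    for name in INPUT_NAMES:
        if name != "automated_motor":
            total = total + vectors[name]
    return total


__all__ = [
    "INPUT_NAMES", "EXCITATORY", "INHIBITORY", "VISUAL_BURST_MS",
    "InputAttributes", "EventClock", "InputBank",
    "amp_transient", "amp_rise_hold", "amp_hold_decay", "amp_ramp",
    "amp_unbounded", "gate_field", "peripheral_field",
    "apply_crosstalk", "sum_inputs",
]
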