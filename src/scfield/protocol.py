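"""Trial protocol: task geometry, attribute levels, and the factorial grid.

Ten attributes take one of three monotonically increasing values
(small / medium / large); every combination is simulated in both the pro-
and the anti-saccade task, giving the 3^10 x 2 = 118,098-trial experiment.
The five voluntary/inhibitory inputs share a single onset delay per trial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .inputs import InputAttributes
from .params import FieldParams, TrialTimeline

#: eccentricity of the peripheral stimulus / goal sites, mm of SCi
STIMULUS_ECCENTRICITY_MM = 2.5

LEVELS = ("small", "medium", "large")

#: the ten varied attributes, in canonical (lexicographic enumeration) order
VARIED_ATTRIBUTES = (
    "shared_onset_delay",
    "automated_motor_ror",
    "automated_motor_max",
    "voluntary_motor_ror",
    "voluntary_fixation_max",
    "voluntary_preparation_max",
    "inhibitory_gate_ror",
    "inhibitory_gate_max",
    "peripheral_inhibition_ror",
    "peripheral_inhibition_max",
)

#: small / medium / large values of each varied attribute
LEVEL_VALUES: Dict[str, Tuple[float, float, float]] = {
    "shared_onset_delay": (140.0, 155.0, 170.0),
    "automated_motor_ror": (0.04, 0.06, 0.08),
    "automated_motor_max": (4.0, 6.0, 8.0),
    "voluntary_motor_ror": (0.05, 0.10, 0.15),
    "voluntary_fixation_max": (4.0, 6.0, 8.0),
    "voluntary_preparation_max": (4.0, 6.0, 8.0),
    "inhibitory_gate_ror": (0.05, 0.10, 0.15),
    "inhibitory_gate_max": (4.0, 6.0, 8.0),
    "peripheral_inhibition_ror": (0.05, 0.10, 0.15),
    "peripheral_inhibition_max": (4.0, 6.0, 8.0),
}

#: fixed attributes (identical sensory stimulation on every trial)
VISUAL_TRANSIENT_DELAY = 50.0
VISUAL_TRANSIENT_ROR = 0.15
VISUAL_TRANSIENT_MAX = 8.0
AUTOMATED_DELAY = 60.0
AUTOMATED_FIXATION_ROR = 0.10
AUTOMATED_FIXATION_MAX = 6.0
VOLUNTARY_FIXATION_ROR = 0.10

TASKS = ("pro", "anti")
SIDES = ("left", "right")


@dataclass(frozen=True)
class TrialSettings:
    """One trial's task, stimulus side, and level assignment for the ten
    varied attributes."""

    task: str
    stimulus_side: str
    levels: Tuple[str, ...]  # one level per VARIED_ATTRIBUTES entry

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.stimulus_side not in SIDES:
            raise ValueError(f"unknown side {self.stimulus_side!r}")
        if len(self.levels) != len(VARIED_ATTRIBUTES):
            raise ValueError("need one level per varied attribute")
        for lev in self.levels:
            if lev not in LEVELS:
                raise ValueError(f"unknown level {lev!r}")

    def level(self, attribute: str) -> str:
        return self.levels[VARIED_ATTRIBUTES.index(attribute)]

    def value(self, attribute: str) -> float:
        return level_value(attribute, self.level(attribute))

    @property
    def stimulus_x(self) -> float:
        return (STIMULUS_ECCENTRICITY_MM if self.stimulus_side == "right"
                else -STIMULUS_ECCENTRICITY_MM)

    @property
    def goal_x(self) -> float:
        """Saccade goal: the stimulus site (pro) or its mirror (anti)."""
        return self.stimulus_x if self.task == "pro" else -self.stimulus_x


def level_value(attribute: str, level: str) -> float:
    try:
        vals = LEVEL_VALUES[attribute]
    except KeyError:
        raise KeyError(f"unknown attribute {attribute!r}") from None
    try:
        return vals[LEVELS.index(level)]
    except ValueError:
        raise KeyError(f"unknown level {level!r}") from None


def preparation_ror(max_val: float, onset_delay: float, params: FieldParams,
                    timeline: TrialTimeline) -> float:
    """Dependent RoR of the voluntary-preparation input: both peaks reach
    MaxVal exactly at the expected stimulus onset."""
    ramp = (timeline.stimulus_on_t - timeline.fixation_acquired_t) - onset_delay
    if ramp <= 0:
        raise ValueError("preparation ramp duration must be positive")
    return max_val / (params.input_amp * ramp)


def resolve_settings(settings: TrialSettings, params: FieldParams,
                     timeline: TrialTimeline) -> Dict[str, InputAttributes]:
    """Resolve a trial's level assignment into concrete attributes for all
    eight inputs."""
    v = settings.value
    delay = v("shared_onset_delay")
    stim = settings.stimulus_x
    goal = settings.goal_x
    ecc = abs(stim)
    return {
        "visual_transient": InputAttributes(
            VISUAL_TRANSIENT_DELAY, VISUAL_TRANSIENT_ROR,
            VISUAL_TRANSIENT_MAX, (stim,), "excitatory"),
        "automated_motor": InputAttributes(
            AUTOMATED_DELAY, v("automated_motor_ror"),
            v("automated_motor_max"), (stim,), "excitatory"),
        "automated_fixation": InputAttributes(
            AUTOMATED_DELAY, AUTOMATED_FIXATION_ROR,
            AUTOMATED_FIXATION_MAX, (0.0,), "excitatory"),
        "voluntary_motor": InputAttributes(
            delay, v("voluntary_motor_ror"), None, (goal,), "excitatory"),
        "voluntary_fixation": InputAttributes(
            delay, VOLUNTARY_FIXATION_ROR, v("voluntary_fixation_max"),
            (0.0,), "excitatory"),
        "voluntary_preparation": InputAttributes(
            delay,
            preparation_ror(v("voluntary_preparation_max"), delay, params,
                            timeline),
            v("voluntary_preparation_max"), (-ecc, ecc), "excitatory"),
        "inhibitory_gate": InputAttributes(
            delay, v("inhibitory_gate_ror"), v("inhibitory_gate_max"),
            (goal,), "inhibitory"),
        "peripheral_inhibition": InputAttributes(
            delay, v("peripheral_inhibition_ror"),
            v("peripheral_inhibition_max"), (0.0,), "inhibitory"),
    }


def enumerate_grid(tasks: Sequence[str] = TASKS,
                   side: str = "right") -> List[TrialSettings]:
    """The full factorial grid: 3^10 unique level tuples per task, in
    deterministic lexicographic order (pro block first).

    The stimulus side is fixed (mirror symmetry of the field makes the
    opposite-side grid redundant; run it explicitly as a symmetry check).
    """
    grid: List[TrialSettings] = []
    for task in tasks:
        for combo in itertools.product(LEVELS, repeat=len(VARIED_ATTRIBUTES)):
            grid.append(TrialSettings(task=task, stimulus_side=side,
                                      levels=combo))
    return grid


def grid_frame(grid: Iterable[TrialSettings]) -> pd.DataFrame:
    """Tabular view of a settings grid: trial_id, task, side, level labels
    and resolved numeric values."""
    grid = list(grid)
    data: Dict[str, list] = {
        "trial_id": list(range(len(grid))),
        "task": [s.task for s in grid],
        "stimulus_side": [s.stimulus_side for s in grid],
    }
    for k, attr in enumerate(VARIED_ATTRIBUTES):
        data[attr] = [s.levels[k] for s in grid]
    for attr in VARIED_ATTRIBUTES:
        data[attr + "_value"] = [s.value(attr) for s in grid]
    return pd.DataFrame(data)


__all__ = [
    "STIMULUS_ECCENTRICITY_MM", "LEVELS", "VARIED_ATTRIBUTES", "LEVEL_VALUES",
    "TASKS", "SIDES", "TrialSettings", "level_value", "preparation_ror",
    "resolve_settings", "enumerate_grid", "grid_frame",
]
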