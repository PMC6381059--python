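"""Post-hoc manipulations of the baseline experiment.

1. Input ablation: an input's RoR is forced to zero for every trial, so it
   never leaves its initial state (identically zero for inputs that rise
   from zero; frozen for fixation/inhibition inputs that start non-zero).
2. Intentional-state filtering: pure post-selection of trials emulating a
   task-dependent bias — pro trials with large fixation/inhibition MaxVals
   and anti trials with small ones are removed; no simulated outcome changes.
3. Voluntary-to-automated inhibitory crosstalk (an engine option), assessed
   through the early/late regular-error ratio.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Tuple

import pandas as pd

from .engine import RunOptions
from .inputs import INPUT_NAMES

#: the fixation/inhibition inputs whose MaxVal defines the intentional state
INTENTIONAL_STATE_INPUTS = (
    "voluntary_fixation", "inhibitory_gate", "peripheral_inhibition",
)

EARLY_WINDOW = (140.0, 199.0)
LATE_WINDOW = (200.0, 259.0)


def ablate(options: RunOptions, input_name: str) -> RunOptions:
    """Return run options with the named input's RoR forced to zero."""
    if input_name not in INPUT_NAMES:
        raise KeyError(f"unknown input {input_name!r}")
    return replace(options, ablations=options.ablations | {input_name})


def with_crosstalk(options: RunOptions, fraction: float = 0.25) -> RunOptions:
    """Return run options with the inhibitory crosstalk enabled."""
    return replace(options, crosstalk_enabled=True,
                   crosstalk_fraction=fraction)


def intentional_state_filter(records: pd.DataFrame, mode: str,
                             combine: str = "any") -> pd.DataFrame:
    """Drop trials incompatible with a task-specific intentional state.

    ``mode`` is ``"off"``, one of :data:`INTENTIONAL_STATE_INPUTS` (filter on
    that input's MaxVal level only), or ``"combined"``.  For the combined
    filter, ``combine="any"`` drops a pro trial if *any* of the three MaxVals
    is large (and an anti trial if any is small); ``combine="all"`` requires
    all three.
    """
    if mode == "off":
        return records
    if mode == "combined":
        names = INTENTIONAL_STATE_INPUTS
    elif mode in INTENTIONAL_STATE_INPUTS:
        names = (mode,)
    else:
        raise KeyError(f"unknown intentional-state mode {mode!r}")
    if combine not in ("any", "all"):
        raise ValueError("combine must be 'any' or 'all'")
    cols = [name + "_max" for name in names]
    pro_large = records[cols].eq("large")
    anti_small = records[cols].eq("small")
    if combine == "any":
        drop_pro = pro_large.any(axis=1)
        drop_anti = anti_small.any(axis=1)
    else:
        drop_pro = pro_large.all(axis=1)
        drop_anti = anti_small.all(axis=1)
    is_pro = records["task"] == "pro"
    keep = ~((is_pro & drop_pro) | (~is_pro & drop_anti))
    survivors = records[keep]
    if survivors.empty:
        raise ValueError("intentional-state filter removed every trial")
    return survivors


def early_late_ratio(records: pd.DataFrame,
                     early: Tuple[float, float] = EARLY_WINDOW,
                     late: Tuple[float, float] = LATE_WINDOW
                     ) -> Optional[float]:
    """Count ratio of early to late regular-latency direction errors
    (windows inclusive at both ends); None if the late window is empty."""
    err = records[(records["task"] == "anti")
                  & (records["saccade_type"] == "regular_error")]
    srt = err["srt"]
    n_early = int(srt.between(*early).sum())
    n_late = int(srt.between(*late).sum())
    if n_late == 0:
        return None
    return n_early / n_late


__all__ = [
    "INTENTIONAL_STATE_INPUTS", "EARLY_WINDOW", "LATE_WINDOW",
    "ablate", "with_crosstalk", "intentional_state_filter",
    "early_late_ratio",
]
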