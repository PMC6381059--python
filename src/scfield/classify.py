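"""Five-type saccade classification.

Saccades are labelled by task, direction relative to the stimulus, and
latency window: anticipatory (< 90 ms), express ([90, 138] ms, inclusive at
both edges) or regular.  Correct anti-saccades are not split by latency.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .params import ClassificationWindows

SACCADE_TYPES = (
    "regular_pro", "express_pro", "correct_anti", "regular_error",
    "express_error",
)
#: outcomes outside the five-type taxonomy
EXTRA_TYPES = ("anticipatory", "pro_error", "no_response")

PRO_TYPES = ("regular_pro", "express_pro")
ANTI_TYPES = ("correct_anti", "regular_error", "express_error")


def classify(task: str, stimulus_side: str, direction: str, srt: float,
             windows: Optional[ClassificationWindows] = None) -> str:
    """Map (task, stimulus side, saccade direction, SRT) to a saccade type.

    Pro-task saccades away from the stimulus (which the baseline model never
    produces) are labelled ``pro_error`` and excluded from the five-type
    tables.
    """
    if windows is None:
        windows = ClassificationWindows()
    if srt is None or (isinstance(srt, float) and np.isnan(srt)):
        raise ValueError("classify requires a set SRT (use no_response "
                         "for trials without a saccade)")
    if direction not in ("left", "right"):
        raise ValueError(f"invalid direction {direction!r}")
    if srt < windows.anticipatory_max:
        return "anticipatory"
    toward = direction == stimulus_side
    express = windows.express_lo <= srt <= windows.express_hi
    if task == "pro":
        if not toward:
            return "pro_error"
        return "express_pro" if express else "regular_pro"
    if task == "anti":
        if toward:
            return "express_error" if express else "regular_error"
        return "correct_anti"
    raise ValueError(f"unknown task {task!r}")


def classify_frame(records: pd.DataFrame,
                   windows: Optional[ClassificationWindows] = None
                   ) -> pd.Series:
    """Vectorized classification of a records table with columns
    ``task``, ``stimulus_side``, ``direction``, ``srt``."""
    if windows is None:
        windows = ClassificationWindows()
    srt = records["srt"].to_numpy(dtype=float)
    task = records["task"].to_numpy()
    toward = (records["direction"] == records["stimulus_side"]).to_numpy()
    has_saccade = records["direction"].isin(["left", "right"]).to_numpy()

    out = np.full(len(records), "no_response", dtype=object)
    express = (windows.express_lo <= srt) & (srt <= windows.express_hi)
    anticipatory = srt < windows.anticipatory_max
    pro = task == "pro"

    out[has_saccade & anticipatory] = "anticipatory"
    regular = has_saccade & ~anticipatory
    out[regular & pro & toward & express] = "express_pro"
    out[regular & pro & toward & ~express] = "regular_pro"
    out[regular & pro & ~toward] = "pro_error"
    out[regular & ~pro & toward & express] = "express_error"
    out[regular & ~pro & toward & ~express] = "regular_error"
    out[regular & ~pro & ~toward] = "correct_anti"
    return pd.Series(out, index=records.index, name="saccade_type")


__all__ = ["SACCADE_TYPES", "EXTRA_TYPES", "PRO_TYPES", "ANTI_TYPES",
           "classify", "classify_frame"]
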