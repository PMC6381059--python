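"""Published human reference behavior (74 healthy adults, ages 18-39,
gap pro-/anti-saccade tasks; population summary statistics).

Shipped as read-only constants for side-by-side reporting against the model;
the raw human trials are not available, so no inferential statistics are
computed on them.
"""

from __future__ import annotations

import pandas as pd

from .analysis import summarize

#: population summary per saccade type
HUMAN_REFERENCE = pd.DataFrame(
    {
        "total_count": [4502, 818, 8171, 390, 259],
        "mean_count": [61.7, 11.2, 110.4, 5.3, 3.5],
        "percent": [86.6, 13.4, 92.3, 4.7, 3.0],
        "median_srt": [206.3, 120.0, 253.6, 212.9, 117.6],
        "mean_srt": [213.8, 119.3, 259.9, 226.7, 117.4],
        "std_srt": [42.0, 10.7, 50.1, 63.6, 10.0],
    },
    index=pd.Index(["regular_pro", "express_pro", "correct_anti",
                    "regular_error", "express_error"], name="saccade_type"),
)

#: mean human Voluntary Override Time, ms
HUMAN_OVERRIDE_TIME_MS = 168.0


def compare_to_human(model_summary: pd.DataFrame,
                     human: pd.DataFrame = HUMAN_REFERENCE) -> pd.DataFrame:
    """Side-by-side model vs. human table with differences
    (model - human) for the shared statistics."""
    cols = ["percent", "median_srt", "mean_srt", "std_srt"]
    out = {}
    for c in cols:
        out[f"model_{c}"] = model_summary[c]
        out[f"human_{c}"] = human[c]
        out[f"delta_{c}"] = model_summary[c] - human[c]
    return pd.DataFrame(out, index=human.index)


def compare_records_to_human(records: pd.DataFrame) -> pd.DataFrame:
    """Convenience wrapper: summarize the records, then compare."""
    return compare_to_human(summarize(records))


__all__ = ["HUMAN_REFERENCE", "HUMAN_OVERRIDE_TIME_MS", "compare_to_human",
           "compare_records_to_human"]
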