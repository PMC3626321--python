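"""Per-object confusion tallies, sensitivity and specificity.

The unit of evaluation is the aortic object per slice; ascending and
descending cross-sections are counted separately.  "Positive" means the
system flagged a disease candidate.  Summary figures are reported to 4
decimal places using round-half-even.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Mapping

import pandas as pd

from .types import ConfusionCounts

__all__ = [
    "PRED_CANDIDATE",
    "PRED_HEALTHY",
    "TRUTH_DISEASED",
    "TRUTH_HEALTHY",
    "tally",
    "sensitivity",
    "specificity",
    "round4",
    "summary_table",
    "write_summary_csv",
]

PRED_CANDIDATE = "candidate"
PRED_HEALTHY = "healthy"
TRUTH_DISEASED = "diseased"
TRUTH_HEALTHY = "healthy"


def tally(decisions: Iterable[tuple[str, str]]) -> ConfusionCounts:
    """Count (predicted, truth) label pairs into a confusion tally.

    A true positive is a diseased object flagged as a candidate; a true
    negative is a healthy object labeled healthy, and so on.

    Raises
    ------
    ValueError
        On any label outside {candidate, healthy} x {diseased, healthy}.
    """
    tp = fp = tn = fn = 0
    for pred, truth in decisions:
        if pred not in (PRED_CANDIDATE, PRED_HEALTHY):
            raise ValueError(f"unknown predicted label {pred!r}")
        if truth not in (TRUTH_DISEASED, TRUTH_HEALTHY):
            raise ValueError(f"unknown truth label {truth!r}")
        if pred == PRED_CANDIDATE:
            if truth == TRUTH_DISEASED:
                tp += 1
            else:
                fp += 1
        else:
            if truth == TRUTH_DISEASED:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when no diseased objects exist."""
    if c.tp + c.fn == 0:
        return math.nan
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when no healthy objects exist."""
    if c.tn + c.fp == 0:
        return math.nan
    return c.tn / (c.tn + c.fp)


def round4(x: float) -> float:
    """Round to 4 decimals with round-half-even, as printed in summaries."""
    if math.isnan(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_EVEN))


def summary_table(by_region: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Confusion counts per region plus an all-aorta row summing them."""
    total = ConfusionCounts()
    rows = []
    for region, c in by_region.items():
        total = total + c
        rows.append({"data_type": region, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn})
    rows.insert(0, {"data_type": "all", "tp": total.tp, "fp": total.fp,
                    "tn": total.tn, "fn": total.fn})
    return pd.DataFrame(rows)


def write_summary_csv(by_region: Mapping[str, ConfusionCounts], path) -> None:
    """Write the per-region count table with a sensitivity/specificity footer."""
    frame = summary_table(by_region)
    total = ConfusionCounts(
        tp=int(frame.iloc[0]["tp"]), fp=int(frame.iloc[0]["fp"]),
        tn=int(frame.iloc[0]["tn"]), fn=int(frame.iloc[0]["fn"]),
    )
    with open(path, "w") as fh:
        frame.to_csv(fh, index=False)
        fh.write(f"sensitivity,{round4(sensitivity(total))}\n")
        fh.write(f"specificity,{round4(specificity(total))}\n")
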