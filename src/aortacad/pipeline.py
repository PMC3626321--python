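"""End-to-end wiring of segmentation, shape and PAU analysis.

Produces one report row per (slice, vessel): anatomy label, circle
score and shape decision, PAU candidate count and peak HU.  Everything
is deterministic — identical inputs and configuration give identical
reports.
"""

from __future__ import annotations

import logging
import math
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .circle import PairTolerances, circle_score
from .gradients import sobel_field
from .pau import detect_pau
from .segmentation import SeedPoint, segment_series
from .types import CTSlice, HURange

__all__ = ["analyze_series", "confusion_from_report"]

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "slice_index", "anatomy", "linked", "n_pixels", "circle_score",
    "shape_label", "pau_count", "peak_hu",
]


def analyze_series(
    slices: Sequence[CTSlice],
    config: dict[str, Any],
    seeds: Sequence[SeedPoint],
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Run both diagnostic pipelines over a slice series.

    Returns the per-slice report and, for overlay rendering, a map of
    slice index to the mask of pixels flagged on that slice (flagged
    object boundaries and PAU candidate pixels).
    """
    hu_range = HURange(*config["hu_range"])
    tol = PairTolerances(
        angle_tol_deg=config["angle_tol_deg"], line_tol_px=config["line_tol_px"]
    )
    threshold = float(config["circle_threshold"])
    log.info(
        "pipeline config: hu_range=%s threshold=%.2f tol=(%.1f deg, %.1f px) "
        "min_component=%d continuity=%.1f pau_min=%d",
        config["hu_range"], threshold, tol.angle_tol_deg, tol.line_tol_px,
        config["min_component_px"], config["continuity_limit_px"], config["pau_min_px"],
    )

    tracks = segment_series(
        slices, hu_range, seeds,
        min_size=config["min_component_px"],
        continuity_limit=config["continuity_limit_px"],
    )
    by_index = {ct.slice_index: ct for ct in slices}
    fields = {ct.slice_index: sobel_field(ct) for ct in slices}

    rows = []
    highlights: dict[int, np.ndarray] = {}
    for track in tracks:
        for idx in sorted(set(track.objects) | set(track.gaps)):
            ct = by_index[idx]
            obj = track.objects.get(idx)
            if obj is None:
                rows.append(dict(zip(REPORT_COLUMNS, [
                    idx, track.anatomy_label, False, 0, math.nan, "gap", 0, math.nan,
                ])))
                continue
            if len(obj.boundary) >= 8:
                score = circle_score(obj, fields[idx], tol)
                shape_label = (
                    evaluation.PRED_HEALTHY if score >= threshold
                    else evaluation.PRED_CANDIDATE
                )
            else:
                score, shape_label = math.nan, "degenerate"
            candidates = detect_pau(ct, obj, hu_range, min_size=config["pau_min_px"])
            peak = max((c.peak_hu for c in candidates), default=math.nan)
            rows.append(dict(zip(REPORT_COLUMNS, [
                idx, track.anatomy_label, True, obj.n_pixels, score,
                shape_label, len(candidates), peak,
            ])))
            if shape_label == evaluation.PRED_CANDIDATE or candidates:
                mark = highlights.setdefault(idx, np.zeros(ct.shape, dtype=bool))
                if shape_label == evaluation.PRED_CANDIDATE:
                    for r, c in obj.boundary:
                        mark[r, c] = True
                for cand in candidates:
                    for r, c in cand.pixel_coords:
                        mark[r, c] = True
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = report.sort_values(["slice_index", "anatomy"]).reset_index(drop=True)
    log.info(
        "report: %d rows, %d shape candidates, %d slices with PAU candidates",
        len(report),
        int((report["shape_label"] == evaluation.PRED_CANDIDATE).sum()),
        int((report["pau_count"] > 0).sum()),
    )
    return report, highlights


def confusion_from_report(
    report: pd.DataFrame,
    truth: pd.DataFrame,
    task: str,
) -> dict[str, "evaluation.ConfusionCounts"]:
    """Join report rows with truth labels and tally per anatomy region.

    ``truth`` needs columns ``slice_index`` and, per task,
    ``shape_truth`` or ``pau_truth`` holding healthy/diseased; an
    optional ``anatomy`` column restricts rows to one vessel.
    """
    if task not in ("dissection", "pau"):
        raise ValueError(f"task must be dissection/pau, got {task!r}")
    truth_col = "shape_truth" if task == "dissection" else "pau_truth"
    keys = ["slice_index", "anatomy"] if "anatomy" in truth.columns else ["slice_index"]
    merged = report[report["linked"]].merge(truth, on=keys, how="inner")
    by_region = {}
    for region, grp in merged.groupby("anatomy"):
        if task == "dissection":
            pred = grp["shape_label"]
        else:
            pred = np.where(
                grp["pau_count"] > 0, evaluation.PRED_CANDIDATE, evaluation.PRED_HEALTHY
            )
        by_region[str(region)] = evaluation.tally(list(zip(pred, grp[truth_col])))
    return by_region
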