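"""Overlap metrics (DSC, IoU), cohort reports, paired test and tear-size ANOVA.

For one class in one case the confusion counts are the voxel tallies

    TP = |truth ∩ prediction|,  FP = |prediction \\ truth|,  FN = |truth \\ prediction|

from which DSC = 2TP/(2TP+FP+FN) and IoU = TP/(TP+FP+FN); algebraically
IoU = DSC/(2−DSC).  A class absent from both maps scores 1.0 by convention
(a correctly absent class should not poison a case mean); this is
configurable via ``empty_value``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "dsc",
    "iou",
    "cohort_report",
    "paired_test",
    "anova_by_group",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN voxel counts for one class in one case (TN is never needed)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(truth, predicted, class_id: int) -> ConfusionCounts:
    """Exact voxelwise TP/FP/FN tallies for one class."""
    t = np.asarray(truth.labels if hasattr(truth, "labels") else truth)
    p = np.asarray(predicted.labels if hasattr(predicted, "labels") else predicted)
    if t.shape != p.shape:
        raise ValueError(f"grid mismatch: truth {t.shape} vs predicted {p.shape}")
    tm, pm = t == class_id, p == class_id
    tp = int(np.count_nonzero(tm & pm))
    return ConfusionCounts(
        tp=tp,
        fp=int(np.count_nonzero(pm)) - tp,
        fn=int(np.count_nonzero(tm)) - tp,
    )


def dsc(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return 2.0 * c.tp / denom


def iou(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Intersection over union TP/(TP+FP+FN)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return c.tp / denom


@dataclass
class MetricsReport:
    """Per-case per-class DSC/IoU plus cohort summaries (mean ± sample SD)."""

    per_case: pd.DataFrame  # columns: case_id, class_id, class_name, dsc, iou
    summary: pd.DataFrame  # index: class names + "overall"; columns: dsc_mean, dsc_sd, iou_mean, iou_sd

    def to_csv(self, per_case_path, summary_path) -> None:
        self.per_case.to_csv(per_case_path, index=False)
        self.summary.to_csv(summary_path)


def cohort_report(case_ids, truths, predictions, class_names: dict) -> MetricsReport:
    """Tabulate DSC/IoU per (case, foreground class) and summarize the cohort.

    ``class_names`` maps class index -> name; background (0) is excluded.
    The "overall" row is the mean over the per-class means, with the SD of
    the per-class means alongside.
    """
    if not (len(case_ids) == len(truths) == len(predictions)):
        raise ValueError("case_ids, truths and predictions must be aligned lists")
    rows = []
    for cid, t, p in zip(case_ids, truths, predictions):
        for k, name in class_names.items():
            if k == 0:
                continue
            c = confusion_counts(t, p, k)
            rows.append(
                {"case_id": cid, "class_id": k, "class_name": name,
                 "dsc": dsc(c), "iou": iou(c)}
            )
    per_case = pd.DataFrame(rows)

    grp = per_case.groupby("class_name", sort=False)
    summary = pd.DataFrame(
        {
            "dsc_mean": grp["dsc"].mean(),
            "dsc_sd": grp["dsc"].std(ddof=1),
            "iou_mean": grp["iou"].mean(),
            "iou_sd": grp["iou"].std(ddof=1),
        }
    )
    summary.loc["overall"] = [
        summary["dsc_mean"].mean(),
        summary["dsc_mean"].std(ddof=1),
        summary["iou_mean"].mean(),
        summary["iou_mean"].std(ddof=1),
    ]
    return MetricsReport(per_case=per_case, summary=summary)


def paired_test(metric_a, metric_b):
    """Two-sided paired t-test on per-case metric differences.

    Returns ``(t, p)``.  Raises on zero-variance differences (including the
    identical-vectors case), where the statistic is undefined.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D vectors with >= 2 entries")
    diff = a - b
    if np.std(diff, ddof=1) == 0.0:
        raise ValueError("degenerate input: differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def anova_by_group(values, groups):
    """Classical one-way ANOVA of a per-case metric across (tear-size) groups.

    Returns ``(F, p)``.  Raises when fewer than two groups are present or the
    within-group variance is zero (F undefined).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must be aligned")
    keys = pd.unique(groups)
    if len(keys) < 2:
        raise ValueError("need at least two groups for ANOVA")
    samples = [values[groups == k] for k in keys]
    if len(values) <= len(keys):
        raise ValueError("need more observations than groups")
    within_ss = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if within_ss == 0.0:
        raise ValueError("degenerate input: zero within-group variance")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)
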