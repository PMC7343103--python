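"""Diagnostic performance: confusion matrix, sensitivity/specificity,
arm comparison t-test, threshold sweep, and the pre-/post-exclusion
re-analysis of a cohort.

Cancer is the positive class throughout.  The threshold sweep is a
calibration on the data in hand (Youden index), not validated
inference: with 8 + 8 samples no confidence intervals or resampling are
attempted, mirroring the pilot-study character of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .mdv import EXCLUDED, MDVConfig, MDVResult, classify, compute_mdv
from .processing import DEFAULT_DEAD_THRESHOLD, process_sample

__all__ = [
    "ConfusionMatrix",
    "SweepResult",
    "DiagnosticReport",
    "confusion_matrix",
    "sensitivity",
    "specificity",
    "two_tailed_t_test",
    "threshold_sweep",
    "run_full_analysis",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with cancer as the positive class."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_matrix(results: Sequence[MDVResult]) -> ConfusionMatrix:
    """Tally predictions against true arm labels.

    Excluded samples never enter the matrix (they are reported
    separately as ``n_excluded``).
    """
    tp = fn = tn = fp = 0
    for r in results:
        if r.excluded or r.predicted == EXCLUDED:
            continue
        if r.arm is None:
            raise ValueError(f"sample {r.sample_id}: true arm label missing")
        if r.arm == "cancer":
            if r.predicted == "cancer":
                tp += 1
            else:
                fn += 1
        elif r.arm == "control":
            if r.predicted == "control":
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(f"sample {r.sample_id}: unknown arm {r.arm!r}")
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no negative samples")
    return cm.tn / (cm.tn + cm.fp)


def two_tailed_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "pooled",
) -> tuple[float, float]:
    """Two-sample t-test between the arms' MDVs.

    ``variant='pooled'`` is the classical Student test (equal variances
    assumed); ``'welch'`` drops that assumption.  Degenerate input with
    zero pooled variance and equal means returns ``(0.0, 1.0)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p)


@dataclass
class SweepResult:
    """Threshold sweep table with the Youden-optimal operating point.

    ``best_interval`` is the span of candidate thresholds tying for the
    maximal Youden index; ``best_threshold`` is its midpoint.
    """

    table: pd.DataFrame
    best_threshold: float
    best_interval: tuple[float, float]
    best_sensitivity: float
    best_specificity: float
    best_youden: float


def threshold_sweep(
    results: Sequence[MDVResult],
    thresholds: Optional[Sequence[float]] = None,
) -> SweepResult:
    """Sensitivity/specificity at every candidate threshold.

    Every threshold inside one gap between consecutive sorted MDVs
    produces the same confusion matrix, so the candidate thresholds
    default to the gap midpoints (plus one point outside each extreme),
    covering every distinct operating point the rule can produce.  The
    optimum maximises the Youden index (sensitivity + specificity - 1);
    the reported interval is the full data gap containing the optimal
    candidate (the range of thresholds attaining it) and the chosen
    threshold is its midpoint.  Should several disjoint gaps tie, the
    lowest-threshold gap wins.
    """
    included = [r for r in results if not r.excluded]
    mdvs_cancer = np.array([r.mdv for r in included if r.arm == "cancer"])
    mdvs_control = np.array([r.mdv for r in included if r.arm == "control"])
    if mdvs_cancer.size == 0:
        raise ValueError("sensitivity undefined: no included cancer samples")
    if mdvs_control.size == 0:
        raise ValueError("specificity undefined: no included control samples")

    all_mdv = np.sort(np.concatenate([mdvs_cancer, mdvs_control]))
    span = max(all_mdv[-1] - all_mdv[0], 1.0)
    if thresholds is None:
        bounds_lo = np.concatenate([[all_mdv[0] - 0.1 * span], all_mdv])
        bounds_hi = np.concatenate([all_mdv, [all_mdv[-1] + 0.1 * span]])
        thresholds = (bounds_lo + bounds_hi) / 2.0
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        bounds_lo = bounds_hi = None

    rows = []
    for thr in thresholds:
        sens = float((mdvs_cancer < thr).mean())
        spec = float((mdvs_control >= thr).mean())
        rows.append((float(thr), sens, spec, sens + spec - 1.0))
    table = pd.DataFrame(
        rows, columns=["threshold", "sensitivity", "specificity", "youden"]
    )

    youden = table["youden"].to_numpy()
    i_best = int(np.argmax(youden))
    if bounds_lo is not None:
        interval = (float(bounds_lo[i_best]), float(bounds_hi[i_best]))
    else:
        interval = (float(thresholds[i_best]), float(thresholds[i_best]))
    best_thr = 0.5 * (interval[0] + interval[1])
    return SweepResult(
        table=table,
        best_threshold=best_thr,
        best_interval=interval,
        best_sensitivity=float(table["sensitivity"].iloc[i_best]),
        best_specificity=float(table["specificity"].iloc[i_best]),
        best_youden=float(youden[i_best]),
    )


@dataclass
class DiagnosticReport:
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    t_statistic: float
    p_value: float
    n_excluded: int
    threshold_used: float
    sweep: SweepResult
    results: list[MDVResult] = field(default_factory=list)

    def summary(self) -> dict:
        cm = self.confusion
        return {
            "n_samples": cm.n + self.n_excluded,
            "n_excluded": self.n_excluded,
            "tp": cm.tp,
            "fn": cm.fn,
            "tn": cm.tn,
            "fp": cm.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "threshold_used": self.threshold_used,
            "optimal_threshold_interval": list(self.sweep.best_interval),
        }


def _report(
    results: list[MDVResult], config: MDVConfig, threshold: Optional[float]
) -> DiagnosticReport:
    sweep = threshold_sweep(results)
    thr = sweep.best_threshold if threshold is None else threshold
    cfg = MDVConfig(
        n_low=config.n_low,
        n_high=config.n_high,
        threshold=thr,
        sd_min=config.sd_min,
        band_mode=config.band_mode,
        sign=config.sign,
    )
    classified = [classify(r, cfg) for r in results]
    cm = confusion_matrix(classified)
    mdv_cancer = [r.mdv for r in classified if not r.excluded and r.arm == "cancer"]
    mdv_control = [r.mdv for r in classified if not r.excluded and r.arm == "control"]
    t, p = two_tailed_t_test(mdv_cancer, mdv_control)
    return DiagnosticReport(
        confusion=cm,
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        t_statistic=t,
        p_value=p,
        n_excluded=sum(r.excluded for r in classified),
        threshold_used=thr,
        sweep=sweep,
        results=classified,
    )


def run_full_analysis(
    dataset: CohortDataset,
    config: MDVConfig = MDVConfig(),
    dead_threshold: float = DEFAULT_DEAD_THRESHOLD,
    calibrate: bool = True,
) -> tuple[DiagnosticReport, DiagnosticReport]:
    """Process, score and classify a cohort twice: exclusion off and on.

    With ``calibrate`` (default) the classification threshold is the
    Youden optimum of the *unfiltered* analysis and the same threshold
    is reused for the filtered re-analysis, so the two reports differ
    only in which samples enter the statistics.  With
    ``calibrate=False`` the ``config.threshold`` value is used as-is.
    Deterministic given the dataset.
    """
    processed = [process_sample(rec, dead_threshold) for rec in dataset.samples]
    unfiltered_results = [
        compute_mdv(s, config, apply_exclusion=False, allow_overlap=True)
        for s in processed
    ]
    filtered_results = [
        compute_mdv(s, config, apply_exclusion=True, allow_overlap=True)
        for s in processed
    ]

    threshold = None if calibrate else config.threshold
    report_unfiltered = _report(unfiltered_results, config, threshold)
    thr = report_unfiltered.threshold_used if calibrate else config.threshold
    report_filtered = _report(filtered_results, config, thr)
    return report_unfiltered, report_filtered
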