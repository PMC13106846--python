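"""Cohort comparison, heart-rate-band sweeps and diagnostic test metrics.

Per-subject corrected-complexity scores are compared between cases and
controls with Welch's unequal-variance t-test, and separability is summarised
by a rank-based AUC oriented so that *lower* scores indicate a case (the
direction observed in the study population: corrected complexity is reduced
in affected subjects).  The band sweep re-runs the whole extraction +
correction pipeline per heart-rate band and summarises the 63 FD masks by
median/minimum p and median/maximum AUC.  No multiple-testing correction is
applied across masks -- the sweep is exploratory and reports raw p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import EcgError, InsufficientDataError, ParameterError, UndefinedMetricError

__all__ = [
    "GroupComparison",
    "SweepResult",
    "DiagnosticMetrics",
    "welch_t_test",
    "roc_auc",
    "compare_groups",
    "hr_range_sweep",
    "rank_algorithms",
    "diagnostic_metrics",
    "confusion_from_rates",
    "classify_threshold",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GroupComparison:
    """Case/control comparison of one estimator x mask x band combination."""

    estimator: str
    mask: int
    hr_band: tuple
    n_cases: int
    n_controls: int
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    t: float
    df: float
    p: float
    auc: float
    scheme: str = "FD"


@dataclass
class SweepResult:
    """Per-cell mask-aggregated statistics of a heart-rate-band sweep.

    ``cells`` maps ``(hr_lo, hr_hi)`` to ``{estimator: stats_dict}``; cells
    whose pipeline left a class empty are marked missing (None), never
    fabricated.
    """

    cells: dict = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lo, hi), per_est in self.cells.items():
            for est, stats_ in per_est.items():
                row = {"hr_lo": lo, "hr_hi": hi, "estimator": est}
                row.update(stats_ if stats_ is not None
                           else dict.fromkeys(("median_p", "min_p", "median_auc", "max_auc")))
                rows.append(row)
        return pd.DataFrame(rows)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t-test: returns (t, Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Welch's t-test needs >= 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise UndefinedMetricError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC with cases-score-lower orientation.

    ``AUC = P(control score > case score) + 0.5 P(tie)``, identical to the
    Mann-Whitney U statistic divided by ``n_case * n_control``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == "case"
    is_control = labels == "control"
    n_case, n_control = int(is_case.sum()), int(is_control.sum())
    if n_case == 0 or n_control == 0:
        raise ParameterError("ROC analysis needs both classes present (one class empty)")
    ranks = stats.rankdata(scores)
    u_control = float(ranks[is_control].sum()) - n_control * (n_control + 1) / 2.0
    return u_control / (n_case * n_control)


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        return scores
    return pd.DataFrame([vars(s) for s in scores])


def compare_groups(
    scores,
    estimator: str = "",
    mask: int = 0,
    band: tuple = (float("nan"), float("nan")),
    scheme: str = "FD",
) -> GroupComparison:
    """Bundle Welch's t-test and the oriented AUC on per-subject scores."""
    frame = _scores_frame(scores)
    case = frame.loc[frame["label"] == "case", "score"].to_numpy(float)
    control = frame.loc[frame["label"] == "control", "score"].to_numpy(float)
    if len(case) < 2 or len(control) < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects per class, got {len(case)} cases / {len(control)} controls"
        )
    t, df, p = welch_t_test(case, control)
    auc = roc_auc(frame["score"].to_numpy(float), frame["label"].to_numpy())
    return GroupComparison(
        estimator=estimator, mask=mask, hr_band=tuple(band),
        n_cases=len(case), n_controls=len(control),
        mean_case=float(case.mean()), sd_case=float(case.std(ddof=1)),
        mean_control=float(control.mean()), sd_control=float(control.std(ddof=1)),
        t=t, df=df, p=p, auc=auc, scheme=scheme,
    )


def hr_range_sweep(
    recordings,
    lo_values,
    hi_values,
    estimators=("LZ76",),
    masks=None,
    **pipeline_kwargs,
) -> SweepResult:
    """Re-run extraction, correction and comparison per heart-rate band.

    For every ``(lo, hi)`` cell with ``lo < hi``, strips are re-extracted in
    that band, complexity recomputed, heart-rate-corrected, scored per
    subject and compared per mask; the cell stores the median/minimum p and
    median/maximum AUC across masks for each estimator.
    """
    from .pipeline import analyze_cohort  # local import to avoid a cycle

    lo_values = list(lo_values)
    hi_values = list(hi_values)
    if not lo_values or not hi_values:
        raise ParameterError("sweep grids must be non-empty")
    result = SweepResult()
    all_comparisons = []
    for lo in lo_values:
        for hi in hi_values:
            if lo >= hi:
                continue
            try:
                res = analyze_cohort(
                    recordings, hr_band=(lo, hi), estimators=estimators,
                    masks=masks, include_tc=False, **pipeline_kwargs,
                )
                comparisons = res.comparisons
            except EcgError as exc:
                logger.warning("sweep cell (%g, %g) missing: %s", lo, hi, exc)
                result.cells[(lo, hi)] = {est: None for est in estimators}
                continue
            cell = {}
            for est in estimators:
                sub = comparisons[comparisons["estimator"] == est]
                if sub.empty:
                    cell[est] = None
                    continue
                cell[est] = {
                    "median_p": float(sub["p"].median()),
                    "min_p": float(sub["p"].min()),
                    "median_auc": float(sub["auc"].median()),
                    "max_auc": float(sub["auc"].max()),
                }
            result.cells[(lo, hi)] = cell
            all_comparisons.append(comparisons)
    if all_comparisons:
        result.comparisons = pd.concat(all_comparisons, ignore_index=True)
    return result


def rank_algorithms(comparisons) -> pd.DataFrame:
    """Order estimator x mask combinations by ascending p, then descending
    AUC, then ascending mask code (fully deterministic)."""
    if isinstance(comparisons, pd.DataFrame):
        frame = comparisons.copy()
    else:
        frame = pd.DataFrame([vars(c) for c in comparisons])
    if frame.empty:
        raise ParameterError("nothing to rank")
    return frame.sort_values(
        ["p", "auc", "mask"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)


def _wald_ci(p_hat: float, n: int) -> tuple[float, float]:
    half = Z_95 * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half) * 100.0, min(1.0, p_hat + half) * 100.0)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/predictive values (%) with 95% Wald CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None  # None when tp + fp == 0 (undefined)
    npv: float | None
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple | None
    npv_ci: tuple | None
    cui_positive: float | None  # sensitivity x PPV, as fractions
    cui_negative: float | None  # specificity x NPV


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Diagnostic performance from a confusion matrix.

    Proportions are reported in percent with Wald 95% intervals clipped to
    [0, 100]%; the clinical utility indices are products of fractions
    (CUI+ = Se x PPV, CUI- = Sp x NPV).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise ParameterError("need at least one positive and one negative subject")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return DiagnosticMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se * 100.0,
        specificity=sp * 100.0,
        ppv=None if ppv is None else ppv * 100.0,
        npv=None if npv is None else npv * 100.0,
        sensitivity_ci=_wald_ci(se, tp + fn),
        specificity_ci=_wald_ci(sp, tn + fp),
        ppv_ci=None if ppv is None else _wald_ci(ppv, tp + fp),
        npv_ci=None if npv is None else _wald_ci(npv, tn + fn),
        cui_positive=None if ppv is None else se * ppv,
        cui_negative=None if npv is None else sp * npv,
    )


def confusion_from_rates(
    sensitivity_pct: float, n_positive: int, specificity_pct: float, n_negative: int
) -> list[tuple[int, int, int, int]]:
    """All integer confusion matrices (tp, fn, tn, fp) consistent with
    sensitivity/specificity printed to one decimal place at the given class
    sizes.  Brute-force enumeration; the caller decides what to do when the
    reconstruction is not unique."""
    out = []
    for tp in range(n_positive + 1):
        if round(100.0 * tp / n_positive, 1) != round(sensitivity_pct, 1):
            continue
        for tn in range(n_negative + 1):
            if round(100.0 * tn / n_negative, 1) == round(specificity_pct, 1):
                out.append((tp, n_positive - tp, tn, n_negative - tn))
    return out


def classify_threshold(scores, threshold: float) -> tuple[int, int, int, int]:
    """Confusion counts (tp, fp, tn, fn) predicting "case" when score < threshold."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    frame = _scores_frame(scores)
    predicted_case = frame["score"].to_numpy(float) < threshold
    actual_case = frame["label"].to_numpy() == "case"
    tp = int(np.sum(predicted_case & actual_case))
    fp = int(np.sum(predicted_case & ~actual_case))
    tn = int(np.sum(~predicted_case & ~actual_case))
    fn = int(np.sum(~predicted_case & actual_case))
    return tp, fp, tn, fn
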