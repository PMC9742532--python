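"""Classification metrics, curve comparison and the paired-AUC test.

AUC is the Mann–Whitney pair statistic (ties counted one half); auPR is
the step-wise (non-interpolated) summation of precision over recall
increments, whose random-classifier baseline equals the prevalence.
Confidence intervals use a stratified percentile bootstrap. Correlated
AUCs on the same subjects are compared with the DeLong placement-value
covariance estimator.

Strategy-level comparison (:func:`compare_at_matched`) sweeps each
strategy's decision threshold over its observed score distribution, runs
the full screening cascade at every cutpoint, and matches the two
strategies either at equal sensitivity or at equal average detection
cost, reporting the per-participant economics and their relative
reductions at each matched level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .cascade import CascadeSpec, ConfusionCounts, DiagnosticThresholds, run_cascade, tally
from .economics import CostSchedule, complication_cost, detection_cost, proportion_confirmatory

__all__ = [
    "MetricCurve",
    "ComparisonResult",
    "MetricsError",
    "confusion_metrics",
    "roc",
    "pr",
    "bootstrap_ci",
    "delong_test",
    "threshold_for_sensitivity",
    "sweep_thresholds",
    "compare_at_matched",
    "relative_reduction",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMetrics:
    """Exact ratios; a metric whose denominator is zero is None, never 0."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(FP+TN), precision TP/(TP+FP)."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.fp + counts.tn),
        precision=ratio(counts.tp, counts.tp + counts.fp),
    )


@dataclass
class MetricCurve:
    """Operating points of a scored classifier, thresholds descending."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    auc: float
    aupr: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        })


def _check_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricsError("scores and labels must be 1-D and of equal length")
    if not np.all(np.isfinite(scores)):
        raise MetricsError("scores must be finite")
    if labels.all() or not labels.any():
        raise MetricsError("both classes must be present")
    return scores, labels


def _curve(scores: np.ndarray, labels: np.ndarray) -> MetricCurve:
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    tp = tpr * n_pos
    fp = fpr * n_neg
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), np.nan)
    return MetricCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        precision=precision,
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
    )


def roc(scores, labels, n_boot: int | None = None, seed: int = 0) -> MetricCurve:
    """ROC operating points; AUC equals the Mann–Whitney statistic.

    With ``n_boot`` set, 95% stratified-bootstrap CIs for AUC and auPR
    are attached under ``ci95``.
    """
    scores, labels = _check_scores(scores, labels)
    curve = _curve(scores, labels)
    if n_boot:
        curve.ci95["auc"] = bootstrap_ci(
            scores, labels, lambda s, y: roc_auc_score(y, s), B=n_boot, seed=seed)
        curve.ci95["aupr"] = bootstrap_ci(
            scores, labels, lambda s, y: average_precision_score(y, s),
            B=n_boot, seed=seed)
    return curve


def pr(scores, labels, n_boot: int | None = None, seed: int = 0) -> MetricCurve:
    """Precision–recall view of the same operating points."""
    return roc(scores, labels, n_boot=n_boot, seed=seed)


def bootstrap_ci(scores, labels, statistic, B: int = 2000,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI over B stratified resamples of (scores, labels)."""
    if B < 100:
        raise MetricsError("B must be at least 100 for a percentile CI")
    scores, labels = _check_scores(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    stats = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(pos_idx, len(pos_idx), replace=True),
                              rng.choice(neg_idx, len(neg_idx), replace=True)])
        stats[b] = statistic(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (placement values) via midranks."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v01 = (tz[:m] - tx) / n           # per-positive placement
    v10 = 1.0 - (tz[m:] - ty) / m     # per-negative placement
    return auc, v01, v10


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired comparison of two AUCs on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided p from the normal
    approximation; identical (or rank-identical) score vectors give
    z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise MetricsError("paired scores must have identical length")
    _, labels = _check_scores(scores_a, labels)
    auc_a, v01_a, v10_a = _placements(scores_a, labels)
    auc_b, v01_b, v10_b = _placements(scores_b, labels)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0 or np.isclose(auc_a, auc_b, atol=1e-12) and var < 1e-16:
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def threshold_for_sensitivity(scores, labels, target_sens: float) -> float:
    """Largest threshold whose sensitivity reaches the target.

    Positivity is ``score >= threshold``; the largest qualifying
    threshold flags the fewest persons and therefore has the greatest
    specificity among qualifying cutpoints.
    """
    if not 0.0 < target_sens <= 1.0:
        raise MetricsError("target sensitivity must lie in (0, 1]")
    scores, labels = _check_scores(scores, labels)
    pos = np.sort(scores[labels])[::-1]
    candidates = np.unique(scores)[::-1]
    if len(candidates) == 1:
        warnings.warn("all scores identical; returning the single observed score "
                      "(sensitivity 1 at that cutpoint)")
        return float(candidates[0])
    for t in candidates:
        sens = np.mean(pos >= t)
        if sens >= target_sens:
            return float(t)
    return float(candidates[-1])


def _candidate_thresholds(scores: np.ndarray, max_candidates: int = 201) -> np.ndarray:
    """Descending cutpoint grid over the observed scores, plus one above max."""
    uniq = np.unique(scores)
    if len(uniq) > max_candidates:
        qs = np.quantile(uniq, np.linspace(0.0, 1.0, max_candidates))
        uniq = np.unique(np.concatenate([qs, [uniq[0], uniq[-1]]]))
    above = uniq[-1] + max(1.0, abs(uniq[-1]))  # flags nobody
    return np.concatenate([[above], uniq[::-1]])


def sweep_thresholds(pop_test: pd.DataFrame, spec: CascadeSpec,
                     schedule: CostSchedule,
                     horizons: tuple[int, ...] = (15,),
                     thresholds: DiagnosticThresholds | None = None,
                     max_candidates: int = 201) -> pd.DataFrame:
    """Whole-cascade operating curve over the model's decision threshold.

    One row per cutpoint: sensitivity/specificity/precision of the full
    cascade plus the per-participant economics. This is the step curve
    behind matched-sensitivity and matched-cost comparisons.
    """
    scores = np.asarray(spec.model.predict_risk(pop_test), dtype=float)
    rows = []
    for t in _candidate_thresholds(scores, max_candidates):
        s = CascadeSpec(name=spec.name, model=spec.model,
                        screening_lab=spec.screening_lab,
                        decision_threshold=float(t),
                        confirmatory_test=spec.confirmatory_test,
                        target_condition=spec.target_condition)
        records = run_cascade(pop_test, s, thresholds, scores=scores)
        counts = tally(records)
        cm = confusion_metrics(counts)
        row = {
            "strategy": spec.name,
            "threshold": float(t),
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "precision": cm.precision,
            "prop_confirmatory": proportion_confirmatory(records),
            "avg_detection_cost": detection_cost(records, schedule),
            "fn_count": counts.fn,
        }
        for h in horizons:
            lo, hi = complication_cost(records, schedule, h)
            row[f"complication_low_{h}y"] = lo
            row[f"complication_high_{h}y"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Two strategies matched at equal sensitivity or equal detection cost."""

    strategy_a: str
    strategy_b: str
    matched_quantity: str  # "SENSITIVITY" or "DETECTION_COST"
    #: tidy table: one row per (matched value, strategy)
    table: pd.DataFrame
    #: one row per matched value with relative reductions (a - b) / a
    reductions: pd.DataFrame
    curves: dict[str, pd.DataFrame]
    delong: tuple[float, float, float, float] | None = None

    @property
    def delong_p(self) -> float | None:
        return self.delong[3] if self.delong else None


def relative_reduction(a: float, b: float) -> float:
    """(a - b) / a, computed from unrounded values."""
    if a == 0:
        raise MetricsError("relative reduction undefined for a baseline of 0")
    return (a - b) / a


def _pick_row(curve: pd.DataFrame, match: str, value: float) -> pd.Series:
    if match == "SENSITIVITY":
        ok = curve[curve["sensitivity"] >= value - 1e-12]
        if len(ok) == 0:
            raise MetricsError(
                f"sensitivity {value} unattainable; attainable range "
                f"[{curve['sensitivity'].min():.4f}, {curve['sensitivity'].max():.4f}]")
        # fewest positives = largest threshold among qualifying cutpoints
        return ok.sort_values(["threshold"], ascending=False).iloc[0]
    if match == "DETECTION_COST":
        ok = curve[curve["avg_detection_cost"] <= value + 1e-9]
        if len(ok) == 0:
            raise MetricsError(
                f"detection cost {value} unattainable; attainable range "
                f"[{curve['avg_detection_cost'].min():.4f}, "
                f"{curve['avg_detection_cost'].max():.4f}]")
        return ok.sort_values(["sensitivity", "avg_detection_cost"],
                              ascending=[False, True]).iloc[0]
    raise MetricsError(f"unknown matched quantity {match!r}")


def compare_at_matched(pop_test: pd.DataFrame, spec_a: CascadeSpec,
                       spec_b: CascadeSpec, schedule: CostSchedule,
                       match: str = "SENSITIVITY",
                       match_values: np.ndarray | None = None,
                       horizons: tuple[int, ...] = (15,),
                       thresholds: DiagnosticThresholds | None = None) -> ComparisonResult:
    """Match two screening strategies and compare their economics.

    At each matched sensitivity the operating point with the fewest
    screen-positives achieving it is used (matched cost: the most
    sensitive point not exceeding the cost). Reductions are
    ``(a - b) / a`` with strategy *a* as baseline. A DeLong paired-AUC
    test on the two score vectors is attached when both models score the
    same cohort.
    """
    curves = {spec.name: sweep_thresholds(pop_test, spec, schedule, horizons, thresholds)
              for spec in (spec_a, spec_b)}
    ca, cb = curves[spec_a.name], curves[spec_b.name]
    if match_values is None:
        if match == "SENSITIVITY":
            match_values = np.round(np.linspace(0.0, 1.0, 21), 10)[1:]  # 0 is vacuous
        else:
            lo = max(ca["avg_detection_cost"].min(), cb["avg_detection_cost"].min())
            hi = min(ca["avg_detection_cost"].max(), cb["avg_detection_cost"].max())
            match_values = np.linspace(lo, hi, 21)

    rows, reds = [], []
    comp_cols = [c for c in ca.columns if c.startswith("complication_")]
    for v in np.asarray(match_values, dtype=float):
        ra = _pick_row(ca, match, v)
        rb = _pick_row(cb, match, v)
        for r in (ra, rb):
            d = r.to_dict()
            d["matched_value"] = v
            rows.append(d)
        red = {"matched_value": v}
        for colname in ["prop_confirmatory", "avg_detection_cost", *comp_cols]:
            if ra[colname] > 0:
                red[f"reduction_{colname}"] = relative_reduction(ra[colname], rb[colname])
            else:
                red[f"reduction_{colname}"] = np.nan
        reds.append(red)

    delong = None
    try:
        sa = np.asarray(spec_a.model.predict_risk(pop_test), dtype=float)
        sb = np.asarray(spec_b.model.predict_risk(pop_test), dtype=float)
        labels = pop_test["dm_status"].to_numpy(dtype=bool)
        delong = delong_test(sa, sb, labels)
    except (AttributeError, MetricsError, KeyError):
        pass
    return ComparisonResult(
        strategy_a=spec_a.name, strategy_b=spec_b.name, matched_quantity=match,
        table=pd.DataFrame(rows), reductions=pd.DataFrame(reds),
        curves=curves, delong=delong)
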