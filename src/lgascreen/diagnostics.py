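"""Diagnostic-accuracy statistics for the LGA screening pipeline.

Covers the 2x2 machinery (sensitivity/specificity/PPV/NPV with exact
Clopper-Pearson intervals), the Mann-Whitney AUC with midrank tie handling,
logistic combination of a chart flag with HbA1c, and DeLong's nonparametric
comparison of two correlated AUCs via placement values.

For a binary flag the empirical ROC has a single interior vertex, so its
trapezoidal AUC equals (sensitivity + specificity)/2; feeding the bare flag
to :func:`roc_auc` therefore reproduces a chart-alone AUC exactly.

The module also provides :func:`reconstruct_confusion`, which recovers the
unique integer 2x2 table consistent with published margins (cohort size,
number diseased, number flagged) and one or more accuracy metrics printed at
fixed rounding precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "DiagnosticSummary",
    "RocComparison",
    "LogisticModel",
    "DiagnosticsError",
    "SeparationError",
    "confusion_matrix",
    "diagnostic_metrics",
    "roc_auc",
    "auc_with_ci",
    "fit_logistic",
    "delong_compare",
    "reconstruct_confusion",
]


class DiagnosticsError(ValueError):
    pass


class SeparationError(DiagnosticsError):
    """Complete or quasi-complete separation in a logistic fit."""


# ---------------------------------------------------------------------------
# 2x2 counts and accuracy metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise DiagnosticsError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise DiagnosticsError("confusion matrix must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricWithCI:
    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low - 1e-12 <= self.point <= self.ci_high + 1e-12:
            raise DiagnosticsError("CI bounds must bracket the point estimate")

    @property
    def pct(self) -> float:
        return 100.0 * self.point


@dataclass(frozen=True)
class DiagnosticSummary:
    """Accuracy metrics as fractions with CIs; None where the denominator is 0."""

    sensitivity: MetricWithCI | None
    specificity: MetricWithCI | None
    ppv: MetricWithCI | None
    npv: MetricWithCI | None
    auc: MetricWithCI | None = None
    ci_level: float = 0.95


def confusion_matrix(flags, outcomes) -> ConfusionMatrix:
    """Cross-classify boolean screen flags against boolean outcomes."""
    f = np.asarray(flags)
    o = np.asarray(outcomes)
    if f.shape != o.shape or f.ndim != 1 or f.size < 1:
        raise DiagnosticsError("flags and outcomes must be equal-length 1-D arrays")
    for name, arr in (("flags", f), ("outcomes", o)):
        if arr.dtype.kind == "f" and np.isnan(arr).any():
            raise DiagnosticsError(f"{name} contain missing values")
    f = f.astype(bool)
    o = o.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(f & o)), fp=int(np.sum(f & ~o)),
        fn=int(np.sum(~f & o)), tn=int(np.sum(~f & ~o)),
    )


def _proportion_ci(k: int, n: int, ci_level: float) -> MetricWithCI | None:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=1.0 - ci_level, method="beta")
    return MetricWithCI(point=k / n, ci_low=float(lo), ci_high=float(hi))


def diagnostic_metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV with exact Clopper-Pearson CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    if not 0.5 < ci_level < 1.0:
        raise DiagnosticsError(f"ci_level must be in (0.5, 1), got {ci_level}")
    return DiagnosticSummary(
        sensitivity=_proportion_ci(cm.tp, cm.tp + cm.fn, ci_level),
        specificity=_proportion_ci(cm.tn, cm.tn + cm.fp, ci_level),
        ppv=_proportion_ci(cm.tp, cm.tp + cm.fp, ci_level),
        npv=_proportion_ci(cm.tn, cm.tn + cm.fn, ci_level),
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# AUC and DeLong comparison
# ---------------------------------------------------------------------------

def _split(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DiagnosticsError("scores and labels must be equal-length 1-D arrays")
    if np.isnan(s).any():
        raise DiagnosticsError("scores contain missing values")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise DiagnosticsError("labels must contain both classes")
    return s, y


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values and AUC by the midrank construction.

    For each positive: the fraction of negatives it outranks (ties 1/2); for
    each negative: the fraction of positives ranking below it (ties 1/2).
    The AUC is the mean of either vector.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v_pos = (tz[:m] - tx) / n
    v_neg = 1.0 - (tz[m:] - ty) / m
    auc = float(v_pos.mean())
    return v_pos, v_neg, auc


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie).

    Equals the trapezoidal area under the empirical ROC curve; ties are
    handled with the midrank convention throughout.
    """
    s, y = _split(scores, labels)
    return _placements(s, y)[2]


@dataclass(frozen=True)
class RocComparison:
    """Paired comparison of two correlated empirical AUCs (DeLong)."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def delong_compare(scores_a, scores_b, labels) -> RocComparison:
    """DeLong z-test for the difference of two paired AUCs.

    The variance of (AUC_a - AUC_b) combines the empirical covariance
    matrices of the per-positive and per-negative placement values across
    the two markers: var = (S10_aa + S10_bb - 2 S10_ab)/m + (S01 terms)/n.
    The p-value is two-sided normal.
    """
    sa, ya = _split(scores_a, labels)
    sb, yb = _split(scores_b, labels)
    if not np.array_equal(ya, yb):  # same labels object reused; defensive
        raise DiagnosticsError("labels mismatch between the two score vectors")
    vp_a, vn_a, auc_a = _placements(sa, ya)
    vp_b, vn_b, auc_b = _placements(sb, ya)
    m, n = vp_a.size, vn_a.size
    var_diff = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([vp_a, vp_b]), ddof=1)
        var_diff += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([vn_a, vn_b]), ddof=1)
        var_diff += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    var_diff = max(float(var_diff), 0.0)
    diff = auc_a - auc_b
    if var_diff == 0.0:
        if abs(diff) > 1e-12:
            raise DiagnosticsError(
                "degenerate DeLong variance: AUCs differ but the placement "
                "difference has zero variance"
            )
        z = 0.0
        p = 1.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return RocComparison(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff, z=z, p_value=p)


def auc_with_ci(scores, labels, ci_level: float = 0.95) -> MetricWithCI:
    """AUC with a DeLong-variance normal CI, clipped to [0, 1]."""
    s, y = _split(scores, labels)
    vp, vn, auc = _placements(s, y)
    var = 0.0
    if vp.size > 1:
        var += float(np.var(vp, ddof=1)) / vp.size
    if vn.size > 1:
        var += float(np.var(vn, ddof=1)) / vn.size
    half = norm.ppf(0.5 + ci_level / 2.0) * math.sqrt(max(var, 0.0))
    return MetricWithCI(point=auc, ci_low=max(0.0, auc - half),
                        ci_high=min(1.0, auc + half))


# ---------------------------------------------------------------------------
# Logistic combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """A converged maximum-likelihood logistic fit."""

    coefficients: pd.Series
    fitted_probabilities: np.ndarray
    converged: bool

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(predictors.astype(float), has_constant="add")
        X = X[self.coefficients.index]
        eta = X.to_numpy() @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(outcome, predictors) -> LogisticModel:
    """Maximum-likelihood logistic regression (Newton/IRLS, statsmodels).

    ``predictors`` is a DataFrame (or array) of numeric columns without
    missing values; an intercept is added.  Complete separation and
    rank-deficient designs raise :class:`SeparationError` /
    :class:`DiagnosticsError`.
    """
    y = np.asarray(outcome).astype(float)
    X = pd.DataFrame(predictors)
    if X.isna().any().any() or np.isnan(y).any():
        raise DiagnosticsError("missing values in logistic inputs; subset first")
    if y.size <= X.shape[1] + 1:
        raise DiagnosticsError("need more observations than coefficients")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise DiagnosticsError("rank-deficient design matrix")
    model = sm.Logit(y, Xc)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
    params = res.params
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(params)) > 1e3:
        raise SeparationError("logistic fit did not converge (possible separation)")
    fitted = np.asarray(res.predict())
    return LogisticModel(
        coefficients=pd.Series(params, index=Xc.columns),
        fitted_probabilities=fitted,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Reconstruction of a 2x2 table from published margins + printed metrics
# ---------------------------------------------------------------------------

def _metrics_pct(tp: int, n: int, n_pos: int, n_flag: int) -> dict[str, float]:
    fp = n_flag - tp
    fn = n_pos - tp
    tn = n - tp - fp - fn
    out = {}
    if n_pos:
        out["sensitivity"] = 100.0 * tp / n_pos
    if n - n_pos:
        out["specificity"] = 100.0 * tn / (n - n_pos)
    if n_flag:
        out["ppv"] = 100.0 * tp / n_flag
    if n - n_flag:
        out["npv"] = 100.0 * tn / (n - n_flag)
    return out


def reconstruct_confusion(
    n: int,
    n_diseased: int,
    n_flagged: int,
    printed_metrics: dict[str, float],
    tolerance_pct: float = 0.1,
) -> ConfusionMatrix:
    """Unique integer 2x2 table matching published margins and metrics.

    ``printed_metrics`` maps metric names (sensitivity/specificity/ppv/npv,
    percent scale) to their published, rounded values.  Every admissible
    true-positive count is scored by its worst absolute deviation from the
    printed metrics; the minimizer must be unique and within
    ``tolerance_pct`` (default 0.1, i.e. one unit in the last printed digit
    plus rounding slack).
    """
    if not printed_metrics:
        raise DiagnosticsError("at least one printed metric is required")
    lo = max(0, n_flagged - (n - n_diseased))
    hi = min(n_diseased, n_flagged)
    scored = []
    for tp in range(lo, hi + 1):
        derived = _metrics_pct(tp, n, n_diseased, n_flagged)
        devs = [abs(derived[k] - v) for k, v in printed_metrics.items() if k in derived]
        if len(devs) != len(printed_metrics):
            raise DiagnosticsError("printed metric undefined for these margins")
        scored.append((max(devs), tp))
    scored.sort()
    best_score, best_tp = scored[0]
    if best_score > tolerance_pct:
        raise DiagnosticsError(
            f"no integer table within {tolerance_pct} points of the printed "
            f"metrics (best deviation {best_score:.3f})"
        )
    if len(scored) > 1 and scored[1][0] - best_score < 1e-9:
        raise DiagnosticsError("reconstruction is ambiguous: two tables fit equally")
    return ConfusionMatrix(
        tp=best_tp, fp=n_flagged - best_tp, fn=n_diseased - best_tp,
        tn=n - n_diseased - (n_flagged - best_tp),
    )
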