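"""Accuracy metrics, Mann-Whitney AUC, logistic fits and the DeLong test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta
from sklearn.metrics import roc_auc_score

from lgascreen.diagnostics import (
    ConfusionMatrix,
    DiagnosticsError,
    SeparationError,
    confusion_matrix,
    delong_compare,
    diagnostic_metrics,
    fit_logistic,
    reconstruct_confusion,
    roc_auc,
)

# Published accuracy table used as the reconstruction fixture: margins
# (cohort 358, 147 with the outcome, flagged counts per chart) plus the
# rounded per-chart metrics, and the integer 2x2 cells they determine.
PUBLISHED = {
    "fmf": dict(flagged=152, sensitivity=76.9, specificity=81.5, ppv=74.3,
                npv=83.5, cells=(113, 39, 34, 172)),
    "nichd": dict(flagged=152, sensitivity=68.7, specificity=75.8, ppv=66.5,
                  npv=77.7, cells=(101, 51, 46, 160)),
    "hadlock": dict(flagged=123, sensitivity=63.2, specificity=85.8, ppv=75.6,
                    npv=77.0, cells=(93, 30, 54, 181)),
}


def expand_flags(cm: ConfusionMatrix):
    flags = np.r_[np.ones(cm.tp), np.ones(cm.fp), np.zeros(cm.fn), np.zeros(cm.tn)]
    labels = np.r_[np.ones(cm.tp), np.zeros(cm.fp), np.ones(cm.fn), np.zeros(cm.tn)]
    return flags, labels.astype(bool)


# ---------------------------------------------------------------------------
# confusion matrix + metrics
# ---------------------------------------------------------------------------

def test_confusion_matrix_cross_classification():
    cm = confusion_matrix([True] * 5, [True] * 5)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 0)
    cm = confusion_matrix([False, False, False], [True, False, True])
    assert (cm.tp, cm.fp) == (0, 0) and (cm.fn, cm.tn) == (2, 1)
    with pytest.raises(DiagnosticsError, match="equal-length"):
        confusion_matrix([True], [True, False])
    with pytest.raises(DiagnosticsError, match="missing"):
        confusion_matrix([1.0, np.nan], [1.0, 0.0])


@pytest.mark.parametrize("chart", sorted(PUBLISHED))
def test_reconstruction_from_margins_and_one_metric(chart):
    """Margins + the rounded sensitivity pin down the integer 2x2 uniquely."""
    pub = PUBLISHED[chart]
    cm = reconstruct_confusion(358, 147, pub["flagged"],
                               {"sensitivity": pub["sensitivity"]})
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == pub["cells"]


@pytest.mark.parametrize("chart", sorted(PUBLISHED))
def test_metrics_match_published_rows(chart):
    pub = PUBLISHED[chart]
    summ = diagnostic_metrics(ConfusionMatrix(*pub["cells"]))
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        got = getattr(summ, name).pct
        # the published table rounds to 1 decimal; two entries carry a
        # one-digit rounding slip (hadlock sensitivity, nichd ppv), so
        # agreement is asserted to 0.1 points rather than exact rounding
        assert got == pytest.approx(pub[name], abs=0.1)


def test_metrics_perfect_two_subject_table():
    summ = diagnostic_metrics(ConfusionMatrix(1, 0, 0, 1))
    assert summ.sensitivity.point == 1.0
    assert summ.specificity.point == 1.0


def test_undefined_metric_is_none_not_zero():
    summ = diagnostic_metrics(ConfusionMatrix(0, 0, 3, 4))  # nobody flagged
    assert summ.ppv is None
    assert summ.npv.point == pytest.approx(4 / 7)


def test_clopper_pearson_equals_beta_quantiles():
    """CI bounds agree with the exact beta-quantile closed form."""
    summ = diagnostic_metrics(ConfusionMatrix(113, 39, 34, 172))
    k, n = 113, 147
    lo = beta.ppf(0.025, k, n - k + 1)
    hi = beta.ppf(0.975, k + 1, n - k)
    assert summ.sensitivity.ci_low == pytest.approx(lo, abs=1e-10)
    assert summ.sensitivity.ci_high == pytest.approx(hi, abs=1e-10)


def test_clopper_pearson_coverage_at_least_nominal(rng):
    """Exact intervals are conservative: >= 95% coverage at n=147, p=0.77."""
    n, p, sims = 147, 0.77, 10_000
    k = rng.binomial(n, p, size=sims)
    lo = beta.ppf(0.025, k, n - k + 1)
    lo = np.where(k == 0, 0.0, lo)
    hi = beta.ppf(0.975, k + 1, n - k)
    hi = np.where(k == n, 1.0, hi)
    coverage = np.mean((lo <= p) & (p <= hi))
    assert coverage >= 0.95


def test_reconstruction_ambiguity_and_tolerance():
    with pytest.raises(DiagnosticsError, match="printed metric"):
        reconstruct_confusion(10, 5, 5, {})
    with pytest.raises(DiagnosticsError, match="no integer table"):
        reconstruct_confusion(358, 147, 152, {"sensitivity": 10.0})


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_uninformative_scores():
    assert roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5


def test_auc_four_subject_pair_count():
    assert roc_auc([0.9, 0.2, 0.7, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)


def test_auc_requires_both_classes():
    with pytest.raises(DiagnosticsError, match="both classes"):
        roc_auc([0.1, 0.2], [1, 1])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_auc_equals_brute_force_pair_count(data):
    """Midrank AUC equals the O(n^2) pair count, ties counted 1/2."""
    n = data.draw(st.integers(4, 200))
    # coarse grid of scores forces plenty of ties
    scores = np.asarray(data.draw(
        st.lists(st.integers(0, 8), min_size=n, max_size=n)), dtype=float)
    labels = np.asarray(data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n)))
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    pos, neg = scores[labels], scores[~labels]
    brute = np.mean((pos[:, None] > neg[None, :])
                    + 0.5 * (pos[:, None] == neg[None, :]))
    assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)


def test_auc_matches_sklearn(rng):
    labels = rng.uniform(size=500) < 0.4
    scores = labels * 0.8 + rng.standard_normal(500)
    scores = np.round(scores, 1)  # induce ties
    assert roc_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(tp=st.integers(1, 60), fp=st.integers(1, 60),
       fn=st.integers(1, 60), tn=st.integers(1, 60))
def test_binary_flag_auc_is_mean_of_se_and_sp(tp, fp, fn, tn):
    cm = ConfusionMatrix(tp, fp, fn, tn)
    flags, labels = expand_flags(cm)
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    assert roc_auc(flags, labels) == pytest.approx((se + sp) / 2, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_saturated_binary_predictor(rng):
    """One binary predictor: fitted probabilities are the two group rates."""
    x = rng.uniform(size=400) < 0.5
    y = np.where(x, rng.uniform(size=400) < 0.7, rng.uniform(size=400) < 0.3)
    model = fit_logistic(y, pd.DataFrame({"x": x.astype(float)}))
    fitted = model.fitted_probabilities
    assert len(np.unique(np.round(fitted, 12))) == 2
    assert fitted[x].mean() == pytest.approx(y[x].mean(), abs=1e-8)
    assert fitted[~x].mean() == pytest.approx(y[~x].mean(), abs=1e-8)


def test_logistic_null_slope_within_3se(rng):
    y = rng.uniform(size=10_000) < 0.4
    x = rng.standard_normal(10_000)
    model = fit_logistic(y, pd.DataFrame({"x": x}))
    slope = model.coefficients["x"]
    # SE of the slope under the null ~ 1/sqrt(n p (1-p) var(x))
    se = 1.0 / np.sqrt(10_000 * 0.4 * 0.6)
    assert abs(slope) < 3 * se


def test_logistic_separation_detected():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = np.r_[np.ones(20), np.zeros(20)]
    with pytest.raises(SeparationError):
        fit_logistic(y, pd.DataFrame({"x": x}))


def test_logistic_rank_deficiency_detected(rng):
    x = rng.standard_normal(100)
    y = rng.uniform(size=100) < 0.5
    with pytest.raises(DiagnosticsError, match="rank"):
        fit_logistic(y, pd.DataFrame({"a": x, "b": 2 * x}))


# ---------------------------------------------------------------------------
# DeLong comparison
# ---------------------------------------------------------------------------

def _brute_delong(scores_a, scores_b, labels):
    """Placement-value DeLong variance by exhaustive enumeration."""
    out = {}
    labels = np.asarray(labels).astype(bool)
    for key, s in (("a", np.asarray(scores_a)), ("b", np.asarray(scores_b))):
        pos, neg = s[labels], s[~labels]
        v_pos = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
        v_neg = np.array([np.mean((pos < q) + 0.5 * (pos == q)) for q in neg])
        out[key] = (v_pos, v_neg, v_pos.mean())
    (va_p, va_n, auc_a), (vb_p, vb_n, auc_b) = out["a"], out["b"]
    m, n = va_p.size, va_n.size
    var = 0.0
    if m > 1:
        c = np.cov(np.vstack([va_p, vb_p]), ddof=1)
        var += (c[0, 0] + c[1, 1] - 2 * c[0, 1]) / m
    if n > 1:
        c = np.cov(np.vstack([va_n, vb_n]), ddof=1)
        var += (c[0, 0] + c[1, 1] - 2 * c[0, 1]) / n
    return auc_a, auc_b, var


def test_delong_identical_scores():
    labels = np.r_[np.ones(10), np.zeros(10)].astype(bool)
    s = np.arange(20.0)
    cmp_ = delong_compare(s, s, labels)
    assert cmp_.z == 0.0 and cmp_.p_value == 1.0


def test_delong_four_subject_hand_example():
    labels = np.array([1, 1, 0, 0], dtype=bool)
    a = np.array([0.9, 0.8, 0.7, 0.1])
    b = np.array([0.9, 0.2, 0.7, 0.1])
    cmp_ = delong_compare(a, b, labels)
    auc_a, auc_b, var = _brute_delong(a, b, labels)
    assert cmp_.auc_a == pytest.approx(1.0)
    assert cmp_.auc_b == pytest.approx(0.75)
    assert (auc_a, auc_b) == (1.0, 0.75)
    assert cmp_.var_diff == pytest.approx(var, abs=1e-12)


def test_delong_matches_enumeration_with_ties(rng):
    labels = rng.uniform(size=60) < 0.4
    labels[:2] = [True, False]
    a = np.round(labels * 1.0 + rng.standard_normal(60), 1)
    b = np.round(labels * 0.5 + rng.standard_normal(60), 1)
    cmp_ = delong_compare(a, b, labels)
    auc_a, auc_b, var = _brute_delong(a, b, labels)
    assert cmp_.auc_a == pytest.approx(auc_a, abs=1e-12)
    assert cmp_.auc_b == pytest.approx(auc_b, abs=1e-12)
    assert cmp_.var_diff == pytest.approx(var, rel=1e-10)


def test_delong_antisymmetry(rng):
    labels = rng.uniform(size=100) < 0.5
    labels[:2] = [True, False]
    a = labels * 1.0 + rng.standard_normal(100)
    b = labels * 0.4 + rng.standard_normal(100)
    fwd = delong_compare(a, b, labels)
    rev = delong_compare(b, a, labels)
    assert rev.z == pytest.approx(-fwd.z, abs=1e-12)
    assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)
    assert rev.var_diff == pytest.approx(fwd.var_diff, abs=1e-15)
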