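"""Diagnostic statistics: oracles for ROC/AUC, Youden, DeLong, ICC, CV, CIs."""

import numpy as np
import pytest
from scipy.stats import norm

from ctqpr import (
    binormal_auc,
    compare_auc_paired,
    cv_percent,
    diagnostic_metrics,
    evaluate_index,
    ffr_eligible,
    icc_two_rater,
    label_significant,
    roc_auc,
    spearman_r,
    two_sample_t,
    youden_cutoff,
)
from ctqpr.core import InputError


def moments_exact(mean, sd, n, seed):
    """A sample with exactly the requested mean and (ddof=1) SD."""
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def pair_counting_auc(scores, labels, lower_is_positive=True):
    """Exhaustive O(n_pos * n_neg) oracle with ties counted 1/2."""
    s = -np.asarray(scores, float) if lower_is_positive else np.asarray(scores, float)
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestLabeling:
    def test_ffr_boundary(self):
        labels = label_significant(np.array([0.80, 0.81, 1.0]))
        assert labels.tolist() == [True, False, False]

    def test_all_normal_gives_no_positives(self):
        assert not label_significant(np.full(5, 1.0)).any()

    @pytest.mark.parametrize(
        "qca,expected", [(30.0, True), (69.0, True), (29.9, False), (70.0, False)]
    )
    def test_qca_band(self, qca, expected):
        assert ffr_eligible(qca) is expected


class TestCorrelationAndT:
    def test_monotone_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_r(x, np.exp(x)) == pytest.approx(1.0)

    def test_hand_ranked_oracle(self):
        # ranks are identities; Pearson of ranks (1,2,3,4) vs (2,1,4,3) = 0.6
        assert spearman_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert spearman_r(x, y) == pytest.approx(-spearman_r(x, -y))

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_t(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_printed_group_summaries_significant(self):
        # groups matching 1.38 +/- 0.27 (n=20) vs 1.74 +/- 0.35 (n=19)
        a = moments_exact(1.38, 0.27, 20, seed=1)
        b = moments_exact(1.74, 0.35, 19, seed=2)
        _, p = two_sample_t(a, b)
        assert p < 0.05

    def test_swap_negates_t(self):
        a = moments_exact(1.0, 0.2, 10, seed=3)
        b = moments_exact(1.5, 0.2, 12, seed=4)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc([0.5, 0.6, 1.5, 1.6], [True, True, False, False])
        assert roc.auc == 1.0

    def test_ties_give_half(self):
        roc = roc_auc([1, 1, 2, 2], [True, False, True, False])
        assert roc.auc == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 60)
        scores = np.round(rng.normal(size=n), 1)  # force ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        roc = roc_auc(scores, labels)
        trap = np.trapezoid(np.r_[0.0, roc.tpr], np.r_[0.0, roc.fpr])
        assert roc.auc == pytest.approx(trap, abs=1e-12)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(77)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        roc = roc_auc(scores, labels, lower_is_positive=True)
        assert roc.auc == pytest.approx(roc_auc_score(labels, -scores))

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1.0, 2.0], [True, True])


class TestYouden:
    def test_toy_cutoff_in_gap(self):
        roc = roc_auc(
            [0.6, 0.7, 0.75, 0.85, 0.9], [True, True, True, False, False]
        )
        cut = youden_cutoff(roc)
        assert 0.75 < cut <= 0.85
        assert cut == pytest.approx(0.8)

    def test_perfect_separation_returns_midpoint(self):
        roc = roc_auc([1.0, 1.2, 2.0, 2.2], [True, True, False, False])
        assert youden_cutoff(roc) == pytest.approx(1.6)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        roc1 = roc_auc(scores, labels)
        roc2 = roc_auc(np.exp(scores), labels)
        j1 = (roc1.tpr - roc1.fpr).max()
        j2 = (roc2.tpr - roc2.fpr).max()
        assert j1 == pytest.approx(j2)

    def test_cutoff_reproduces_reported_operating_point(self):
        rng = np.random.default_rng(15)
        scores = np.r_[rng.normal(1.4, 0.3, 20), rng.normal(1.7, 0.3, 19)]
        labels = np.r_[np.ones(20, bool), np.zeros(19, bool)]
        roc = roc_auc(scores, labels)
        cut = youden_cutoff(roc)
        preds = scores <= cut
        m = diagnostic_metrics(preds, labels)
        sens = 100.0 * m["tp"] / (m["tp"] + m["fn"])
        spec = 100.0 * m["tn"] / (m["tn"] + m["fp"])
        j_from_counts = sens / 100 + spec / 100 - 1
        assert j_from_counts == pytest.approx((roc.tpr - roc.fpr).max())


class TestDiagnosticMetrics:
    def test_sensitivity_95_wald_lower_85(self):
        labels = np.r_[np.ones(20, bool), np.zeros(19, bool)]
        preds = labels.copy()
        preds[0] = False  # 19/20 sensitivity
        m = diagnostic_metrics(preds, labels)
        value, (lo, hi) = m["sensitivity"]
        assert value == pytest.approx(95.0)
        assert round(lo) == 85
        assert hi == 100.0

    def test_specificity_895_wald_76_100(self):
        labels = np.r_[np.ones(20, bool), np.zeros(19, bool)]
        preds = labels.copy()
        preds[20:22] = True  # 17/19 specificity
        m = diagnostic_metrics(preds, labels)
        value, (lo, hi) = m["specificity"]
        assert value == pytest.approx(100.0 * 17 / 19)
        assert round(value) == 89  # prints as ~90 at integer precision
        assert round(lo) == 76
        assert hi == 100.0

    def test_all_correct_degenerate_cis(self):
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        m = diagnostic_metrics(labels, labels)
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            value, (lo, hi) = m[key]
            assert value == 100.0 and lo == 100.0 and hi == 100.0

    def test_undefined_ppv_flagged(self):
        labels = np.r_[np.ones(3, bool), np.zeros(3, bool)]
        m = diagnostic_metrics(np.zeros(6, bool), labels)
        assert m["ppv"] is None


def bootstrap_auc_p(scores_a, scores_b, labels, n_boot=4000, seed=0):
    """Stratified-bootstrap oracle for the paired AUC difference: normal
    p-value from the bootstrap SE of (AUC_a - AUC_b)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.r_[rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        lab = labels[idx]
        diffs[i] = (
            roc_auc(np.asarray(scores_a)[idx], lab).auc
            - roc_auc(np.asarray(scores_b)[idx], lab).auc
        )
    d0 = roc_auc(scores_a, labels).auc - roc_auc(scores_b, labels).auc
    se = diffs.std(ddof=1)
    if se == 0:
        return 1.0
    return 2.0 * float(norm.sf(abs(d0) / se))


class TestCompareAucPaired:
    def test_identical_scores_null(self):
        scores = [0.5, 0.7, 0.8, 0.9, 1.1, 1.3]
        labels = [True, True, True, False, False, False]
        a, b, p = compare_auc_paired(scores, scores, labels)
        assert a == b
        assert p == 1.0

    def test_aucs_match_roc_auc(self):
        rng = np.random.default_rng(10)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        s_a, s_b = rng.normal(size=30), rng.normal(size=30)
        a, b, _ = compare_auc_paired(s_a, s_b, labels)
        assert a == pytest.approx(roc_auc(s_a, labels).auc)
        assert b == pytest.approx(roc_auc(s_b, labels).auc)

    def test_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(21)
        labels = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        ffr_like = np.r_[rng.normal(0.7, 0.1, 6), rng.normal(0.9, 0.1, 6)]
        s_a = ffr_like + rng.normal(0, 0.08, 12)
        s_b = ffr_like + rng.normal(0, 0.03, 12)
        _, _, p = compare_auc_paired(s_a, s_b, labels)
        p_boot = bootstrap_auc_p(s_a, s_b, labels, seed=5)
        assert abs(p - p_boot) <= 0.05


class TestIccAndCv:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_two_rater(x) == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # 5x2 table evaluated by hand through the mean-squares decomposition
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0], [4.0, 4.0], [5.0, 6.0]])
        n, k = 5, 2
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_rater(x) == pytest.approx(expected)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(12)
        base = rng.normal(2.0, 0.5, 12)
        x = np.column_stack([base + rng.normal(0, 0.1, 12),
                             base + 0.1 + rng.normal(0, 0.1, 12)])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": x.reshape(-1),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        # ICC(A,1): single-rater absolute agreement, i.e. ICC(2,1)
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_rater(x) == pytest.approx(icc2, abs=1e-9)

    def test_rater_bias_lowers_absolute_agreement(self):
        rng = np.random.default_rng(13)
        base = rng.normal(2.0, 0.5, 15)
        unbiased = np.column_stack([base, base + rng.normal(0, 0.05, 15)])
        biased = unbiased.copy()
        biased[:, 1] += 0.6
        assert icc_two_rater(biased) < icc_two_rater(unbiased)

    def test_cv_zero_for_constant(self):
        cv, (lo, hi) = cv_percent([2.0, 2.0, 2.0])
        assert cv == 0.0 and lo == 0.0 and hi == 0.0

    def test_cv_of_study_scale_values(self):
        vals = moments_exact(1.55, 0.36, 39, seed=7)
        cv, _ = cv_percent(vals)
        assert cv == pytest.approx(100 * 0.36 / 1.55, rel=1e-9)  # ~23.2%

    def test_cv_scale_invariant(self):
        vals = moments_exact(1.55, 0.36, 39, seed=8)
        assert cv_percent(vals)[0] == pytest.approx(cv_percent(5.0 * vals)[0])


class TestBinormalAuc:
    def test_equal_means_is_chance(self):
        assert binormal_auc(1.0, 0.2, 1.0, 0.3) == 0.5

    def test_printed_group_statistics_give_079(self):
        assert round(binormal_auc(1.38, 0.27, 1.74, 0.35), 2) == 0.79

    def test_symmetric_under_group_swap(self):
        assert binormal_auc(1.38, 0.27, 1.74, 0.35) == pytest.approx(
            binormal_auc(1.74, 0.35, 1.38, 0.27)
        )


class TestEvaluateIndex:
    def test_report_consistency(self):
        rng = np.random.default_rng(30)
        scores = np.r_[rng.normal(1.4, 0.3, 20), rng.normal(1.75, 0.35, 19)]
        labels = np.r_[np.ones(20, bool), np.zeros(19, bool)]
        rep = evaluate_index(scores, labels, "mbf")
        assert rep.n_pos == 20 and rep.n_neg == 19
        assert rep.auc == pytest.approx(roc_auc(scores, labels).auc)
        assert 0.0 <= rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1] <= 1.0
        preds = scores <= rep.cutoff
        m = diagnostic_metrics(preds, labels)
        assert rep.sensitivity == pytest.approx(m["sensitivity"][0])
        assert rep.specificity == pytest.approx(m["specificity"][0])


# ------------------------------------------------------ property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scores=st.lists(st.integers(-5, 5), min_size=4, max_size=40),
    flips=st.lists(st.booleans(), min_size=4, max_size=40),
)
def test_auc_pair_counting_equals_trapezoid_property(scores, flips):
    n = min(len(scores), len(flips))
    scores, labels = np.asarray(scores[:n], float), np.asarray(flips[:n])
    if labels.all() or not labels.any():
        labels[0], labels[1] = True, False
    roc = roc_auc(scores, labels)
    trap = np.trapezoid(np.r_[0.0, roc.tpr], np.r_[0.0, roc.fpr])
    assert roc.auc == pytest.approx(trap, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 50))
def test_spearman_invariant_to_monotone_affine_maps(shift, scale):
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=15), rng.normal(size=15)
    assert spearman_r(x, scale * y + shift) == pytest.approx(spearman_r(x, y))
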