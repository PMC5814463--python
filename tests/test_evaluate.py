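import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sepsisprog import evaluate as ev
from sepsisprog.scoring import ScoreVector
from .conftest import make_sample_table


def pair_concordance(scores, labels):
    """Exhaustive pairwise AUROC oracle, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    return np.mean((pos[:, None] > neg[None, :])
                   + 0.5 * (pos[:, None] == neg[None, :]))


class TestAuroc:
    def test_hand_example(self):
        assert ev.auroc_point([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert ev.auroc_point([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert ev.auroc_point([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ev.auroc_point([1, 2], [1, 1])

    @given(st.integers(0, 10_000))
    def test_equals_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert ev.auroc_point(s, y) == pytest.approx(pair_concordance(s, y),
                                                     abs=1e-12)

    def test_monotone_transform_invariance_and_reversal(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.3).astype(int)
        a = ev.auroc_point(s, y)
        assert ev.auroc_point(np.exp(s), y) == pytest.approx(a)
        assert ev.auroc_point(-s, y) == pytest.approx(1 - a)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        y = (rng.random(120) < 0.3).astype(int)
        s = rng.normal(y, 1.0)
        res = ev.auroc(s, y, n_boot=500, seed=0)
        assert res.ci_95[0] <= res.auroc <= res.ci_95[1]
        assert res.ci_95[1] - res.ci_95[0] < 0.5


class TestAuprc:
    def test_perfect_classifier(self):
        assert ev.auprc([4, 3, 2, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_single_positive_ranked_first(self):
        assert ev.auprc([9, 1, 2, 3], [1, 0, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        s = rng.random(2000)
        y = (rng.random(2000) < 0.2).astype(int)
        assert ev.auprc(s, y) == pytest.approx(0.2, abs=0.03)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ev.auprc([1, 2], [0, 0])


class TestRocCurve:
    def test_endpoints_present_and_sensitivity_monotone(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.4).astype(int)
        roc = ev.roc_curve_points(s, y)
        assert roc.sensitivity[-1] == 0 and roc.specificity[-1] == 1
        assert roc.sensitivity[0] == 1 and roc.specificity[0] == 0
        assert (np.diff(roc.sensitivity) <= 0).all()
        assert (np.diff(roc.thresholds) > 0).all()


class TestSummaryRoc:
    def _binormal_curves(self, auc, k, n, seed):
        mu = np.sqrt(2) * stats.norm.ppf(auc)
        rng = np.random.default_rng(seed)
        curves = []
        for _ in range(k):
            y = (rng.random(n) < 0.3).astype(int)
            s = rng.normal(mu * y, 1.0)
            curves.append(ev.roc_curve_points(s, y))
        return curves

    def test_identical_cohorts_recover_single_cohort_auroc(self):
        [c] = self._binormal_curves(0.8, 1, 400, seed=3)
        single = np.trapezoid(c.tpr[::-1], c.fpr[::-1])
        sroc = ev.summary_roc([c, c, c], n_boot=50, seed=0)
        assert sroc.auroc == pytest.approx(single, abs=0.02)

    def test_zero_slope_curve_symmetric_about_antidiagonal(self):
        # operating points drawn exactly from the symmetric family member
        # logit(TPR) = a + logit(FPR) force a zero-slope fit, whose curve
        # must satisfy: (f, t) on curve => (1 - t, 1 - f) on curve
        from scipy.special import expit, logit
        a = 2.0
        fpr = np.linspace(0.1, 0.9, 9)
        tpr = expit(a + logit(fpr))
        curve = ev.ROCCurve(thresholds=np.linspace(1, 0, 9),
                            sensitivity=tpr[::-1], specificity=1 - fpr[::-1],
                            n_pos=100, n_neg=100)
        sroc = ev.summary_roc([curve, curve], n_boot=10, seed=0)
        assert abs(sroc.slope) < 1e-6
        x = np.linspace(0.05, 0.95, 19)
        t = np.interp(x, sroc.fpr_grid, sroc.tpr_grid)
        t_reflected = np.interp(1 - t, sroc.fpr_grid, sroc.tpr_grid)
        assert np.allclose(t_reflected, 1 - x, atol=1e-3)

    def test_recovers_binormal_auc(self):
        curves = self._binormal_curves(0.8, 2, 500, seed=7)
        sroc = ev.summary_roc(curves, n_boot=200, seed=0)
        assert sroc.auroc == pytest.approx(0.8, abs=0.03)
        assert sroc.ci_95[0] <= sroc.auroc <= sroc.ci_95[1]

    def test_no_curves_rejected(self):
        with pytest.raises(ValueError):
            ev.summary_roc([])


class TestThresholds:
    def test_discrete_achievability_with_three_positives(self):
        # sensitivities achievable: 1/3, 2/3, 1; above 0.9 only 1.0 remains
        s = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
        y = [1, 1, 1, 0, 0, 0]
        roc = ev.roc_curve_points(s, y)
        op = ev.threshold_at_sensitivity(roc, 0.9)
        assert op["sensitivity"] == 1.0
        assert op["specificity"] == 1.0

    def test_target_zero_returns_lowest_positive_sensitivity(self):
        s = [0.9, 0.8, 0.2, 0.1]
        y = [1, 1, 0, 0]
        op = ev.threshold_at_sensitivity(ev.roc_curve_points(s, y), 0.0)
        assert op["sensitivity"] == 0.5

    def test_continuous_scores_nearest_above_target(self):
        rng = np.random.default_rng(5)
        n = 1000
        y = (rng.random(n) < 0.5).astype(int)
        s = rng.normal(y * 1.5, 1)
        op = ev.threshold_at_sensitivity(ev.roc_curve_points(s, y), 0.95)
        assert 0.95 < op["sensitivity"] <= 0.96


class TestTestCharacteristics:
    def test_all_correct(self):
        out = ev.test_characteristics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert all(out[k] == 1.0
                   for k in ("accuracy", "sensitivity", "specificity",
                             "ppv", "npv"))

    def test_predict_all_positive(self):
        out = ev.test_characteristics([1, 1, 1, 1], [1, 0, 0, 0], 0.5)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 0.0
        assert out["ppv"] == 0.25
        assert out["npv"] is None  # zero denominator reported as missing

    def test_hand_two_by_two(self):
        # TP=2 FP=1 TN=3 FN=0
        s = [0.9, 0.8, 0.6, 0.3, 0.2, 0.1]
        y = [1, 1, 0, 0, 0, 0]
        out = ev.test_characteristics(s, y, 0.5)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 0.75
        assert out["ppv"] == pytest.approx(2 / 3)
        assert out["npv"] == 1.0
        assert out["accuracy"] == pytest.approx(5 / 6)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(6)
        s = rng.random(50)
        y = np.r_[1, 0, (rng.random(48) < 0.3).astype(int)]
        out = ev.test_characteristics(s, y, 0.5)
        n_pos, n_neg = y.sum(), len(y) - y.sum()
        assert out["accuracy"] == pytest.approx(
            (out["sensitivity"] * n_pos + out["specificity"] * n_neg) / len(y))


class TestJointSeverityModel:
    def _table(self, y, severity, ids):
        return make_sample_table(ids, y, severity=severity)

    def test_redundant_covariate_adds_nothing(self):
        rng = np.random.default_rng(0)
        n = 120
        sev = rng.normal(20, 5, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(sev - 20) / 5))).astype(int)
        ids = [f"s{i}" for i in range(n)]
        t = self._table(y, sev, ids)
        gene = ScoreVector(pd.Series(sev, index=ids), "gene=severity")
        jm = ev.joint_severity_model(t, gene)
        assert jm.auroc_joint == pytest.approx(jm.auroc_severity, abs=1e-6)

    def test_nested_loglikelihood_ordering(self):
        rng = np.random.default_rng(1)
        n = 150
        sev = rng.normal(20, 5, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(sev - 20) / 6))).astype(int)
        ids = [f"s{i}" for i in range(n)]
        gene = ScoreVector(pd.Series(rng.normal(size=n), index=ids), "noise")
        jm = ev.joint_severity_model(self._table(y, sev, ids), gene)
        if not jm.penalized:  # nesting guaranteed only for exact MLE
            assert jm.loglik_joint >= jm.loglik_severity - 1e-6

    def test_samples_without_severity_dropped(self):
        rng = np.random.default_rng(2)
        n = 60
        sev = rng.normal(20, 5, n)
        sev[:10] = np.nan
        y = np.r_[1, 0, (rng.random(n - 2) < 0.4).astype(int)]
        ids = [f"s{i}" for i in range(n)]
        gene = ScoreVector(pd.Series(rng.normal(size=n), index=ids), "g")
        jm = ev.joint_severity_model(self._table(y, sev, ids), gene)
        assert jm.n == n - 10
        assert jm.n_dropped_no_severity == 10

    def test_complementary_halves_favour_joint_model(self):
        rng = np.random.default_rng(3)
        n = 250
        h1, h2 = rng.standard_normal(n), rng.standard_normal(n)
        risk = (h1 + h2) / np.sqrt(2)
        y = (rng.random(n) < 1 / (1 + np.exp(-(2 * risk - 1.2)))).astype(int)
        ids = [f"s{i}" for i in range(n)]
        gene = ScoreVector(pd.Series(h2, index=ids), "g")
        jm = ev.joint_severity_model(self._table(y, h1, ids), gene)
        assert jm.auroc_joint > max(jm.auroc_severity, jm.auroc_gene)


def cnri_oracle(old, new, labels):
    """Direct-counting cNRI oracle."""
    old, new, labels = map(np.asarray, (old, new, labels))
    ev_mask = labels == 1
    up = new > old
    down = new < old
    e = np.mean(up[ev_mask]) - np.mean(down[ev_mask])
    ne = np.mean(down[~ev_mask]) - np.mean(up[~ev_mask])
    return e, ne, e + ne


class TestCnri:
    def test_identical_risks_give_zero(self):
        r = ev.cnri([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4], [1, 1, 0, 0])
        assert r.cnri == 0.0

    def test_counting_example(self):
        r = ev.cnri([0.2, 0.5, 0.7, 0.3], [0.6, 0.4, 0.2, 0.3], [1, 1, 0, 0])
        assert r.event_component == 0.0
        assert r.nonevent_component == 0.5
        assert r.cnri == 0.5

    def test_maximum_of_two_attained(self):
        old = np.r_[np.linspace(0.0, 0.4, 10), np.linspace(0.6, 1.0, 10)]
        new = np.r_[np.linspace(0.6, 1.0, 10), np.linspace(0.0, 0.4, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert ev.cnri(old, new, labels).cnri == 2.0

    @given(st.integers(0, 5000))
    def test_matches_counting_oracle_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        old = np.round(rng.random(n), 1)
        new = np.round(rng.random(n), 1)
        r = ev.cnri(old, new, labels)
        e, ne, tot = cnri_oracle(old, new, labels)
        assert r.cnri == pytest.approx(tot, abs=1e-12)
        assert -2 <= r.cnri <= 2
        assert r.cnri == pytest.approx(-ev.cnri(new, old, labels).cnri)

    def test_bootstrap_ci_contains_estimate(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.ones(20), np.zeros(40)].astype(int)
        old, new = rng.random(60), rng.random(60)
        r = ev.cnri(old, new, labels, bootstrap=True, n_boot=300, seed=0)
        assert r.ci_95[0] <= r.cnri <= r.ci_95[1]


class TestPairedAurocTest:
    def test_identical_vectors_mean_zero(self):
        out = ev.paired_auroc_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert out["mean_difference"] == 0.0
        assert out["p_value"] == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        out = ev.paired_auroc_test([0.8] * 5, [0.7] * 5)
        assert out["degenerate"]
        assert out["p_value"] == 0.0

    def test_matches_t_distribution_oracle(self):
        diffs = np.array([0.05, 0.1, 0.02, 0.08])
        out = ev.paired_auroc_test(0.7 + diffs, np.full(4, 0.7))
        t_hand = diffs.mean() / (diffs.std(ddof=1) / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=3)
        assert out["t"] == pytest.approx(t_hand)
        assert out["p_value"] == pytest.approx(p_hand)


class TestRankCorrelation:
    def _sv(self, values, name):
        ids = [f"s{i}" for i in range(len(values))]
        return ScoreVector(pd.Series(values, index=ids, dtype=float), name)

    def test_identical_and_reversed_rankings(self):
        a = self._sv([1, 2, 3, 4, 5], "a")
        b = self._sv([10, 20, 30, 40, 50], "b")
        c = self._sv([5, 4, 3, 2, 1], "c")
        m = ev.model_rank_correlation([a, b, c])
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)

    def test_hand_computed_rho_half(self):
        # ranks (1..5) vs (2,4,1,3,5): sum d^2 = 10 -> rho = 1 - 60/120 = 0.5
        a = self._sv([1, 2, 3, 4, 5], "a")
        b = self._sv([2, 4, 1, 3, 5], "b")
        assert ev.model_rank_correlation([a, b]).loc["a", "b"] == \
            pytest.approx(0.5)

    def test_too_few_shared_samples_rejected(self):
        a = self._sv([1, 2], "a")
        b = self._sv([2, 1], "b")
        with pytest.raises(ValueError, match="shared"):
            ev.model_rank_correlation([a, b])


class TestConsensus:
    def test_category_boundaries(self):
        flags = np.array([[1, 1, 1, 0],   # 3 correct -> consensus
                          [1, 1, 0, 0],   # 2 -> no consensus
                          [0, 0, 0, 0],   # 0 -> always misclassified
                          [1, 1, 1, 1]])  # 4 -> consensus
        out = ev.consensus_classification(flags)
        assert list(out["category"]) == ["consensus", "no_consensus",
                                         "always_misclassified", "consensus"]
        assert out.attrs["fractions"]["consensus"] == 0.5

    def test_wrong_model_count_rejected(self):
        with pytest.raises(ValueError, match="4 model"):
            ev.consensus_classification(np.ones((3, 3)))


class TestLongitudinalSlope:
    def _frame(self, slopes, offsets, n_per=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, (m, b) in enumerate(zip(slopes, offsets)):
            for t in np.linspace(0, 48, n_per):
                rows.append({"patient_id": f"p{i}", "time_h": t,
                             "score": b + m * t / 24
                             + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_flat_equal_groups_give_large_p(self):
        df = self._frame([0.0] * 8, [1.0] * 8, noise=0.05)
        labels = pd.Series([1] * 4 + [0] * 4,
                           index=[f"p{i}" for i in range(8)])
        out = ev.longitudinal_slope_test(df, labels)
        assert out["slope_p"] > 0.05 and out["level_p"] > 0.05

    def test_level_offset_detected_without_slope_difference(self):
        rng = np.random.default_rng(1)
        n = 20
        offsets = np.r_[1.0 + rng.normal(0, 0.3, n), rng.normal(0, 0.3, n)]
        df = self._frame([0.0] * (2 * n), offsets, noise=0.1, seed=2)
        labels = pd.Series([1] * n + [0] * n,
                           index=[f"p{i}" for i in range(2 * n)])
        out = ev.longitudinal_slope_test(df, labels)
        assert out["slope_p"] > 0.05
        assert out["level_p"] < 0.01

    def test_constructed_slope_difference_detected(self):
        n = 10
        slopes = np.r_[np.full(n, 0.5), np.zeros(n)]
        df = self._frame(slopes, [0.0] * (2 * n), noise=0.1, seed=3)
        labels = pd.Series([1] * n + [0] * n,
                           index=[f"p{i}" for i in range(2 * n)])
        assert ev.longitudinal_slope_test(df, labels)["slope_p"] < 0.01

    def test_single_timepoint_patients_excluded(self):
        df = self._frame([0.0] * 8, [0.0] * 8, noise=0.05, seed=4)
        df = pd.concat([df, pd.DataFrame([{"patient_id": "solo", "time_h": 0.0,
                                           "score": 1.0}])])
        labels = pd.Series([1] * 4 + [0] * 4 + [1],
                           index=[f"p{i}" for i in range(8)] + ["solo"])
        out = ev.longitudinal_slope_test(df, labels)
        assert out["n_excluded"] == 1
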