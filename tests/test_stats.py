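from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats as sps

from poafkit.stats import (
    ConfusionMatrix,
    InversionError,
    UndefinedComparisonError,
    accuracy_metrics,
    bonferroni_adjust_p,
    bonferroni_alpha,
    cohen_kappa,
    compare_se_sp,
    confusion_matrix,
    invert_rounded_table,
    leisenring_pv_test,
    mcnemar_test,
    npv_from_se_sp_prevalence,
    ppv_from_se_sp_prevalence,
    proportion_ci,
    round_half_up_pct,
    unpaired_proportion_test,
)
from helpers import gs_statistic_oracle


class TestConfusionMatrix:
    def test_perfect_and_degenerate_predictors(self):
        truth = [True] * 4 + [False] * 6
        cm = confusion_matrix(truth, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (4, 0, 0, 6)
        cm = confusion_matrix([False] * 10, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 4, 6)

    def test_mapping_join_detects_mismatch(self):
        pred = {("P1", "V1"): True}
        ref = {("P2", "V2"): True}
        with pytest.raises(KeyError):
            confusion_matrix(pred, ref)

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        pred, truth = rng.random(50) < 0.4, rng.random(50) < 0.3
        assert confusion_matrix(pred, truth).n == 50


class TestAccuracyMetrics:
    def test_reconstructed_best_algorithm_matrix(self):
        # (228, 91, 96, 561): n_pos=324, n_neg=652
        cm = ConfusionMatrix(tp=228, fp=91, fn=96, tn=561)
        m = accuracy_metrics(cm)
        assert m["sensitivity"].point == pytest.approx(0.7037, abs=1e-4)
        assert m["specificity"].point == pytest.approx(0.8604, abs=1e-4)
        assert m["ppv"].point == pytest.approx(0.7147, abs=1e-4)
        assert m["npv"].point == pytest.approx(0.8539, abs=1e-4)
        for metric, printed in [
            ("sensitivity", "70.4"), ("specificity", "86.0"),
            ("ppv", "71.5"), ("npv", "85.4"),
        ]:
            e = m[metric]
            assert round_half_up_pct(e.n_numerator, e.n_denominator) == Fraction(printed)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = accuracy_metrics(ConfusionMatrix(0, 0, 4, 6))
        assert m["sensitivity"].point == 0.0
        assert m["ppv"].undefined and m["ppv"].point is None

    def test_all_correct(self):
        m = accuracy_metrics(ConfusionMatrix(5, 0, 0, 7))
        assert all(m[k].point == 1.0 for k in m)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_bayes_consistency_exact(self, tp, fp, fn, tn):
        # PPV/NPV from (Se, Sp, prevalence) equal their direct ratios exactly
        cm = ConfusionMatrix(tp, fp, fn, tn)
        se, sp = cm.metric_fraction("sensitivity"), cm.metric_fraction("specificity")
        if se is None or sp is None or cm.n == 0:
            return
        prev = Fraction(cm.n_positive, cm.n)
        if cm.tp + cm.fp > 0:
            assert ppv_from_se_sp_prevalence(se, sp, prev) == cm.metric_fraction("ppv")
        if cm.fn + cm.tn > 0:
            assert npv_from_se_sp_prevalence(se, sp, prev) == cm.metric_fraction("npv")


class TestProportionCI:
    def test_exact_interval_matches_binomial_tail_roots(self):
        # oracle: numerical roots of the binomial tail equations
        for k, n in [(228, 324), (561, 652), (7, 20), (1, 30)]:
            low, high = proportion_ci(k, n)
            low_oracle = optimize.brentq(
                lambda p: sps.binom.sf(k - 1, n, p) - 0.025, 1e-12, 1 - 1e-12
            )
            high_oracle = optimize.brentq(
                lambda p: sps.binom.cdf(k, n, p) - 0.025, 1e-12, 1 - 1e-12
            )
            assert low == pytest.approx(low_oracle, abs=1e-9)
            assert high == pytest.approx(high_oracle, abs=1e-9)

    def test_edge_cases_exact(self):
        assert proportion_ci(0, 20)[0] == 0.0
        assert proportion_ci(20, 20)[1] == 1.0

    def test_ordering_and_validation(self):
        low, high = proportion_ci(5, 10)
        assert low <= 0.5 <= high
        with pytest.raises(ValueError):
            proportion_ci(11, 10)

    def test_wilson_differs_from_exact(self):
        # only the exact interval reproduces the printed 65.1 lower bound;
        # Wilson is narrower (65.2) on this denominator
        cp = proportion_ci(228, 324, method="clopper_pearson")
        wilson = proportion_ci(228, 324, method="wilson")
        assert round(100 * cp[0], 1) == 65.1
        assert round(100 * wilson[0], 1) == 65.2


class TestMcNemar:
    def test_symmetry_null(self):
        a = [True] * 5 + [False] * 5
        b = [False] * 5 + [True] * 5
        res = mcnemar_test(a, b)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_b10_c0(self):
        res = mcnemar_test([True] * 10, [False] * 10)
        assert res.statistic == pytest.approx(10.0)
        assert res.p_value == pytest.approx(0.001565402258, abs=1e-9)

    def test_swap_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(60) < 0.5, rng.random(60) < 0.5
        assert mcnemar_test(a, b).p_value == pytest.approx(mcnemar_test(b, a).p_value)

    def test_no_discordance_flagged(self):
        res = mcnemar_test([True, False], [True, False])
        assert res.p_value == 1.0 and res.warning is not None

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(5)
        a, b = rng.random(80) < 0.6, rng.random(80) < 0.5
        res = mcnemar_test(a, b)
        n11 = int(np.sum(a & b))
        n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b))
        n00 = int(np.sum(~a & ~b))
        sm = sm_mcnemar([[n11, n10], [n01, n00]], exact=False, correction=False)
        assert res.statistic == pytest.approx(float(sm.statistic))
        assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_compare_se_sp_subsetting(self):
        truth = np.array([True] * 4 + [False] * 4)
        pa = np.array([True, True, False, False, False, False, True, True])
        pb = np.array([True, False, True, False, False, True, False, True])
        se = compare_se_sp(truth, pa, pb, "sensitivity")
        assert se.details == {"b": 1, "c": 1}
        sp = compare_se_sp(truth, pa, pb, "specificity")
        assert sp.details == {"b": 1, "c": 1}


# hand-built 12-subject worked example; oracle values computed with
# gs_statistic_oracle (explicit stacking + sandwich variance) and frozen
GS_D = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 0], dtype=bool)
GS_A = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 0, 1], dtype=bool)
GS_B = np.array([1, 0, 1, 1, 0, 0, 1, 1, 1, 1, 1, 0], dtype=bool)


class TestLeisenring:
    def test_identical_predictions_null_identity(self):
        d = np.array([True, False, True, False, True])
        p = np.array([True, True, False, False, True])
        for which in ("ppv", "npv"):
            res = leisenring_pv_test(d, p, p, which)
            assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize(
        "which,frozen", [("ppv", 0.463768115942029), ("npv", 0.5333333333333333)]
    )
    def test_worked_example_matches_oracle(self, which, frozen):
        res = leisenring_pv_test(GS_D, GS_A, GS_B, which)
        assert res.statistic == pytest.approx(frozen, abs=1e-12)
        assert res.statistic == pytest.approx(
            gs_statistic_oracle(GS_D, GS_A, GS_B, which), abs=1e-12
        )

    def test_oracle_agreement_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = rng.random(30) < 0.4
            pa = rng.random(30) < 0.5
            pb = rng.random(30) < 0.5
            if not (pa.any() and pb.any() and (~pa).any() and (~pb).any()):
                continue
            for which in ("ppv", "npv"):
                res = leisenring_pv_test(d, pa, pb, which)
                assert res.statistic == pytest.approx(
                    gs_statistic_oracle(d, pa, pb, which), abs=1e-10
                )

    def test_no_qualifying_records_is_error(self):
        d = np.array([True, False])
        with pytest.raises(UndefinedComparisonError):
            leisenring_pv_test(d, np.array([False, False]), np.array([True, False]), "ppv")


class TestUnpaired:
    def test_equal_proportions(self):
        res = unpaired_proportion_test(10, 20, 10, 20)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_site_sensitivity_difference(self):
        # reconstructed site-level sensitivities 107/174 vs 118/150
        res = unpaired_proportion_test(107, 174, 118, 150)
        assert abs(res.statistic) == pytest.approx(3.35, abs=0.01)
        assert res.p_value < 0.001

    def test_sign_flip_on_swap(self):
        a = unpaired_proportion_test(30, 50, 20, 60)
        b = unpaired_proportion_test(20, 60, 30, 50)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            unpaired_proportion_test(0, 0, 1, 10)


class TestBonferroni:
    def test_alpha_adjustment(self):
        assert bonferroni_alpha(0.05, 15) == pytest.approx(0.05 / 15)
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_p_adjustment_caps_and_preserves_order(self):
        adj = bonferroni_adjust_p([0.2, 0.001, 0.02], 10)
        assert adj == [1.0, 0.01, 0.2]
        assert sorted(adj) == [adj[1], adj[2], adj[0]]

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestKappa:
    def test_perfect_agreement_both_classes(self):
        a = [True] * 30 + [False] * 19  # 49 re-reviewed charts, all agreeing
        assert cohen_kappa(a, list(a)) == 1.0

    def test_hand_computed_zero(self):
        # p_o = 0.5, p_e = 0.5
        assert cohen_kappa(["+", "+", "-", "-"], ["+", "-", "-", "+"]) == 0.0

    def test_chance_level_for_independent_ratings(self):
        rng = np.random.default_rng(8)
        a = (rng.random(20000) < 0.5).tolist()
        b = (rng.random(20000) < 0.5).tolist()
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_constant_raters_convention(self):
        assert cohen_kappa([True] * 5, [True] * 5) == 1.0

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(13)
        a = (rng.random(200) < 0.4).tolist()
        b = [x if rng.random() < 0.8 else not x for x in a]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([True], [True, False])


class TestInversion:
    def test_roundtrip_recovers_known_matrix(self):
        cm = ConfusionMatrix(tp=228, fp=91, fn=96, tn=561)
        printed = {
            m: float(round_half_up_pct(
                accuracy_metrics(cm)[m].n_numerator,
                accuracy_metrics(cm)[m].n_denominator,
            ))
            for m in ("sensitivity", "specificity", "ppv", "npv")
        }
        sols = invert_rounded_table(printed, cm.n_positive, cm.n_negative)
        assert sols == [cm]

    def test_inconsistent_row_raises(self):
        with pytest.raises(InversionError):
            invert_rounded_table((50.0, 50.0, 99.9, 0.1), 10, 10)

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 60), st.integers(0, 60))
    def test_roundtrip_property(self, npos, nneg, tp, tn):
        tp, tn = min(tp, npos), min(tn, nneg)
        cm = ConfusionMatrix(tp=tp, fp=nneg - tn, fn=npos - tp, tn=tn)
        printed = tuple(
            float(round_half_up_pct(*{
                "sensitivity": (tp, npos),
                "specificity": (tn, nneg),
                "ppv": (tp, tp + cm.fp) if tp + cm.fp else (0, 1),
                "npv": (tn, cm.fn + tn) if cm.fn + tn else (0, 1),
            }[m]))
            for m in ("sensitivity", "specificity", "ppv", "npv")
        )
        # degenerate rows (empty PPV/NPV denominators) are skipped
        if tp + cm.fp == 0 or cm.fn + tn == 0:
            return
        assert cm in invert_rounded_table(printed, npos, nneg)


def test_round_half_up_is_half_up():
    assert round_half_up_pct(1, 16) == Fraction("6.3")  # 6.25 rounds up
    assert round_half_up_pct(5, 8) == Fraction("62.5")
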