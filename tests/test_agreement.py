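import numpy as np
import pytest

from cacskit.agreement import (
    CategoricalPairs,
    DegenerateDataError,
    PairedScores,
    bland_altman,
    confuser_leak_fraction,
    f1_per_vessel,
    icc,
    mcnemar,
    paired_t,
    reclassification_table,
    run_battery,
    scores_to_long,
    wilcoxon_signed_rank,
)
from cacskit.core_io import VesselLabelMask


def _pairs(x, y):
    return PairedScores(case_ids=[f"c{i}" for i in range(len(x))], x=x, y=y)


class TestIcc:
    def test_matches_hand_anova_on_four_pairs(self):
        # two-way ANOVA by hand: MSR = 10/3, MSC = 2, MSE = 0 -> ICC = 10/13
        result = icc(_pairs([1, 2, 3, 4], [2, 3, 4, 5]))
        assert result["icc"] == pytest.approx(10 / 13, abs=1e-12)

    def test_identical_raters_give_unity(self):
        result = icc(_pairs([1, 2, 3, 4], [1, 2, 3, 4]))
        assert result["icc"] == pytest.approx(1.0)
        assert result["ci95"] == (1.0, 1.0)

    def test_anticorrelated_raters_give_nonpositive_icc(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert icc(_pairs(x, -x))["icc"] <= 0.0

    def test_needs_three_pairs_and_nonconstant_data(self):
        with pytest.raises(DegenerateDataError):
            icc(_pairs([1, 2], [1, 2]))
        with pytest.raises(DegenerateDataError):
            icc(_pairs([3, 3, 3], [3, 3, 3]))


class TestBlandAltman:
    def test_zero_differences_collapse_the_limits(self):
        result = bland_altman(_pairs([1, 2, 3], [1, 2, 3]))
        assert result["loa_low"] == result["loa_high"] == 0.0
        assert result["n_outside"] == 0

    def test_alternating_unit_differences_closed_form(self):
        result = bland_altman(_pairs([1, -1, 1, -1], [0, 0, 0, 0]))
        sd = 2 / np.sqrt(3)
        assert result["mean_diff"] == 0.0
        assert result["sd_diff"] == pytest.approx(sd)
        assert result["loa_high"] == pytest.approx(1.96 * sd)
        assert result["loa_low"] == pytest.approx(-1.96 * sd)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = bland_altman(_pairs(x, y))
        shifted = bland_altman(_pairs(x + 5.0, y))
        assert shifted["mean_diff"] == pytest.approx(base["mean_diff"] + 5.0)
        assert shifted["sd_diff"] == pytest.approx(base["sd_diff"])
        assert shifted["loa_low"] == pytest.approx(base["loa_low"] + 5.0)


class TestPairedT:
    def test_hand_computed_statistic(self):
        # differences (1,1,1,-1): mean 0.5, sd 1 -> t = 0.5/(1/2) = 1
        t_stat, p = paired_t(_pairs([1, 1, 1, -1], [0, 0, 0, 0]))
        assert t_stat == pytest.approx(1.0)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(1.0, df=3))

    def test_identical_arms_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t(_pairs([1, 2, 3], [1, 2, 3]))


class TestMcnemar:
    def test_single_discordant_pair_exact_p_is_one(self):
        pairs = CategoricalPairs(case_ids=list("ab"), auto=[True, False],
                                 manual=[False, False])
        result = mcnemar(pairs)
        assert (result["b"], result["c"]) == (1, 0)
        assert result["p"] == pytest.approx(1.0)

    def test_no_discordance_is_p_one_by_convention(self):
        pairs = CategoricalPairs(case_ids=list("ab"), auto=[True, False],
                                 manual=[True, False])
        assert mcnemar(pairs)["p"] == 1.0

    def test_binomial_tail_b6_c1(self):
        # exact two-sided p = 2 * sum_{k<=1} C(7,k) / 2^7 = 0.125
        pairs = CategoricalPairs(case_ids=list("abcdefg"),
                                 auto=[1, 1, 1, 1, 1, 1, 0],
                                 manual=[0, 0, 0, 0, 0, 0, 1])
        result = mcnemar(pairs)
        assert (result["b"], result["c"]) == (6, 1)
        assert result["p"] == pytest.approx(0.125)

    def test_large_discordance_uses_chi_square(self):
        n = 40
        pairs = CategoricalPairs(case_ids=[str(i) for i in range(n)],
                                 auto=[i % 2 == 0 for i in range(n)],
                                 manual=[i % 2 == 1 for i in range(n)])
        assert mcnemar(pairs)["method"] == "chi2-cc"


class TestWilcoxon:
    def test_opposite_unit_differences_are_symmetric(self):
        pairs = CategoricalPairs(case_ids=list("ab"), auto=["A1", "A0"],
                                 manual=["A0", "A1"])
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(1.0)

    def test_identical_vectors_warn_and_return_one(self):
        pairs = CategoricalPairs(case_ids=list("abc"),
                                 auto=["A1", "A2", "A0"],
                                 manual=["A1", "A2", "A0"])
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(pairs)[1] == 1.0

    def test_single_discordant_pair_conventions(self):
        # among 46 cases one A0 read as A1: exact drop-zeros p = 1.0, the
        # normal-approximation convention gives p = 2*(1-Phi(1)) = 0.317
        auto = ["A1"] + ["A0"] * 45
        manual = ["A0"] * 46
        pairs = CategoricalPairs(case_ids=[str(i) for i in range(46)],
                                 auto=auto, manual=manual)
        assert wilcoxon_signed_rank(pairs, method="exact")[1] == pytest.approx(1.0)
        assert wilcoxon_signed_rank(pairs, method="approx")[1] == pytest.approx(
            0.31731050786, abs=1e-6)


class TestF1:
    def _mask(self, labels):
        return VesselLabelMask(labels=np.asarray(labels, dtype=np.int64),
                               spacing=(3.0, 0.5, 0.5))

    def test_perfect_prediction_is_unity_for_present_labels(self):
        labels = np.zeros((2, 8, 8))
        labels[0, 2:4, 2:4] = 1
        labels[1, 4:6, 4:6] = 4
        mask = self._mask(labels)
        f1 = f1_per_vessel(mask, mask)
        assert f1["LM"] == 1.0 and f1["RCA"] == 1.0
        assert f1["LAD"] is None and f1["LCX"] is None

    def test_empty_prediction_scores_zero(self):
        truth = np.zeros((1, 8, 8))
        truth[0, 2:4, 2:4] = 2
        f1 = f1_per_vessel(self._mask(np.zeros((1, 8, 8))), self._mask(truth))
        assert f1["LAD"] == 0.0

    def test_half_coverage_is_two_thirds(self):
        truth = np.zeros((1, 8, 8))
        truth[0, 1:3, 1:6] = 3  # 10 voxels
        pred = np.zeros((1, 8, 8))
        pred[0, 1, 1:6] = 3  # 5 of them, no false positives
        assert f1_per_vessel(self._mask(pred), self._mask(truth))["LCX"] == \
            pytest.approx(2 * 5 / (2 * 5 + 0 + 5))

    def test_confuser_leak_fraction(self):
        truth = np.zeros((1, 8, 8))
        truth[0, 2:4, 2:6] = 5  # 8 confuser voxels
        pred = np.zeros((1, 8, 8))
        pred[0, 2, 2:6] = 1  # 4 of them called LM
        pred[0, 3, 2:6] = 5
        assert confuser_leak_fraction(self._mask(pred), self._mask(truth)) == \
            pytest.approx(0.5)
        no_confuser = self._mask(np.zeros((1, 8, 8)))
        assert confuser_leak_fraction(no_confuser, no_confuser) is None


class TestReclassification:
    def test_identical_vectors_make_a_diagonal_table(self):
        pairs = CategoricalPairs(case_ids=list("abcd"),
                                 auto=["A0", "A1", "A1", "A3"],
                                 manual=["A0", "A1", "A1", "A3"])
        table = reclassification_table(pairs)
        off_diag = table.loc["A0":"A3", "A0":"A3"].to_numpy()
        assert off_diag.sum() == np.trace(off_diag) == 4

    def test_single_shift_moves_one_marginal_count(self):
        auto = ["A1"] + ["A0"] * 4 + ["A2"] * 2
        manual = ["A0"] * 5 + ["A2"] * 2
        pairs = CategoricalPairs(case_ids=[str(i) for i in range(7)],
                                 auto=auto, manual=manual)
        table = reclassification_table(pairs)
        assert table.loc["A1", "A0"] == 1
        assert table.loc["Total", "Total"] == 7
        assert table.loc["A0", "Total"] == 4
        assert table.loc["Total", "A0"] == 5


class TestCalibration:
    def test_paired_t_type_i_error_is_near_nominal(self):
        rng = np.random.default_rng(42)
        reps, n = 2000, 20
        diffs = rng.normal(size=(reps, n))
        from scipy import stats

        p = stats.ttest_1samp(diffs, 0.0, axis=1).pvalue
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_loa_contains_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10_000)
        result = bland_altman(_pairs(x, np.zeros_like(x)))
        inside = 1.0 - result["n_outside"] / result["n"]
        assert 0.93 <= inside <= 0.97


def test_battery_on_identical_tables_is_the_perfect_agreement_fixture(cohort10):
    from cacskit.scoring import score_case

    scores = {c.record.case_id: score_case(c.volume, c.mask)
              for c in cohort10}
    auto = scores_to_long(scores, "automatic")
    manual = scores_to_long(scores, "manual")
    battery = run_battery(auto, manual)
    as_total = battery["continuous"]["AS/Total"]
    assert as_total["icc"]["icc"] == pytest.approx(1.0)
    assert as_total["bland_altman"]["loa_low"] == 0.0
    assert as_total["bland_altman"]["loa_high"] == 0.0
    assert as_total["paired_t"]["p"] == 1.0
    for vessel_entry in battery["mcnemar"].values():
        assert vessel_entry["p"] == 1.0
    for cat_entry in battery["cac_drs"].values():
        assert cat_entry["wilcoxon"]["p"] == 1.0


def test_battery_detects_a_seeded_perturbation(cohort10):
    from cacskit.phantom import perturb_mask
    from cacskit.scoring import score_case

    calcified = [c for c in cohort10 if c.certificate.n_vessels > 0]
    manual_scores = {c.record.case_id: score_case(c.volume, c.mask)
                     for c in calcified}
    auto_scores = {
        c.record.case_id: score_case(
            c.volume, perturb_mask(c.mask, "drop-smallest-lesion"))
        for c in calcified
    }
    battery = run_battery(scores_to_long(auto_scores, "automatic"),
                          scores_to_long(manual_scores, "manual"))
    ba = battery["continuous"]["AS/Total"]["bland_altman"]
    assert ba["mean_diff"] < 0.0  # dropping lesions can only lower scores
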