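import numpy as np
import pytest
import scipy.stats

from qsrec.errors import DomainError, SchemaError
from qsrec.stats import (
    GroupSummary,
    anova_from_summary,
    bonferroni,
    chi_square_gof,
    fleiss_kappa,
    paired_t,
    transition_summary,
)


def reconstruct_group(n: int, mean: float, sd: float, rng=None) -> np.ndarray:
    """Data with exactly the requested mean and sample SD (standardized base)."""
    base = np.zeros(n)
    base[0], base[1] = -1.0, 1.0
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


class TestAnovaFromSummary:
    BASELINE = [(20, 22.25, 3.40), (25, 20.36, 5.60)]

    def test_printed_baseline_row(self):
        """Two-group baseline row: F 1.75, eta2p 0.04, observed power 0.25."""
        res = anova_from_summary(self.BASELINE)
        assert res.F == pytest.approx(1.75, abs=0.01)
        assert round(res.eta2p, 2) == 0.04
        assert round(res.observed_power, 2) == 0.25
        assert (res.df_between, res.df_within) == (1, 43)

    def test_equal_means_give_zero_f(self):
        res = anova_from_summary([(10, 5.0, 1.0), (10, 5.0, 2.0)])
        assert res.F == 0.0 and res.eta2p == 0.0

    def test_hand_computed_three_point_groups(self):
        """SSb = 6, SSw = 4 -> F = 6.0, eta2p = 0.6."""
        res = anova_from_summary([(3, 1.0, 1.0), (3, 3.0, 1.0)])
        assert res.F == pytest.approx(6.0, abs=1e-12)
        assert res.eta2p == pytest.approx(0.6, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            anova_from_summary([(1, 5.0, 1.0), (10, 5.0, 1.0)])

    def test_degenerate_zero_variation_rejected(self):
        with pytest.raises(DomainError):
            anova_from_summary([(5, 2.0, 0.0), (5, 2.0, 0.0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_anova_on_reconstructed_data(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [
            (int(rng.integers(3, 40)), float(rng.normal(20, 5)),
             float(rng.uniform(0.5, 8)))
            for _ in range(k)
        ]
        res = anova_from_summary(groups)
        data = [reconstruct_group(*g) for g in groups]
        F_direct, p_direct = scipy.stats.f_oneway(*data)
        assert res.F == pytest.approx(F_direct, rel=1e-9, abs=1e-9)
        assert res.p == pytest.approx(p_direct, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_groups_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [
            (int(rng.integers(3, 30)), float(rng.normal(0, 3)), float(rng.uniform(0.5, 4)))
            for _ in range(2)
        ]
        res = anova_from_summary(groups)
        data = [reconstruct_group(*g) for g in groups]
        t, _ = scipy.stats.ttest_ind(*data)  # pooled-variance two-sample t
        assert res.F == pytest.approx(t**2, rel=1e-9)


class TestChiSquareGof:
    def test_perfect_fit_is_zero(self):
        res = chi_square_gof([10, 10, 10], [10, 10, 10])
        assert res.chi2 == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_uniform(self):
        """(50,30,20) vs uniform: 8.333 + 0.333 + 5.333 = 14.0."""
        res = chi_square_gof([50, 30, 20])
        assert res.chi2 == pytest.approx(14.0, abs=1e-9)
        assert res.df == 2

    def test_proportions_rescaled(self):
        res = chi_square_gof([50, 30, 20], [0.5, 0.3, 0.2])
        assert res.chi2 == 0.0

    def test_single_category_rejected(self):
        with pytest.raises(DomainError):
            chi_square_gof([30])

    def test_zero_expected_rejected(self):
        with pytest.raises(DomainError):
            chi_square_gof([1, 2], [0, 3])

    def test_category_permutation_invariance(self):
        obs, exp = [40, 25, 35], [30, 30, 40]
        a = chi_square_gof(obs, exp).chi2
        b = chi_square_gof(obs[::-1], exp[::-1]).chi2
        assert a == pytest.approx(b)

    def test_agrees_with_scipy(self):
        res = chi_square_gof([50, 30, 20])
        chi2, p = scipy.stats.chisquare([50, 30, 20])
        assert res.chi2 == pytest.approx(chi2) and res.p == pytest.approx(p)


class TestFleissKappa:
    def test_complete_agreement(self):
        mat = [[3, 0], [0, 3], [3, 0], [0, 3]]
        res = fleiss_kappa(mat)
        assert res.kappa == pytest.approx(1.0)
        assert res.fleiss_band == "excellent"

    def test_hand_computed_two_subject_example(self):
        """P-bar = 2/3, Pe-bar = 13/18 -> kappa = -0.2."""
        res = fleiss_kappa([[3, 0], [2, 1]])
        assert res.kappa == pytest.approx(-0.2, abs=1e-12)

    def test_bands_at_0_84(self):
        """kappa 0.84: excellent per Fleiss, very good per Altman."""
        from qsrec.stats import _altman_band, _fleiss_band

        assert _fleiss_band(0.84) == "excellent"
        assert _altman_band(0.84) == "very good"

    @pytest.mark.parametrize(
        "kappa,fleiss,altman",
        [(0.2, "poor", "poor"), (0.5, "intermediate-good", "moderate"),
         (0.7, "intermediate-good", "good"), (0.76, "excellent", "good"),
         (0.81, "excellent", "very good")],
    )
    def test_band_edges(self, kappa, fleiss, altman):
        from qsrec.stats import _altman_band, _fleiss_band

        assert _fleiss_band(kappa) == fleiss and _altman_band(kappa) == altman

    def test_inconsistent_row_sums_rejected(self):
        with pytest.raises(SchemaError):
            fleiss_kappa([[3, 0], [2, 2]])

    def test_degenerate_agreement_rejected(self):
        with pytest.raises(DomainError):
            fleiss_kappa([[3, 0], [3, 0]])

    def test_subject_order_and_category_relabeling_invariance(self):
        mat = np.array([[2, 1, 0], [0, 2, 1], [1, 1, 1], [3, 0, 0]])
        base = fleiss_kappa(mat).kappa
        assert fleiss_kappa(mat[::-1]).kappa == pytest.approx(base)
        assert fleiss_kappa(mat[:, [2, 0, 1]]).kappa == pytest.approx(base)


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(DomainError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_constant_shift_rejected(self):
        with pytest.raises(DomainError):
            paired_t([1, 2, 3], [3, 4, 5])

    def test_hand_computed_example(self):
        """diffs (-1,-2,0): mean -1, sd 1 -> t = -1.732, d = -1."""
        res = paired_t([1, 2, 3], [2, 4, 3])
        assert res.t == pytest.approx(-np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.d == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        before, after = rng.normal(size=24), rng.normal(size=24)
        res = paired_t(before, after)
        t, p = scipy.stats.ttest_rel(before, after)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.01], [0.01]), ([0.01, 0.02, 0.03], [0.03, 0.06, 0.09]),
         ([0.5, 0.9], [1.0, 1.0])],
    )
    def test_adjustment(self, ps, expected):
        assert bonferroni(ps) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bonferroni([0.5, 1.2])


class TestTransitionSummary:
    def test_all_neutral_to_positive(self):
        res = transition_summary([("neutral", "positive")] * 7)
        assert res.row_percentages["neutral"]["positive"] == 100.0
        assert res.counts["neutral"]["positive"] == 7

    def test_eighty_twenty_split(self):
        pairs = [("negative", "positive")] * 4 + [("negative", "neutral")]
        res = transition_summary(pairs)
        assert res.row_percentages["negative"]["positive"] == pytest.approx(80.0)
        assert res.row_percentages["negative"]["neutral"] == pytest.approx(20.0)

    def test_empty_rows_flagged_undefined(self):
        res = transition_summary([])
        assert all(v is None for v in res.row_percentages.values())
        assert sum(sum(r.values()) for r in res.counts.values()) == 0

    def test_unknown_valence_rejected(self):
        with pytest.raises(DomainError):
            transition_summary([("happy", "positive")])

    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(8)
        labels = ["positive", "negative", "neutral"]
        pairs = [(labels[int(rng.integers(3))], labels[int(rng.integers(3))])
                 for _ in range(200)]
        res = transition_summary(pairs)
        for row, percents in res.row_percentages.items():
            if percents is not None:
                assert sum(percents.values()) == pytest.approx(100.0, abs=0.01)
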