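import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from xsc.conservation import (
    age_trend,
    age_trend_counts,
    compare_to_null,
    correlation_null,
    fisher_combine,
    pergene_correlation,
    pergroup_correlation,
    stratified_fisher,
    theoretical_r_distribution,
)


def frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by direct summation of hypergeometric point masses.

    Margins: row1 = a+b draws, column1 total K = a+c, population
    N = a+b+c+d.
    """
    n_draw, K, N = a + b, a + c, a + b + c + d
    total = 0.0
    for x in range(max(0, n_draw + K - N), min(n_draw, K) + 1):
        if x >= a:
            total += (
                math.comb(K, x) * math.comb(N - K, n_draw - x) / math.comb(N, n_draw)
            )
    return total


class TestPerGeneCorrelation:
    def test_copied_matrix_gives_unit_r(self):
        rng = np.random.default_rng(0)
        a = frame(rng.normal(size=(50, 6)))
        res = pergene_correlation(a, a.copy())
        assert np.allclose(res.loc[res["defined"], "r"], 1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = frame(rng.normal(size=(40, 5)))
        res = pergene_correlation(a, 2.0 * a + 3.0)
        assert np.allclose(res["r"], 1.0)

    def test_independent_rows_center_at_zero(self):
        rng = np.random.default_rng(2)
        a = frame(rng.normal(size=(2000, 15)))
        b = frame(rng.normal(size=(2000, 15)))
        res = pergene_correlation(a, b)
        assert abs(res["r"].median()) < 0.05

    def test_constant_row_undefined_and_counted(self):
        a = frame([[1, 2, 3], [5, 5, 5]])
        b = frame([[1, 2, 3], [1, 2, 3]])
        res = pergene_correlation(a, b)
        assert res["defined"].tolist() == [True, False]

    def test_too_few_cell_types_raises(self):
        a = frame([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            pergene_correlation(a, a)


class TestPerGroupCorrelation:
    def test_identical_matrices(self):
        rng = np.random.default_rng(3)
        a = frame(rng.normal(size=(30, 4)))
        res = pergroup_correlation(a, a.copy())
        assert np.allclose(res["r"], 1.0)

    def test_gene_shifts_lower_per_cell_type_r(self):
        # gene-specific multiplicative divergence lowers correlation
        # across genes within each cell type
        rng = np.random.default_rng(4)
        a = frame(rng.normal(5, 2, size=(500, 6)))
        shifts = np.where(rng.random(500) < 0.5, 2.0, 0.0)
        b_shifted = a + shifts[:, None] * np.sign(rng.normal(size=(500, 1)))
        r_clean = pergroup_correlation(a, a + rng.normal(0, 0.5, a.shape)).r.mean()
        r_div = pergroup_correlation(a, b_shifted + rng.normal(0, 0.5, a.shape)).r.mean()
        assert r_div < r_clean


class TestTheoreticalNull:
    @pytest.mark.parametrize("n", [5, 10, 50])
    def test_density_integrates_to_one(self, n):
        dist = theoretical_r_distribution(n)
        integral, _ = quad(dist.pdf, -1, 1)
        assert integral == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n", [5, 10, 50])
    def test_variance_matches_closed_form(self, n):
        dist = theoretical_r_distribution(n)
        second, _ = quad(lambda r: r * r * dist.pdf(r), -1, 1)
        assert second == pytest.approx(1.0 / (n - 1), rel=1e-8)

    def test_symmetric_cdf_at_zero(self):
        assert theoretical_r_distribution(100).cdf(0.0) == pytest.approx(0.5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            theoretical_r_distribution(3)


class TestPermutationNulls:
    def test_gene_permute_destroys_pairing(self):
        rng = np.random.default_rng(5)
        a = frame(rng.normal(size=(500, 8)))
        null = correlation_null(a, a.copy(), "gene_permute", n_draws=2, seed=1)
        assert abs(np.median(null)) < 0.1
        matched = pergene_correlation(a, a.copy())
        assert np.allclose(matched["r"], 1.0)

    def test_sample_permute_agrees_with_theoretical(self):
        # on Gaussian data the permutation and closed-form nulls coincide
        rng = np.random.default_rng(6)
        a = frame(rng.normal(size=(2000, 15)))
        b = frame(rng.normal(size=(2000, 15)))
        null = correlation_null(a, b, "sample_permute", n_draws=1, seed=2)
        dist = correlation_null(a, b, "theoretical_normal")
        from scipy.stats import ks_1samp

        assert ks_1samp(null, dist.cdf).pvalue > 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        a = frame(rng.normal(size=(50, 5)))
        b = frame(rng.normal(size=(50, 5)))
        n1 = correlation_null(a, b, "gene_permute", n_draws=3, seed=9)
        n2 = correlation_null(a, b, "gene_permute", n_draws=3, seed=9)
        assert np.array_equal(n1, n2)


class TestCompareToNull:
    def test_identical_sets_give_half(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        _, p = compare_to_null(x, x)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_complete_separation(self):
        _, p = compare_to_null(np.ones(50), np.zeros(50))
        assert p < 1e-10

    def test_power_on_conserved_correlations(self):
        rng = np.random.default_rng(9)
        observed = np.clip(rng.normal(0.5, 0.2, size=2000), -1, 1)
        null = np.clip(rng.normal(0.0, 0.25, size=2000), -1, 1)
        _, p = compare_to_null(observed, null)
        assert p < 1e-10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_to_null([], [0.1])


class TestStratifiedFisher:
    @staticmethod
    def flags_from_table(a, b, c, d):
        # a: DE & stratum, b: DE & not, c: notDE & stratum, d: notDE & not
        de, stratum = {}, {}
        i = 0
        for count, is_de, in_s in ((a, 1, 1), (b, 1, 0), (c, 0, 1), (d, 0, 0)):
            for _ in range(count):
                de[f"g{i}"] = bool(is_de)
                stratum[f"g{i}"] = bool(in_s)
                i += 1
        return de, stratum

    def test_balanced_table_is_null(self):
        de, s = self.flags_from_table(10, 10, 10, 10)
        odds, p = stratified_fisher(de, s)
        assert odds == 1.0
        assert p > 0.5

    def test_worked_example_against_tail_oracle(self):
        de, s = self.flags_from_table(30, 20, 10, 40)
        odds, p = stratified_fisher(de, s)
        assert odds == pytest.approx(6.0)
        assert p == pytest.approx(hypergeom_tail_oracle(30, 20, 10, 40), rel=1e-10)

    def test_matches_tail_oracle_over_margin_grid(self):
        # exhaustive sweep of 2x2 tables with all margins <= 12
        for a in range(0, 13, 3):
            for b in range(0, 13, 4):
                for c in range(0, 13, 4):
                    for d in range(0, 13, 3):
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        de, s = self.flags_from_table(a, b, c, d)
                        _, p = stratified_fisher(de, s)
                        assert p == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)

    def test_planted_promoter_effect_recovered(self, small_dataset):
        cm_a, cm_b, ortho, truth = small_dataset
        de = {g: g in truth.divergent_genes for g in ortho["gene_a"]}
        nonortho = {g: not truth.promoter_ortho[g] for g in ortho["gene_a"]}
        odds, p = stratified_fisher(de, nonortho)
        assert odds > 1.0
        assert p < 0.05

    def test_empty_stratum_rejected(self):
        de, s = self.flags_from_table(5, 0, 5, 0)
        with pytest.raises(ValueError):
            stratified_fisher(de, s)


class TestAgeTrend:
    def test_equal_rates_are_null(self):
        res = age_trend_counts([200, 200, 200], [1000, 1000, 1000])
        assert abs(res.slope) < 1e-6
        assert res.p_one_sided == pytest.approx(0.5, abs=0.01)

    def test_increasing_rates_match_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        y = [rng.binomial(1000, r) for r in (0.2, 0.4, 0.6)]
        res = age_trend_counts(y, [1000, 1000, 1000])
        assert res.slope > 0
        assert res.p_one_sided < 1e-6
        # brute-force profile-likelihood grid search over the slope
        yv, nv, k = np.array(y, float), np.full(3, 1000.0), np.arange(3.0)
        grid = np.arange(-2, 2, 1e-5)
        lls = []
        for bb in grid:
            aa = np.log(yv.sum()) - np.log((nv * np.exp(bb * k)).sum())
            eta = aa + bb * k + np.log(nv)
            lls.append((yv * eta - np.exp(eta)).sum())
        assert abs(grid[int(np.argmax(lls))] - res.slope) < 1e-3

    def test_reversed_rates_give_large_one_sided_p(self):
        res = age_trend_counts([600, 400, 200], [1000, 1000, 1000])
        assert res.slope < 0
        assert res.p_one_sided > 0.5

    def test_poisson_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            n = np.array([400, 400, 400])
            y = rng.poisson(0.3 * n)
            res = age_trend_counts(y, n)
            rejections += res.p_one_sided < 0.05
        assert abs(rejections / reps - 0.05) < 0.03

    def test_offset_absorbs_unequal_class_sizes(self):
        # same DE rate but very different class sizes: no trend with the
        # offset, spurious trend without it
        res = age_trend_counts([10, 40, 160], [100, 400, 1600])
        assert abs(res.slope) < 1e-6
        res_no = age_trend_counts([10, 40, 160], [100, 400, 1600], use_offset=False)
        assert res_no.slope > 1.0

    def test_flag_interface_drops_empty_class(self):
        de = {f"g{i}": i % 4 == 0 for i in range(100)}
        ages = {f"g{i}": ("bilateria", "mammal")[i % 2] for i in range(100)}
        with pytest.warns(UserWarning, match="vertebrate"):
            res = age_trend(de, ages)
        assert set(res.class_counts) == {"bilateria", "vertebrate", "mammal"}


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_moderate_p_values(self):
        # X^2 = -2 ln(0.05) * 2 = 11.98 on 4 df
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)

    def test_single_p_identity(self):
        assert fisher_combine([0.2]) == pytest.approx(0.2, rel=1e-9)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_combine([0.0, 0.5]) < 1e-100
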