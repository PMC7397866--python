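import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xsc.expression import (
    CountMatrix,
    PromoterRegion,
    SampleInfo,
    average_replicates,
    dominant_promoter,
    estimate_alpha,
    filter_by_n_fraction,
    merge_intervals,
    normalize_counts,
    size_factors,
    vst,
)
from tests.conftest import nb_counts


def make_matrix(values: dict, species="human", cell_type="ct0") -> CountMatrix:
    counts = pd.DataFrame(values, index=[f"g{i}" for i in range(len(next(iter(values.values()))))])
    samples = [SampleInfo(sid, species, cell_type, i + 1) for i, sid in enumerate(values)]
    return CountMatrix(counts, samples)


class TestSizeFactors:
    def test_totals_divided_by_median(self):
        cm = make_matrix({"s1": [50, 50], "s2": [100, 100]})
        f = size_factors(cm)
        assert np.allclose(f.to_numpy(), [100 / 150, 200 / 150])

    def test_equal_totals_give_unit_factors(self):
        cm = make_matrix({"s1": [30, 70], "s2": [60, 40], "s3": [10, 90]})
        assert np.allclose(size_factors(cm).to_numpy(), 1.0)

    def test_single_sample_factor_is_one(self):
        cm = make_matrix({"s1": [5, 7]})
        assert np.allclose(size_factors(cm).to_numpy(), [1.0])

    def test_zero_total_sample_is_named(self):
        cm = make_matrix({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="s2"):
            size_factors(cm)

    def test_scaling_one_sample_leaves_others_normalized_counts(self):
        # scaling a non-median sample by c changes only its own factor
        cm1 = make_matrix({"s1": [10, 20], "s2": [40, 20], "s3": [100, 100]})
        cm2 = make_matrix({"s1": [10, 20], "s2": [40, 20], "s3": [200, 200]})
        n1 = normalize_counts(cm1)
        n2 = normalize_counts(cm2)
        pd.testing.assert_series_equal(n1["s1"], n2["s1"])
        pd.testing.assert_series_equal(n1["s2"], n2["s2"])
        pd.testing.assert_series_equal(n1["s3"], n2["s3"])


class TestAlphaEstimation:
    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, 200.0, 0.05, (500, 3))
        cm = make_matrix({f"s{i}": counts[:, i] for i in range(3)})
        assert 0.03 <= estimate_alpha(cm) <= 0.08

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(150.0, size=(800, 4))
        cm = make_matrix({f"s{i}": counts[:, i] for i in range(4)})
        assert estimate_alpha(cm) <= 0.01

    def test_identical_replicates_floor_at_zero(self):
        col = np.array([10, 20, 30, 40])
        cm = make_matrix({"s1": col, "s2": col})
        assert estimate_alpha(cm) == 0.0

    def test_no_replicated_group_raises(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["g0", "g1"])
        samples = [SampleInfo("s1", "human", "ct0", 1), SampleInfo("s2", "human", "ct1", 1)]
        with pytest.raises(ValueError, match="alpha"):
            estimate_alpha(CountMatrix(counts, samples))


class TestVST:
    def test_zero_count_quarter_alpha_is_exactly_zero(self):
        assert vst(0, 0.25) == pytest.approx(0.0, abs=1e-12)

    def test_large_x_asymptote_is_log2(self):
        assert vst(1e6, 0.1) == pytest.approx(np.log2(1e6), abs=0.01)

    @given(
        x1=st.floats(0, 1e8),
        dx=st.floats(1e-6, 1e6),
        alpha=st.floats(1e-4, 2.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_strictly_increasing(self, x1, dx, alpha):
        assert vst(x1 + dx, alpha) > vst(x1, alpha)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            vst(10.0, 0.0)

    def test_stabilizes_nb_variance_across_deciles(self):
        # raw-count variance spans orders of magnitude across the mean
        # range; after the VST the per-decile variances are within 3x
        rng = np.random.default_rng(7)
        mu = np.exp(rng.uniform(np.log(5), np.log(5000), size=8000))
        alpha = 0.1
        counts = nb_counts(rng, mu[:, None], alpha, (len(mu), 10))
        deciles = pd.qcut(mu, 10, labels=False)
        raw_var = np.array([counts[deciles == d].var(axis=1).mean() for d in range(10)])
        t = vst(counts, alpha)
        vst_var = np.array([t[deciles == d].var(axis=1).mean() for d in range(10)])
        assert raw_var.max() / raw_var.min() > 50
        assert vst_var.max() / vst_var.min() < 3


class TestAverageReplicates:
    def test_single_replicate_passthrough_and_pairs(self):
        values = pd.DataFrame({"a": [1.0, 3.0], "b": [3.0, 5.0], "c": [7.0, 9.0]})
        samples = [
            SampleInfo("a", "human", "ct0", 1),
            SampleInfo("b", "human", "ct0", 2),
            SampleInfo("c", "human", "ct1", 1),
        ]
        out = average_replicates(values, samples)
        assert out[("human", "ct0")].tolist() == [2.0, 4.0]
        assert out[("human", "ct1")].tolist() == [7.0, 9.0]

    def test_columns_sorted_by_species_then_cell_type(self):
        values = pd.DataFrame({"m1": [1.0], "h1": [2.0]})
        samples = [SampleInfo("m1", "mouse", "ct0", 1), SampleInfo("h1", "human", "ct0", 1)]
        out = average_replicates(values, samples)
        assert list(out.columns) == [("human", "ct0"), ("mouse", "ct0")]


class TestDominantPromoter:
    def test_argmax(self):
        assert dominant_promoter({"p1": 5, "p2": 10, "p3": 2}) == "p2"

    def test_single_promoter(self):
        assert dominant_promoter({"p1": 0}) == "p1"

    def test_tie_broken_by_lowest_start(self):
        assert dominant_promoter({"p1": 7, "p2": 7}, starts={"p1": 900, "p2": 100}) == "p2"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dominant_promoter({})


def write_fasta(path, seqs: dict):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


class TestNFractionFilter:
    def test_boundary_and_any_semantics(self, tmp_path):
        fa = tmp_path / "g.fa"
        # chr1: exactly 10% N (retained, strict inequality);
        # chr2: 101/1000 N (removed); chr3: clean
        write_fasta(
            fa,
            {
                "chr1": "N" * 100 + "A" * 900,
                "chr2": "N" * 101 + "C" * 899,
                "chr3": "G" * 1000,
            },
        )
        regions = [
            PromoterRegion("g_border", "chr1", ((0, 1000),)),
            PromoterRegion("g_over", "chr2", ((0, 1000),)),
            # one clean region plus one bad region -> removed ("any")
            PromoterRegion("g_any", "chr2", ((500, 600), (0, 200))[::-1]),
            PromoterRegion("g_clean", "chr3", ((100, 300),)),
        ]
        kept = filter_by_n_fraction(regions, fa)
        assert kept == ["g_border", "g_clean"]

    def test_region_clipped_at_chromosome_start(self, tmp_path):
        fa = tmp_path / "g.fa"
        write_fasta(fa, {"chr1": "N" * 30 + "A" * 270})
        # nominal span [-700, 300) clips to [0, 300): 30/300 = 10%, retained
        region = PromoterRegion("g_edge", "chr1", ((-700, 300),))
        assert filter_by_n_fraction([region], fa) == ["g_edge"]

    def test_missing_chromosome_is_named(self, tmp_path):
        fa = tmp_path / "g.fa"
        write_fasta(fa, {"chr1": "ACGT" * 100})
        with pytest.raises(ValueError, match="chrX"):
            filter_by_n_fraction([PromoterRegion("g", "chrX", ((0, 10),))], fa)


def test_merge_intervals_merges_overlaps():
    assert merge_intervals([(10, 20), (15, 30), (40, 50)]) == ((10, 30), (40, 50))


def test_count_matrix_tsv_round_trip(tmp_path, tiny_matrix):
    tiny_matrix.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
    back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(back.counts, tiny_matrix.counts)
    assert back.samples == tiny_matrix.samples


def test_count_matrix_rejects_negative_and_duplicate(tiny_matrix):
    bad = tiny_matrix.counts.copy()
    bad.iloc[0, 0] = -1
    with pytest.raises(ValueError, match="negative"):
        CountMatrix(bad, tiny_matrix.samples)
    dup = tiny_matrix.counts.copy()
    dup.index = ["gA", "gA", "gC", "gD"]
    with pytest.raises(ValueError, match="unique"):
        CountMatrix(dup, tiny_matrix.samples)
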