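import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stresscan.annotations_io import GeneModel, GenomeLayout, ValidationError
from stresscan.quantify import (
    active_genes,
    default_pseudocount,
    gene_density,
    geometric_mean_difference,
    library_scale,
    metagene_promoter,
    metagene_scaled,
    normalize_to_h3,
    ratio,
    zscore,
)

from conftest import make_track


@pytest.fixture
def big_layout():
    return GenomeLayout(("chr1",), (100_000,))


class TestGeneDensity:
    def test_uniform_track(self, layout):
        t = make_track(layout, {"chr1": [(0, 10_000, 2.0)]})
        g = GeneModel("a", "chr1", 2_000, 4_000, "+")
        assert gene_density(t, g, 500) == 2.0

    def test_piecewise_hand_summed_mean(self, layout):
        t = make_track(layout, {"chr1": [(0, 1_000, 1.0), (1_000, 2_000, 3.0)]})
        g = GeneModel("a", "chr1", 500, 1_500, "+")
        assert gene_density(t, g, 0) == 2.0

    def test_zero_track_gives_zero(self, layout):
        t = make_track(layout, {})
        g = GeneModel("a", "chr1", 500, 1_500, "+")
        assert gene_density(t, g, 500) == 0.0

    def test_concatenated_window_is_length_weighted_mean(self, layout):
        t = make_track(layout, {"chr1": [(0, 1_000, 1.0), (1_000, 4_000, 2.5)]})
        m1 = t.mean("chr1", 0, 1_000)
        m2 = t.mean("chr1", 1_000, 4_000)
        assert t.mean("chr1", 0, 4_000) == pytest.approx(
            (1_000 * m1 + 3_000 * m2) / 4_000, rel=1e-12
        )


class TestLibraryScale:
    def test_factors_to_common_million(self, layout):
        t1 = make_track(layout, {"chr1": [(0, 2_000, 1_000.0)]})  # total 2e6
        t2 = make_track(layout, {"chr1": [(0, 1_000, 1_000.0)]})  # total 1e6
        f = library_scale({"a": t1, "b": t2})
        assert f == {"a": 0.5, "b": 1.0}

    def test_equal_totals_equal_factors(self, layout):
        t1 = make_track(layout, {"chr1": [(0, 100, 3.0)]})
        t2 = make_track(layout, {"chr2": [(50, 150, 3.0)]})
        f = library_scale({"a": t1, "b": t2})
        assert f["a"] == f["b"]

    def test_post_scaling_totals_agree(self, layout):
        rng = np.random.default_rng(5)
        tracks = {}
        for i in range(4):
            vals = rng.uniform(0.1, 5.0, size=10)
            starts = np.arange(10) * 100
            tracks[i] = make_track(
                layout, {"chr1": list(zip(starts, starts + 100, vals))}
            )
        f = library_scale(tracks)
        totals = [tracks[i].scaled(f[i]).total() for i in tracks]
        assert np.allclose(totals, totals[0], rtol=1e-9)

    def test_zero_total_rejected(self, layout):
        with pytest.raises(ValidationError):
            library_scale({"a": make_track(layout, {})})


class TestRatios:
    def test_fold_change(self):
        assert ratio(3.0, 2.0, 0.0) == 1.5

    def test_h3_normalization(self):
        assert normalize_to_h3(3.0, 2.0) == 1.5

    @pytest.mark.parametrize("eps", [0.0, 0.1, 5.0])
    def test_identity_for_equal_inputs(self, eps):
        assert ratio(2.5, 2.5, eps) == 1.0

    def test_double_zero_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="0/0"):
            assert np.isnan(ratio(0.0, 0.0, 0.0))

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            ratio(-1.0, 2.0)

    def test_default_pseudocount_is_fraction_of_median(self):
        assert default_pseudocount([1.0, 2.0, 3.0]) == pytest.approx(0.02)


class TestZscore:
    def test_simple_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        z = zscore(rng.normal(5, 3, size=100))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-100, 100), min_size=3, max_size=30).filter(
            lambda v: np.std(v) > 1e-6
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
    )
    def test_shift_scale_invariance(self, x, a, b):
        np.testing.assert_allclose(
            zscore(a * np.asarray(x) + b), zscore(x), rtol=1e-7, atol=1e-7
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            zscore([1.0])
        with pytest.raises(ValidationError):
            zscore([2.0, 2.0, 2.0])


class TestGeometricMean:
    @pytest.mark.parametrize(
        "ratios,expected",
        [([2.0, 0.5], 1.0), ([4.0, 1.0], 2.0), ([1.2, 1.8], 1.4696938456699067)],
    )
    def test_values(self, ratios, expected):
        assert geometric_mean_difference(ratios) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean_difference([1.0, 0.0])


class TestMetagenePromoter:
    def test_uniform_track_gives_flat_profile(self, big_layout):
        t = make_track(big_layout, {"chr1": [(0, 100_000, 3.0)]})
        genes = [GeneModel("a", "chr1", 50_000, 60_000, "+"),
                 GeneModel("b", "chr1", 20_000, 30_000, "-")]
        p = metagene_promoter(t, genes, span=2_000, bin_width=100)
        np.testing.assert_allclose(p.mean, 3.0)
        assert (p.n_per_bin == 2).all()

    def test_minus_strand_is_orientation_flipped(self, big_layout):
        # minus-strand gene: downstream of the TSS means genomic left of end
        t = make_track(big_layout, {"chr1": [(9_000, 10_000, 5.0)]})
        g = GeneModel("a", "chr1", 5_000, 10_000, "-")
        p = metagene_promoter(t, [g], span=1_000, bin_width=500)
        # offsets [-1000, -500, 0, 500); signal in [9000,10000) = first 1 kb downstream
        np.testing.assert_allclose(p.mean, [0.0, 0.0, 5.0, 5.0])

    def test_linearity_in_the_track(self, big_layout):
        rng = np.random.default_rng(1)
        starts = np.arange(40) * 250
        va, vb = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        mk = lambda v: make_track(big_layout, {"chr1": list(zip(starts, starts + 250, v))})
        genes = [GeneModel("a", "chr1", 3_000, 6_000, "+"),
                 GeneModel("b", "chr1", 5_000, 8_000, "-")]
        pa = metagene_promoter(mk(va), genes, span=2_000, bin_width=100)
        pb = metagene_promoter(mk(vb), genes, span=2_000, bin_width=100)
        pab = metagene_promoter(mk(va + vb), genes, span=2_000, bin_width=100)
        np.testing.assert_allclose(pab.mean, pa.mean + pb.mean, rtol=1e-9)

    def test_edge_truncated_gene_contributes_covered_bins_only(self, big_layout):
        t = make_track(big_layout, {"chr1": [(0, 100_000, 1.0)]})
        g = GeneModel("a", "chr1", 500, 5_000, "+")  # TSS 500: upstream clipped
        p = metagene_promoter(t, [g], span=2_000, bin_width=500)
        assert p.n_per_bin.tolist() == [0, 0, 0, 1, 1, 1, 1, 1]

    def test_empty_gene_set_rejected(self, big_layout):
        t = make_track(big_layout, {})
        with pytest.raises(ValidationError):
            metagene_promoter(t, [], span=2_000, bin_width=100)

    def test_gene_order_invariance(self, big_layout):
        t = make_track(big_layout, {"chr1": [(0, 50_000, 1.0), (50_000, 100_000, 4.0)]})
        genes = [GeneModel("a", "chr1", 30_000, 40_000, "+"),
                 GeneModel("b", "chr1", 60_000, 70_000, "-"),
                 GeneModel("c", "chr1", 45_000, 55_000, "+")]
        p1 = metagene_promoter(t, genes, span=2_000, bin_width=100)
        p2 = metagene_promoter(t, genes[::-1], span=2_000, bin_width=100)
        np.testing.assert_array_equal(p1.mean, p2.mean)


class TestMetageneScaled:
    def test_uniform_track_gives_flat_profile(self, big_layout):
        t = make_track(big_layout, {"chr1": [(0, 100_000, 2.0)]})
        genes = [GeneModel("a", "chr1", 10_000, 20_000, "+")]
        p = metagene_scaled(t, genes, body_bins=50, flank=2_000, flank_bins=10)
        np.testing.assert_allclose(p.mean, 2.0)

    def test_body_confined_signal_leaves_flanks_empty(self, big_layout):
        t = make_track(big_layout, {"chr1": [(10_000, 20_000, 1.0)]})
        genes = [GeneModel("a", "chr1", 10_000, 20_000, "+")]
        p = metagene_scaled(t, genes, body_bins=20, flank=2_000, flank_bins=5)
        assert (p.mean[p.segment == "body"] == 1.0).all()
        assert (p.mean[p.segment != "body"] == 0.0).all()

    def test_rescaling_invariance_for_same_relative_shape(self, big_layout):
        # signal over the first half of each gene body, genes of 2 kb and 8 kb
        t = make_track(
            big_layout, {"chr1": [(10_000, 11_000, 2.0), (50_000, 54_000, 2.0)]}
        )
        g_short = [GeneModel("s", "chr1", 10_000, 12_000, "+")]
        g_long = [GeneModel("l", "chr1", 50_000, 58_000, "+")]
        ps = metagene_scaled(t, g_short, body_bins=10, flank=1_000, flank_bins=4)
        pl = metagene_scaled(t, g_long, body_bins=10, flank=1_000, flank_bins=4)
        np.testing.assert_allclose(
            ps.mean[ps.segment == "body"], pl.mean[pl.segment == "body"], rtol=1e-12
        )

    def test_minus_strand_flip(self, big_layout):
        # signal over the 5' half of a minus-strand gene (genomic right half)
        t = make_track(big_layout, {"chr1": [(15_000, 20_000, 1.0)]})
        g = [GeneModel("a", "chr1", 10_000, 20_000, "-")]
        p = metagene_scaled(t, g, body_bins=10, flank=1_000, flank_bins=2)
        body = p.mean[p.segment == "body"]
        np.testing.assert_allclose(body, [1] * 5 + [0] * 5)

    def test_short_genes_skipped_and_all_short_rejected(self, big_layout):
        t = make_track(big_layout, {"chr1": [(0, 100_000, 1.0)]})
        short = GeneModel("s", "chr1", 100, 150, "+")
        ok = GeneModel("l", "chr1", 10_000, 20_000, "+")
        p = metagene_scaled(t, [short, ok], body_bins=100)
        assert p.n_genes == 1
        with pytest.raises(ValidationError):
            metagene_scaled(t, [short], body_bins=100)


class TestActiveGenes:
    def test_zero_threshold_keeps_any_signal(self):
        d = pd.Series({"a": 0.0, "b": 0.5, "c": 2.0})
        assert list(active_genes(d)) == ["b", "c"]

    def test_threshold_above_max_empties_set(self):
        d = pd.Series({"a": 0.5, "b": 2.0})
        assert len(active_genes(d, threshold=5.0)) == 0

    def test_min_total_filter(self):
        d = pd.Series({"a": 0.5, "b": 0.5})
        totals = pd.Series({"a": 5.0, "b": 50.0})
        assert list(active_genes(d, totals=totals, min_total=10.0)) == ["b"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        d = pd.Series(rng.uniform(0, 3, 50), index=[f"g{i}" for i in range(50)])
        prev = set(active_genes(d, threshold=0.0))
        for thr in (0.5, 1.0, 2.0, 3.5):
            cur = set(active_genes(d, threshold=thr))
            assert cur <= prev
            prev = cur

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            active_genes(pd.Series({"a": 1.0}), threshold=-1.0)
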