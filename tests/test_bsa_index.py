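"""SNP-index, Δ(SNP-index), smoothing and region calling."""

import math

import numpy as np
import pandas as pd
import pytest

from bsamap.bsa_index import (
    AssociationRegion,
    call_regions,
    compute_index_table,
    delta_snp_index,
    filter_informative_snps,
    region_size_mb,
    smooth_delta,
    snp_index,
    span_kb,
)


class TestSnpIndex:
    def test_fraction_of_m_reads(self):
        assert snp_index(9, 3) == pytest.approx(0.75)

    def test_boundaries_and_symmetry(self):
        assert snp_index(0, 12) == 0.0
        assert snp_index(12, 0) == 1.0
        assert snp_index(7, 7) == 0.5

    def test_undefined_below_min_depth(self):
        assert math.isnan(snp_index(1, 2, min_depth=4))
        assert math.isnan(snp_index(0, 0))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            snp_index(-1, 5)


class TestDelta:
    def test_all_m_in_sterile_all_p_in_fertile_gives_plus_one(self):
        # sterile bulk entirely fertile-parent genome, fertile bulk entirely
        # sterile-parent genome
        assert delta_snp_index(snp_index(30, 0), snp_index(0, 30)) == 1.0

    def test_equal_indices_give_zero(self):
        assert delta_snp_index(snp_index(0, 30), snp_index(0, 30)) == 0.0
        assert delta_snp_index(snp_index(30, 0), snp_index(30, 0)) == 0.0

    def test_causal_configuration_gives_minus_one(self):
        # sterile bulk fixed for the sterile-parent allele, homozygous-
        # fertile bulk fixed for the fertile-parent allele
        assert delta_snp_index(snp_index(0, 30), snp_index(30, 0)) == -1.0

    def test_undefined_propagates(self):
        assert math.isnan(delta_snp_index(float("nan"), 0.5))

    def test_label_swap_negates_delta(self, rng):
        for _ in range(20):
            paa, maa, pab, mab = rng.integers(0, 40, size=4)
            d = delta_snp_index(snp_index(maa, paa), snp_index(mab, pab))
            d_swapped = delta_snp_index(snp_index(paa, maa), snp_index(pab, mab))
            if not math.isnan(d):
                assert d_swapped == pytest.approx(-d)


def _points(pos, delta, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "delta": delta})


class TestSmoothing:
    def test_constant_delta_smooths_to_itself(self):
        df = _points(range(1000, 11000, 1000), [0.8] * 10)
        out = smooth_delta(df, window_bp=5000)
        assert np.allclose(out["smoothed"], 0.8)

    def test_single_point_is_its_own_mean(self):
        out = smooth_delta(_points([100], [-0.4]), window_bp=1000)
        assert out["smoothed"].iloc[0] == pytest.approx(0.4)

    def test_uses_absolute_delta(self):
        out = smooth_delta(_points([100, 200], [0.5, -0.5]), window_bp=1000)
        assert np.allclose(out["smoothed"], 0.5)

    def test_min_markers_yields_undefined(self):
        out = smooth_delta(_points([100, 100_000], [0.5, 0.5]), window_bp=1000, min_markers=2)
        assert out["smoothed"].isna().all()

    def test_empty_input(self):
        out = smooth_delta(_points([], []), window_bp=1000)
        assert out.empty

    def test_matches_naive_recomputation(self, rng):
        n = 400
        pos = np.sort(rng.choice(np.arange(1, 500_000), size=n, replace=False))
        delta = rng.uniform(-1, 1, size=n)
        delta[rng.random(n) < 0.1] = np.nan
        df = _points(pos, delta)
        out = smooth_delta(df, window_bp=20_000, min_markers=1)
        for i in range(n):
            in_win = (np.abs(pos - pos[i]) <= 10_000) & ~np.isnan(delta)
            expected = np.abs(delta[in_win]).mean() if in_win.any() else np.nan
            got = out["smoothed"].iloc[i]
            assert (math.isnan(expected) and math.isnan(got)) or got == pytest.approx(expected)

    def test_loess_mode_tracks_constant_signal(self):
        df = _points(range(1000, 51000, 1000), [0.7] * 50)
        out = smooth_delta(df, window_bp=5000, method="loess", span=0.2)
        assert np.allclose(out["smoothed"], 0.7)


class TestRegionCalling:
    def test_printed_coordinates_reproduce_sizes(self):
        r1 = AssociationRegion("chr9", 2_628_112, 3_491_020, n_markers=63, peak_abs_delta=0.9)
        r2 = AssociationRegion("chr9", 4_304_282, 6_053_037, n_markers=127, peak_abs_delta=0.9)
        assert r1.size_mb == 0.86
        assert r2.size_mb == 1.75

    def test_span_kb(self):
        assert span_kb(2_522_791, 2_555_104) == 32

    def test_single_run_called(self):
        pos = list(range(10_000, 110_000, 10_000))
        val = [0.1, 0.1, 0.7, 0.8, 0.9, 0.8, 0.7, 0.1, 0.1, 0.1]
        df = _points(pos, [0.0] * 10).assign(smoothed=val)
        regions = call_regions(df, delta_threshold=0.6, min_markers=3, merge_gap_bp=1)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (30_000, 70_000)
        assert regions[0].peak_abs_delta == pytest.approx(0.9)

    def test_nearby_runs_merge(self):
        pos = list(range(10_000, 110_000, 10_000))
        val = [0.7, 0.7, 0.1, 0.7, 0.7, 0.7, 0.1, 0.1, 0.1, 0.1]
        df = _points(pos, [0.0] * 10).assign(smoothed=val)
        merged = call_regions(df, min_markers=3, merge_gap_bp=50_000)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (10_000, 60_000)
        split = call_regions(df, min_markers=2, merge_gap_bp=10_000)
        assert len(split) == 2

    def test_all_below_threshold_yields_nothing(self):
        df = _points([1, 2, 3], [0, 0, 0]).assign(smoothed=[0.5, 0.5, 0.5])
        assert call_regions(df, delta_threshold=0.6, min_markers=1) == []

    def test_regions_stay_per_chromosome(self):
        df = pd.concat(
            [
                _points([1000, 2000, 3000], [0] * 3, chrom="chr1").assign(smoothed=0.9),
                _points([1000, 2000, 3000], [0] * 3, chrom="chr2").assign(smoothed=0.9),
            ]
        )
        regions = call_regions(df, min_markers=2, merge_gap_bp=10_000)
        assert [r.chrom for r in regions] == ["chr1", "chr2"]


def test_region_size_rounding_matches_reported_total():
    sizes = [
        region_size_mb(2_628_112, 3_491_020),
        region_size_mb(3_838_547, 4_102_757),
        region_size_mb(4_304_282, 6_053_037),
        region_size_mb(7_178_780, 8_599_536),
    ]
    assert sizes == [0.86, 0.26, 1.75, 1.42]
    assert round(sum(sizes), 2) == 4.29


class TestFilterInformative:
    def _df(self, **cols):
        base = {
            "chrom": ["chr1"] * 3,
            "pos": [100, 200, 300],
            "allele_P": ["A", "A", "A"],
            "allele_M": ["C", "C", "A"],
        }
        base.update(cols)
        return pd.DataFrame(base)

    def test_same_allele_snps_dropped(self):
        out = filter_informative_snps(self._df())
        assert list(out["pos"]) == [100, 200]

    def test_heterozygous_parent_dropped(self):
        df = self._df(P_gt=["A/A", "A/C", "A/A"], M_gt=["C/C", "C/C", "C/C"])
        out = filter_informative_snps(df)
        assert list(out["pos"]) == [100]

    def test_shallow_parent_dropped(self):
        df = self._df(P_depth=[10, 2, 10], M_depth=[10, 10, 10])
        out = filter_informative_snps(df, min_depth=4)
        assert list(out["pos"]) == [100]


def test_delta_track_figure_written(tmp_path):
    df = _points(range(1000, 51000, 1000), [0.1] * 50)
    sm = smooth_delta(df, window_bp=5000)
    out = tmp_path / "track.png"
    from bsamap.bsa_index import plot_delta_track

    plot_delta_track(sm, out)
    assert out.stat().st_size > 0


def test_index_table_ranges_on_simulation(small_cross, small_snps, small_f2):
    from bsamap.synthetic_data import make_bulks_and_depths

    depths = make_bulks_and_depths(small_f2, small_snps, small_cross)
    idx = compute_index_table(depths)
    defined = idx.dropna(subset=["delta"])
    assert defined["index_aa"].between(0, 1).all()
    assert defined["index_ab"].between(0, 1).all()
    assert defined["delta"].between(-1, 1).all()
    sm = smooth_delta(idx, window_bp=50_000)
    assert sm["smoothed"].dropna().between(0, 1).all()
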