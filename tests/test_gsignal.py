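"""Coverage-track arithmetic, region definitions, meta-profiles, enrichment."""

import numpy as np
import pandas as pd
import pytest

from polkin.gsignal import (
    CoverageTrack,
    MetaProfile,
    cpm_normalize,
    define_regions,
    filter_expressed,
    infer_tss_tes,
    metagene,
    metasite,
    ratio_zscore,
    region_signal,
    relative_region_enrichment,
    smooth,
    subtract_background,
)


def _uniform_track(value=1.0, n=10_000, contig="chrI", units="counts"):
    return CoverageTrack(data={contig: np.full(n, float(value))}, units=units)


class TestCpmNormalize:
    def test_uniform_megabase(self):
        track = _uniform_track(1.0, n=1_000_000)
        out = cpm_normalize(track)
        assert out.units == "CPM"
        np.testing.assert_allclose(out["chrI"], 1.0)

    def test_point_mass(self):
        arr = np.zeros(1000)
        arr[500] = 200.0
        out = cpm_normalize(CoverageTrack(data={"chrI": arr}))
        assert out["chrI"][500] == pytest.approx(1e6)
        assert out.total == pytest.approx(1e6)

    def test_idempotent_up_to_scaling(self):
        rng = np.random.default_rng(1)
        track = CoverageTrack(data={"chrI": rng.poisson(5.0, 5000).astype(float)})
        once = cpm_normalize(track)
        twice = cpm_normalize(once)
        np.testing.assert_allclose(once["chrI"], twice["chrI"], rtol=1e-12)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cpm_normalize(CoverageTrack(data={"chrI": np.zeros(100)}))
        with pytest.raises(ValueError, match="negative"):
            CoverageTrack(data={"chrI": np.array([-1.0, 2.0])})


class TestDefineRegions:
    def test_plus_strand_worked_intervals(self):
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "+",
                               "tss": 10_000, "tes": 12_000}])
        reg, exc = define_regions(genes)
        assert exc.empty
        got = {r.region: (r.start, r.end) for r in reg.itertuples(index=False)}
        # inclusive bounds converted to half-open: promoter -150..+25 spans 176 bp
        assert got["UAS"] == (9_500, 9_850)
        assert got["promoter"] == (9_850, 10_026)
        assert got["transcript"] == (10_026, 11_925)
        assert got["terminator"] == (11_925, 12_151)
        assert got["promoter"][1] - got["promoter"][0] == 176

    def test_minus_strand_is_mirror_image(self):
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "-",
                               "tss": 12_000, "tes": 10_000}])
        reg, _ = define_regions(genes)
        got = {r.region: (r.start, r.end) for r in reg.itertuples(index=False)}
        assert got["UAS"] == (12_151, 12_501)
        assert got["promoter"] == (11_975, 12_151)
        assert got["transcript"] == (10_076, 11_975)
        assert got["terminator"] == (9_850, 10_076)
        # mirror property: lengths equal the + strand case
        plus = define_regions(pd.DataFrame([{"gene_id": "g", "contig": "chrI",
                                             "strand": "+", "tss": 10_000,
                                             "tes": 12_000}]))[0]
        plus_len = {r.region: r.end - r.start for r in plus.itertuples(index=False)}
        minus_len = {r.region: r.end - r.start for r in reg.itertuples(index=False)}
        assert plus_len == minus_len

    def test_short_transcript_excluded_with_reason(self):
        genes = pd.DataFrame([{"gene_id": "tiny", "contig": "chrI", "strand": "+",
                               "tss": 1_000, "tes": 1_050}])
        reg, exc = define_regions(genes)
        assert reg.empty
        assert exc.iloc[0].gene_id == "tiny"
        assert "encroachment" in exc.iloc[0].reason


class TestInferTssTes:
    def test_utr_defaults(self):
        assert infer_tss_tes(1000, 2000, "+") == (953, 2118)
        assert infer_tss_tes(1000, 2000, "-") == (2047, 882)

    def test_measured_values_win(self):
        assert infer_tss_tes(1000, 2000, "+", tss=990, tes=2050) == (990, 2050)


class TestRegionSignal:
    def _setup(self, value=3.0):
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "+",
                               "tss": 5_000, "tes": 7_000}])
        regions, _ = define_regions(genes)
        return _uniform_track(value), regions

    def test_uniform_track_quarters(self):
        track, regions = self._setup()
        means = region_signal(track, regions, mode="per-bp-mean")
        np.testing.assert_allclose(means.iloc[0].values, 3.0)
        frac = region_signal(track, regions, mode="fraction-of-total")
        np.testing.assert_allclose(frac.iloc[0].values, 0.25)

    def test_promoter_only_signal(self):
        track, regions = self._setup(0.0)
        prom = regions[regions.region == "promoter"].iloc[0]
        track.data["chrI"][prom.start:prom.end] = 5.0
        frac = region_signal(track, regions, mode="fraction-of-total")
        assert frac.iloc[0]["promoter"] == pytest.approx(1.0)
        assert frac.iloc[0][["UAS", "transcript", "terminator"]].sum() == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        track, regions = self._setup()
        track.data["chrI"] += rng.random(10_000)
        frac = region_signal(track, regions, mode="fraction-of-total")
        assert frac.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_region_names_gene(self):
        track = _uniform_track(1.0, n=100)
        genes = pd.DataFrame([{"gene_id": "gX", "contig": "chrI", "strand": "+",
                               "tss": 50, "tes": 2_000}])
        regions, _ = define_regions(genes)
        with pytest.raises(ValueError, match="gX"):
            region_signal(track, regions)


class TestMetagene:
    def test_constant_track_all_bins(self):
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "+",
                               "tss": 3_000, "tes": 5_000}])
        prof = metagene(_uniform_track(2.5), genes)
        assert len(prof.values) == 300
        np.testing.assert_allclose(prof.values, 2.5)

    def test_length_normalisation_shared_shape(self):
        """Two genes of different length, same relative triangular body profile."""
        n = 40_000
        arr = np.zeros(n)
        genes = []
        for gid, (tss, length) in enumerate([(5_000, 2_000), (15_000, 4_000)]):
            tes = tss + length
            x = np.linspace(0, 1, length + 1)
            arr[tss:tes + 1] = 1 - np.abs(2 * x - 1)  # triangle, peak mid-gene
            genes.append({"gene_id": f"g{gid}", "contig": "chrI", "strand": "+",
                          "tss": tss, "tes": tes})
        prof = metagene(CoverageTrack(data={"chrI": arr}), pd.DataFrame(genes))
        body = prof.values[100:200]
        centers = (np.arange(100) + 0.5) / 100
        expected = 1 - np.abs(2 * centers - 1)
        np.testing.assert_allclose(body, expected, atol=5e-3)

    def test_single_gene_equals_own_profile(self):
        rng = np.random.default_rng(9)
        arr = rng.random(10_000)
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "+",
                               "tss": 3_000, "tes": 5_000}])
        prof = metagene(CoverageTrack(data={"chrI": arr}), genes)
        # first upstream bin = mean of the first 10 flank bases
        assert prof.values[0] == pytest.approx(arr[2_000:2_010].mean())

    def test_minus_strand_reversal(self):
        arr = np.zeros(10_000)
        arr[6_000:6_010] = 7.0  # just downstream of the minus-strand TSS flankwards
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "-",
                               "tss": 5_999, "tes": 4_000}])
        prof = metagene(CoverageTrack(data={"chrI": arr}), genes)
        # on the minus strand those bases are the first upstream-flank bin
        assert prof.values[99] == pytest.approx(7.0)

    def test_no_usable_genes(self):
        genes = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "strand": "+",
                               "tss": 100, "tes": 600}])
        with pytest.raises(ValueError, match="no usable genes"):
            metagene(_uniform_track(1.0, n=1_000), genes)


class TestMetasite:
    def test_flat_track(self):
        sites = pd.DataFrame([{"contig": "chrI", "position": 5_000, "strand": "+"}])
        prof = metasite(_uniform_track(4.0), sites, smooth_window=1)
        np.testing.assert_allclose(prof.values, 4.0)
        assert len(prof.values) == 501

    def test_delta_at_center_pre_smoothing(self):
        arr = np.zeros(10_000)
        arr[5_000] = 9.0
        arr[7_000] = 9.0
        sites = pd.DataFrame([{"contig": "chrI", "position": 5_000, "strand": "+"},
                              {"contig": "chrI", "position": 7_000, "strand": "+"}])
        prof = metasite(CoverageTrack(data={"chrI": arr}), sites, smooth_window=1)
        center = np.flatnonzero(prof.values)
        assert list(prof.positions[center]) == [0]
        assert prof.values[250] == pytest.approx(9.0)

    def test_minus_strand_mirrored(self):
        arr = np.zeros(10_000)
        arr[5_010] = 6.0  # +10 in genome coords
        plus = pd.DataFrame([{"contig": "chrI", "position": 5_000, "strand": "+"}])
        minus = pd.DataFrame([{"contig": "chrI", "position": 5_000, "strand": "-"}])
        track = CoverageTrack(data={"chrI": arr})
        p = metasite(track, plus, smooth_window=1)
        m = metasite(track, minus, smooth_window=1)
        assert p.values[250 + 10] == pytest.approx(6.0)
        assert m.values[250 - 10] == pytest.approx(6.0)

    def test_no_sites_error(self):
        with pytest.raises(ValueError, match="no usable sites"):
            metasite(_uniform_track(1.0, n=100), pd.DataFrame(columns=["contig", "position", "strand"]))


class TestSmooth:
    def test_constant(self):
        c, v = smooth(np.full(50, 3.0))
        np.testing.assert_allclose(v, 3.0)

    def test_step_signal_first_window(self):
        sig = np.array([0.0] * 5 + [10.0] * 5)
        c, v = smooth(sig, window=10, step=5)
        assert v[0] == pytest.approx(5.0)

    def test_step_equal_to_length(self):
        sig = np.arange(10, dtype=float)
        c, v = smooth(sig, window=10, step=10)
        assert len(v) == 1 and v[0] == pytest.approx(4.5)

    def test_window_longer_than_signal(self):
        c, v = smooth(np.array([1.0, 3.0]), window=10, step=5)
        assert v[0] == pytest.approx(2.0)


class TestSubtractBackground:
    def test_identical_tracks_zero(self):
        a = _uniform_track(2.0, n=100, units="CPM")
        out = subtract_background(a, a)
        np.testing.assert_allclose(out["chrI"], 0.0)

    def test_negative_values_retained(self):
        a = _uniform_track(1.0, n=10, units="CPM")
        b = _uniform_track(3.0, n=10, units="CPM")
        out = subtract_background(a, b)
        np.testing.assert_allclose(out["chrI"], -2.0)

    def test_unit_mismatch(self):
        a = _uniform_track(1.0, n=10, units="counts")
        b = _uniform_track(1.0, n=10, units="CPM")
        with pytest.raises(ValueError, match="unit"):
            subtract_background(a, b)


class TestFilterExpressed:
    def test_threshold_is_inclusive(self):
        genes = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "nascent_count": [50.0, 49.9, np.nan]})
        kept = filter_expressed(genes)
        assert list(kept.gene_id) == ["a"]

    def test_empty_input(self):
        genes = pd.DataFrame({"gene_id": [], "nascent_count": []})
        assert filter_expressed(genes).empty


class TestRelativeEnrichment:
    def _reps(self, factor_scale):
        idx = ["g1", "g2"]
        cols = ["promoter", "transcript"]
        ref = pd.DataFrame([[2.0, 4.0], [1.0, 2.0]], index=idx, columns=cols)
        return [ref * factor_scale, ref * factor_scale * 1.1], [ref, ref]

    def test_identity_ratio_one(self):
        fac, ref = [pd.DataFrame([[2.0, 4.0]], index=["g"], columns=["p", "t"])] * 2, None
        out = relative_region_enrichment(fac, fac)
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_constant_factor_of_two(self):
        ref = [pd.DataFrame([[2.0, 4.0]], index=["g"], columns=["p", "t"])] * 3
        fac = [df * 2 for df in ref]
        out = relative_region_enrichment(fac, ref)
        np.testing.assert_allclose(out["ratio"], 2.0)
        np.testing.assert_allclose(out["se"], 0.0, atol=1e-15)

    def test_replicate_dispersion_finite_z(self):
        fac, ref = self._reps(2.0)
        out = relative_region_enrichment(fac, ref)
        assert (out["se"] > 0).all()
        z, p = ratio_zscore(out["ratio"].iloc[0], out["se"].iloc[0], 1.0, 0.0)
        assert np.isfinite(z) and 0 <= p <= 1

    def test_zero_reference_gene_skipped(self):
        ref = pd.DataFrame([[0.0, 4.0], [1.0, 2.0]], index=["g1", "g2"],
                           columns=["p", "t"])
        fac = ref * 3
        out = relative_region_enrichment([fac], [ref])
        np.testing.assert_allclose(out["ratio"], 3.0)  # only g2 contributes
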