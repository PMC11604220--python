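"""Region aggregation, cosine scoring, grid-search ensemble, perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polkin import (
    FitConfig,
    GeneArchitecture,
    PerturbationScenario,
    RegionVector,
    SimulationConfig,
    TranscriptionCycleModel,
    aggregate_regions,
    cosine_similarity,
    ctmc_stationary_occupancy,
    l2_scale,
    score_perturbation_fit,
    simulate_population,
)
from polkin.engine import OccupancyProfile
from polkin.fitting import ZeroVectorError, grid_search
from polkin.presets import published_rates, scenario


def _profile(labels, values):
    vals = np.asarray(values, dtype=float)
    return OccupancyProfile(labels=tuple(labels), mean=vals,
                            se=np.zeros_like(vals), n_genes=0, window=(0.0, 1.0))


class TestAggregateRegions:
    def test_transcript_is_bin_mean(self):
        labels = ("promoter",) + tuple(f"bin_{i}" for i in range(1, 11)) + ("terminator",)
        prof = _profile(labels, [0.5] + [0.1] * 10 + [0.3])
        vec = aggregate_regions(prof, "TFO")
        np.testing.assert_allclose(vec.values, [0.5, 0.1, 0.3])

    def test_sparse_bins_average_down(self):
        labels = ("promoter",) + tuple(f"bin_{i}" for i in range(1, 11)) + ("terminator",)
        prof = _profile(labels, [0.5, 0.2] + [0.0] * 9 + [0.3])
        vec = aggregate_regions(prof, "TFO")
        assert vec["transcript"] == pytest.approx(0.02)

    def test_stm_requires_uas(self):
        labels = ("promoter",) + tuple(f"bin_{i}" for i in range(1, 11)) + ("terminator",)
        with pytest.raises(ValueError, match="UAS"):
            aggregate_regions(_profile(labels, [0.1] * 12), "STM")


class TestCosineSimilarity:
    def test_proportional_vectors(self):
        a = RegionVector("TFO", [1, 2, 2])
        b = RegionVector("TFO", [2, 4, 4])
        assert cosine_similarity(a, b) == pytest.approx(1.0)

    def test_orthogonal(self):
        a = RegionVector("TFO", [1, 0, 0])
        b = RegionVector("TFO", [0, 1, 0])
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_printed_formula_value(self):
        a = RegionVector("TFO", [1, 1, 0])
        b = RegionVector("TFO", [1, 0, 0])
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_is_an_error(self):
        a = RegionVector("TFO", [0, 0, 0])
        b = RegionVector("TFO", [1, 1, 1])
        with pytest.raises(ZeroVectorError):
            cosine_similarity(a, b)


class TestL2Scale:
    def test_norm_matching(self):
        m = RegionVector("TFO", [3, 4, 0])
        e = RegionVector("TFO", [0, 6, 8])
        out = l2_scale(m, e)
        np.testing.assert_allclose(out.values, [6, 8, 0])
        assert out.norm == pytest.approx(e.norm, abs=1e-12)

    def test_identity(self):
        e = RegionVector("TFO", [1, 2, 3])
        np.testing.assert_allclose(l2_scale(e, e).values, e.values)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 100.0), min_size=3, max_size=3))
    def test_scaling_preserves_cosine(self, mv, ev):
        m, e = RegionVector("TFO", mv), RegionVector("TFO", ev)
        assert cosine_similarity(l2_scale(m, e), e) == pytest.approx(
            cosine_similarity(m, e), abs=1e-12
        )


class TestFitConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError, match="threshold"):
            FitConfig(fixed_rates=published_rates("TFO"), threshold=1.0 + 1e-9)

    def test_resolution_bounds(self):
        with pytest.raises(ValueError, match="resolution"):
            FitConfig(fixed_rates=published_rates("TFO"), resolution=1)

    def test_defaults_follow_published_ranges(self):
        cfg = FitConfig(fixed_rates=published_rates("STM"))
        assert set(cfg.free_ranges) == {"k2", "k_rev2", "k_rev3", "k4"}
        assert cfg.free_ranges["k4"] == (0.0075, 0.0275)


@pytest.fixture(scope="module")
def tfo_recovery():
    """Small self-consistency fit: target generated inside a 3x3 grid."""
    true = published_rates("TFO").replace(k_rev3=0.015, k4=0.0175)
    arch = GeneArchitecture(n_transcript_bins=2)
    target_prof = simulate_population(true, arch, SimulationConfig(n_genes=30_000, seed=91))
    target = aggregate_regions(target_prof, "TFO")
    cfg = FitConfig(
        fixed_rates=published_rates("TFO"),
        free_ranges={"k_rev3": (0.0, 0.03), "k4": (0.0075, 0.0275)},
        resolution=3, threshold=0.995,
        sim=SimulationConfig(n_genes=8000, seed=17),
        arch=arch,
    )
    return TranscriptionCycleModel(target, cfg).fit(), target


class TestGridSearch:
    def test_true_point_recovered(self, tfo_recovery):
        res, _target = tfo_recovery
        assert not res.fallback
        assert res.contains(k_rev3=0.015, k4=0.0175)

    def test_scores_sorted_and_above_threshold(self, tfo_recovery):
        res, _ = tfo_recovery
        assert np.all(np.diff(res.scores) <= 1e-15)
        assert res.scores.min() >= res.threshold

    def test_ensemble_average_close_to_target(self, tfo_recovery):
        res, target = tfo_recovery
        assert cosine_similarity(res.predicted_regions, target) >= 0.995

    def test_scale_invariance_of_membership(self, tfo_recovery):
        res, target = tfo_recovery
        scaled = RegionVector("TFO", target.values * 137.0, units=target.units)
        res2 = TranscriptionCycleModel(scaled, res.model.config).fit()
        np.testing.assert_allclose(res2.to_frame().values, res.to_frame().values,
                                   rtol=0, atol=1e-9)

    def test_fallback_on_unreachable_shape(self):
        """Transcript-dominated target with empty promoter: no model passes."""
        target = RegionVector("TFO", [0.001, 1.0, 0.05], units="CPMn")
        cfg = FitConfig(
            fixed_rates=published_rates("TFO"),
            free_ranges={"k_rev3": (0.0, 0.03), "k4": (0.0075, 0.0275)},
            resolution=2, threshold=0.995, fallback_top_n=3,
            sim=SimulationConfig(n_genes=1500, seed=23),
            arch=GeneArchitecture(n_transcript_bins=2),
        )
        res = grid_search(target, cfg)
        assert res.fallback
        assert res.n_members == 3
        assert res.scores.max() < 0.995

    def test_summary_mentions_ensemble_size(self, tfo_recovery):
        res, _ = tfo_recovery
        text = res.summary()
        assert "ensemble size" in text and str(res.n_members) in text


class TestPerturbation:
    def test_identity_scenario_zero_delta(self, tfo_recovery):
        res, _ = tfo_recovery
        out = res.perturb(PerturbationScenario("identity", {}))
        np.testing.assert_allclose(out.delta_mean, 0.0, atol=1e-12)

    def test_unknown_rate_rejected(self):
        with pytest.raises(ValueError, match="unknown rate"):
            PerturbationScenario("bad", {"k9": 0.5})

    def test_recruitment_loss_lowers_all_regions(self, tfo_recovery):
        res, _ = tfo_recovery
        out = res.perturb(scenario("tfiib-20min", "TFO", 1))
        assert np.all(out.delta_mean < 0)

    def test_initiation_loss_accumulates_at_promoter(self, tfo_recovery):
        res, _ = tfo_recovery
        out = res.perturb(scenario("kin28-cmk", "TFO", 1))
        assert out["promoter"] > 0

    def test_delta_scores(self):
        a = RegionVector("TFO", [-1, -2, -1], units="delta")
        b = RegionVector("TFO", [-2, -4, -2], units="delta")
        assert score_perturbation_fit(a, b) == pytest.approx(1.0)
        c = RegionVector("TFO", [1, 2, 1], units="delta")
        assert score_perturbation_fit(a, c) == pytest.approx(-1.0)

    def test_oracle_confirms_perturbation_signs(self, arch_reduced):
        """Exact stationary check of the two qualitative sign patterns."""
        base = published_rates("TFO").replace(k_rev3=0.015, k4=0.0175)
        b = ctmc_stationary_occupancy(base, arch_reduced)
        low_recruit = ctmc_stationary_occupancy(base.replace(k3=0.0008), arch_reduced)
        assert np.all(low_recruit.mean < b.mean)
        low_init = ctmc_stationary_occupancy(base.replace(k5=0.02), arch_reduced)
        assert low_init["promoter"] > b["promoter"]
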