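"""Generator contracts: determinism, truth completeness, and the statistical
structure each synthetic dataset promises."""
import numpy as np
import pandas as pd
import pytest

from acidoquant.quench_kinetics import hill_rate
from acidoquant.synthetic_data import (
    ChannelSpec,
    CountDistribution,
    CytometrySimConfig,
    DeathSimConfig,
    PlacementError,
    TissueSimConfig,
    TraceSimConfig,
    simulate_coloc_pair,
    simulate_coexpression_counts,
    simulate_cytometry,
    simulate_death_field,
    simulate_tissue_field,
    simulate_traces,
)


class TestTissueField:
    def test_empty_field_has_empty_truth_and_background_only_image(self):
        field = simulate_tissue_field(TissueSimConfig(n_cells=0, field_size_px=(128, 128)))
        assert len(field.truth) == 0
        assert field.nuclei_truth.n_labels == 0
        assert field.channels["PACC1"].pixels.max() < 0.3  # background + noise only

    def test_same_seed_gives_bit_identical_output(self):
        cfg = TissueSimConfig(n_cells=20, field_size_px=(256, 256), seed=42)
        a = simulate_tissue_field(cfg)
        b = simulate_tissue_field(cfg)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].pixels, b.channels[name].pixels)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_has_one_row_per_cell_with_nonnegative_counts(self):
        field = simulate_tissue_field(TissueSimConfig(n_cells=30, field_size_px=(512, 512), seed=3))
        assert len(field.truth) == 30
        assert set(field.truth["cell_id"]) == set(range(1, 31))
        assert (field.truth["dots_PACC1"] >= 0).all()

    def test_rendered_signal_area_matches_dot_count(self, small_tissue_field):
        """Noiseless, non-clustered rendering: supra-half-max area per cell is
        the true count times the unit dot area, within ~1 px per dot."""
        field = small_tissue_field
        cfg = field.config
        px_area = cfg.pixel_size_um**2
        supra = field.channels["PACC1"].pixels >= 0.5 * cfg.dot_amplitude
        for _, row in field.truth.iterrows():
            region = field.territory_truth.labels == row["cell_id"]
            area = (supra & region).sum() * px_area
            expected = row["dots_PACC1"] * cfg.dot_area_um2
            tol = row["dots_PACC1"] * px_area * 4  # one boundary ring per dot
            assert abs(area - expected) <= max(tol, 1.5)

    def test_overfull_field_raises_placement_error_with_count(self):
        with pytest.raises(PlacementError) as err:
            simulate_tissue_field(TissueSimConfig(n_cells=500, field_size_px=(128, 128)))
        assert 0 <= err.value.n_placed < 500

    def test_nonpositive_cells_have_zero_dots(self):
        cfg = TissueSimConfig(
            n_cells=40,
            field_size_px=(512, 512),
            seed=5,
            channels=(ChannelSpec("PACC1", 0.0, CountDistribution("constant", 5)),),
        )
        field = simulate_tissue_field(cfg)
        assert (field.truth["dots_PACC1"] == 0).all()
        assert not field.truth["positive_PACC1"].any()


class TestCountDistribution:
    def test_zero_truncation_never_returns_zero(self, rng):
        counts = CountDistribution("negbin", 1.0, 0.5).sample(rng, 2000, zero_truncated=True)
        assert counts.min() >= 1

    @pytest.mark.parametrize("family", ["constant", "poisson", "negbin"])
    def test_mean_is_approximately_respected(self, family, rng):
        counts = CountDistribution(family, 8.0, 2.0).sample(rng, 4000)
        assert counts.mean() == pytest.approx(8.0, rel=0.1)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            CountDistribution("zipf", 3.0)


class TestColocPair:
    def test_rho_one_makes_channel_b_affine_in_channel_a(self):
        sim = simulate_coloc_pair(1.0, 0.5, shape=(128, 128), seed=0)
        a, b = sim.channel_a.pixels.ravel(), sim.channel_b.pixels.ravel()
        assert abs(np.corrcoef(a, b)[0, 1] - 1.0) < 1e-12

    def test_null_correlation_mean_near_zero_over_seeds(self):
        rs = []
        for seed in range(20):
            sim = simulate_coloc_pair(0.0, 0.5, shape=(512, 512), seed=seed)
            rs.append(np.corrcoef(sim.channel_a.pixels.ravel(), sim.channel_b.pixels.ravel())[0, 1])
        assert abs(np.mean(rs)) < 0.02

    def test_overlap_construction_is_exact_in_structure_counts(self):
        sim = simulate_coloc_pair(0.0, 0.5, shape=(512, 512), seed=1, n_structures=100)
        assert sim.truth["n_inside"] == 50
        marker = sim.marker.pixels >= 0.5
        signal = sim.signal.pixels >= 0.5
        overlap = (marker & signal).sum() / marker.sum()
        assert overlap == pytest.approx(0.5, abs=1e-9)

    def test_out_of_range_targets_rejected(self):
        with pytest.raises(ValueError):
            simulate_coloc_pair(1.5, 0.5)
        with pytest.raises(ValueError):
            simulate_coloc_pair(0.0, -0.1)


class TestCytometry:
    def test_noiseless_fully_transfected_ratios_equal_response(self):
        cfg = CytometrySimConfig(n_events=500, noise_cv=0.0, transfected_fraction=1.0, seed=0)
        sim = simulate_cytometry(cfg)
        for sid, table in sim.samples.items():
            expected = cfg.fitc_ph_response(cfg.true_pH[sid])
            np.testing.assert_allclose(table["fitc"] / table["af633"], expected, rtol=1e-12)

    def test_median_ratio_close_to_response_at_default_noise(self):
        cfg = CytometrySimConfig(
            n_events=10_000, true_pH={"s": 5.3}, transfected_fraction=1.0, seed=2
        )
        sim = simulate_cytometry(cfg)
        med = np.median(sim.samples["s"]["fitc"] / sim.samples["s"]["af633"])
        assert med == pytest.approx(float(cfg.fitc_ph_response(5.3)), rel=0.01)

    def test_half_transfected_reporter_is_bimodal_with_balanced_fraction(self):
        cfg = CytometrySimConfig(n_events=10_000, transfected_fraction=0.5, seed=3)
        sim = simulate_cytometry(cfg)
        mch = sim.samples["parental"]["mcherry"]
        gate = np.sqrt(
            cfg.mcherry_positive_level[0] * cfg.mcherry_negative_level[0]
        )  # geometric midpoint between modes
        frac = (mch > gate).mean()
        se = np.sqrt(0.25 / len(mch))
        assert abs(frac - 0.5) < 3 * se

    def test_response_must_be_monotone(self):
        with pytest.raises(ValueError):
            CytometrySimConfig(calibration_pHs=(7.4, 5.5, 6.5, 4.5))


class TestTraces:
    def test_noiseless_trace_is_flat_at_neutral_pH(self):
        cfg = TraceSimConfig(pH_values=(7.5,), noise_sd=0.0, n_replicate_wells=1)
        ts = simulate_traces(cfg)
        norm = (ts.traces[0].fluorescence - cfg.background) / cfg.amplitude
        assert np.all(np.abs(norm - 1.0) < 0.01)

    def test_initial_slope_at_midpoint_is_half_of_maximum(self):
        cfg = TraceSimConfig(noise_sd=0.0)
        truth = simulate_traces(cfg).truth
        at_mid = truth[truth["pH"] == cfg.hill_pH50]["true_rate"].iloc[0]
        assert at_mid == pytest.approx(cfg.rate_max / 2, rel=1e-12)

    def test_noiseless_normalized_value_at_injection_is_one(self):
        cfg = TraceSimConfig(pH_values=(5.0,), noise_sd=0.0, n_replicate_wells=1)
        tr = simulate_traces(cfg).traces[0]
        norm = (tr.fluorescence - cfg.background) / cfg.amplitude
        i = np.argmin(np.abs(tr.time_s - cfg.baseline_s))
        assert norm[i] == pytest.approx(1.0, abs=1e-12)

    def test_hill_rate_strictly_decreasing_in_pH(self):
        ph = np.linspace(4.0, 7.5, 100)
        rates = hill_rate(ph, 0.23, 5.5, 2.0)
        assert np.all(np.diff(rates) < 0)


class TestDeathField:
    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 1)])
    def test_extreme_probabilities_give_uniform_truth(self, p, expected):
        field = simulate_death_field(
            DeathSimConfig(n_nuclei=50, field_size_px=(256, 256), death_probability=p, seed=0)
        )
        assert (field.truth["dead"] == bool(expected)).all()

    def test_truth_dead_fraction_within_binomial_error(self):
        fracs = [
            simulate_death_field(
                DeathSimConfig(n_nuclei=100, field_size_px=(320, 320),
                               death_probability=0.3, seed=s)
            ).truth["dead"].mean()
            for s in range(10)
        ]
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert abs(np.mean(fracs) - 0.3) < 3 * se

    def test_inseparable_intensities_rejected(self):
        with pytest.raises(ValueError):
            DeathSimConfig(pi_positive_level=(0.1, 0.05), pi_negative_level=(0.08, 0.02))


class TestCoexpressionCounts:
    def test_shared_latent_factor_gives_predicted_correlation(self):
        a, b, rho = simulate_coexpression_counts(20_000, 8.0, 6.0, 1.0, seed=0)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(rho, abs=0.02)

    def test_independent_channels_are_uncorrelated(self):
        a, b, rho = simulate_coexpression_counts(20_000, 8.0, 6.0, None, seed=1)
        assert rho == 0.0
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.02
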