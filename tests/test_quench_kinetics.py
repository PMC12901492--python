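"""Trace normalization, exponential rate extraction and Hill fitting against
closed-form constructions and the generator's own model."""
import numpy as np
import pytest

from acidoquant.quench_kinetics import (
    QuenchFitError,
    Trace,
    compare_isoform_curves,
    compare_rate_sets,
    fit_hill,
    fit_quench,
    hill_rate,
    normalize_trace,
)
from acidoquant.synthetic_data import TraceSimConfig, simulate_traces


def _trace(f, dt=0.2, injection=2.0, pH=None):
    t = np.arange(len(f)) * dt
    return Trace(t, np.asarray(f, dtype=float), injection, "w", pH)


class TestNormalize:
    def test_constant_trace_normalizes_to_ones(self):
        tr = normalize_trace(_trace([100.0] * 70))
        np.testing.assert_allclose(tr.fluorescence, 1.0)

    def test_scale_invariance(self):
        base = np.linspace(100, 60, 70)
        a = normalize_trace(_trace(base))
        b = normalize_trace(_trace(base * 3))
        np.testing.assert_allclose(a.fluorescence, b.fluorescence, rtol=1e-12)

    def test_noiseless_generator_trace_recovers_model_curve(self):
        cfg = TraceSimConfig(pH_values=(5.2,), noise_sd=0.0, n_replicate_wells=1)
        ts = simulate_traces(cfg)
        norm = normalize_trace(ts.traces[0], background=cfg.background)
        from acidoquant.synthetic_data.traces import model_curve

        np.testing.assert_allclose(
            norm.fluorescence, model_curve(norm.time_s, cfg, 5.2), rtol=1e-12
        )

    def test_blank_well_background_subtraction(self):
        blank = _trace([7.0] * 70)
        tr = normalize_trace(_trace(np.full(70, 107.0)), background=blank)
        np.testing.assert_allclose(tr.fluorescence, 1.0)

    def test_too_few_preinjection_samples_signaled(self):
        with pytest.raises(ValueError):
            normalize_trace(_trace([1.0] * 70, injection=0.1))

    def test_nonpositive_baseline_signaled(self):
        with pytest.raises(ValueError):
            normalize_trace(_trace([0.0] * 70))


class TestFitQuench:
    def test_closed_form_self_fit_recovers_k_and_rate(self):
        t = np.arange(0.0, 14.01, 0.2)
        f = np.where(t < 2.0, 1.0, 0.2 + 0.8 * np.exp(-0.5 * np.clip(t - 2.0, 0, None)))
        fit = fit_quench(Trace(t, f, 2.0))
        assert fit.k == pytest.approx(0.5, abs=1e-6)
        assert fit.rate == pytest.approx(0.4, abs=1e-6)
        assert fit.f_plateau == pytest.approx(0.2, abs=1e-6)

    def test_flat_trace_has_zero_rate(self):
        fit = fit_quench(_trace([1.0] * 70))
        assert fit.rate <= 1e-6
        assert fit.k == 0.0

    def test_noisy_flat_trace_stays_below_rate_floor(self, rng):
        f = 1.0 + rng.normal(0, 0.02, 70)
        fit = fit_quench(_trace(f))
        assert fit.rate < 0.01

    def test_rate_estimates_unbiased_at_moderate_noise(self, rng):
        cfg = TraceSimConfig(pH_values=(5.0,), noise_sd=0.01, n_replicate_wells=1)
        true_rate = float(hill_rate(5.0, cfg.rate_max, cfg.hill_pH50, cfg.hill_n))
        rates = []
        for s in range(50):
            ts = simulate_traces(TraceSimConfig(
                pH_values=(5.0,), noise_sd=0.01, n_replicate_wells=1, seed=s))
            rates.append(fit_quench(normalize_trace(ts.traces[0], cfg.background)).rate)
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - true_rate) < 2 * se + 1e-4

    def test_window_start_later_extrapolates_rate_to_injection(self):
        t = np.arange(0.0, 14.01, 0.2)
        f = np.where(t < 2.0, 1.0, 0.2 + 0.8 * np.exp(-0.3 * np.clip(t - 2.0, 0, None)))
        fit = fit_quench(Trace(t, f, 2.0), window=(4.0, 14.0))
        assert fit.rate == pytest.approx(0.8 * 0.3, rel=1e-4)

    def test_short_window_signaled(self):
        with pytest.raises(ValueError):
            fit_quench(_trace([1.0] * 70), window=(2.0, 3.0))


class TestFitHill:
    PHS = (7.5, 6.5, 6.0, 5.8, 5.5, 5.2, 4.8, 4.2)

    def test_exact_rates_recover_parameters_to_numerical_tolerance(self):
        pairs = [(p, float(hill_rate(p, 0.23, 5.5, 2.0))) for p in self.PHS]
        fit = fit_hill(pairs)
        assert fit.pH50 == pytest.approx(5.5, abs=1e-6)
        assert fit.hill_n == pytest.approx(2.0, abs=1e-6)
        assert fit.rate_max == pytest.approx(0.23, abs=1e-6)

    def test_fitted_curve_halves_at_ph50(self):
        pairs = [(p, float(hill_rate(p, 0.2, 5.4, 1.5))) for p in self.PHS]
        fit = fit_hill(pairs)
        assert fit(fit.pH50) == pytest.approx(fit.rate_max / 2, rel=1e-9)

    def test_fitted_curve_is_strictly_decreasing(self):
        pairs = [(p, float(hill_rate(p, 0.2, 5.4, 1.5))) for p in self.PHS]
        fit = fit_hill(pairs)
        grid = np.linspace(4.0, 7.5, 200)
        assert np.all(np.diff(fit(grid)) < 0)

    def test_all_zero_rates_rejected_with_diagnostic(self):
        with pytest.raises(QuenchFitError, match="no activation"):
            fit_hill([(p, 0.0) for p in self.PHS])

    def test_too_few_ph_values_signaled(self):
        with pytest.raises(ValueError):
            fit_hill([(7.0, 0.0), (6.0, 0.1), (5.0, 0.2)])


class TestIsoformComparison:
    def _fit(self, rmax):
        pairs = [(p, float(hill_rate(p, rmax, 5.5, 2.0))) for p in TestFitHill.PHS]
        return fit_hill(pairs), pairs

    def test_identical_datasets_give_zero_difference_and_p_near_one(self, rng):
        rates = [(4.2, r) for r in rng.normal(0.23, 0.01, 6)]
        fit, _ = self._fit(0.23)
        rep = compare_isoform_curves(fit, fit, rates, rates)
        assert rep["rate_ttest"]["difference"] == 0.0
        assert rep["rate_ttest"]["p_value"] == pytest.approx(1.0)

    def test_swapped_arguments_flip_sign_keep_p(self, rng):
        ra = [(4.2, r) for r in rng.normal(0.23, 0.02, 8)]
        rb = [(4.2, r) for r in rng.normal(0.17, 0.02, 8)]
        fa, _ = self._fit(0.23)
        fb, _ = self._fit(0.17)
        fwd = compare_isoform_curves(fa, fb, ra, rb)
        rev = compare_isoform_curves(fb, fa, rb, ra)
        assert fwd["rate_ttest"]["difference"] == pytest.approx(
            -rev["rate_ttest"]["difference"]
        )
        assert fwd["rate_ttest"]["p_value"] == pytest.approx(rev["rate_ttest"]["p_value"])

    def test_non_overlapping_ph_ranges_signaled(self):
        fa, ra = self._fit(0.2)
        with pytest.raises(ValueError):
            compare_isoform_curves(fa, fa, [(5.0, 0.2)], [(4.0, 0.2)])

    def test_rate_set_comparison_detects_known_difference(self, rng):
        a = rng.normal(0.23, 0.03, 12)
        b = rng.normal(0.17, 0.02, 12)
        assert compare_rate_sets(a, b)["p_value"] < 0.05
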