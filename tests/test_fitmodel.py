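"""Diffusion-model evaluation, fitting, initial guesses and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fccs
from fccs.exceptions import ConfigError, NumericalError


def make_model(n=5.0, tau=2e-4, s=5.0, **kw):
    return fccs.DiffusionModel(
        n_particles=n, components=((1.0, tau),), structure_parameter=s, **kw)


def noiseless_curve(model, n_lags=64, lo=1e-5, hi=1e-1, kind="gg"):
    lags = np.logspace(math.log10(lo), math.log10(hi), n_lags)
    return fccs.CorrelationCurve(
        kind=kind, lags=lags, values=fccs.model_eval(model, lags),
        source_bin_time=lo)


class TestModelEval:
    def test_zero_lag_amplitude_is_one_over_n(self):
        model = fccs.DiffusionModel(
            n_particles=4.0,
            components=((0.3, 1e-4), (0.7, 1e-3)),
            structure_parameter=5.0)
        assert fccs.model_eval(model, [0.0])[0] == pytest.approx(1.25, rel=1e-12)

    def test_infinite_structure_parameter_reduces_to_2d_model(self):
        # s -> inf: G(tau_1) = 1 + (1/N) * 1/2
        model = make_model(n=1.0, tau=1e-3, s=1e6)
        assert fccs.model_eval(model, [1e-3])[0] == pytest.approx(1.5, rel=1e-6)
        lags = np.logspace(-5, -1, 40)
        two_d = 1.0 + 1.0 / (1.0 + lags / 1e-3)
        np.testing.assert_allclose(
            fccs.model_eval(model, lags), two_d, rtol=1e-6)

    def test_hand_computed_value(self):
        # N=2, tau_1=1e-3, s=5 at tau=tau_1:
        # 1 + 0.5 * 0.5 * (1 + 1/25)^(-1/2) = 1.245145...
        model = make_model(n=2.0, tau=1e-3, s=5.0)
        expected = 1.0 + 0.25 / math.sqrt(1.04)
        assert fccs.model_eval(model, [1e-3])[0] == pytest.approx(expected, rel=1e-12)

    def test_negative_lag_rejected(self):
        with pytest.raises(ConfigError):
            fccs.model_eval(make_model(), [-1e-6])

    def test_triplet_amplitude_identity(self):
        # G(0) - 1 = (1/N)(1 + T/(1-T)) exactly
        model = make_model(n=2.5, triplet_fraction=0.2, triplet_time=5e-6)
        amp = fccs.model_eval(model, [0.0])[0] - 1.0
        assert amp == pytest.approx((1 / 2.5) * (1 + 0.2 / 0.8), rel=1e-12)
        assert model.amplitude == pytest.approx(amp, rel=1e-12)

    def test_long_lag_limit_is_one(self):
        model = make_model()
        assert fccs.model_eval(model, [1e6])[0] == pytest.approx(1.0, abs=1e-4)

    @given(
        st.floats(0.01, 1e4),
        st.floats(1e-6, 1e-1),
        st.floats(0.5, 100.0),
    )
    def test_strictly_decreasing_without_triplet(self, n, tau, s):
        model = make_model(n=n, tau=tau, s=s)
        lags = np.logspace(-7, 2, 200)
        values = fccs.model_eval(model, lags)
        diffs = np.diff(values)
        assert np.all(diffs <= 0)
        # strict wherever the value is still numerically above the baseline
        above = values[:-1] > 1 + 1e-9
        assert np.all(diffs[above] < 0)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            fccs.DiffusionModel(1.0, ((0.5, 1e-4), (0.4, 1e-3)), 5.0)
        with pytest.raises(ConfigError, match="strictly increasing"):
            fccs.DiffusionModel(1.0, ((0.5, 1e-3), (0.5, 1e-4)), 5.0)


class TestInitialGuess:
    def test_amplitude_inversion(self):
        curve = noiseless_curve(make_model(n=4.0))
        guess = fccs.initial_guess(curve)
        # the anchor lag sits slightly off zero, so the guess overshoots a bit
        assert guess.n_particles == pytest.approx(4.0, rel=0.1)

    def test_half_decay_lag_brackets_true_diffusion_time(self):
        from scipy.optimize import brentq

        model = make_model(n=2.0, tau=1e-3)
        curve = noiseless_curve(model, n_lags=200)
        guess = fccs.initial_guess(curve)
        # independent oracle: exact half-decay lag of the model via brentq
        half = brentq(
            lambda x: 1.0 / ((1 + x) * math.sqrt(1 + x / 25.0)) - 0.5, 0.1, 10.0)
        ratio = guess.components[0][1] / (half * 1e-3)
        # log-grid spacing: 200 points over 4 decades
        spacing = 10 ** (4 / 199)
        assert 1 / spacing**2 < ratio < spacing**2

    def test_flat_curve_raises_no_correlated_signal(self):
        lags = np.logspace(-5, -1, 30)
        curve = fccs.CorrelationCurve("gg", lags, np.ones_like(lags))
        with pytest.raises(NumericalError, match="no correlated signal"):
            fccs.initial_guess(curve)


class TestFitCurve:
    def test_noiseless_single_component_inversion(self):
        truth = make_model(n=5.0, tau=2e-4, s=5.0)
        fit = fccs.fit_curve(noiseless_curve(truth), n_components=1,
                             fixed={"structure_parameter": 5.0})
        assert fit.converged
        assert fit.model.n_particles == pytest.approx(5.0, rel=1e-6)
        assert fit.model.components[0][1] == pytest.approx(2e-4, rel=1e-6)

    def test_noiseless_two_component_inversion(self):
        truth = fccs.DiffusionModel(
            n_particles=3.0,
            components=((0.4, 1e-4), (0.6, 5e-3)),
            structure_parameter=5.0)
        fit = fccs.fit_curve(noiseless_curve(truth, n_lags=96), n_components=2,
                             fixed={"structure_parameter": 5.0})
        assert fit.converged
        assert fit.model.n_particles == pytest.approx(3.0, rel=1e-5)
        (f1, t1), (f2, t2) = fit.model.components
        assert f1 == pytest.approx(0.4, abs=1e-4)
        assert t1 == pytest.approx(1e-4, rel=1e-4)
        assert t2 == pytest.approx(5e-3, rel=1e-4)

    def test_noiseless_triplet_inversion(self):
        truth = make_model(n=5.0, tau=2e-4, triplet_fraction=0.15,
                           triplet_time=4e-6)
        curve = noiseless_curve(truth, n_lags=96, lo=5e-7)
        fit = fccs.fit_curve(curve, n_components=1,
                             fixed={"structure_parameter": 5.0},
                             use_triplet=True)
        assert fit.converged
        assert fit.model.n_particles == pytest.approx(5.0, rel=1e-4)
        assert fit.model.triplet_fraction == pytest.approx(0.15, abs=1e-4)

    def test_fit_idempotence(self):
        truth = make_model(n=5.0, tau=2e-4)
        curve = noiseless_curve(truth)
        first = fccs.fit_curve(curve, 1, fixed={"structure_parameter": 5.0})
        second = fccs.fit_curve(curve, 1, fixed={"structure_parameter": 5.0},
                                init=first.model)
        assert second.model.n_particles == pytest.approx(
            first.model.n_particles, rel=1e-9)
        assert second.model.components[0][1] == pytest.approx(
            first.model.components[0][1], rel=1e-9)

    def test_overparameterized_fit_reports_degeneracy(self):
        truth = make_model(n=5.0, tau=2e-4)
        fit = fccs.fit_curve(noiseless_curve(truth, n_lags=96), n_components=2,
                             fixed={"structure_parameter": 5.0})
        fractions = [f for f, _ in fit.model.components]
        taus = [t for _, t in fit.model.components]
        degenerate = max(fractions) >= 0.95 or taus[1] / taus[0] < 2.0
        assert degenerate
        assert any("degenerate" in w for w in fit.warnings)

    def test_too_few_lags_rejected(self):
        truth = make_model()
        with pytest.raises(ConfigError, match="usable lags"):
            fccs.fit_curve(noiseless_curve(truth, n_lags=5), n_components=3)

    def test_weighted_and_unweighted_paths(self):
        truth = make_model(n=2.0, tau=1e-3)
        curve = noiseless_curve(truth)
        unweighted = fccs.fit_curve(curve, 1, fixed={"structure_parameter": 5.0})
        assert not unweighted.weighted
        noisy = fccs.CorrelationCurve(
            "gg", curve.lags, curve.values,
            stderr=np.full(len(curve), 1e-3), n_segments=10,
            source_bin_time=curve.source_bin_time)
        weighted = fccs.fit_curve(noisy, 1, fixed={"structure_parameter": 5.0})
        assert weighted.weighted
        assert weighted.model.n_particles == pytest.approx(2.0, rel=1e-6)

    def test_parameter_recovery_from_simulated_trace(self, single_species_trace):
        # D = 1 um^2/s, w0 = 0.25 um -> tau_D = 1.5625e-2 s
        trace, config, species = single_species_trace
        curve = fccs.estimate_curve(trace, "gg")
        fit = fccs.fit_curve(curve, 1, fixed={"structure_parameter": 5.0})
        assert fit.converged
        realized = trace.metadata["realized_particle_counts"][0]
        n_eff = fccs.effective_particle_number(
            float(realized), config.optics, config.box_edge_lengths)
        assert fit.model.n_particles == pytest.approx(n_eff, rel=0.25)
        assert fit.model.components[0][1] == pytest.approx(1.5625e-2, rel=0.5)


class TestCalibration:
    def test_noiseless_structure_parameter_recovery(self):
        truth = make_model(n=2.0, tau=1e-3, s=5.0)
        cal = fccs.calibrate_structure_parameter(
            noiseless_curve(truth, n_lags=96), known_D=400.0)
        assert cal.structure_parameter == pytest.approx(5.0, rel=1e-6)
        assert cal.diffusion_time == pytest.approx(1e-3, rel=1e-6)

    def test_waist_scaling_with_known_diffusion_coefficient(self):
        # w0 = sqrt(4 D tau_D): halving D shrinks w0 by sqrt(2) at fixed tau_D
        truth = make_model(n=2.0, tau=1e-3, s=5.0)
        curve = noiseless_curve(truth, n_lags=96)
        full = fccs.calibrate_structure_parameter(curve, known_D=400.0)
        half = fccs.calibrate_structure_parameter(curve, known_D=200.0)
        assert half.structure_parameter == pytest.approx(
            full.structure_parameter, rel=1e-9)
        assert half.waist_w0 == pytest.approx(
            full.waist_w0 / math.sqrt(2), rel=1e-9)
        assert full.waist_w0 == pytest.approx(math.sqrt(4 * 400.0 * 1e-3), rel=1e-6)

    def test_invalid_known_d_rejected(self):
        truth = make_model()
        with pytest.raises(ConfigError):
            fccs.calibrate_structure_parameter(noiseless_curve(truth), known_D=0.0)
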