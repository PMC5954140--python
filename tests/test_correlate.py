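"""Correlation estimators: hand-computed values, oracle equivalence, errors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fccs
from fccs.correlate import multitau_lag_grid
from fccs.exceptions import ConfigError, ZeroSignalError

from conftest import tiled_trace


class TestDirect:
    def test_constant_trace_is_one_at_every_lag(self):
        trace = tiled_trace([5], [5], reps=120)
        curve = fccs.correlate_direct(trace, "gg", 10)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_alternating_pattern_autocorrelation_amplitude(self):
        # counts [1,3]: mean 2, dI = [-1,+1] -> G(0) = 1 + 1/4
        trace = tiled_trace([1, 3], [1, 1])
        curve = fccs.correlate_direct(trace, "gg", 2)
        assert curve.values[0] == pytest.approx(1.25, abs=1e-12)
        # one-bin shift flips the product sign on a period-2 pattern
        assert curve.values[1] == pytest.approx(0.75, rel=1e-3)
        assert curve.values[2] == pytest.approx(1.25, rel=1e-3)

    def test_anticorrelated_channels_cross_amplitude(self):
        # counts_g=[1,3] vs counts_r=[3,1]: G_gr(0) = 1 - 1/4
        trace = tiled_trace([1, 3], [3, 1])
        curve = fccs.correlate_direct(trace, "gr", 0)
        assert curve.values[0] == pytest.approx(0.75, abs=1e-12)

    def test_zero_mean_channel_rejected(self):
        trace = tiled_trace([0], [1], reps=120)
        with pytest.raises(ZeroSignalError, match="mean is zero"):
            fccs.correlate_direct(trace, "gg", 5)

    def test_max_lag_too_large_rejected(self):
        trace = tiled_trace([1, 2], [1, 1])
        with pytest.raises(ConfigError, match="half the trace length"):
            fccs.correlate_direct(trace, "gg", len(trace) // 2)

    def test_lag_grid_in_seconds(self):
        trace = tiled_trace([1, 2], [1, 1], bin_time=1e-3)
        curve = fccs.correlate_direct(trace, "gg", 3)
        np.testing.assert_allclose(curve.lags, [0, 1e-3, 2e-3, 3e-3])

    @given(st.integers(1, 30))
    def test_constant_traces_always_flat(self, value):
        trace = tiled_trace([value], [value], reps=150)
        curve = fccs.correlate_direct(trace, "gr", 8)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)


class TestCrossSymmetry:
    def test_both_index_orders_agree_at_lag_zero(self):
        rng = np.random.default_rng(0)
        g = rng.poisson(5.0, 2000)
        r = g + rng.poisson(2.0, 2000)
        t1 = fccs.TwoChannelTrace(1e-3, g, r)
        t2 = fccs.TwoChannelTrace(1e-3, r, g)
        v1 = fccs.correlate_direct(t1, "gr", 0).values[0]
        v2 = fccs.correlate_direct(t2, "gr", 0).values[0]
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestMultitau:
    def test_grid_is_strictly_increasing_quasi_log(self):
        lags = multitau_lag_grid(10_000, points_per_stage=16)
        assert np.all(np.diff(lags) > 0)
        assert lags[0] == 0 and lags[15] == 15
        # doubled spacing beyond the first stage
        assert 17 not in lags and 18 in lags

    def test_stage_zero_matches_direct_exactly(self, single_species_trace):
        trace, _, _ = single_species_trace
        mt = fccs.correlate_multitau(trace, "gg")
        direct = fccs.correlate_direct(trace, "gg", 15)
        np.testing.assert_allclose(mt.values[:16], direct.values, rtol=1e-12)

    def test_all_shared_lags_match_direct(self, single_species_trace):
        trace, _, _ = single_species_trace
        mt = fccs.correlate_multitau(trace, "gg", n_stages=6)
        bins = np.rint(mt.lags / trace.bin_time).astype(int)
        direct = fccs.correlate_direct(trace, "gg", int(bins[-1]))
        np.testing.assert_allclose(
            mt.values, direct.values[bins], rtol=1e-12)

    def test_constant_trace_flat(self):
        trace = tiled_trace([7], [7], reps=1024)
        curve = fccs.correlate_multitau(trace, "gg", n_stages=3)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_insufficient_length_names_minimum(self):
        trace = tiled_trace([1, 2], [1, 1], reps=60)
        with pytest.raises(ConfigError, match="need at least 2048 bins"):
            fccs.correlate_multitau(trace, "gg", n_stages=7)

    def test_poisson_white_noise_stays_within_shot_noise_band(self, optics):
        # background only: no emitters, so bins are independent Poisson and
        # every lag >= 1 bin must sit within 5 sigma of 1
        config = fccs.SimulationConfig(
            species=(),
            optics=fccs.OpticsSpec(0.25, 1.25, background_rate_green=1e5,
                                   background_rate_red=1e5),
            box_edge_lengths=(10, 10, 10),
            duration=10.0, time_step=1e-4, bin_time=1e-4, rng_seed=21)
        trace = fccs.simulate_trace(config)
        assert len(trace) == 100_000
        for kind in ("gg", "rr", "gr"):
            curve = fccs.correlate_multitau(trace, kind)
            mask = curve.lags > 0
            assert np.all(np.abs(curve.values[mask] - 1.0) < 5 / np.sqrt(100_000))

    def test_shuffled_trace_destroys_temporal_correlation(self, single_species_trace):
        trace, _, _ = single_species_trace
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(trace))
        shuffled = fccs.TwoChannelTrace(
            trace.bin_time, trace.counts_green[perm], trace.counts_green[perm])
        curve = fccs.correlate_multitau(shuffled, "gg")
        mask = curve.lags > 0
        mean_dev = np.abs(curve.values[mask] - 1.0).mean()
        assert mean_dev < 3 / np.sqrt(len(trace))


class TestSegmentErrors:
    def test_constant_trace_mean_one_stderr_zero(self):
        trace = tiled_trace([4], [4], reps=3000)
        curve = fccs.segment_errors(trace, "gg", n_segments=3, estimator="direct",
                                    max_lag_bins=10)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(curve.stderr, 0.0, atol=1e-12)
        assert curve.n_segments == 3

    def test_too_few_bins_per_segment_rejected(self):
        trace = tiled_trace([1, 2], [1, 1], reps=100)
        with pytest.raises(ConfigError, match="at least 100 bins"):
            fccs.segment_errors(trace, "gg", n_segments=10)

    def test_stderr_shrinks_with_trace_length(self, optics):
        # doubling the trace at fixed segment count must lower the median
        # stderr in every seed (resampling ~ 1/sqrt(segment length))
        species = fccs.SpeciesSpec("green_only", 1.0, 100.0, brightness_green=2e4)
        shorter, longer = [], []
        for seed in range(10):
            for dur, out in ((5.0, shorter), (10.0, longer)):
                config = fccs.SimulationConfig(
                    species=(species,), optics=optics,
                    box_edge_lengths=(3.0, 3.0, 5.0),
                    duration=dur, time_step=4e-4, bin_time=4e-4, rng_seed=seed)
                trace = fccs.simulate_trace(config)
                curve = fccs.segment_errors(trace, "gg", n_segments=20,
                                            n_stages=3)
                out.append(np.median(curve.stderr[curve.lags > 0]))
        assert all(l < s for s, l in zip(shorter, longer))

    def test_segment_mean_consistent_with_full_trace_curve(self, optics):
        # fast-decaying species so segments are long compared to the
        # correlation time and the segment-mean bias stays below the errors
        species = fccs.SpeciesSpec("green_only", 25.0, 100.0, brightness_green=5e5)
        config = fccs.SimulationConfig(
            species=(species,), optics=optics, box_edge_lengths=(3.0, 3.0, 5.0),
            duration=10.0, time_step=5e-5, bin_time=5e-5, rng_seed=17)
        trace = fccs.simulate_trace(config)
        seg = fccs.segment_errors(trace, "gg", n_segments=5, n_stages=6)
        full = fccs.correlate_multitau(trace, "gg", n_stages=6)
        mask = seg.stderr > 0
        dev = np.abs(seg.values[mask] - full.values[mask])
        assert np.all(dev <= 2 * seg.stderr[mask] + 1e-4)

    def test_estimate_curve_combines_full_values_and_segment_errors(
            self, single_species_trace):
        trace, _, _ = single_species_trace
        est = fccs.estimate_curve(trace, "gg", n_segments=5)
        seg = fccs.segment_errors(trace, "gg", n_segments=5)
        np.testing.assert_allclose(est.lags, seg.lags)
        np.testing.assert_allclose(est.stderr, seg.stderr)
        assert est.n_segments == 5


class TestAmplitudeLaw:
    def test_first_lag_amplitude_inverts_particle_number(self, single_species_trace):
        # G(first lag) - 1 = 1/N_eff within 3 resampling standard errors
        trace, config, species = single_species_trace
        curve = fccs.estimate_curve(trace, "gg")
        # the per-realization truth uses the realized Poisson particle count
        realized = trace.metadata["realized_particle_counts"][0]
        n_eff = fccs.effective_particle_number(
            float(realized), config.optics, config.box_edge_lengths)
        idx = np.nonzero(curve.lags > 0)[0][0]
        amp = curve.values[idx] - 1.0
        assert abs(amp - 1.0 / n_eff) < 3 * max(curve.stderr[idx], 0.01 / n_eff)
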