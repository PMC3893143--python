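import numpy as np
import pytest

from motifnet import netsim
from motifnet.params import NeuronParams, TripletParams

from conftest import toy_params


def _run(composition, seed, **overrides):
    params = toy_params(**overrides)
    rng = np.random.default_rng(seed)
    wiring = netsim.build_wiring(params["n"], params["prune_fraction"], rng, params["a_pA"])
    netsim.assign_sd_kinds(wiring, composition, seed=rng)
    w0 = netsim.init_weights(wiring, seed=rng)
    protocol = netsim.StimulusProtocol(
        baseline_pA=params["baseline_pA"],
        pulse_pA=params["pulse_pA"],
        dwell_ms=params["dwell_ms"],
        sigma_idx=params["sigma_idx"],
        noise_mean_pA=params["noise_mean_pA"],
        noise_std_pA=params["noise_std_pA"],
    )
    rule = TripletParams(rate=params["plasticity_rate"])
    result = netsim.simulate(
        wiring, w0, protocol, params["duration_ms"], rule=rule,
        dt_ms=params["dt_ms"], seed=seed,
    )
    return result, wiring, w0


class TestBuildWiring:
    def test_no_pruning_gives_complete_digraph(self):
        w = netsim.build_wiring(7, 0.0, 0)
        assert w.C.sum() == 7 * 6
        assert np.all(np.diagonal(w.C) == 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            netsim.build_wiring(1, 0.0, 0)
        with pytest.raises(ValueError):
            netsim.build_wiring(5, 1.0, 0)

    def test_determinism(self):
        a = netsim.build_wiring(20, 0.3, 42)
        b = netsim.build_wiring(20, 0.3, 42)
        np.testing.assert_array_equal(a.C, b.C)

    def test_heavy_pruning_edge_count_binomial(self):
        # edges ~ Binomial(N(N-1), eps); check a 5-sigma interval
        n, eps = 50, 0.1
        w = netsim.build_wiring(n, 1.0 - eps, 3)
        m = n * (n - 1)
        mean, sd = m * eps, np.sqrt(m * eps * (1 - eps))
        assert abs(w.C.sum() - mean) < 5 * sd


class TestTravelingWave:
    PROTO = netsim.StimulusProtocol(baseline_pA=100.0, pulse_pA=500.0, dwell_ms=20.0,
                                    sigma_idx=0.4)

    def test_center_gets_unit_peak(self):
        # at t just inside the 3rd dwell window the wave sits on unit 3
        val = netsim.traveling_wave_current(61.0, 3, self.PROTO, 10)
        assert val == pytest.approx(600.0)

    def test_far_neuron_at_baseline(self):
        val = netsim.traveling_wave_current(61.0, 8, self.PROTO, 10)
        assert val == pytest.approx(100.0, abs=1e-3)

    def test_periodicity(self):
        t = 37.0
        a = netsim.traveling_wave_current(t, 5, self.PROTO, 10)
        b = netsim.traveling_wave_current(t + 10 * 20.0, 5, self.PROTO, 10)
        assert a == pytest.approx(b)

    def test_wrap_distance(self):
        # unit 9 is one ring-step from unit 0
        v1 = netsim.traveling_wave_current(1.0, 9, self.PROTO, 10)
        v2 = netsim.traveling_wave_current(1.0, 1, self.PROTO, 10)
        assert v1 == pytest.approx(v2)


class TestBackgroundNoise:
    def test_zero_std_gives_constant_means(self):
        proto = netsim.StimulusProtocol(noise_mean_pA=100.0, noise_std_pA=0.0)
        stream = netsim.background_noise_current(4, proto, 0.5, 100, seed=1)
        assert np.all(stream.std(axis=0) < 1e-9)
        np.testing.assert_allclose(stream[0], stream[-1], rtol=1e-12)

    def test_autocorrelation_time(self):
        tau = 5.0
        proto = netsim.StimulusProtocol(noise_mean_pA=0.0, noise_std_pA=50.0,
                                        noise_tau_ms=tau)
        dt = 0.5
        stream = netsim.background_noise_current(1, proto, dt, 400_000, seed=2)[:, 0]
        lag = int(tau / dt)
        x = stream - stream.mean()
        rho = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
        assert rho == pytest.approx(np.exp(-1.0), abs=0.05)

    def test_streams_uncorrelated_across_neurons(self):
        proto = netsim.StimulusProtocol(noise_mean_pA=0.0, noise_std_pA=50.0)
        stream = netsim.background_noise_current(2, proto, 0.5, 200_000, seed=3)
        r = np.corrcoef(stream[:, 0], stream[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_dt_above_tau_rejected(self):
        proto = netsim.StimulusProtocol(noise_tau_ms=1.0)
        with pytest.raises(ValueError):
            netsim.background_noise_current(2, proto, 2.0, 10)


class TestSimulate:
    def test_uncoupled_network_follows_wave(self):
        # A = 0, single-spike pulses: every neuron fires once per wave
        # revolution, i.e. at 1 / (N * dwell)
        rng = np.random.default_rng(0)
        wiring = netsim.build_wiring(10, 0.2, rng, 0.0)
        netsim.assign_sd_kinds(wiring, "depressing", seed=rng)
        w0 = netsim.init_weights(wiring, seed=rng)
        protocol = netsim.StimulusProtocol(
            baseline_pA=480.0, pulse_pA=1200.0, dwell_ms=20.0,
            pulse_duration_ms=10.0, sigma_idx=0.4,
        )
        res = netsim.simulate(wiring, w0, protocol, 10_000.0, rule=TripletParams(rate=0.0), seed=0)
        expected = 1000.0 / (10 * 20.0)
        np.testing.assert_allclose(res.rates_hz, expected, atol=0.11)

    def test_determinism(self):
        a, _, _ = _run("facilitating", 5, duration_ms=2000.0)
        b, _, _ = _run("facilitating", 5, duration_ms=2000.0)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)
        np.testing.assert_array_equal(a.spikes.ids, b.spikes.ids)
        np.testing.assert_array_equal(a.w_final, b.w_final)

    def test_isi_respects_refractory_period(self):
        res, _, _ = _run("facilitating", 1, duration_ms=3000.0)
        refractory = NeuronParams().refractory_period
        for i in range(res.spikes.n_neurons):
            t = res.spikes.times[res.spikes.ids == i]
            if len(t) > 1:
                assert np.min(np.diff(t)) >= refractory

    def test_spike_times_nondecreasing(self):
        res, _, _ = _run("depressing", 2, duration_ms=2000.0)
        assert np.all(np.diff(res.spikes.times) >= 0)

    def test_plasticity_disabled_freezes_weights(self):
        res, _, w0 = _run("facilitating", 3, plasticity_rate=0.0, duration_ms=3000.0)
        for snap in res.snapshots:
            np.testing.assert_array_equal(snap, w0)

    def test_facilitating_fires_above_depressing(self):
        # full >= 20-seed version lives in the acceptance suite
        for seed in range(3):
            rd, _, _ = _run("depressing", seed, duration_ms=10_000.0)
            rf, _, _ = _run("facilitating", seed, duration_ms=10_000.0)
            assert rf.rates_hz.mean() > rd.rates_hz.mean()

    def test_dimension_mismatch_rejected(self):
        wiring = netsim.build_wiring(5, 0.0, 0)
        netsim.assign_sd_kinds(wiring, "depressing")
        with pytest.raises(ValueError):
            netsim.simulate(wiring, np.zeros((4, 4)), netsim.StimulusProtocol(), 100.0)

    def test_euler_convergence_on_uncoupled_drive(self):
        # halving dt changes per-neuron spike counts by <= 1 over 1 s
        counts = {}
        for dt in (0.1, 0.05):
            params = toy_params(a_pA=0.0, duration_ms=1000.0, dt_ms=dt)
            rng = np.random.default_rng(0)
            wiring = netsim.build_wiring(10, 0.2, rng, 0.0)
            netsim.assign_sd_kinds(wiring, "depressing", seed=rng)
            w0 = netsim.init_weights(wiring, seed=rng)
            protocol = netsim.StimulusProtocol(
                baseline_pA=480.0, pulse_pA=600.0, dwell_ms=20.0, sigma_idx=0.4
            )
            res = netsim.simulate(
                wiring, w0, protocol, 1000.0, rule=TripletParams(rate=0.0),
                dt_ms=dt, seed=0,
            )
            counts[dt] = np.bincount(res.spikes.ids, minlength=10)
        assert np.max(np.abs(counts[0.1] - counts[0.05])) <= 1


class TestRateSummary:
    def test_counts_over_window(self):
        spikes = netsim.SpikeRecord(
            times=np.array([100.0, 500.0, 900.0]),
            ids=np.array([0, 0, 0]),
            duration_ms=1000.0,
            dt_ms=0.1,
            n_neurons=2,
        )
        rates, _, _ = netsim.rate_summary(spikes, 1000.0)
        assert rates[0] == pytest.approx(3.0)
        assert rates[1] == 0.0

    def test_window_longer_than_run_rejected(self):
        spikes = netsim.SpikeRecord(np.array([]), np.array([], dtype=int), 1000.0, 0.1, 2)
        with pytest.raises(ValueError):
            netsim.rate_summary(spikes, 2000.0)

    def test_empty_record_gives_zero_rates(self):
        spikes = netsim.SpikeRecord(np.array([]), np.array([], dtype=int), 1000.0, 0.1, 3)
        rates, hist, _ = netsim.rate_summary(spikes, 500.0)
        np.testing.assert_array_equal(rates, 0.0)

    def test_histogram_permutation_invariant(self, rng):
        ids = rng.integers(0, 8, 200)
        times = np.sort(rng.uniform(0, 1000.0, 200))
        perm = rng.permutation(8)
        a = netsim.SpikeRecord(times, ids, 1000.0, 0.1, 8)
        b = netsim.SpikeRecord(times, perm[ids], 1000.0, 0.1, 8)
        _, ha, ea = netsim.rate_summary(a, 1000.0, bins=np.arange(0, 300, 10.0))
        _, hb, _ = netsim.rate_summary(b, 1000.0, bins=np.arange(0, 300, 10.0))
        np.testing.assert_array_equal(ha, hb)
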