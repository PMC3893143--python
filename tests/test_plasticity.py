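import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifnet import plasticity as pl
from motifnet.params import TRIPLET_MINIMAL, TripletParams


class TestDecayTraces:
    def test_zero_traces_stay_zero(self, triplet_rule):
        traces = pl.TraceState.zeros(4)
        out = pl.decay_traces(traces, 10.0, triplet_rule)
        for tr in (out.r1, out.r2, out.o1, out.o2):
            assert np.all(tr == 0.0)

    def test_closed_form(self, triplet_rule):
        traces = pl.TraceState.zeros(1)
        traces.r1[0] = 1.0
        out = pl.decay_traces(traces, triplet_rule.tau_plus, triplet_rule)
        assert out.r1[0] == pytest.approx(math.exp(-1.0))

    def test_semigroup_property(self, rng, triplet_rule):
        traces = pl.TraceState(*(rng.uniform(0, 3, 5) for _ in range(4)))
        one = pl.decay_traces(traces, 7.0, triplet_rule)
        two = pl.decay_traces(pl.decay_traces(traces, 3.5, triplet_rule), 3.5, triplet_rule)
        for a, b in zip((one.r1, one.r2, one.o1, one.o2), (two.r1, two.r2, two.o1, two.o2)):
            np.testing.assert_allclose(a, b, rtol=1e-12)


class TestOnSpike:
    def test_isolated_spike_changes_nothing(self, triplet_rule):
        n = 3
        wiring = np.ones((n, n)) - np.eye(n)
        w = np.full((n, n), 0.4) * wiring
        traces = pl.TraceState.zeros(n)
        new_traces, new_w = pl.on_spike(1, traces, w, wiring, triplet_rule)
        np.testing.assert_array_equal(new_w, w)
        for tr in (new_traces.r1, new_traces.r2, new_traces.o1, new_traces.o2):
            assert tr[1] == 1.0

    def test_unwired_entries_never_change(self, rng, triplet_rule):
        n = 4
        wiring = (rng.random((n, n)) > 0.5).astype(float)
        np.fill_diagonal(wiring, 0)
        w = rng.uniform(0, 1, (n, n)) * wiring
        traces = pl.TraceState(*(rng.uniform(0, 2, n) for _ in range(4)))
        for j in range(n):
            traces, w_new = pl.on_spike(j, traces, w, wiring, triplet_rule)
            np.testing.assert_array_equal(w_new[wiring == 0], w[wiring == 0])
            w = w_new

    def test_pre_post_pairing_gives_ltp(self):
        assert pl.run_timing_protocol(10.0, 60, 1.0, TRIPLET_MINIMAL) > 0

    def test_post_pre_pairing_gives_ltd(self):
        assert pl.run_timing_protocol(-10.0, 60, 1.0, TRIPLET_MINIMAL) < 0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_weights_bounded_under_random_spikes(self, seed):
        rng = np.random.default_rng(seed)
        n = 4
        rule = TripletParams(rate=50.0)  # exaggerate updates
        wiring = np.ones((n, n)) - np.eye(n)
        w = rng.uniform(0, rule.w_max, (n, n)) * wiring
        traces = pl.TraceState.zeros(n)
        for _ in range(60):
            traces = pl.decay_traces(traces, rng.uniform(0.1, 30.0), rule)
            traces, w = pl.on_spike(int(rng.integers(n)), traces, w, wiring, rule)
            assert np.all(w >= 0.0) and np.all(w <= rule.w_max)


class TestConfigureRule:
    def test_triplet_is_identity(self, triplet_rule):
        out = pl.configure_rule("triplet", triplet_rule)
        assert out == triplet_rule

    def test_unknown_variant_rejected(self, triplet_rule):
        with pytest.raises(ValueError):
            pl.configure_rule("quadruplet", triplet_rule)

    def test_pair_window_matches_triplet_at_reference_rate(self):
        ref_rate = 5.0
        pair = pl.configure_rule("pair", TRIPLET_MINIMAL, ref_rate)
        assert pair.a3_plus == 0.0 and pair.a3_minus == 0.0
        grid = np.concatenate([np.arange(-80, 0, 10.0), np.arange(10, 90, 10.0)])
        tri = [pl.run_timing_protocol(d, 60, ref_rate, TRIPLET_MINIMAL) for d in grid]
        par = [pl.run_timing_protocol(d, 60, ref_rate, pair) for d in grid]
        np.testing.assert_allclose(par, tri, atol=5e-3)

    def test_anti_window_mirrors_triplet(self):
        # inverted temporal dependency: the anti response at +dt tracks
        # the triplet response at -dt (sign and comparable magnitude)
        anti = pl.configure_rule("anti", TRIPLET_MINIMAL)
        for dt in (5.0, 10.0, 20.0, 40.0):
            tri_ltd = pl.run_timing_protocol(-dt, 60, 1.0, TRIPLET_MINIMAL)
            anti_ltd = pl.run_timing_protocol(dt, 60, 1.0, anti)
            assert anti_ltd < 0 and tri_ltd < 0
            assert 0.3 < anti_ltd / tri_ltd < 3.0
            tri_ltp = pl.run_timing_protocol(dt, 60, 1.0, TRIPLET_MINIMAL)
            anti_ltp = pl.run_timing_protocol(-dt, 60, 1.0, anti)
            assert tri_ltp >= 0 and anti_ltp >= 0


class TestTimingProtocol:
    def test_zero_pairs(self):
        assert pl.run_timing_protocol(10.0, 0, 1.0, TRIPLET_MINIMAL) == 0.0

    def test_anti_inverts_low_frequency_sign(self):
        anti = pl.configure_rule("anti", TRIPLET_MINIMAL)
        assert pl.run_timing_protocol(-10.0, 60, 1.0, TRIPLET_MINIMAL) < 0
        assert pl.run_timing_protocol(-10.0, 60, 1.0, anti) > 0

    def test_degenerate_rate_rejected(self):
        with pytest.raises(ValueError):
            pl.run_timing_protocol(10.0, 10, 200.0, TRIPLET_MINIMAL)


class TestFrequencyProtocol:
    def test_triplet_reversal(self):
        rates = np.array([1.0, 5.0, 10.0, 45.0, 50.0])
        vals = pl.run_frequency_protocol(-10.0, TRIPLET_MINIMAL, rates)
        assert np.all(vals[:3] < 0)
        assert np.all(vals[-2:] > 0)

    def test_pair_rule_no_reversal(self):
        pair = pl.configure_rule("pair", TRIPLET_MINIMAL)
        vals = pl.run_frequency_protocol(-10.0, pair, np.array([1.0, 10.0, 30.0, 50.0]))
        assert np.all(vals < 0)

    def test_anti_rule_keeps_reversal(self):
        anti = pl.configure_rule("anti", TRIPLET_MINIMAL)
        vals = pl.run_frequency_protocol(10.0, anti, np.array([1.0, 5.0, 40.0, 50.0]))
        assert vals[0] < 0 and vals[-1] > 0

    def test_too_high_rate_rejected(self):
        with pytest.raises(ValueError):
            pl.run_frequency_protocol(-10.0, TRIPLET_MINIMAL, np.array([150.0]))


class TestCrossover:
    def test_triplet_crossover_in_published_band(self):
        cross = pl.ltd_ltp_crossover(TRIPLET_MINIMAL, -10.0)
        assert cross is not None
        assert 30.0 <= cross <= 40.0

    def test_pair_rule_reports_no_crossover(self):
        pair = pl.configure_rule("pair", TRIPLET_MINIMAL)
        assert pl.ltd_ltp_crossover(pair, -10.0) is None

    def test_pure_ltd_reports_no_crossover(self):
        rule = TripletParams(a2_plus=0.0, a3_plus=0.0)
        assert pl.ltd_ltp_crossover(rule, -10.0) is None


class TestRatePairMap:
    RULE = TRIPLET_MINIMAL

    def test_zero_post_rate_row_nonpositive(self):
        out = pl.rate_pair_map(
            np.array([0.0, 10.0, 20.0]), np.array([0.0]), -10.0, self.RULE,
            duration_ms=1000.0,
        )
        assert np.all(out <= 0.0)

    def test_zero_pre_rate_column_zero(self):
        out = pl.rate_pair_map(
            np.array([0.0]), np.array([0.0, 20.0, 50.0]), -10.0, self.RULE,
            duration_ms=1000.0,
        )
        np.testing.assert_array_equal(out, 0.0)

    def test_high_post_rate_dominates_timing(self):
        # incommensurate pre rate, post rate above the crossover: LTP
        out = pl.rate_pair_map(
            np.array([7.0]), np.array([50.0]), -10.0, self.RULE, duration_ms=3000.0
        )
        assert out[0, 0] > 0


class TestPairEquivalence:
    def test_zeroed_triplet_terms_match_pair_implementation(self, rng):
        # dual-route check: the generic engine with zeroed triplet
        # amplitudes must agree bit-for-bit with a direct pair-based
        # accumulation over all spike pairs (all-to-all, unclipped).
        a2p, a2m = 4e-3, 6e-3
        rule = TripletParams(
            a2_plus=a2p, a2_minus=a2m, a3_plus=0.0, a3_minus=0.0, variant="pair"
        )
        for _ in range(5):
            pre = np.sort(rng.uniform(0, 2000.0, 40))
            post = np.sort(rng.uniform(0, 2000.0, 40))
            got = pl.run_spike_trains(pre, post, rule, w0=0.0, clip=False)
            expected = 0.0
            for tp in post:  # LTP: sum over earlier pre spikes
                expected += a2p * sum(
                    math.exp(-(tp - tq) / rule.tau_plus) for tq in pre if tq < tp
                )
            for tq in pre:  # LTD: sum over earlier post spikes
                expected -= a2m * sum(
                    math.exp(-(tq - tp) / rule.tau_minus) for tp in post if tp < tq
                )
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestPoissonDriftSign:
    @pytest.mark.parametrize(
        "nu_pre,nu_post,expect_positive",
        [(20.0, 10.0, False), (20.0, 30.0, True), (10.0, 25.0, True)],
    )
    def test_drift_sign_matches_mean_field(self, nu_pre, nu_post, expect_positive):
        from motifnet.meanfield import critical_frequency

        nu_theta = critical_frequency(TRIPLET_MINIMAL)
        assert (nu_post > nu_theta) == expect_positive  # consistency of the setup
        rng = np.random.default_rng(99)
        drifts = [
            pl.poisson_drift(TRIPLET_MINIMAL, nu_pre, nu_post, 100_000.0, rng)
            for _ in range(4)
        ]
        mean = np.mean(drifts)
        assert (mean > 0) == expect_positive
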