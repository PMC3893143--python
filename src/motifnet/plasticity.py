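"""Long-term plasticity: triplet STDP and its pair-based / anti controls.

Each neuron carries four exponentially decaying spike detectors: two
presynaptic (``r1``, ``r2``) and two postsynaptic (``o1``, ``o2``).  On a
spike of neuron *i*, every outgoing synapse is depressed proportionally
to the postsynaptic ``o1`` detector (pair LTD, optionally gated by
``r2``), every incoming synapse is potentiated proportionally to the
presynaptic ``r1`` detector gated by ``o2`` (triplet LTP), and the four
detectors of neuron *i* are then incremented by one.  Second-order
detectors are always evaluated just before the increment.

The ``anti`` variant swaps the (pair, triplet) amplitude values between
the LTD and LTP branches and inverts the sign of both updates, which
mirrors the low-rate timing window while preserving the high-rate
reversal of depression into potentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import TripletParams

__all__ = [
    "TraceState",
    "decay_traces",
    "on_spike",
    "configure_rule",
    "run_spike_trains",
    "run_timing_protocol",
    "run_frequency_protocol",
    "ltd_ltp_crossover",
    "rate_pair_map",
    "update_signs",
]


@dataclass
class TraceState:
    """Per-neuron detector vectors, all nonnegative."""

    r1: np.ndarray
    r2: np.ndarray
    o1: np.ndarray
    o2: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "TraceState":
        return cls(*(np.zeros(n) for _ in range(4)))

    def copy(self) -> "TraceState":
        return TraceState(self.r1.copy(), self.r2.copy(), self.o1.copy(), self.o2.copy())


def update_signs(params: TripletParams) -> tuple[float, float]:
    """Signs of the (pre-spike, post-spike) weight updates.

    ``(-1, +1)`` for the triplet and pair rules (depression when the
    presynaptic side fires, potentiation when the postsynaptic side
    fires); inverted for the anti variant.
    """
    return (1.0, -1.0) if params.variant == "anti" else (-1.0, 1.0)


def decay_traces(traces: TraceState, dt: float, params: TripletParams) -> TraceState:
    """Exponential relaxation of all four detectors over ``dt`` (ms)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return TraceState(
        traces.r1 * math.exp(-dt / params.tau_plus),
        traces.r2 * math.exp(-dt / params.tau_x),
        traces.o1 * math.exp(-dt / params.tau_minus),
        traces.o2 * math.exp(-dt / params.tau_y),
    )


def on_spike(
    neuron_id: int,
    traces: TraceState,
    w: np.ndarray,
    wiring: np.ndarray,
    params: TripletParams,
) -> tuple[TraceState, np.ndarray]:
    """Apply all weight updates triggered by a spike of ``neuron_id``.

    ``w`` and ``wiring`` are ``(N, N)`` matrices indexed ``[post, pre]``.
    Returns updated traces and weights (inputs are not mutated).
    """
    n = w.shape[0]
    if not 0 <= neuron_id < n:
        raise ValueError(f"neuron_id {neuron_id} out of range for N={n}")
    sign_pre, sign_post = update_signs(params)
    lam = params.rate
    w = w.copy()
    j = neuron_id

    # neuron j as presynaptic: all outgoing synapses w[:, j]
    mask_out = wiring[:, j] != 0
    w[mask_out, j] += sign_pre * lam * traces.o1[mask_out] * (
        params.a2_minus + params.a3_minus * traces.r2[j]
    )
    # neuron j as postsynaptic: all incoming synapses w[j, :]
    mask_in = wiring[j, :] != 0
    w[j, mask_in] += sign_post * lam * traces.r1[mask_in] * (
        params.a2_plus + params.a3_plus * traces.o2[j]
    )
    np.clip(w, 0.0, params.w_max, out=w)

    traces = traces.copy()
    for tr in (traces.r1, traces.r2, traces.o1, traces.o2):
        tr[j] += 1.0
    return traces, w


def _steady_pre_spike_o2(rate_hz: float, tau_y: float) -> float:
    """Steady-state value of o2 just before a spike of a regular train."""
    if rate_hz <= 0:
        return 0.0
    decay = math.exp(-1000.0 / rate_hz / tau_y)
    return decay / (1.0 - decay)


def configure_rule(
    variant: str,
    params: TripletParams,
    pair_reference_rate_hz: float = 5.0,
) -> TripletParams:
    """Return the parameter set implementing the requested rule variant.

    ``pair``: triplet amplitudes are zeroed and the pair LTP amplitude is
    re-tuned so the timing window at ``pair_reference_rate_hz`` matches
    the triplet rule's window at that (low) pairing rate.

    ``anti``: the (pair, triplet) amplitude values are swapped between
    the LTD and LTP branches; the engine then inverts the update signs
    (see :func:`update_signs`).
    """
    if variant == "triplet":
        return replace(params, variant="triplet")
    if variant == "pair":
        o2_bar = _steady_pre_spike_o2(pair_reference_rate_hz, params.tau_y)
        return replace(
            params,
            a2_plus=params.a2_plus + params.a3_plus * o2_bar,
            a3_plus=0.0,
            a3_minus=0.0,
            variant="pair",
        )
    if variant == "anti":
        return replace(
            params,
            a2_plus=params.a2_minus,
            a3_plus=params.a3_minus,
            a2_minus=params.a2_plus,
            a3_minus=params.a3_plus,
            variant="anti",
        )
    raise ValueError(f"unknown variant {variant!r}")


def run_spike_trains(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    rule: TripletParams,
    w0: float = 0.5,
    clip: bool = True,
) -> float:
    """Total weight change on one synapse for given pre/post spike trains.

    Event-driven with exact inter-event decay.  Spikes that coincide in
    time are processed presynaptic-side first, so the depression branch
    sees the postsynaptic detectors before they are incremented.
    Returns ``w_final - w0``.
    """
    events = [(float(t), 0) for t in np.asarray(pre_times, dtype=float)]
    events += [(float(t), 1) for t in np.asarray(post_times, dtype=float)]
    events.sort()
    sign_pre, sign_post = update_signs(rule)
    lam = rule.rate
    r1 = r2 = o1 = o2 = 0.0
    w = w0
    t_last = None
    for t, side in events:
        if t_last is not None:
            dt = t - t_last
            if dt > 0:
                r1 *= math.exp(-dt / rule.tau_plus)
                r2 *= math.exp(-dt / rule.tau_x)
                o1 *= math.exp(-dt / rule.tau_minus)
                o2 *= math.exp(-dt / rule.tau_y)
        if side == 0:  # presynaptic spike: depression branch, then r-increments
            w += sign_pre * lam * o1 * (rule.a2_minus + rule.a3_minus * r2)
            r1 += 1.0
            r2 += 1.0
        else:  # postsynaptic spike: potentiation branch, then o-increments
            w += sign_post * lam * r1 * (rule.a2_plus + rule.a3_plus * o2)
            o1 += 1.0
            o2 += 1.0
        if clip:
            w = min(max(w, 0.0), rule.w_max)
        t_last = t
    return w - w0


def _pair_trains(
    delta_t_ms: float, n_pairs: int, pairing_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    period = 1000.0 / pairing_rate_hz
    base = np.arange(n_pairs) * period + abs(delta_t_ms)
    return base, base + delta_t_ms


def run_timing_protocol(
    delta_t_ms: float,
    n_pairs: int = 60,
    pairing_rate_hz: float = 1.0,
    rule: TripletParams | None = None,
    w0: float = 0.5,
) -> float:
    """Relative weight change for ``n_pairs`` pre/post pairs at fixed offset.

    Positive ``delta_t_ms`` means the presynaptic spike leads.  Returns
    ``(w_final - w0) / w0``.
    """
    rule = TripletParams() if rule is None else rule
    if n_pairs == 0:
        return 0.0
    if n_pairs < 0:
        raise ValueError("n_pairs must be nonnegative")
    period = 1000.0 / pairing_rate_hz
    if period <= abs(delta_t_ms):
        raise ValueError(
            f"pairing rate {pairing_rate_hz} Hz too high for |delta_t| = {abs(delta_t_ms)} ms"
        )
    pre, post = _pair_trains(delta_t_ms, n_pairs, pairing_rate_hz)
    return run_spike_trains(pre, post, rule, w0=w0) / w0


def run_frequency_protocol(
    delta_t_ms: float,
    rule: TripletParams,
    rates_hz: np.ndarray,
    n_pairs: int = 60,
    w0: float = 0.5,
) -> np.ndarray:
    """Relative weight change per pairing rate, fixed spike-pair offset."""
    rates = np.asarray(rates_hz, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("pairing rates must be positive")
    bad = rates[1000.0 / rates <= abs(delta_t_ms)]
    if bad.size:
        raise ValueError(
            f"rates {bad} Hz leave no room for |delta_t| = {abs(delta_t_ms)} ms between pairs"
        )
    return np.array(
        [
            run_timing_protocol(delta_t_ms, n_pairs, rate, rule, w0=w0)
            for rate in rates
        ]
    )


def ltd_ltp_crossover(
    rule: TripletParams,
    delta_t_ms: float = -10.0,
    bracket_hz: tuple[float, float] = (0.5, 60.0),
    n_pairs: int = 60,
    tol_hz: float = 0.1,
) -> float | None:
    """Pairing rate at which the net weight change crosses zero.

    Bisection on the frequency-protocol response.  Returns ``None`` when
    the response does not change sign over the bracket (e.g. for the
    pair-based control, which shows no reversal).
    """
    lo, hi = bracket_hz

    def f(rate: float) -> float:
        return run_timing_protocol(delta_t_ms, n_pairs, rate, rule)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None
    while hi - lo > tol_hz:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def rate_pair_map(
    pre_rates_hz: np.ndarray,
    post_rates_hz: np.ndarray,
    delta_t_ms: float,
    rule: TripletParams,
    duration_ms: float = 2000.0,
    w0: float = 0.5,
) -> np.ndarray:
    """Weight-change map over independent pre/post regular-train rates.

    Entry ``[i, j]`` is the relative change for postsynaptic rate
    ``post_rates_hz[i]`` and presynaptic rate ``pre_rates_hz[j]``; the
    postsynaptic train is shifted by ``delta_t_ms`` relative to the
    presynaptic one.
    """
    pre_rates = np.asarray(pre_rates_hz, dtype=float)
    post_rates = np.asarray(post_rates_hz, dtype=float)
    out = np.zeros((post_rates.size, pre_rates.size))
    t0 = abs(delta_t_ms)
    for j, nu_pre in enumerate(pre_rates):
        if nu_pre <= 0:
            continue  # no synaptic events at all
        pre = t0 + np.arange(0.0, duration_ms, 1000.0 / nu_pre)
        for i, nu_post in enumerate(post_rates):
            if nu_post <= 0:
                post = np.empty(0)
            else:
                post = t0 + delta_t_ms + np.arange(0.0, duration_ms, 1000.0 / nu_post)
            out[i, j] = run_spike_trains(pre, post, rule, w0=w0) / w0
    return out


def poisson_drift(
    rule: TripletParams,
    rate_pre_hz: float,
    rate_post_hz: float,
    duration_ms: float,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo mean weight drift (per second) under independent
    Poisson pre/post trains, unclipped; used to cross-check the
    mean-field drift expression."""
    n_pre = rng.poisson(rate_pre_hz * duration_ms / 1000.0)
    n_post = rng.poisson(rate_post_hz * duration_ms / 1000.0)
    pre = np.sort(rng.uniform(0.0, duration_ms, n_pre))
    post = np.sort(rng.uniform(0.0, duration_ms, n_post))
    dw = run_spike_trains(pre, post, rule, w0=0.5, clip=False)
    return dw / (duration_ms / 1000.0)
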