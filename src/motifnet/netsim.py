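"""Network assembly, stimulus generation, and the coupled simulator.

Networks are all-to-all minus autapses with random pruning.  External
drive is a deterministic traveling wave of depolarizing pulses over the
(ring of) neuron indices, optionally with per-neuron colored background
noise and a constant extra drive to a chosen subset of units.  The
simulation loop advances neurons, per-synapse short-term dynamics,
postsynaptic currents, plasticity detectors and the scaling-factor
matrix with a shared forward-Euler step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import (
    DEFAULT_A_PA,
    DEFAULT_DT_MS,
    DEFAULT_PRUNE_FRACTION,
    DEFAULT_W_MAX,
    NeuronParams,
    SDParams,
    TripletParams,
    SD_DEPRESSING,
    SD_FACILITATING,
)
from . import plasticity

__all__ = [
    "Wiring",
    "StimulusProtocol",
    "SpikeRecord",
    "SimResult",
    "build_wiring",
    "assign_sd_kinds",
    "init_weights",
    "traveling_wave_current",
    "background_noise_current",
    "simulate",
    "rate_summary",
]

KIND_NONE, KIND_D, KIND_F = -1, 0, 1
KIND_LABELS = {KIND_D: "D", KIND_F: "F", KIND_NONE: "-"}


@dataclass
class Wiring:
    """Binary directed wiring ``C[post, pre]`` with efficacies and SD kinds."""

    C: np.ndarray                  # (N, N) int8, zero diagonal
    A: np.ndarray                  # (N, N) maximal efficacy, pA
    labels: np.ndarray             # (N,) population label per neuron, 'D'/'F'
    kind: np.ndarray               # (N, N) int8: KIND_D / KIND_F / KIND_NONE

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass
class StimulusProtocol:
    """Traveling-wave drive plus optional colored noise and extra drive."""

    baseline_pA: float = 0.0
    pulse_pA: float = 0.0
    dwell_ms: float = 20.0         # time the wave spends on one unit
    sigma_idx: float = 0.4         # spatial width of the pulse profile
    pulse_duration_ms: float | None = None  # defaults to dwell_ms
    wrap: bool = True
    noise_mean_pA: float = 0.0     # mean of the per-neuron OU means
    noise_std_pA: float = 0.0
    noise_tau_ms: float = 5.0
    drive_extra_pA: np.ndarray | None = None  # constant extra drive per neuron

    def __post_init__(self) -> None:
        if self.dwell_ms <= 0 or self.sigma_idx <= 0:
            raise ValueError("dwell_ms and sigma_idx must be positive")
        if self.noise_std_pA < 0 or self.noise_tau_ms <= 0:
            raise ValueError("noise parameters must be nonnegative / positive")
        if self.pulse_duration_ms is None:
            self.pulse_duration_ms = self.dwell_ms


@dataclass
class SpikeRecord:
    times: np.ndarray      # ms, nondecreasing
    ids: np.ndarray        # int
    duration_ms: float
    dt_ms: float
    n_neurons: int


@dataclass
class SimResult:
    spikes: SpikeRecord
    w_final: np.ndarray
    snapshots: np.ndarray        # (n_snap, N, N)
    snapshot_times_ms: np.ndarray
    rates_hz: np.ndarray         # per-neuron mean rate over the full run


def build_wiring(
    n: int,
    prune_fraction: float = DEFAULT_PRUNE_FRACTION,
    seed: int | np.random.Generator = 0,
    a_pA: float = DEFAULT_A_PA,
) -> Wiring:
    """All-to-all wiring without autapses, each off-diagonal entry kept
    independently with probability ``1 - prune_fraction``."""
    if n < 2:
        raise ValueError(f"need at least 2 neurons, got {n}")
    if not 0.0 <= prune_fraction < 1.0:
        raise ValueError(f"prune_fraction must be in [0, 1), got {prune_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = (rng.random((n, n)) >= prune_fraction).astype(np.int8)
    np.fill_diagonal(C, 0)
    A = np.full((n, n), float(a_pA))
    labels = np.full(n, "D")
    kind = np.where(C != 0, KIND_D, KIND_NONE).astype(np.int8)
    return Wiring(C=C, A=A, labels=labels, kind=kind)


def assign_sd_kinds(
    wiring: Wiring,
    composition: str = "depressing",
    p_depressing: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> Wiring:
    """Label populations and per-synapse SD kinds in place.

    ``composition``: ``depressing`` / ``facilitating`` (homogeneous),
    ``heterogeneous`` (two equal-size subpopulations, kind set by the
    presynaptic neuron) or ``overlapping`` (kind drawn independently per
    synapse with probability ``p_depressing`` of being depressing).
    """
    n = wiring.n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if composition == "depressing":
        wiring.labels = np.full(n, "D")
        per_syn = np.full((n, n), KIND_D, dtype=np.int8)
    elif composition == "facilitating":
        wiring.labels = np.full(n, "F")
        per_syn = np.full((n, n), KIND_F, dtype=np.int8)
    elif composition == "heterogeneous":
        wiring.labels = np.where(np.arange(n) < n // 2, "D", "F")
        pre_kind = np.where(wiring.labels == "D", KIND_D, KIND_F).astype(np.int8)
        per_syn = np.broadcast_to(pre_kind[None, :], (n, n)).copy()
    elif composition == "overlapping":
        wiring.labels = np.full(n, "M")
        per_syn = np.where(rng.random((n, n)) < p_depressing, KIND_D, KIND_F).astype(np.int8)
    else:
        raise ValueError(f"unknown composition {composition!r}")
    wiring.kind = np.where(wiring.C != 0, per_syn, KIND_NONE).astype(np.int8)
    return wiring


def init_weights(
    wiring: Wiring,
    w_max: float = DEFAULT_W_MAX,
    seed: int | np.random.Generator = 0,
    cross_population_ratio: float = 1.0,
) -> np.ndarray:
    """Uniformly random initial scaling factors on the wired synapses.

    For two-population networks, weights across populations are scaled
    by ``cross_population_ratio`` (initialized slightly weaker than the
    intra-population ones when the ratio is below 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = wiring.n
    w = rng.uniform(0.0, w_max, (n, n))
    if cross_population_ratio != 1.0:
        cross = wiring.labels[:, None] != wiring.labels[None, :]
        w = np.where(cross, w * cross_population_ratio, w)
    w *= wiring.C != 0
    return w


def traveling_wave_current(
    t_ms: float,
    neuron_index: int,
    protocol: StimulusProtocol,
    n: int,
) -> float:
    """Reference implementation of the wave drive for one neuron (pA)."""
    if not 0 <= neuron_index < n:
        raise ValueError("neuron index out of range")
    if t_ms < 0:
        raise ValueError("t must be nonnegative")
    center = int(t_ms // protocol.dwell_ms) % n
    phase = t_ms - (t_ms // protocol.dwell_ms) * protocol.dwell_ms
    current = protocol.baseline_pA
    if phase < protocol.pulse_duration_ms:
        d = abs(neuron_index - center)
        if protocol.wrap:
            d = min(d, n - d)
        current += protocol.pulse_pA * math.exp(-(d * d) / (2.0 * protocol.sigma_idx**2))
    return current


def background_noise_current(
    n: int,
    protocol: StimulusProtocol,
    dt_ms: float,
    n_steps: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Exactly discretized per-neuron OU current streams, shape (n_steps, n).

    Per-neuron means are drawn once with unit coefficient of variation
    around ``noise_mean_pA``; streams are spatially uncorrelated and
    their statistics do not depend on ``dt_ms``.
    """
    if dt_ms >= protocol.noise_tau_ms:
        raise ValueError("dt must be below the noise autocorrelation time")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = rng.normal(protocol.noise_mean_pA, abs(protocol.noise_mean_pA), n)
    decay = math.exp(-dt_ms / protocol.noise_tau_ms)
    kick = protocol.noise_std_pA * math.sqrt(1.0 - decay * decay)
    out = np.empty((n_steps, n))
    state = mu + protocol.noise_std_pA * rng.standard_normal(n)
    for k in range(n_steps):
        state = mu + (state - mu) * decay + kick * rng.standard_normal(n)
        out[k] = state
    return out


@njit(cache=True)
def _run_core(  # noqa: PLR0913 - flat argument list keeps numba simple
    n_steps, dt, n,
    # neuron parameters
    cm, gl, el, vre, dtexp, vem, vt, tref, aad, bad, tauw,
    # synapse / SD
    C, A, U, eu, ex, tau_syn_decay, w, w_max,
    # plasticity
    lam, a2p, a2m, a3p, a3m, dr1, dr2, do1, do2, sign_pre, sign_post,
    # stimulus
    baseline, pulse, dwell, pulse_dur, sigma, wrap, mu_noise, noise_std,
    noise_decay, drive_extra, noise_on,
    # outputs
    spike_t, spike_i, snap_every, snaps, snap_times, seed,
):
    np.random.seed(seed)
    V = np.full(n, el)
    wad = np.zeros(n)
    refr = np.zeros(n)
    isyn = np.zeros(n)
    inoise = mu_noise.copy()
    r1 = np.zeros(n)
    r2 = np.zeros(n)
    o1 = np.zeros(n)
    o2 = np.zeros(n)
    u = U.copy()
    x = np.ones((n, n))
    spiked = np.zeros(n, dtype=np.bool_)
    noise_kick = noise_std * math.sqrt(1.0 - noise_decay * noise_decay)
    n_spikes = 0
    n_snap = 0
    two_sig2 = 2.0 * sigma * sigma

    for step in range(n_steps):
        t = step * dt
        # --- relax detectors, SD states and PSCs
        for i in range(n):
            r1[i] *= dr1
            r2[i] *= dr2
            o1[i] *= do1
            o2[i] *= do2
            isyn[i] *= tau_syn_decay
        for i in range(n):
            for j in range(n):
                if C[i, j] != 0:
                    u[i, j] = U[i, j] + (u[i, j] - U[i, j]) * eu[i, j]
                    x[i, j] = 1.0 + (x[i, j] - 1.0) * ex[i, j]

        # --- external currents
        center = int(t / dwell) % n
        phase = t - math.floor(t / dwell) * dwell
        pulse_on = phase < pulse_dur
        for i in range(n):
            iext = baseline + drive_extra[i]
            if pulse_on:
                d = abs(i - center)
                if wrap and n - d < d:
                    d = n - d
                iext += pulse * math.exp(-(d * d) / two_sig2)
            if noise_on:
                inoise[i] = (
                    mu_noise[i]
                    + (inoise[i] - mu_noise[i]) * noise_decay
                    + noise_kick * np.random.normal()
                )
                iext += inoise[i]

            # --- membrane update
            wa = wad[i]
            wad[i] = wa + dt * (aad * (V[i] - el) - wa) / tauw
            if refr[i] > 0.0:
                V[i] = vre
                refr[i] -= dt
                spiked[i] = False
                continue
            dv = (
                -gl * (V[i] - el)
                + gl * dtexp * math.exp((V[i] - vt) / dtexp)
                - wa
                + isyn[i]
                + iext
            ) / cm
            vnew = V[i] + dt * dv
            if vnew >= vem:
                V[i] = vre
                wad[i] += bad
                refr[i] = tref
                spiked[i] = True
            else:
                V[i] = vnew
                spiked[i] = False

        # --- spike-triggered synaptic release (affects next step's input)
        for j in range(n):
            if not spiked[j]:
                continue
            for i in range(n):
                if C[i, j] != 0:
                    us = u[i, j] + U[i, j] * (1.0 - u[i, j])
                    rel = us * x[i, j]
                    isyn[i] += A[i, j] * w[i, j] * rel
                    u[i, j] = us
                    x[i, j] = x[i, j] * (1.0 - us)

        # --- plasticity: depression branch first, then potentiation,
        #     both evaluated on pre-increment detectors
        if lam > 0.0:
            for j in range(n):
                if not spiked[j]:
                    continue
                gate = a2m + a3m * r2[j]
                for i in range(n):
                    if C[i, j] != 0:
                        wv = w[i, j] + sign_pre * lam * o1[i] * gate
                        if wv < 0.0:
                            wv = 0.0
                        elif wv > w_max:
                            wv = w_max
                        w[i, j] = wv
            for i in range(n):
                if not spiked[i]:
                    continue
                gate = a2p + a3p * o2[i]
                for j in range(n):
                    if C[i, j] != 0:
                        wv = w[i, j] + sign_post * lam * r1[j] * gate
                        if wv < 0.0:
                            wv = 0.0
                        elif wv > w_max:
                            wv = w_max
                        w[i, j] = wv

        # --- trace increments and spike recording
        for i in range(n):
            if spiked[i]:
                r1[i] += 1.0
                r2[i] += 1.0
                o1[i] += 1.0
                o2[i] += 1.0
                if n_spikes < spike_t.shape[0]:
                    spike_t[n_spikes] = t
                    spike_i[n_spikes] = i
                    n_spikes += 1

        if snap_every > 0 and (step + 1) % snap_every == 0:
            if n_snap < snaps.shape[0]:
                snaps[n_snap] = w
                snap_times[n_snap] = t + dt
                n_snap += 1

    return n_spikes, n_snap


def _sd_param_matrices(
    wiring: Wiring,
    sd_depressing: SDParams,
    sd_facilitating: SDParams,
    dt_ms: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = wiring.n
    U = np.empty((n, n))
    tau_f = np.empty((n, n))
    tau_r = np.empty((n, n))
    dep = wiring.kind != KIND_F
    U[:] = np.where(dep, sd_depressing.U, sd_facilitating.U)
    tau_f[:] = np.where(dep, sd_depressing.tau_facil, sd_facilitating.tau_facil)
    tau_r[:] = np.where(dep, sd_depressing.tau_rec, sd_facilitating.tau_rec)
    if sd_depressing.tau_syn != sd_facilitating.tau_syn:
        raise ValueError("PSC decay must be shared across SD kinds")
    eu = np.exp(-dt_ms / tau_f)
    ex = np.exp(-dt_ms / tau_r)
    return U, eu, ex, sd_depressing.tau_syn


def simulate(
    wiring: Wiring,
    w0: np.ndarray,
    protocol: StimulusProtocol,
    duration_ms: float,
    neuron: NeuronParams | None = None,
    sd_depressing: SDParams = SD_DEPRESSING,
    sd_facilitating: SDParams = SD_FACILITATING,
    rule: TripletParams | None = None,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
    snapshot_every_ms: float = 1000.0,
    max_rate_hz: float = 400.0,
) -> SimResult:
    """Run the coupled network simulation; fully reproducible per seed."""
    neuron = NeuronParams() if neuron is None else neuron
    rule = TripletParams() if rule is None else rule
    n = wiring.n
    if w0.shape != (n, n):
        raise ValueError(f"w0 shape {w0.shape} does not match N={n}")
    if duration_ms < dt_ms:
        raise ValueError("duration must cover at least one step")
    n_steps = int(round(duration_ms / dt_ms))

    U, eu, ex, tau_syn = _sd_param_matrices(wiring, sd_depressing, sd_facilitating, dt_ms)
    sign_pre, sign_post = plasticity.update_signs(rule)

    rng = np.random.default_rng(seed)
    noise_on = protocol.noise_std_pA > 0 or protocol.noise_mean_pA != 0
    if noise_on:
        mu_noise = rng.normal(protocol.noise_mean_pA, abs(protocol.noise_mean_pA), n)
    else:
        mu_noise = np.zeros(n)
    drive_extra = (
        np.zeros(n)
        if protocol.drive_extra_pA is None
        else np.asarray(protocol.drive_extra_pA, dtype=float)
    )
    if drive_extra.shape != (n,):
        raise ValueError("drive_extra_pA must have one entry per neuron")

    cap = int(n * duration_ms / 1000.0 * max_rate_hz) + 1024
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)
    snap_every = int(round(snapshot_every_ms / dt_ms)) if snapshot_every_ms > 0 else 0
    n_snap_max = (n_steps // snap_every + 1) if snap_every > 0 else 1
    snaps = np.empty((n_snap_max, n, n))
    snap_times = np.empty(n_snap_max)

    w = w0.copy()
    n_spikes, n_snap = _run_core(
        n_steps, dt_ms, n,
        neuron.capacitance, neuron.leak_conductance, neuron.resting_potential,
        neuron.reset_potential, neuron.spike_steepness, neuron.emission_threshold,
        neuron.threshold_voltage, neuron.refractory_period,
        neuron.adaptation_coupling, neuron.adaptation_increment, neuron.adaptation_tau,
        wiring.C, wiring.A, U, eu, ex, math.exp(-dt_ms / tau_syn), w, rule.w_max,
        rule.rate, rule.a2_plus, rule.a2_minus, rule.a3_plus, rule.a3_minus,
        math.exp(-dt_ms / rule.tau_plus), math.exp(-dt_ms / rule.tau_x),
        math.exp(-dt_ms / rule.tau_minus), math.exp(-dt_ms / rule.tau_y),
        sign_pre, sign_post,
        protocol.baseline_pA, protocol.pulse_pA, protocol.dwell_ms,
        protocol.pulse_duration_ms, protocol.sigma_idx, protocol.wrap,
        mu_noise, protocol.noise_std_pA, math.exp(-dt_ms / protocol.noise_tau_ms),
        drive_extra, noise_on,
        spike_t, spike_i, snap_every, snaps, snap_times,
        int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1)),
    )
    if n_spikes >= cap:
        raise RuntimeError(
            f"spike buffer overflow at {n_spikes} spikes; raise max_rate_hz"
        )
    if not np.all(np.isfinite(w)):
        raise RuntimeError("non-finite weights at end of simulation")

    # final snapshot always taken
    if n_snap == 0 or snap_times[n_snap - 1] != n_steps * dt_ms:
        if n_snap < snaps.shape[0]:
            snaps[n_snap] = w
            snap_times[n_snap] = n_steps * dt_ms
            n_snap += 1

    spikes = SpikeRecord(
        times=spike_t[:n_spikes].copy(),
        ids=spike_i[:n_spikes].copy(),
        duration_ms=duration_ms,
        dt_ms=dt_ms,
        n_neurons=n,
    )
    rates = np.bincount(spikes.ids, minlength=n) / (duration_ms / 1000.0)
    return SimResult(
        spikes=spikes,
        w_final=w,
        snapshots=snaps[:n_snap].copy(),
        snapshot_times_ms=snap_times[:n_snap].copy(),
        rates_hz=rates,
    )


def rate_summary(
    spikes: SpikeRecord,
    window_ms: float | None = None,
    bins: int | np.ndarray = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron mean rates over the final window plus a histogram.

    Returns ``(rates_hz, hist_counts, hist_edges)``.
    """
    window_ms = spikes.duration_ms if window_ms is None else window_ms
    if window_ms > spikes.duration_ms:
        raise ValueError("window exceeds simulation duration")
    t0 = spikes.duration_ms - window_ms
    sel = spikes.times >= t0
    rates = np.bincount(spikes.ids[sel], minlength=spikes.n_neurons) / (window_ms / 1000.0)
    hist, edges = np.histogram(rates, bins=bins)
    return rates, hist, edges
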