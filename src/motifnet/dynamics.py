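"""Single-neuron and single-synapse dynamics.

Forward-Euler integration of the adaptive exponential integrate-and-fire
neuron, instantaneous-rise/exponential-decay postsynaptic currents, and
the utilization/resource model of short-term synaptic dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .params import NeuronParams, SDParams

__all__ = [
    "NeuronState",
    "SDState",
    "adex_step",
    "psc_step",
    "sd_step",
    "sd_stationary",
    "rest_state",
]


@dataclass
class NeuronState:
    """Membrane potential, adaptation current and refractory bookkeeping."""

    V: float                          # mV
    w_adapt: float = 0.0              # pA
    refractory_remaining: float = 0.0  # ms
    last_spike_time: float | None = None


@dataclass
class SDState:
    """Per-synapse utilization ``u`` and available resources ``x``."""

    u: float
    x: float = 1.0
    psc: float = 0.0  # pA, running PSC contribution of this synapse


def rest_state(params: NeuronParams) -> NeuronState:
    return NeuronState(V=params.resting_potential)


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} is not finite: {value!r}")


def adex_step(
    state: NeuronState,
    params: NeuronParams,
    i_syn: float,
    i_ext: float,
    dt: float,
    t: float | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one Euler step of size ``dt`` (ms).

    Returns the new state and whether a spike was emitted during the
    step.  While the refractory clock is running, integration of the
    membrane equation is suspended and ``V`` stays clamped at the reset
    potential; the adaptation current keeps relaxing.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    for name, value in (("i_syn", i_syn), ("i_ext", i_ext), ("V", state.V), ("w_adapt", state.w_adapt)):
        _check_finite(name, value)

    p = params
    w = state.w_adapt
    dw = (p.adaptation_coupling * (state.V - p.resting_potential) - w) / p.adaptation_tau
    w_new = w + dt * dw

    if state.refractory_remaining > 0.0:
        return (
            replace(
                state,
                V=p.reset_potential,
                w_adapt=w_new,
                refractory_remaining=max(0.0, state.refractory_remaining - dt),
            ),
            False,
        )

    exp_drive = p.leak_conductance * p.spike_steepness * math.exp(
        (state.V - p.threshold_voltage) / p.spike_steepness
    )
    dv = (
        -p.leak_conductance * (state.V - p.resting_potential)
        + exp_drive
        - w
        + i_syn
        + i_ext
    ) / p.capacitance
    v_new = state.V + dt * dv

    if v_new >= p.emission_threshold:
        return (
            NeuronState(
                V=p.reset_potential,
                w_adapt=w_new + p.adaptation_increment,
                refractory_remaining=p.refractory_period,
                last_spike_time=t,
            ),
            True,
        )
    return replace(state, V=v_new, w_adapt=w_new), False


def psc_step(
    psc: float,
    tau_syn: float,
    dt: float,
    spike_amplitudes: Sequence[float] | Iterable[float] = (),
) -> float:
    """Decay a PSC over ``dt`` then add instantaneous spike kicks (pA)."""
    if tau_syn <= 0:
        raise ValueError(f"tau_syn must be positive, got {tau_syn}")
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    out = psc * math.exp(-dt / tau_syn)
    for amp in spike_amplitudes:
        out += amp
    return out


def sd_step(
    state: SDState,
    params: SDParams,
    dt: float,
    pre_spiked: bool,
) -> tuple[SDState, float]:
    """Advance the short-term dynamics of one synapse by ``dt`` (ms).

    Without a presynaptic spike, ``u`` relaxes towards its resting value
    ``U`` with time constant ``tau_facil`` and ``x`` towards 1 with
    ``tau_rec``.  At a spike, the utilization is facilitated first,
    ``u -> u + U*(1-u)``, the released fraction is ``u_new * x``, and the
    resources are then depleted, ``x -> x * (1 - u_new)``.  The returned
    release fraction scales the PSC peak (``J = w * A * u * x``).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    U = params.U
    u = U + (state.u - U) * math.exp(-dt / params.tau_facil)
    x = 1.0 + (state.x - 1.0) * math.exp(-dt / params.tau_rec)
    if not pre_spiked:
        return replace(state, u=u, x=x), 0.0
    u_spike = u + U * (1.0 - u)
    release = u_spike * x
    x_after = x * (1.0 - u_spike)
    return replace(state, u=u_spike, x=x_after), release


def sd_stationary(rate_hz: float, params: SDParams) -> tuple[float, float, float]:
    """Stationary mean-field ``(u, x, u*x)`` under Poisson drive at ``rate_hz``.

    The closed forms follow from averaging the between-spike relaxation
    and the spike-triggered updates of :func:`sd_step`::

        u_inf = U * (1 + tau_f * nu) / (1 + U * tau_f * nu)
        x_inf = 1 / (1 + u_inf * tau_r * nu)

    with time constants in seconds and ``nu`` in Hz.
    """
    if rate_hz < 0:
        raise ValueError(f"rate must be nonnegative, got {rate_hz}")
    nu = rate_hz
    tau_f = params.tau_facil * 1e-3
    tau_r = params.tau_rec * 1e-3
    U = params.U
    u_inf = U * (1.0 + tau_f * nu) / (1.0 + U * tau_f * nu)
    x_inf = 1.0 / (1.0 + u_inf * tau_r * nu)
    return u_inf, x_inf, u_inf * x_inf


def sd_train(
    spike_times_ms: np.ndarray,
    params: SDParams,
    u0: float | None = None,
    x0: float = 1.0,
) -> np.ndarray:
    """Release fractions ``u*x`` at each spike of an arbitrary train.

    Event-driven (exact between-spike relaxation); used both by tests and
    by the mean-field cross-checks.
    """
    u = params.U if u0 is None else u0
    x = x0
    t_prev = -math.inf
    out = np.empty(len(spike_times_ms))
    for i, t in enumerate(np.asarray(spike_times_ms, dtype=float)):
        dt = t - t_prev
        if math.isfinite(dt):
            u = params.U + (u - params.U) * math.exp(-dt / params.tau_facil)
            x = 1.0 + (x - 1.0) * math.exp(-dt / params.tau_rec)
        u = u + params.U * (1.0 - u)
        out[i] = u * x
        x = x * (1.0 - u)
        t_prev = t
    return out
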