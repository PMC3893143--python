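"""Rate-model description: threshold-linear populations with short-term
dynamics in the mean efficacy and a rate-dependent long-term drift.

One or two excitatory populations relax over a characteristic time
``tau`` towards a threshold-linear function of their total input; the
recurrent efficacy of each block is ``A * w * u(nu_pre) * x(nu_pre)``
with the stationary utilization/resource values of the presynaptic
population.  Long-term drift of ``w`` follows the Poisson-train average
of the triplet rule, which for the shipped (minimal) amplitudes reduces
to ``lam * k * nu_pre * nu_post * (nu_post - nu_theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import SDParams, TripletParams, SD_DEPRESSING, SD_FACILITATING
from .dynamics import sd_stationary

__all__ = [
    "MeanFieldConfig",
    "Equilibrium",
    "gain",
    "mean_efficacy",
    "rate_field",
    "equilibria",
    "stdp_drift",
    "critical_frequency",
    "integrate_meanfield",
    "mixed_equilibria",
    "rate_upper_bound",
]


@dataclass
class MeanFieldConfig:
    """One- or two-population rate-model configuration.

    ``sd`` holds one parameter set per population; ``A[k, l]`` and
    ``w[k, l]`` couple presynaptic population ``l`` to postsynaptic
    ``k``.  ``h`` is the signed external input (0 = balanced), ``nu_thr``
    the gain threshold, both in rate units.
    """

    sd: tuple[SDParams, ...] = (SD_DEPRESSING,)
    A: np.ndarray = field(default_factory=lambda: np.array([[3.0]]))
    w: np.ndarray = field(default_factory=lambda: np.array([[1.0]]))
    h: float = 0.0
    nu_thr: float = 0.0
    tau_ms: float = 10.0
    rule: TripletParams = field(default_factory=TripletParams)
    p_depressing: float | None = None  # overlapping-SD mixing probability

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        k = len(self.sd)
        if self.A.shape != (k, k) or self.w.shape != (k, k):
            raise ValueError("A and w must be (k, k) for k populations")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")
        if np.any(self.A < 0):
            raise ValueError("efficacies must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.sd)


@dataclass
class Equilibrium:
    rates_hz: np.ndarray
    stable: bool
    residual: float


def gain(inp: np.ndarray | float, nu_thr: float = 0.0) -> np.ndarray | float:
    """Threshold-linear frequency response: ``max(0, inp - nu_thr)``."""
    return np.maximum(0.0, np.asarray(inp, dtype=float) - nu_thr) if np.ndim(inp) else max(
        0.0, float(inp) - nu_thr
    )


def mean_efficacy(rate_pre_hz: float, sd: SDParams, a: float, w: float) -> float:
    """Block mean efficacy ``J = A * w * u_inf * x_inf`` at the presynaptic rate."""
    _, _, ux = sd_stationary(rate_pre_hz, sd)
    return a * w * ux


def _block_efficacies(nu: np.ndarray, config: MeanFieldConfig) -> np.ndarray:
    """J[k, l] for every (post, pre) block at the current rates."""
    k = config.k
    J = np.empty((k, k))
    for l in range(k):
        if config.p_depressing is None:
            _, _, ux = sd_stationary(float(nu[l]), config.sd[l])
        else:
            p = config.p_depressing
            _, _, ux_d = sd_stationary(float(nu[l]), SD_DEPRESSING)
            _, _, ux_f = sd_stationary(float(nu[l]), SD_FACILITATING)
            ux = p * ux_d + (1.0 - p) * ux_f
        for kk in range(k):
            J[kk, l] = config.A[kk, l] * config.w[kk, l] * ux
    return J


def rate_field(nu: np.ndarray, config: MeanFieldConfig) -> np.ndarray:
    """``d(nu)/dt`` in Hz per ms for the configured populations."""
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (config.k,):
        raise ValueError(f"rate vector must have shape ({config.k},)")
    J = _block_efficacies(nu, config)
    drive = J @ nu + config.h
    return (-nu + gain(drive, config.nu_thr)) / config.tau_ms


def equilibria(
    config: MeanFieldConfig,
    rate_max_hz: float | None = None,
    grid_points: int = 2000,
) -> list[Equilibrium]:
    """All self-consistent rates on a bracketing grid, bisection-refined.

    For one population the roots of ``nu = gain(J(nu) nu + h)`` are
    bracketed on a dense grid and polished by bisection; stability comes
    from the slope of the return map.  For two populations a coarse grid
    of fixed-point iterations seeds a Newton refinement and stability is
    read off the Jacobian eigenvalues.
    """
    if rate_max_hz is None:
        bound = 200.0
        for sd in config.sd:
            amax = float(np.max(config.A * config.w))
            bound = max(bound, 3.0 * rate_upper_bound(sd, amax, h=config.h, nu_thr=config.nu_thr))
        rate_max_hz = bound
    if config.k == 1:
        return _equilibria_1pop(config, rate_max_hz, grid_points)
    return _equilibria_2pop(config, rate_max_hz, grid_points)


def _field_1d(nu: float, config: MeanFieldConfig) -> float:
    return float(rate_field(np.array([nu]), config)[0])


def _equilibria_1pop(
    config: MeanFieldConfig, rate_max: float, grid_points: int
) -> list[Equilibrium]:
    grid = np.linspace(0.0, rate_max, grid_points)
    vals = np.array([_field_1d(g, config) for g in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0 and (not roots or abs(roots[-1] - a) > 1e-9):
            roots.append(a)
            continue
        if fa * fb < 0:
            for _ in range(100):
                m = 0.5 * (a + b)
                fm = _field_1d(m, config)
                if fa * fm <= 0:
                    b, fb = m, fm
                else:
                    a, fa = m, fm
                if b - a < 1e-10 * max(1.0, b):
                    break
            roots.append(0.5 * (a + b))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    out = []
    for r in roots:
        eps = max(1e-6, 1e-6 * r)
        slope = (_field_1d(r + eps, config) - _field_1d(max(0.0, r - eps), config)) / (
            eps + min(eps, r)
        )
        out.append(
            Equilibrium(
                rates_hz=np.array([r]),
                stable=slope < 0,
                residual=abs(_field_1d(r, config)),
            )
        )
    return out


def _jacobian(nu: np.ndarray, config: MeanFieldConfig, step: float = 1e-6) -> np.ndarray:
    k = config.k
    J = np.empty((k, k))
    for j in range(k):
        up = nu.copy()
        dn = nu.copy()
        up[j] += step
        dn[j] = max(0.0, dn[j] - step)
        J[:, j] = (rate_field(up, config) - rate_field(dn, config)) / (up[j] - dn[j])
    return J


def _equilibria_2pop(
    config: MeanFieldConfig, rate_max: float, grid_points: int
) -> list[Equilibrium]:
    from scipy.optimize import fsolve

    seeds = np.linspace(0.0, rate_max, max(10, int(math.sqrt(grid_points))))
    found: list[np.ndarray] = []
    for s1 in seeds:
        for s2 in seeds:
            sol, info, ier, _ = fsolve(
                lambda v: rate_field(np.maximum(v, 0.0), config),
                np.array([s1, s2]),
                full_output=True,
            )
            sol = np.maximum(sol, 0.0)
            if ier != 1 or np.max(np.abs(rate_field(sol, config))) > 1e-8:
                continue
            if any(np.allclose(sol, f, atol=1e-4) for f in found):
                continue
            found.append(sol)
    out = []
    for sol in found:
        eig = np.linalg.eigvals(_jacobian(sol, config))
        out.append(
            Equilibrium(
                rates_hz=sol,
                stable=bool(np.all(eig.real < 0)),
                residual=float(np.max(np.abs(rate_field(sol, config)))),
            )
        )
    return out


def critical_frequency(rule: TripletParams) -> float:
    """Postsynaptic rate separating net depression from net potentiation
    under independent Poisson trains (Hz); infinite when the triplet LTP
    term vanishes."""
    denom = rule.a3_plus * (rule.tau_plus * 1e-3) * (rule.tau_y * 1e-3)
    num = rule.a2_minus * (rule.tau_minus * 1e-3)
    if denom <= 0:
        return math.inf
    return num / denom


def stdp_drift(
    w: float,
    nu_pre_hz: float,
    nu_post_hz: float,
    config: MeanFieldConfig,
) -> float:
    """Mean drift ``dw/dt`` (per second) of the scaling factor.

    General Poisson average of the triplet rule; with the minimal
    amplitudes this is ``lam * k * nu_pre * nu_post * (nu_post - nu_theta)``
    where ``nu_theta`` is :func:`critical_frequency`.
    """
    if nu_pre_hz < 0 or nu_post_hz < 0:
        raise ValueError("rates must be nonnegative")
    r = config.rule
    tp, tx, tm, ty = (t * 1e-3 for t in (r.tau_plus, r.tau_x, r.tau_minus, r.tau_y))
    ltp = nu_pre_hz * nu_post_hz * (r.a2_plus * tp + r.a3_plus * tp * ty * nu_post_hz)
    ltd = nu_pre_hz * nu_post_hz * (r.a2_minus * tm + r.a3_minus * tm * tx * nu_pre_hz)
    drift = r.rate * (ltp - ltd)
    if w <= 0.0 and drift < 0.0:
        return 0.0
    if w >= r.w_max and drift > 0.0:
        return 0.0
    return drift


def integrate_meanfield(
    config: MeanFieldConfig,
    duration_ms: float,
    dt_ms: float = 1.0,
    nu0: np.ndarray | None = None,
    plastic: bool = True,
    record_every_ms: float = 10.0,
):
    """Coupled Euler integration of the rate and weight dynamics.

    Returns ``(times_ms, nu_traj, w_traj)`` with shapes ``(T,)``,
    ``(T, k)`` and ``(T, k, k)``.
    """
    k = config.k
    nu = np.zeros(k) if nu0 is None else np.asarray(nu0, dtype=float).copy()
    w = config.w.copy()
    cfg = replace(config)
    n_steps = int(round(duration_ms / dt_ms))
    every = max(1, int(round(record_every_ms / dt_ms)))
    times, nus, ws = [], [], []
    for step in range(n_steps + 1):
        if step % every == 0 or step == n_steps:
            times.append(step * dt_ms)
            nus.append(nu.copy())
            ws.append(w.copy())
        if step == n_steps:
            break
        cfg.w = w
        dnu = rate_field(nu, cfg)
        if not np.all(np.isfinite(dnu)):
            raise RuntimeError(f"non-finite rate field at t = {step * dt_ms} ms")
        if plastic:
            dw = np.zeros_like(w)
            for kk in range(k):
                for l in range(k):
                    dw[kk, l] = stdp_drift(w[kk, l], float(nu[l]), float(nu[kk]), config)
            w = np.clip(w + dw * dt_ms * 1e-3, 0.0, config.rule.w_max)
        nu = np.maximum(0.0, nu + dnu * dt_ms)
    return np.array(times), np.array(nus), np.array(ws)


def mixed_equilibria(
    p_grid: np.ndarray,
    config: MeanFieldConfig,
) -> list[tuple[float, list[Equilibrium]]]:
    """Equilibria of a single population whose synapses are depressing
    with probability ``p`` and facilitating otherwise."""
    if config.k != 1:
        raise ValueError("mixed sweep is defined for a single population")
    out = []
    for p in np.asarray(p_grid, dtype=float):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        cfg = MeanFieldConfig(
            sd=config.sd,
            A=config.A.copy(),
            w=config.w.copy(),
            h=config.h,
            nu_thr=config.nu_thr,
            tau_ms=config.tau_ms,
            rule=config.rule,
            p_depressing=float(p),
        )
        out.append((float(p), equilibria(cfg)))
    return out


def rate_upper_bound(
    sd: SDParams,
    a_times_w: float,
    h: float = 0.0,
    nu_thr: float = 0.0,
) -> float:
    """Upper bound on any threshold-linear equilibrium rate (Hz).

    The recurrent drive saturates at ``A * w / tau_rec`` because
    ``u_inf * x_inf * nu <= 1 / tau_rec``; with a unit-slope
    threshold-linear gain every equilibrium therefore satisfies
    ``nu <= max(0, h - nu_thr + A * w / tau_rec)``.
    """
    return max(0.0, h - nu_thr + a_times_w / (sd.tau_rec * 1e-3))
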