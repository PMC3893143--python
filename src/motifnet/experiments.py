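"""Reproducible experiment runner: configs, fixtures, and one entry point
per figure-style protocol.

Every run writes delimited-text artifacts plus a JSON manifest into its
own directory; reruns with the same config and seed produce identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import meanfield, motifs, netsim, plasticity
from .params import (
    DEFAULT_DT_MS,
    SD_DEPRESSING,
    SD_FACILITATING,
    TRIPLET_MINIMAL,
    TripletParams,
)

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "EXPERIMENT_NAMES",
    "default_config",
    "validate_config",
    "run_experiment",
    "generate_fixtures",
    "summarize_run",
    "write_spikes",
    "read_spikes",
    "write_matrix",
    "read_matrix",
]

EXPERIMENT_NAMES = (
    "fig1_toy",
    "fig2_stats",
    "fig3_controls",
    "fig5_rules",
    "fig6_large",
    "fig7_meanfield_hetero",
    "fig8_mixed_sweep",
)

# Defaults shared by the spiking-network experiments; calibrated so the
# toy facilitating network reverberates above the plasticity crossover
# while the depressing one stays pinned to the wave drive.
_NETWORK_DEFAULTS: dict[str, Any] = {
    "n": 10,
    "prune_fraction": 0.2,
    "a_pA": 2600.0,
    "baseline_pA": 480.0,
    "pulse_pA": 600.0,
    "dwell_ms": 20.0,
    "sigma_idx": 0.4,
    "noise_mean_pA": 0.0,
    "noise_std_pA": 0.0,
    "noise_tau_ms": 5.0,
    "plasticity_rate": 2.0,
    "duration_ms": 30000.0,
    "dt_ms": DEFAULT_DT_MS,
    "cross_population_ratio": 1.0,
    "strong_fraction": 0.5,
    "rate_window_ms": 10000.0,
}

_EXPERIMENT_DEFAULTS: dict[str, dict[str, Any]] = {
    "fig1_toy": {**_NETWORK_DEFAULTS},
    "fig2_stats": {**_NETWORK_DEFAULTS, "n_repeats": 20, "null_draws": 2000},
    "fig3_controls": {**_NETWORK_DEFAULTS, "n_driven": 5, "drive_pA": 1000.0},
    "fig5_rules": {
        "delta_t_ms": 10.0,
        "n_pairs": 60,
        "timing_rate_hz": 1.0,
        "rates_hz": [1, 2, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50],
        "pair_reference_rate_hz": 5.0,
    },
    "fig6_large": {
        **_NETWORK_DEFAULTS,
        "n": 100,
        "a_pA": 480.0,
        "noise_std_pA": 100.0,
        "duration_ms": 60000.0,
        "cross_population_ratio": 0.2,
        "composition": "heterogeneous",
        "rate_window_ms": 20000.0,
        "confidence": 0.95,
    },
    "fig7_meanfield_hetero": {
        "A": 3.0,
        "h": 2.0,
        "w_intra": 1.0,
        "w_cross": 0.1,
        "nu_thr": 0.0,
        "tau_ms": 10.0,
        "duration_ms": 30000.0,
        "dt_ms": 1.0,
        "plasticity_rate": 1.0,
    },
    "fig8_mixed_sweep": {
        "A": 3.0,
        "h_values": [0.0, 1.0, 2.0],
        "nu_thr": 0.0,
        "p_grid": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    },
}


@dataclass
class ExperimentConfig:
    name: str
    seed: int = 0
    outdir: str = "runs"
    scale: float = 1.0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError(f"scale must be in (0, 1], got {self.scale}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "seed": self.seed,
            "outdir": self.outdir,
            "scale": self.scale,
            "params": dict(self.params),
        }


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    experiment: str
    scaled_down: bool
    files: list[str]
    wall_seconds: float
    outdir: str

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def default_config(name: str, seed: int = 0, outdir: str = "runs") -> ExperimentConfig:
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}")
    return ExperimentConfig(
        name=name, seed=seed, outdir=outdir, params=dict(_EXPERIMENT_DEFAULTS[name])
    )


_POSITIVE_KEYS = (
    "dwell_ms",
    "duration_ms",
    "dt_ms",
    "a_pA",
    "sigma_idx",
    "noise_tau_ms",
    "tau_ms",
    "plasticity_rate",
)


def validate_config(path: str | Path) -> ExperimentConfig:
    """Load, schema-check and normalize a YAML experiment config.

    Unknown keys are rejected; missing keys are filled with defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "name" not in raw:
        raise ValueError("config must be a mapping with at least a 'name' key")
    name = raw["name"]
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment name {name!r}")
    defaults = _EXPERIMENT_DEFAULTS[name]
    params = dict(defaults)
    user_params = raw.get("params", {}) or {}
    for key, value in user_params.items():
        if key not in defaults:
            raise ValueError(f"unknown parameter key {key!r} for experiment {name!r}")
        params[key] = value
    for key in _POSITIVE_KEYS:
        if key in params and not params[key] > 0:
            raise ValueError(f"parameter {key!r} must be positive, got {params[key]}")
    for key in ("tau_rec", "tau_facil", "tau_syn"):
        if key in user_params and not user_params[key] > 0:
            raise ValueError(f"parameter {key!r} must be positive")
    extra = set(raw) - {"name", "seed", "outdir", "scale", "params"}
    if extra:
        raise ValueError(f"unknown top-level keys: {sorted(extra)}")
    variant = user_params.get("variant")
    if variant == "pair" and (
        user_params.get("a3_plus", 0.0) or user_params.get("a3_minus", 0.0)
    ):
        raise ValueError("variant 'pair' is inconsistent with nonzero triplet amplitudes")
    return ExperimentConfig(
        name=name,
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "runs")),
        scale=float(raw.get("scale", 1.0)),
        params=params,
    )


# ---------------------------------------------------------------------------
# delimited-text IO


def write_spikes(path: Path, spikes: netsim.SpikeRecord, seed: int) -> None:
    header = (
        f"# duration_ms={spikes.duration_ms} dt_ms={spikes.dt_ms} "
        f"n_neurons={spikes.n_neurons} seed={seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("time_ms\tneuron_id\n")
        for t, i in zip(spikes.times, spikes.ids):
            fh.write(f"{t:.4f}\t{int(i)}\n")


def read_spikes(path: Path) -> netsim.SpikeRecord:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        for tok in first.lstrip("# ").split():
            k, v = tok.split("=")
            meta[k] = float(v)
    df = pd.read_csv(path, sep="\t", comment="#")
    return netsim.SpikeRecord(
        times=df["time_ms"].to_numpy(dtype=float),
        ids=df["neuron_id"].to_numpy(dtype=int),
        duration_ms=meta["duration_ms"],
        dt_ms=meta["dt_ms"],
        n_neurons=int(meta["n_neurons"]),
    )


def write_matrix(path: Path, m: np.ndarray) -> None:
    np.savetxt(path, m, delimiter="\t", fmt="%.8g")


def read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


# ---------------------------------------------------------------------------
# network helpers


def build_network(
    n: int,
    composition: str,
    seed: int,
    params: dict[str, Any],
) -> tuple[netsim.Wiring, np.ndarray, netsim.StimulusProtocol]:
    """Wiring, initial weights and stimulus protocol from a parameter block.

    Independent substreams of the master seed drive wiring, SD-kind
    assignment and initial weights, so each is reproducible on its own.
    """
    ss = np.random.SeedSequence(seed)
    s_wiring, s_kind, s_weights = (np.random.default_rng(c) for c in ss.spawn(3))
    wiring = netsim.build_wiring(n, params["prune_fraction"], s_wiring, a_pA=params["a_pA"])
    netsim.assign_sd_kinds(
        wiring, composition, p_depressing=params.get("p_depressing", 0.5), seed=s_kind
    )
    w0 = netsim.init_weights(
        wiring,
        seed=s_weights,
        cross_population_ratio=params.get("cross_population_ratio", 1.0),
    )
    protocol = netsim.StimulusProtocol(
        baseline_pA=params["baseline_pA"],
        pulse_pA=params["pulse_pA"],
        dwell_ms=params["dwell_ms"],
        sigma_idx=params["sigma_idx"],
        noise_mean_pA=params["noise_mean_pA"],
        noise_std_pA=params["noise_std_pA"],
        noise_tau_ms=params["noise_tau_ms"],
    )
    return wiring, w0, protocol


def run_toy(
    composition: str,
    seed: int,
    params: dict[str, Any],
    drive_extra_pA: np.ndarray | None = None,
) -> tuple[netsim.SimResult, netsim.Wiring, np.ndarray]:
    wiring, w0, protocol = build_network(params["n"], composition, seed, params)
    if drive_extra_pA is not None:
        protocol.drive_extra_pA = drive_extra_pA
    rule = TRIPLET_MINIMAL.with_rate(params["plasticity_rate"])
    result = netsim.simulate(
        wiring,
        w0,
        protocol,
        params["duration_ms"],
        rule=rule,
        dt_ms=params["dt_ms"],
        seed=seed,
    )
    return result, wiring, w0


# ---------------------------------------------------------------------------
# experiment bodies


def _final_symmetry(w_final: np.ndarray, strong_fraction: float) -> motifs.SymmetryResult:
    return motifs.symmetry_index(motifs.normalize_clip(w_final, strong_fraction=strong_fraction))


def _exp_fig1_toy(cfg: ExperimentConfig, out: Path) -> list[str]:
    files = []
    rows = []
    for composition in ("depressing", "facilitating"):
        res, wiring, w0 = run_toy(composition, cfg.seed, cfg.params)
        tag = composition[0]
        write_spikes(out / f"spikes_{tag}.tsv", res.spikes, cfg.seed)
        write_matrix(out / f"w_initial_{tag}.tsv", w0)
        write_matrix(out / f"w_final_{tag}.tsv", res.w_final)
        files += [f"spikes_{tag}.tsv", f"w_initial_{tag}.tsv", f"w_final_{tag}.tsv"]
        rates, _, _ = netsim.rate_summary(res.spikes, cfg.params["rate_window_ms"])
        rows.append(
            {
                "composition": composition,
                "mean_rate_hz": rates.mean(),
                "s_initial": _final_symmetry(w0, cfg.params["strong_fraction"]).s,
                "s_final": _final_symmetry(res.w_final, cfg.params["strong_fraction"]).s,
            }
        )
    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    return files + ["summary.tsv"]


def _exp_fig2_stats(cfg: ExperimentConfig, out: Path) -> list[str]:
    n_repeats = max(1, int(round(cfg.params["n_repeats"] * cfg.scale)))
    rows = []
    for composition in ("depressing", "facilitating"):
        for rep in range(n_repeats):
            seed = cfg.seed * 100_003 + rep
            res, wiring, w0 = run_toy(composition, seed, cfg.params)
            rates, _, _ = netsim.rate_summary(res.spikes, cfg.params["rate_window_ms"])
            s0 = _final_symmetry(w0, cfg.params["strong_fraction"])
            s1 = _final_symmetry(res.w_final, cfg.params["strong_fraction"])
            tail = "upper" if composition == "facilitating" else "lower"
            p = motifs.symmetry_null_pvalue(
                s1.s,
                cfg.params["n"],
                prune_fraction=cfg.params["prune_fraction"],
                strong_fraction=cfg.params["strong_fraction"],
                n_draws=cfg.params["null_draws"],
                seed=seed,
                tail=tail,
            )
            rows.append(
                {
                    "composition": composition,
                    "repeat": rep,
                    "seed": seed,
                    "mean_rate_hz": rates.mean(),
                    "s_initial": s0.s,
                    "s_final": s1.s,
                    "p_value": p,
                    "tail": tail,
                }
            )
    pd.DataFrame(rows).to_csv(out / "symmetry_stats.tsv", sep="\t", index=False)
    return ["symmetry_stats.tsv"]


def _exp_fig3_controls(cfg: ExperimentConfig, out: Path) -> list[str]:
    n = cfg.params["n"]
    n_driven = int(cfg.params["n_driven"])
    extra = np.zeros(n)
    extra[:n_driven] = cfg.params["drive_pA"]
    res, wiring, w0 = run_toy("depressing", cfg.seed, cfg.params, drive_extra_pA=extra)
    wc = motifs.normalize_clip(res.w_final, strong_fraction=cfg.params["strong_fraction"])
    rates, _, _ = netsim.rate_summary(res.spikes, cfg.params["rate_window_ms"])
    write_matrix(out / "w_final.tsv", res.w_final)
    write_spikes(out / "spikes.tsv", res.spikes, cfg.seed)
    summary = {
        "s_whole": motifs.symmetry_index(wc).s,
        "s_driven": motifs.symmetry_index(wc[:n_driven, :n_driven]).s,
        "s_undriven": motifs.symmetry_index(wc[n_driven:, n_driven:]).s,
        "rate_driven_hz": float(rates[:n_driven].mean()),
        "rate_undriven_hz": float(rates[n_driven:].mean()),
    }
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    return ["w_final.tsv", "spikes.tsv", "summary.tsv"]


def _exp_fig5_rules(cfg: ExperimentConfig, out: Path) -> list[str]:
    p = cfg.params
    delta = p["delta_t_ms"]
    grid = np.concatenate([np.arange(-100.0, 0.0, 5.0), np.arange(5.0, 105.0, 5.0)])
    rules = {
        "triplet": TRIPLET_MINIMAL,
        "pair": plasticity.configure_rule(
            "pair", TRIPLET_MINIMAL, p["pair_reference_rate_hz"]
        ),
        "anti": plasticity.configure_rule("anti", TRIPLET_MINIMAL),
    }
    window_rows, freq_rows, cross_rows = [], [], []
    for name, rule in rules.items():
        for dt in grid:
            window_rows.append(
                {
                    "rule": name,
                    "delta_t_ms": dt,
                    "dw_rel": plasticity.run_timing_protocol(
                        dt, p["n_pairs"], p["timing_rate_hz"], rule
                    ),
                }
            )
        sweep = plasticity.run_frequency_protocol(
            -delta, rule, np.asarray(p["rates_hz"], float), p["n_pairs"]
        )
        for r, v in zip(p["rates_hz"], sweep):
            freq_rows.append({"rule": name, "rate_hz": r, "dw_rel": v})
        # the anti rule's depression-favouring ordering is pre-leading
        cross_dt = delta if name == "anti" else -delta
        crossover = plasticity.ltd_ltp_crossover(rule, cross_dt, n_pairs=p["n_pairs"])
        cross_rows.append(
            {"rule": name, "delta_t_ms": cross_dt, "crossover_hz": crossover}
        )
    pd.DataFrame(window_rows).to_csv(out / "timing_windows.tsv", sep="\t", index=False)
    pd.DataFrame(freq_rows).to_csv(out / "frequency_sweeps.tsv", sep="\t", index=False)
    pd.DataFrame(cross_rows).to_csv(out / "crossovers.tsv", sep="\t", index=False)
    return ["timing_windows.tsv", "frequency_sweeps.tsv", "crossovers.tsv"]


def _exp_fig6_large(cfg: ExperimentConfig, out: Path) -> list[str]:
    p = dict(cfg.params)
    if cfg.scale < 1.0:
        p["n"] = max(20, int(round(p["n"] * cfg.scale)))
        p["duration_ms"] = max(10_000.0, p["duration_ms"] * cfg.scale)
    res, wiring, w0 = run_toy(p["composition"], cfg.seed, p)
    rates, hist, edges = netsim.rate_summary(res.spikes, p["rate_window_ms"])
    wc = motifs.normalize_clip(res.w_final, strong_fraction=p["strong_fraction"])
    tally = motifs.count_pair_motifs(wc, wiring.kind)
    tally_df = pd.DataFrame(
        {
            "category": list(motifs.MOTIF_CATEGORIES),
            "count": [tally.counts[c] for c in motifs.MOTIF_CATEGORIES],
            "fraction": [tally.fractions[c] for c in motifs.MOTIF_CATEGORIES],
            "null_expectation": [tally.null_expectation[c] for c in motifs.MOTIF_CATEGORIES],
            "ci_low": [tally.ci_low[c] for c in motifs.MOTIF_CATEGORIES],
            "ci_high": [tally.ci_high[c] for c in motifs.MOTIF_CATEGORIES],
            "significant": [tally.significant[c] for c in motifs.MOTIF_CATEGORIES],
        }
    )
    tally_df.to_csv(out / "motif_tally.tsv", sep="\t", index=False)
    rate_df = pd.DataFrame({"neuron": np.arange(len(rates)), "label": wiring.labels, "rate_hz": rates})
    rate_df.to_csv(out / "rates.tsv", sep="\t", index=False)
    write_matrix(out / "w_final.tsv", res.w_final)
    write_matrix(out / "sd_kind.tsv", wiring.kind)
    return ["motif_tally.tsv", "rates.tsv", "w_final.tsv", "sd_kind.tsv"]


def _exp_fig7(cfg: ExperimentConfig, out: Path) -> list[str]:
    p = cfg.params
    config = meanfield.MeanFieldConfig(
        sd=(SD_DEPRESSING, SD_FACILITATING),
        A=np.full((2, 2), p["A"]),
        w=np.array([[p["w_intra"], p["w_cross"]], [p["w_cross"], p["w_intra"]]]),
        h=p["h"],
        nu_thr=p["nu_thr"],
        tau_ms=p["tau_ms"],
        rule=TRIPLET_MINIMAL.with_rate(p["plasticity_rate"]),
    )
    t, nus, ws = meanfield.integrate_meanfield(
        config, p["duration_ms"], dt_ms=p["dt_ms"], nu0=np.array([1.0, 1.0])
    )
    df = pd.DataFrame(
        {
            "time_ms": t,
            "nu_D_hz": nus[:, 0],
            "nu_F_hz": nus[:, 1],
            "w_DD": ws[:, 0, 0],
            "w_DF": ws[:, 0, 1],  # presynaptic F onto postsynaptic D
            "w_FD": ws[:, 1, 0],  # presynaptic D onto postsynaptic F
            "w_FF": ws[:, 1, 1],
        }
    )
    df.to_csv(out / "trajectory.tsv", sep="\t", index=False)
    return ["trajectory.tsv"]


def _exp_fig8(cfg: ExperimentConfig, out: Path) -> list[str]:
    p = cfg.params
    rows = []
    for h in p["h_values"]:
        config = meanfield.MeanFieldConfig(
            sd=(SD_FACILITATING,), A=np.array([[p["A"]]]), h=h, nu_thr=p["nu_thr"]
        )
        for prob, eqs in meanfield.mixed_equilibria(np.asarray(p["p_grid"], float), config):
            for eq in eqs:
                rows.append(
                    {
                        "h": h,
                        "p_depressing": prob,
                        "rate_hz": float(eq.rates_hz[0]),
                        "stable": eq.stable,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "mixed_equilibria.tsv", sep="\t", index=False)
    return ["mixed_equilibria.tsv"]


_BODIES: dict[str, Callable[[ExperimentConfig, Path], list[str]]] = {
    "fig1_toy": _exp_fig1_toy,
    "fig2_stats": _exp_fig2_stats,
    "fig3_controls": _exp_fig3_controls,
    "fig5_rules": _exp_fig5_rules,
    "fig6_large": _exp_fig6_large,
    "fig7_meanfield_hetero": _exp_fig7,
    "fig8_mixed_sweep": _exp_fig8,
}


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Execute the named protocol end-to-end and write its artifacts."""
    from . import __version__

    out = Path(cfg.outdir) / f"{cfg.name}_seed{cfg.seed}"
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        files = _BODIES[cfg.name](cfg, out)
    except Exception as err:  # re-raise with experiment context
        raise RuntimeError(f"experiment {cfg.name!r} (seed {cfg.seed}) failed") from err
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        version=__version__,
        experiment=cfg.name,
        scaled_down=cfg.scale < 1.0,
        files=files,
        wall_seconds=time.time() - t0,
        outdir=str(out),
    )
    manifest.save(out / "manifest.json")
    return manifest


def summarize_run(manifest: RunManifest) -> pd.DataFrame:
    """One-row (or few-row) summary table assembled from a run's files."""
    out = Path(manifest.outdir)
    for name in manifest.files:
        path = out / name
        if not path.exists() or path.stat().st_size == 0:
            raise FileNotFoundError(f"missing or empty output file: {path}")
    tables = {}
    for name in manifest.files:
        if name.endswith(".tsv"):
            tables[name] = pd.read_csv(out / name, sep="\t", comment="#")
    if "summary.tsv" in tables:
        return tables["summary.tsv"]
    if "symmetry_stats.tsv" in tables:
        df = tables["symmetry_stats.tsv"]
        return (
            df.groupby("composition")
            .agg(
                s_final_mean=("s_final", "mean"),
                s_final_std=("s_final", "std"),
                p_median=("p_value", "median"),
                rate_mean_hz=("mean_rate_hz", "mean"),
            )
            .reset_index()
        )
    if "motif_tally.tsv" in tables:
        return tables["motif_tally.tsv"]
    name = next(iter(tables))
    return tables[name]


def generate_fixtures(n: int, seed: int, outdir: str | Path) -> list[Path]:
    """Deterministic wiring/weights/SD-kind fixture files for tests."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_wiring, s_kind, s_weights = (np.random.default_rng(c) for c in ss.spawn(3))
    wiring = netsim.build_wiring(n, 0.2, s_wiring)
    netsim.assign_sd_kinds(wiring, "heterogeneous", seed=s_kind)
    w0 = netsim.init_weights(wiring, seed=s_weights)
    paths = []
    for name, mat in (("wiring", wiring.C), ("weights", w0), ("sd_kind", wiring.kind)):
        path = out / f"{name}_n{n}_seed{seed}.tsv"
        write_matrix(path, np.asarray(mat, dtype=float))
        paths.append(path)
    return paths
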