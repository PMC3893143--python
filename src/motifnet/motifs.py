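"""Strong/weak connection convention, symmetry index, and pair-motif tallies.

A connection is "strong" when its scaling factor exceeds a configurable
fraction of the upper bound; weights are first normalized by the bound
and then zero-clipped.  The symmetry index averages, over all neuron
pairs with at least one surviving connection, the similarity between the
two weights sitting at transposed positions:

    s = mean over non-null pairs of  2 * min(wij, wji) / (wij + wji)

which is 1 for a pair of equal reciprocal strong connections and 0 for a
strictly unidirectional pair.  Pairs with both entries clipped to zero
(the N0 null pairs) are excluded from the average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SymmetryResult",
    "MotifTally",
    "normalize_clip",
    "symmetry_index",
    "symmetry_null_pvalue",
    "count_pair_motifs",
    "motif_null_expectations",
    "MOTIF_CATEGORIES",
]

MOTIF_CATEGORIES = ("-,-", "D,-", "F,-", "D,D", "F,F", "F,D")


@dataclass
class SymmetryResult:
    s: float                 # in [0, 1]; nan when every pair is null
    n: int                   # network size
    n0: int                  # number of null pairs excluded
    p_value: float | None = None
    tail: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.s)


@dataclass
class MotifTally:
    counts: dict[str, int]
    fractions: dict[str, float]
    null_expectation: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    significant: dict[str, bool]
    p_connection: float
    p_facilitating: float
    p_depressing: float
    n_pairs: int


def normalize_clip(
    w: np.ndarray,
    w_max: float = 1.0,
    strong_fraction: float = 0.5,
) -> np.ndarray:
    """Normalize by ``w_max`` and zero out entries at or below the
    strong-connection threshold."""
    if not 0.0 < strong_fraction < 1.0:
        raise ValueError(f"strong_fraction must be in (0, 1), got {strong_fraction}")
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    wn = np.asarray(w, dtype=float) / w_max
    return np.where(wn > strong_fraction, wn, 0.0)


def symmetry_index(w_clipped: np.ndarray, wiring: np.ndarray | None = None) -> SymmetryResult:
    """Symmetry index over the non-null unordered pairs of a clipped matrix.

    ``wiring`` is accepted for interface symmetry with the simulator but
    does not alter the result: entries of unwired synapses are zero by
    construction and contribute through the null-pair count only.
    """
    w = np.asarray(w_clipped, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise ValueError("matrix must be square")
    if np.any(np.diagonal(w) != 0):
        raise ValueError("diagonal must be zero (no autapses)")
    iu, ju = np.triu_indices(n, k=1)
    a = w[iu, ju]
    b = w[ju, iu]
    total = a + b
    null = total == 0
    n0 = int(null.sum())
    if n0 == len(total):
        return SymmetryResult(s=float("nan"), n=n, n0=n0)
    sim = 2.0 * np.minimum(a, b)[~null] / total[~null]
    return SymmetryResult(s=float(sim.mean()), n=n, n0=n0)


def symmetry_null_pvalue(
    s_observed: float,
    n: int,
    prune_fraction: float = 0.2,
    strong_fraction: float = 0.5,
    w_max: float = 1.0,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    tail: str = "upper",
    return_sample: bool = False,
):
    """Monte-Carlo p-value of ``s_observed`` under the uniform-random null.

    Null matrices share the observed network's size, pruning fraction,
    normalization and clipping threshold; weights are uniform on
    ``[0, w_max]``.  The ``(k + 1) / (n_draws + 1)`` estimator is used.
    ``tail``: ``upper`` (s at least as large), ``lower``, or ``two``.
    """
    if n_draws < 1:
        raise ValueError("need at least one null draw")
    if tail not in ("upper", "lower", "two"):
        raise ValueError(f"invalid tail {tail!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample = np.empty(n_draws)
    for k in range(n_draws):
        keep = rng.random((n, n)) >= prune_fraction
        np.fill_diagonal(keep, False)
        w = rng.uniform(0.0, w_max, (n, n)) * keep
        res = symmetry_index(normalize_clip(w, w_max, strong_fraction))
        sample[k] = res.s
    sample = sample[~np.isnan(sample)]
    m = len(sample)
    if m == 0:
        raise RuntimeError("all null draws were fully null; cannot form a p-value")
    hi = (np.sum(sample >= s_observed) + 1) / (m + 1)
    lo = (np.sum(sample <= s_observed) + 1) / (m + 1)
    p = {"upper": hi, "lower": lo, "two": min(1.0, 2.0 * min(hi, lo))}[tail]
    if return_sample:
        return float(p), sample
    return float(p)


def count_pair_motifs(w_clipped: np.ndarray, sd_kind: np.ndarray) -> MotifTally:
    """Tally unordered neuron pairs into the six strong-motif categories.

    ``sd_kind[i, j]`` labels the synapse from presynaptic ``j`` to
    postsynaptic ``i`` (0 = depressing, 1 = facilitating, -1 = absent);
    it must be defined wherever a clipped weight survives.
    """
    w = np.asarray(w_clipped, dtype=float)
    kind = np.asarray(sd_kind)
    n = w.shape[0]
    if kind.shape != w.shape:
        raise ValueError("sd_kind shape must match the weight matrix")
    if np.any((w > 0) & (kind < 0)):
        raise ValueError("strong connection with undefined SD kind")

    counts = dict.fromkeys(MOTIF_CATEGORIES, 0)
    labels = {0: "D", 1: "F"}
    for i in range(n):
        for j in range(i + 1, n):
            fwd, rev = w[j, i] > 0, w[i, j] > 0
            if not fwd and not rev:
                counts["-,-"] += 1
            elif fwd != rev:
                k = kind[j, i] if fwd else kind[i, j]
                counts[f"{labels[int(k)]},-"] += 1
            else:
                ka, kb = labels[int(kind[j, i])], labels[int(kind[i, j])]
                if ka == kb:
                    counts[f"{ka},{kb}"] += 1
                else:
                    counts["F,D"] += 1

    n_pairs = n * (n - 1) // 2
    # connection and kind frequencies, estimated from the strong links
    strong = w > 0
    n_strong = int(strong.sum())
    p_c = n_strong / (n * (n - 1))
    if n_strong > 0:
        p_f = float(np.sum(kind[strong] == 1)) / n_strong
    else:
        p_f = 0.0
    p_d = 1.0 - p_f

    null, lo, hi = motif_null_expectations(p_c, p_f, p_d, n_pairs)
    fractions = {c: counts[c] / n_pairs for c in MOTIF_CATEGORIES}
    significant = {
        c: not (lo[c] <= fractions[c] <= hi[c]) for c in MOTIF_CATEGORIES
    }
    return MotifTally(
        counts=counts,
        fractions=fractions,
        null_expectation=null,
        ci_low=lo,
        ci_high=hi,
        significant=significant,
        p_connection=p_c,
        p_facilitating=p_f,
        p_depressing=p_d,
        n_pairs=n_pairs,
    )


def motif_null_expectations(
    p_c: float,
    p_f: float,
    p_d: float,
    n_pairs: int,
    confidence: float = 0.95,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Bernoulli-independence null fractions per category with binomial CIs.

    Categories follow :data:`MOTIF_CATEGORIES`; expectations sum to one
    for any valid ``(p_c, p_f)`` with ``p_d = 1 - p_f``.
    """
    for name, p in (("p_c", p_c), ("p_f", p_f), ("p_d", p_d)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {p}")
    if abs(p_f + p_d - 1.0) > 1e-9:
        raise ValueError("p_f + p_d must equal 1")
    null = {
        "-,-": (1 - p_c) ** 2,
        "D,-": 2 * p_c * (1 - p_c) * p_d,
        "F,-": 2 * p_c * (1 - p_c) * p_f,
        "D,D": p_c**2 * p_d**2,
        "F,F": p_c**2 * p_f**2,
        "F,D": 2 * p_c**2 * p_f * p_d,
    }
    lo, hi = {}, {}
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    for cat, p in null.items():
        mean = n_pairs * p
        if mean < 5 or n_pairs * (1 - p) < 5:
            # exact Clopper-Pearson for small expected counts
            k = mean  # expected count; bounds on the *fraction* under the null
            lo_k = stats.beta.ppf((1 - confidence) / 2, k + 1e-12, n_pairs - k + 1) if k > 0 else 0.0
            hi_k = stats.beta.ppf(1 - (1 - confidence) / 2, k + 1, max(n_pairs - k, 1e-12))
            lo[cat] = float(0.0 if np.isnan(lo_k) else lo_k)
            hi[cat] = float(1.0 if np.isnan(hi_k) else hi_k)
        else:
            half = z * math.sqrt(p * (1 - p) / n_pairs)
            lo[cat] = max(0.0, p - half)
            hi[cat] = min(1.0, p + half)
    return null, lo, hi
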