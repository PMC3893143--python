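"""Parameter containers and default parameter sets.

Units follow the conventions used throughout the package: time in ms,
voltage in mV, current in pA, capacitance in pF, conductance in nS.
Rates are in Hz unless stated otherwise; internally rates are converted
to spikes/ms where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "NeuronParams",
    "SDParams",
    "TripletParams",
    "DEFAULT_DT_MS",
    "DEFAULT_NEURON",
    "SD_DEPRESSING",
    "SD_FACILITATING",
    "TRIPLET_MINIMAL",
    "DEFAULT_A_PA",
    "DEFAULT_W_MAX",
    "DEFAULT_STRONG_FRACTION",
    "DEFAULT_PRUNE_FRACTION",
]

#: Forward-Euler integration step (ms).
DEFAULT_DT_MS = 0.1

#: Maximal synaptic efficacy A (pA) for the spiking networks.
DEFAULT_A_PA = 2500.0

#: Upper bound of the dimensionless long-term scaling factor.
DEFAULT_W_MAX = 1.0

#: Fraction of w_max above which a connection counts as "strong".
DEFAULT_STRONG_FRACTION = 0.5

#: Fraction of off-diagonal wiring entries removed at network build time.
DEFAULT_PRUNE_FRACTION = 0.2


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive exponential integrate-and-fire neuron parameters."""

    capacitance: float = 281.0          # C (pF)
    leak_conductance: float = 30.0      # g_L (nS)
    resting_potential: float = -70.6    # E_L (mV)
    reset_potential: float = -70.6      # V_reset (mV)
    spike_steepness: float = 2.0        # Delta_T (mV)
    emission_threshold: float = -40.4   # V at which a spike is registered (mV)
    threshold_voltage: float = -50.4    # V_T of the exponential term (mV)
    refractory_period: float = 2.0      # t_ref (ms)
    adaptation_coupling: float = 4.0    # a (nS)
    adaptation_increment: float = 80.5  # b (pA); 0.0805 nA
    adaptation_tau: float = 144.0       # tau_w (ms)

    def __post_init__(self) -> None:
        if self.capacitance <= 0 or self.leak_conductance <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if self.adaptation_tau <= 0 or self.refractory_period < 0:
            raise ValueError("adaptation_tau must be positive, refractory_period nonnegative")
        if self.spike_steepness <= 0:
            raise ValueError("spike_steepness must be positive")
        if not self.reset_potential < self.emission_threshold:
            raise ValueError("reset_potential must lie below the emission threshold")


@dataclass(frozen=True)
class SDParams:
    """Short-term synaptic dynamics (resource/utilization) parameters.

    ``kind`` is a free label used by the motif statistics ("depressing"
    or "facilitating" in all shipped parameter sets).
    """

    U: float                 # baseline utilization, in (0, 1]
    tau_rec: float           # recovery from depression (ms)
    tau_facil: float         # recovery from facilitation (ms)
    tau_syn: float = 5.0     # PSC decay (ms)
    kind: str = "depressing"

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if min(self.tau_rec, self.tau_facil, self.tau_syn) <= 0:
            raise ValueError("all SD time constants must be positive")


@dataclass(frozen=True)
class TripletParams:
    """Amplitudes and detector time constants of the triplet STDP rule.

    ``variant`` selects between the full triplet rule, the re-tuned
    pair-based control and the sign-inverted/amplitude-swapped anti
    control (see :func:`motifnet.plasticity.configure_rule`).
    """

    a2_plus: float = 0.0        # pair LTP amplitude
    a2_minus: float = 7.1e-3    # pair LTD amplitude
    a3_plus: float = 6.5e-3     # triplet LTP amplitude
    a3_minus: float = 0.0       # triplet LTD amplitude
    tau_plus: float = 16.8      # r1 decay (ms)
    tau_x: float = 101.0        # r2 decay (ms)
    tau_minus: float = 33.7     # o1 decay (ms)
    tau_y: float = 114.0        # o2 decay (ms)
    rate: float = 1.0           # plasticity rate lambda, scales every update
    w_max: float = DEFAULT_W_MAX
    variant: str = "triplet"

    def __post_init__(self) -> None:
        if min(self.tau_plus, self.tau_x, self.tau_minus, self.tau_y) <= 0:
            raise ValueError("all detector time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.variant not in ("triplet", "pair", "anti"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "pair" and (self.a3_plus != 0.0 or self.a3_minus != 0.0):
            raise ValueError("pair variant requires zero triplet amplitudes")

    def with_rate(self, rate: float) -> "TripletParams":
        return replace(self, rate=rate)


DEFAULT_NEURON = NeuronParams()

SD_DEPRESSING = SDParams(U=0.25, tau_rec=706.0, tau_facil=21.0, kind="depressing")
SD_FACILITATING = SDParams(U=0.16, tau_rec=45.0, tau_facil=376.0, kind="facilitating")

TRIPLET_MINIMAL = TripletParams()
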