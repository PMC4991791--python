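"""Parameter containers for the recurrent-network model.

All voltages are in mV, times in ms, rates in Hz.  Conductances are
dimensionless multiples of the leak conductance, so the membrane equation
can be written entirely in ratios and the physical value of the leak
conductance never enters the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment conductance-based leaky integrate-and-fire neuron.

    The default values describe a neuron resting at -65 mV with a spike
    threshold of -48 mV, fast inhibitory (5 ms) and slower excitatory
    (10 ms) exponential synapses, and a tonic depolarizing conductance
    equal in magnitude to the leak.
    """

    E_e: float = 0.0          # excitatory reversal potential
    E_i: float = -90.0        # inhibitory reversal potential
    E_t: float = 0.0          # reversal of the tonic depolarizing conductance
    E_leak: float = -65.0     # leak reversal / resting potential
    V_thresh: float = -48.0   # spike threshold
    V_reset: float = -70.0    # post-spike reset
    refractory: float = 1.0   # absolute refractory period, ms
    g_leak: float = 0.20      # leak conductance (unit-bearing constant)
    g_t: float = 0.20         # tonic conductance, same units as g_leak
    tau_m: float = 20.0       # membrane time constant, ms
    tau_e: float = 10.0       # excitatory synaptic time constant, ms
    tau_i: float = 5.0        # inhibitory synaptic time constant, ms

    def __post_init__(self) -> None:
        if not (self.V_reset < self.V_thresh < self.E_e):
            raise ConfigurationError(
                "require V_reset < V_thresh < E_e, got "
                f"{self.V_reset}, {self.V_thresh}, {self.E_e}"
            )
        for name in ("tau_m", "tau_e", "tau_i", "refractory"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("g_leak", "g_t"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def g_t_ratio(self) -> float:
        """Tonic conductance as a multiple of the leak conductance."""
        return self.g_t / self.g_leak


@dataclass(frozen=True)
class ConnectivityParams:
    """Class-dependent random connectivity with lognormal weights.

    ``p_xy`` is the probability of a directed connection onto a neuron of
    class *x* from a neuron of class *y* (target <- source, the J_ij
    convention: e for excitatory, i for inhibitory).  So ``p_ei`` is the
    probability that an inhibitory cell inhibits a given excitatory cell.
    This reading is the one that reproduces the sparse ~1.3 Hz excitatory
    operating regime; the source -> target reading leaves the excitatory
    population under-inhibited by ~30% and settles near 7 Hz.

    Weights are lognormal(mu, sigma) in multiples of the leak
    conductance; inhibitory-to-excitatory weights are scaled by
    ``ie_scale`` on top of the draw, and everything is multiplied by the
    global ``weight_scale`` (2.0 reproduces the double-strength variant).
    """

    N_e: int = 1000
    N_i: int = 200
    N_input: int = 50
    p_ee: float = 0.2
    p_ei: float = 0.35
    p_ie: float = 0.25
    p_ii: float = 0.3
    p_input: float = 0.1
    lognormal_mu: float = -0.64
    lognormal_sigma: float = 0.51
    ie_scale: float = 1.5
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N_e", "N_i", "N_input"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("p_ee", "p_ei", "p_ie", "p_ii", "p_input"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.weight_scale <= 0:
            raise ConfigurationError("weight_scale must be positive")

    @property
    def n_neurons(self) -> int:
        return self.N_e + self.N_i

    def scaled(self, weight_scale: float) -> "ConnectivityParams":
        return replace(self, weight_scale=weight_scale)


@dataclass(frozen=True)
class SimulationConfig:
    """Trial protocol: Poisson drive, then a recorded free-running window.

    Each trial starts with ``input_duration`` ms of independent Poisson
    firing in the input pool at ``input_rate`` Hz; input units then fall
    silent and the next ``record_duration`` ms of network activity are
    recorded.  Input projections onto the excitatory population are
    redrawn every ``trials_per_epoch`` trials.
    """

    dt: float = 0.1
    input_duration: float = 50.0
    record_duration: float = 100.0
    input_rate: float = 15.0
    trials_per_epoch: int = 100
    n_epochs: int = 5
    seed: int = 0
    record_voltage: bool = False
    voltage_sample_interval: float = 1.0
    # "desynchronized": start near the sparse-state operating point
    # (default; avoids igniting the saturated runaway state).
    # "rest": start every neuron exactly at E_leak (deterministic
    # initial condition, used for closed-form single-neuron checks).
    init_mode: str = "desynchronized"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.5:
            raise ConfigurationError("dt must lie in (0, 0.5] ms")
        for name in ("input_duration", "record_duration"):
            dur = getattr(self, name)
            if abs(round(dur / self.dt) * self.dt - dur) > 1e-9:
                raise ConfigurationError(f"dt must divide {name}")
        if self.trials_per_epoch <= 0 or self.n_epochs <= 0:
            raise ConfigurationError("trial counts must be positive")
        if self.init_mode not in ("desynchronized", "rest"):
            raise ConfigurationError(
                f"unknown init_mode {self.init_mode!r}")

    @property
    def trial_duration(self) -> float:
        return self.input_duration + self.record_duration

    @property
    def n_trials(self) -> int:
        return self.trials_per_epoch * self.n_epochs
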