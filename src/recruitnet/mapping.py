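"""Mapping spiking (and voltage) data into activity-based networks.

Four representations are built from a simulation:

* functional network — edge (i, j) is the conditional frequency with
  which j fires in a 1 ms bin given i fired within the preceding lag
  interval T (including the same bin);
* active subnetwork — the synaptic subgraph induced on neurons that
  spiked at least once;
* recruitment network — the functional network masked by synaptic
  connectivity, i.e. the map of where activity actually propagated
  through synapses;
* voltage-conditioned networks — one graph per postsynaptic-voltage
  bin, edge (i, j) the probability that j's membrane potential falls in
  the bin given i was recently active, masked by synaptic connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .graphs import WeightedDigraph
from .network import SynapticNetwork
from .params import ConfigurationError
from .raster import SpikeRaster, VoltageTraces


@dataclass
class ActivityState:
    """Tri-state activity: 2 = firing this 1 ms bin, 1 = fired within the
    preceding T ms, 0 = otherwise.  ``s`` has shape
    (n_trials, n_neurons, n_bins)."""

    s: np.ndarray
    T: float

    def firing(self) -> np.ndarray:
        return self.s == 2

    def active(self) -> np.ndarray:
        return self.s > 0


def activity_state(raster: SpikeRaster, T: float = 25.0,
                   bin_ms: float = 1.0) -> ActivityState:
    """Build the tri-state activity array from a raster.

    The recent-activity window is truncated at trial start; activity
    never leaks across trials.
    """
    if T <= 0:
        raise ConfigurationError("T must be positive")
    if T > raster.record_duration:
        raise ConfigurationError(
            f"lag T={T} ms exceeds the {raster.record_duration} ms "
            "recording window")
    spikes = raster.binned(bin_ms) > 0        # trials x neurons x bins
    lag_bins = int(round(T / bin_ms))
    # recent[t] = any spike in bins [t - lag, t], trial-truncated
    recent = np.zeros_like(spikes)
    for k in range(lag_bins + 1):
        if k == 0:
            recent |= spikes
        else:
            recent[:, :, k:] |= spikes[:, :, :-k]
    s = np.zeros(spikes.shape, dtype=np.int8)
    s[recent] = 1
    s[spikes] = 2
    return ActivityState(s, T)


def spikes_from_state(state: ActivityState,
                      record_window: tuple[float, float],
                      bin_ms: float = 1.0) -> SpikeRaster:
    """Re-extract a (bin-resolution) raster from the s = 2 bins."""
    tr, nrn, b = np.nonzero(state.s == 2)
    times = record_window[0] + (b + 1) * bin_ms
    return SpikeRaster(tr, nrn, times, state.s.shape[0], state.s.shape[1],
                       record_window)


def functional_network(raster: SpikeRaster, T: float = 25.0,
                       n_neurons: int | None = None) -> WeightedDigraph:
    """Lagged-firing conditional-probability network.

    Edge (i, j) = (# 1 ms bins with s_j = 2 and s_i > 0) /
    (# bins with s_i > 0), pooled over trials and recording bins.
    Pairs with no conditioning bins get weight zero; there are no
    self-edges.
    """
    n = n_neurons or raster.n_neurons
    sub = raster if n == raster.n_neurons else raster.subset_neurons(
        np.arange(n))
    state = activity_state(sub, T)
    n_trials, _, n_bins = state.s.shape
    act = state.active().transpose(1, 0, 2).reshape(n, -1)
    fire = state.firing().transpose(1, 0, 2).reshape(n, -1)
    act_sp = csr_matrix(act)
    fire_sp = csr_matrix(fire)
    counts = np.asarray((act_sp @ fire_sp.T).todense(), dtype=float)
    denom = act.sum(axis=1).astype(float)
    W = np.divide(counts, denom[:, None], out=np.zeros_like(counts),
                  where=denom[:, None] > 0)
    np.fill_diagonal(W, 0.0)
    return WeightedDigraph(W, kind="functional")


def active_subnetwork(syn: SynapticNetwork,
                      raster: SpikeRaster) -> WeightedDigraph:
    """Synaptic subgraph induced on excitatory neurons with >= 1 spike.

    The graph keeps the full excitatory node set; rows and columns of
    silent neurons are zeroed, so downstream statistics see the induced
    subgraph while node indexing stays aligned with the other maps.
    """
    n_e = syn.n_excitatory
    if raster.n_neurons not in (n_e, syn.n_neurons):
        raise ValueError("raster and network node sets disagree")
    active = np.zeros(n_e, dtype=bool)
    act = raster.active_neurons()
    active[act[act < n_e]] = True
    W = syn.excitatory_subgraph.copy()
    W[~active, :] = 0.0
    W[:, ~active] = 0.0
    return WeightedDigraph(W, kind="active")


def recruitment_network(func: WeightedDigraph,
                        syn: SynapticNetwork) -> WeightedDigraph:
    """Functional network masked by synaptic connectivity."""
    mask = syn.excitatory_subgraph > 0
    if func.weights.shape != mask.shape:
        raise ValueError("functional network must cover the excitatory "
                         "population")
    return WeightedDigraph(np.where(mask, func.weights, 0.0),
                           kind="recruitment")


@dataclass
class VoltageBinSpec:
    """Contiguous voltage bins with equal sample occupancy."""

    lower: np.ndarray
    upper: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.lower.size

    @classmethod
    def equal_occupancy(cls, samples: np.ndarray,
                        n_bins: int = 8) -> "VoltageBinSpec":
        if samples.size < n_bins:
            raise ConfigurationError("not enough voltage samples for bins")
        qs = np.quantile(samples, np.linspace(0, 1, n_bins + 1))
        qs[0] -= 1e-9
        qs[-1] += 1e-9
        return cls(qs[:-1], qs[1:])


def subthreshold_samples(volts: VoltageTraces, raster: SpikeRaster,
                         V_thresh: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled subthreshold voltage samples and their validity mask.

    Samples in bins where the neuron emitted a spike are excluded.
    Returns (V, valid) with V shaped (n_trials, n_samples, n_neurons).
    """
    V = volts.V
    n_trials, n_samples, n_neurons = V.shape
    valid = np.ones(V.shape, dtype=bool)
    t0 = volts.record_window[0]
    dt = volts.sample_interval
    bin_idx = np.floor((raster.time - t0 - 1e-9) / dt).astype(int)
    m = (raster.neuron < n_neurons) & (bin_idx >= 0) & (bin_idx < n_samples)
    valid[raster.trial[m], bin_idx[m], raster.neuron[m]] = False
    return V, valid


def voltage_conditioned_networks(volts: VoltageTraces, raster: SpikeRaster,
                                 syn: SynapticNetwork,
                                 bins: VoltageBinSpec | int = 8,
                                 T: float = 25.0
                                 ) -> tuple[list[WeightedDigraph],
                                            VoltageBinSpec]:
    """One presynaptic-ensemble graph per postsynaptic voltage bin.

    Edge (i, j) in graph k is the fraction of valid (trial, 1 ms bin)
    samples with a_k < M_j <= b_k among samples where i fired within the
    preceding T ms, masked by synaptic connectivity (i -> j).
    """
    n_e = syn.n_excitatory
    V, valid = subthreshold_samples(volts, raster)
    if isinstance(bins, int):
        bins = VoltageBinSpec.equal_occupancy(V[valid], bins)
    n_trials, n_samples, _ = V.shape

    sub = raster.subset_neurons(np.arange(n_e))
    state = activity_state(sub, T, bin_ms=volts.sample_interval)
    act = state.active()[:, :, :n_samples]
    act_flat = act.transpose(1, 0, 2).reshape(n_e, -1).astype(np.float32)

    mask = (syn.excitatory_subgraph > 0)
    graphs: list[WeightedDigraph] = []
    valid_flat = valid.transpose(2, 0, 1).reshape(n_e, -1)
    denom = act_flat @ valid_flat.T.astype(np.float32)      # i x j
    bin_ids = np.digitize(V, bins.upper)                    # 0..n_bins
    bin_flat = bin_ids.transpose(2, 0, 1).reshape(n_e, -1)
    for k in range(bins.n_bins):
        ind = ((bin_flat == k) & valid_flat).astype(np.float32)
        num = act_flat @ ind.T
        if not np.any(denom > 0):
            raise ConfigurationError("no conditioning samples in any bin")
        W = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
        W = np.where(mask, W, 0.0).astype(float)
        np.fill_diagonal(W, 0.0)
        np.clip(W, 0.0, 1.0, out=W)
        graphs.append(WeightedDigraph(W, kind="voltage-conditioned"))
    return graphs, bins
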