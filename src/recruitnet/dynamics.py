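"""Summary statistics of simulated spiking dynamics.

Covers the quantities used to judge whether the model operates in the
asynchronous-irregular, near-critical regime: sparse excitatory rates,
low pairwise correlation of Gaussian-smoothed rate traces, interspike
interval irregularity, a branching coefficient near one, and
participation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .network import SynapticNetwork
from .params import SimulationConfig
from .raster import SpikeRaster


class EmptyRasterError(ValueError):
    """Statistics are undefined on a raster with no spikes."""


@dataclass
class DynamicsSummary:
    mean_pairwise_corr: float
    isi_cv2: float
    branching_coeff_median: float
    firing_rate_mean: float
    firing_rate_std: float
    participation_per_epoch: float
    participation_per_epoch_std: float
    participation_overall: float
    presyn_spikes_mean: float
    presyn_spikes_std: float


def firing_rates(raster: SpikeRaster, n_neurons: int | None = None
                 ) -> np.ndarray:
    """Per-neuron rate (Hz) over the recorded time across all trials."""
    if raster.n_spikes == 0:
        raise EmptyRasterError("no spikes recorded")
    n = n_neurons or raster.n_neurons
    total_s = raster.n_trials * raster.record_duration / 1000.0
    counts = np.bincount(raster.neuron, minlength=raster.n_neurons)[:n]
    return counts / total_s


def participation(raster: SpikeRaster, trials_per_epoch: int,
                  n_neurons: int | None = None
                  ) -> tuple[np.ndarray, float]:
    """Fraction of neurons spiking at least once, per epoch and overall."""
    n = n_neurons or raster.n_neurons
    epochs = raster.trial // trials_per_epoch
    per_epoch = []
    for ep in range(int(epochs.max()) + 1 if epochs.size else 0):
        m = (epochs == ep) & (raster.neuron < n)
        per_epoch.append(np.unique(raster.neuron[m]).size / n)
    overall = np.unique(raster.neuron[raster.neuron < n]).size / n
    return np.array(per_epoch), overall


def mean_pairwise_correlation(raster: SpikeRaster, sigma_ms: float = 3.0,
                              n_neurons: int | None = None,
                              max_neurons: int = 250,
                              rng_seed: int = 0) -> float:
    """Mean Pearson correlation of Gaussian-smoothed rate traces.

    Spike trains are binned at 1 ms, trials concatenated, smoothed with a
    Gaussian kernel of width ``sigma_ms``, and correlated across neuron
    pairs.  For large populations a random subset of ``max_neurons``
    neurons is used; the pair mean is an unbiased estimate of the full
    population pair mean.
    """
    if raster.n_spikes == 0:
        raise EmptyRasterError("no spikes recorded")
    n = n_neurons or raster.n_neurons
    binned = raster.binned(1.0)[:, :n, :]
    x = binned.transpose(1, 0, 2).reshape(n, -1).astype(np.float32)
    if n > max_neurons:
        sel = np.random.default_rng(rng_seed).choice(n, max_neurons,
                                                     replace=False)
        x = x[np.sort(sel)]
    x = gaussian_filter1d(x, sigma_ms, axis=1)
    sd = x.std(axis=1)
    x = x[sd > 0]
    if x.shape[0] < 2:
        raise EmptyRasterError("fewer than two active neurons")
    C = np.corrcoef(x)
    iu = np.triu_indices(C.shape[0], 1)
    return float(np.mean(C[iu]))


def isi_cv2(raster: SpikeRaster, n_neurons: int | None = None,
            min_intervals: int = 3) -> float:
    """Mean squared coefficient of variation of interspike intervals.

    Intervals are taken within trials and pooled per neuron; neurons
    contributing fewer than ``min_intervals`` intervals are skipped.
    """
    if raster.n_spikes == 0:
        raise EmptyRasterError("no spikes recorded")
    n = n_neurons or raster.n_neurons
    out = []
    for j in range(n):
        m = raster.neuron == j
        if not np.any(m):
            continue
        trs, ts = raster.trial[m], raster.time[m]
        isis = []
        for tr in np.unique(trs):
            x = ts[trs == tr]       # already time-sorted within neuron
            if x.size >= 2:
                isis.append(np.diff(x))
        if isis:
            isis = np.concatenate(isis)
            if isis.size >= min_intervals:
                out.append(isis.var() / isis.mean() ** 2)
    if not out:
        raise EmptyRasterError("no neuron with enough intervals")
    return float(np.mean(out))


def branching_coefficient(raster: SpikeRaster, bin_ms: float = 10.0,
                          n_neurons: int | None = None) -> float:
    """Median descendant/ancestor spike-count ratio in consecutive bins.

    For every trial and consecutive bin pair with a non-empty ancestor
    bin, the ratio of the later bin's spike count to the earlier bin's
    is computed; the median over all such pairs is returned.  A median
    near one indicates near-critical propagation.
    """
    if raster.n_spikes == 0:
        raise EmptyRasterError("no spikes recorded")
    n = n_neurons or raster.n_neurons
    sub = raster if n == raster.n_neurons else raster.subset_neurons(
        np.arange(n))
    counts = sub.binned(bin_ms).sum(axis=1)      # trials x bins
    anc = counts[:, :-1].ravel().astype(float)
    desc = counts[:, 1:].ravel().astype(float)
    ok = anc > 0
    if not np.any(ok):
        raise EmptyRasterError("no occupied ancestor bins")
    return float(np.median(desc[ok] / anc[ok]))


def presyn_spike_counts(net: SynapticNetwork, raster: SpikeRaster,
                        window_ms: float = 25.0) -> np.ndarray:
    """Excitatory presynaptic spikes preceding each postsynaptic spike.

    For every recorded excitatory spike, counts spikes from that
    neuron's excitatory synaptic presynaptic partners in the preceding
    ``window_ms`` (half-open window [t - w, t)), within the same trial.
    Returns the per-spike counts.
    """
    n_e = net.n_excitatory
    pre = net.excitatory_subgraph > 0       # pre x post
    m = raster.neuron < n_e
    trial, nrn, ts = raster.trial[m], raster.neuron[m], raster.time[m]
    counts = []
    for tr in np.unique(trial):
        sel = trial == tr
        n_t, t_t = nrn[sel], ts[sel]
        # pairwise: a is candidate presyn spike, b postsyn spike
        conn = pre[n_t[:, None], n_t[None, :]]
        dt = t_t[None, :] - t_t[:, None]
        in_win = (dt > 0) & (dt <= window_ms)
        counts.append((conn & in_win).sum(axis=0))
    return np.concatenate(counts)


def summarize_dynamics(raster: SpikeRaster, cfg: SimulationConfig,
                       net: SynapticNetwork | None = None,
                       long_raster: SpikeRaster | None = None,
                       ) -> DynamicsSummary:
    """Aggregate regime statistics for an excitatory-population raster.

    ``raster`` is the standard-protocol raster (full network indexing if
    ``net`` is given).  ``long_raster``, when supplied, is used for the
    interspike-interval irregularity (the long free-evolution protocol);
    otherwise the standard raster is used.  ``net`` enables the
    presynaptic spike-count statistic.
    """
    if raster.n_spikes == 0:
        raise EmptyRasterError("no spikes recorded")
    n_e = net.n_excitatory if net is not None else raster.n_neurons
    rates = firing_rates(raster, n_e)
    per_epoch, overall = participation(raster, cfg.trials_per_epoch, n_e)
    corr = mean_pairwise_correlation(raster, n_neurons=n_e)
    cv2 = isi_cv2(long_raster if long_raster is not None else raster,
                  n_neurons=n_e)
    branch = branching_coefficient(raster, 10.0, n_e)
    if net is not None:
        pc = presyn_spike_counts(net, raster)
        pre_mean, pre_std = float(pc.mean()), float(pc.std())
    else:
        pre_mean = pre_std = float("nan")
    return DynamicsSummary(
        mean_pairwise_corr=corr,
        isi_cv2=cv2,
        branching_coeff_median=branch,
        firing_rate_mean=float(rates.mean()),
        firing_rate_std=float(rates.std()),
        participation_per_epoch=float(per_epoch.mean()),
        participation_per_epoch_std=float(per_epoch.std()),
        participation_overall=float(overall),
        presyn_spikes_mean=pre_mean,
        presyn_spikes_std=pre_std,
    )
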