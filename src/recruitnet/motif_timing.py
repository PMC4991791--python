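"""Triplet-level timing analyses on pure fan-in and convergence motifs.

A *pure fan-in* triplet (a, b, t) has exactly the directed edges
a -> t, b -> t and a -> b among its three nodes, and no others; *simple
convergence* has exactly a -> t and b -> t.  The exclusion of any extra
edge (including the reverse b -> a) isolates the contribution of the
single presynaptic-presynaptic connection to spike timing at the shared
target.

A *coincident epoch* is a postsynaptic spike such that both presynaptic
neurons fired within the 50 ms window centered on it.  When a
presynaptic neuron fired several times in the window, the spike nearest
the postsynaptic spike defines its timing for that epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import mannwhitneyu

from .graphs import WeightedDigraph
from .network import SynapticNetwork
from .raster import SpikeRaster

MOTIF_CLASSES = ("fan-in", "convergence")


@dataclass
class TripletSet:
    """Parallel arrays of (presyn_a, presyn_b, postsyn) node indices.

    For fan-in triplets the pair is ordered so the edge runs a -> b.
    For convergence triplets a < b (no edge either way).
    """

    a: np.ndarray
    b: np.ndarray
    post: np.ndarray
    motif_class: str

    @property
    def n_triplets(self) -> int:
        return self.a.size

    def subsample(self, n: int, rng_seed: int = 0) -> "TripletSet":
        """Uniform subsample without replacement (all kept if n >= size)."""
        if n >= self.n_triplets:
            return self
        idx = np.random.default_rng(rng_seed).choice(
            self.n_triplets, n, replace=False)
        idx.sort()
        return TripletSet(self.a[idx], self.b[idx], self.post[idx],
                          self.motif_class)


def enumerate_pure_triplets(syn: SynapticNetwork,
                            motif_class: str) -> TripletSet:
    """All triplets matching the exact-edge-set motif definition.

    Enumerates over the excitatory synaptic subgraph.  Works per target:
    candidate presynaptic neurons are in-neighbors the target does not
    project back to; pair relations among candidates decide the class.
    """
    if motif_class not in MOTIF_CLASSES:
        raise ValueError(f"unknown motif class {motif_class!r}")
    A = syn.excitatory_subgraph > 0
    n = A.shape[0]
    out_a, out_b, out_t = [], [], []
    for t in range(n):
        cand = np.nonzero(A[:, t] & ~A[t, :])[0]
        if cand.size < 2:
            continue
        B = A[np.ix_(cand, cand)]
        if motif_class == "fan-in":
            rows, cols = np.nonzero(B & ~B.T)      # a -> b only
        else:
            iu = np.triu(~B & ~B.T, k=1)           # no edge either way
            rows, cols = np.nonzero(iu)
        if rows.size:
            out_a.append(cand[rows])
            out_b.append(cand[cols])
            out_t.append(np.full(rows.size, t, dtype=np.int64))
    if not out_a:
        empty = np.empty(0, dtype=np.int64)
        return TripletSet(empty, empty, empty, motif_class)
    return TripletSet(np.concatenate(out_a), np.concatenate(out_b),
                      np.concatenate(out_t), motif_class)


# ---------------------------------------------------------------------------
# coincidence counting

@njit(cache=True)
def _coincidence_kernel(times, indptr, n_trials, n_neurons,
                        tri_a, tri_b, tri_t, half_win,
                        n_coinc_out, dt_a_buf, dt_b_buf, max_epochs):
    """Count coincident epochs and collect presynaptic spike offsets.

    ``times``/``indptr`` hold per-(trial, neuron) sorted spike times in
    one flat array; slot index = trial * n_neurons + neuron.  Returns the
    number of recorded epochs; offsets (presyn time - postsyn time) for
    the a and b neurons land in the buffers.
    """
    n_epochs = 0
    for m in range(tri_a.size):
        a, b, t = tri_a[m], tri_b[m], tri_t[m]
        n_c = 0
        for tr in range(n_trials):
            sp = tr * n_neurons + t
            sa = tr * n_neurons + a
            sb = tr * n_neurons + b
            for ip in range(indptr[sp], indptr[sp + 1]):
                ts = times[ip]
                best_a = 1e18
                for ia in range(indptr[sa], indptr[sa + 1]):
                    d = times[ia] - ts
                    if -half_win <= d < half_win and abs(d) < abs(best_a):
                        best_a = d
                if best_a > 1e17:
                    continue
                best_b = 1e18
                for ib in range(indptr[sb], indptr[sb + 1]):
                    d = times[ib] - ts
                    if -half_win <= d < half_win and abs(d) < abs(best_b):
                        best_b = d
                if best_b > 1e17:
                    continue
                n_c += 1
                if n_epochs < max_epochs:
                    dt_a_buf[n_epochs] = best_a
                    dt_b_buf[n_epochs] = best_b
                    n_epochs += 1
        n_coinc_out[m] = n_c
    return n_epochs


@dataclass
class CoincidenceStats:
    motif_class: str
    rate_per_triplet_per_trial: float
    n_triplets: int
    n_trials: int
    n_epochs: int
    presyn_intervals: np.ndarray      # t_b - t_a per epoch, ms
    mean_abs_dt: float
    std_abs_dt: float

    def interval_histogram(self, bin_ms: float = 5.0,
                           lim: float = 50.0) -> tuple[np.ndarray,
                                                       np.ndarray]:
        edges = np.arange(-lim, lim + bin_ms, bin_ms)
        h, _ = np.histogram(self.presyn_intervals, edges, density=True)
        return h, edges

    def asymmetry(self) -> float:
        """Signed imbalance of the interval distribution about zero.

        (mass with t_b before t_a) - (mass with t_a before t_b); zero
        for a label-symmetric process.
        """
        d = self.presyn_intervals
        if d.size == 0:
            return 0.0
        return float(((d < 0).sum() - (d > 0).sum()) / d.size)


def coincidence_analysis(raster: SpikeRaster, triplets: TripletSet,
                         window: float = 50.0) -> CoincidenceStats:
    """Coincident-epoch rate and presynaptic timing at given triplets."""
    if triplets.n_triplets == 0:
        raise ValueError("empty triplet list")
    n_tr, n_nrn = raster.n_trials, raster.n_neurons
    # flat per-(trial, neuron) spike-time slots
    order = np.lexsort((raster.time, raster.neuron, raster.trial))
    times = raster.time[order]
    slot = raster.trial[order] * n_nrn + raster.neuron[order]
    indptr = np.searchsorted(slot, np.arange(n_tr * n_nrn + 1))

    n_coinc = np.zeros(triplets.n_triplets, dtype=np.int64)
    max_epochs = 4_000_000
    dt_a = np.empty(max_epochs)
    dt_b = np.empty(max_epochs)
    n_epochs = _coincidence_kernel(
        times, indptr, n_tr, n_nrn,
        triplets.a, triplets.b, triplets.post, window / 2.0,
        n_coinc, dt_a, dt_b, max_epochs)
    intervals = dt_b[:n_epochs] - dt_a[:n_epochs]
    abs_dt = np.abs(intervals)
    return CoincidenceStats(
        motif_class=triplets.motif_class,
        rate_per_triplet_per_trial=float(
            n_coinc.mean() / n_tr),
        n_triplets=triplets.n_triplets,
        n_trials=n_tr,
        n_epochs=int(n_epochs),
        presyn_intervals=intervals,
        mean_abs_dt=float(abs_dt.mean()) if n_epochs else float("nan"),
        std_abs_dt=float(abs_dt.std()) if n_epochs else float("nan"),
    )


def coincidence_rate_ratio(fan_in: CoincidenceStats,
                           convergence: CoincidenceStats) -> float:
    """Fan-in over convergence coincident-epoch rate."""
    if convergence.rate_per_triplet_per_trial == 0:
        raise ZeroDivisionError("convergence coincidence rate is zero")
    return (fan_in.rate_per_triplet_per_trial
            / convergence.rate_per_triplet_per_trial)


def sample_epoch_timing(stats: CoincidenceStats, n_samples: int = 1000,
                        rng_seed: int = 0) -> np.ndarray:
    """Uniform sample of per-epoch |t_b - t_a| values (ms)."""
    d = np.abs(stats.presyn_intervals)
    if d.size == 0:
        raise ValueError("no coincident epochs to sample")
    if d.size <= n_samples:
        return d
    idx = np.random.default_rng(rng_seed).choice(d.size, n_samples,
                                                 replace=False)
    return d[idx]


# ---------------------------------------------------------------------------
# rate vs. clustering and shared neighbors

def firing_rate_vs_clustering(rates: np.ndarray, coefficients: np.ndarray,
                              thresholds=(0, 20, 40, 60, 80, 90, 95)):
    """Rate distribution of neurons above each clustering percentile.

    Returns a pandas DataFrame with one row per threshold: the
    percentile, the number of supra-threshold neurons, and the median
    and quartiles of their firing rates.  Thresholds that exclude every
    neuron yield a row with n = 0 and NaN statistics.
    """
    import pandas as pd

    if rates.shape != coefficients.shape:
        raise ValueError("rates and coefficients must align")
    rows = []
    for q in thresholds:
        cut = np.percentile(coefficients, q)
        sel = rates[coefficients >= cut]
        rows.append({
            "threshold_pct": q,
            "n_neurons": int(sel.size),
            "rate_q25": float(np.percentile(sel, 25)) if sel.size else
            float("nan"),
            "rate_median": float(np.median(sel)) if sel.size else
            float("nan"),
            "rate_q75": float(np.percentile(sel, 75)) if sel.size else
            float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class SharedNeighborReport:
    n_pairs: int
    recruiting_mean: float
    non_recruiting_mean: float
    statistic: float
    p_value: float


def shared_neighbor_comparison(syn: SynapticNetwork,
                               recruit: WeightedDigraph,
                               n_pairs: int = 500,
                               rng_seed: int = 0) -> SharedNeighborReport:
    """Shared-neighbor counts of recruiting vs. never-sequential edges.

    Synaptic excitatory edges are split by whether the recruitment
    network carries them (weight > 0).  Each sampled non-recruiting edge
    is matched to a recruiting edge with the same target in-degree
    (fallback +-1).  Shared neighbors of an edge (i, j) are nodes
    adjacent (either direction) to both i and j in the synaptic graph.
    One-sided rank-sum: recruiting edges share more neighbors.
    """
    A = syn.excitatory_subgraph > 0
    if recruit.weights.shape != A.shape:
        raise ValueError("recruitment graph must cover the excitatory "
                         "population")
    R = recruit.weights > 0
    src, tgt = np.nonzero(A)
    is_rec = R[src, tgt]
    if is_rec.all() or not is_rec.any():
        side = "recruiting" if is_rec.all() else "non-recruiting"
        raise ValueError(f"degenerate partition: every synaptic edge is "
                         f"{side}")
    U = A | A.T
    d_in = A.sum(axis=0)
    shared = (U[src] & U[tgt]).sum(axis=1)

    rng = np.random.default_rng(rng_seed)
    rec_idx = np.nonzero(is_rec)[0]
    non_idx = np.nonzero(~is_rec)[0]
    rng.shuffle(non_idx)
    rec_by_deg: dict[int, list] = {}
    for k in rec_idx:
        rec_by_deg.setdefault(int(d_in[tgt[k]]), []).append(k)
    for v in rec_by_deg.values():
        rng.shuffle(v)
    rec_sample, non_sample = [], []
    for k in non_idx:
        deg = int(d_in[tgt[k]])
        match = None
        for d in (deg, deg - 1, deg + 1):
            if rec_by_deg.get(d):
                match = rec_by_deg[d].pop()
                break
        if match is None:
            continue
        rec_sample.append(match)
        non_sample.append(k)
        if len(rec_sample) >= n_pairs:
            break
    if len(rec_sample) < n_pairs:
        raise ValueError(f"only {len(rec_sample)} in-degree-matched pairs "
                         f"available (requested {n_pairs})")
    x = shared[np.array(rec_sample)]
    y = shared[np.array(non_sample)]
    stat, p = mannwhitneyu(x, y, alternative="greater")
    return SharedNeighborReport(
        n_pairs=len(rec_sample),
        recruiting_mean=float(x.mean()),
        non_recruiting_mean=float(y.mean()),
        statistic=float(stat), p_value=float(p))
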