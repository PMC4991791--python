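"""Calcium-imaging arm: event detection and functional-map inference.

Fluorescence traces are reduced to binary event rasters (periods of
elevated firing probability) by a signal-to-noise screen and a
two-sigma excursion detector; a directed functional map is then
inferred from single-frame-lagged co-events with an iterative
explaining-away update, thresholded, and characterized by its directed
triangle-motif census under bootstrap false-positive resampling.

The inference update treats each event of a target cell as generated by
exactly one of the cells active in the preceding frame and splits the
credit for it among those candidate parents in proportion to the
current edge weights; edge weights are then re-estimated as credited
events per parent opportunity.  Repeating to convergence suppresses
spurious edges whose co-activation is explained by a stronger competing
parent.  The update is validated by planted-structure recovery, not by
equivalence to any external implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .graph_stats import MOTIFS, directed_clustering
from .graphs import WeightedDigraph
from .params import ConfigurationError


@dataclass
class FluorescenceRecording:
    traces: np.ndarray                 # (n_cells, n_frames)
    frame_rate: float                  # Hz
    positions: np.ndarray | None = None  # (n_cells, 2) micrometres

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ConfigurationError("traces must be (n_cells, n_frames)")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame rate must be positive")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if (self.positions.shape != (self.n_cells, 2)
                    or not np.all(np.isfinite(self.positions))):
                raise ConfigurationError("positions must be finite (n, 2)")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def save_csv(self, path) -> None:
        np.savetxt(path, self.traces.T, delimiter=",")

    @classmethod
    def load_csv(cls, path, frame_rate: float,
                 positions=None) -> "FluorescenceRecording":
        return cls(np.loadtxt(path, delimiter=",").T, frame_rate, positions)


@dataclass
class EventRaster:
    events: np.ndarray                 # (n_cells, n_frames) bool
    snr: np.ndarray                    # per cell
    retained: np.ndarray               # per cell bool
    frame_rate: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=bool)
        if np.any(self.events[~self.retained]):
            raise ConfigurationError("events marked on non-retained cells")

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    @property
    def retention_fraction(self) -> float:
        return float(self.retained.mean())


def detect_events(rec: FluorescenceRecording, snr_cutoff: float = 1.55,
                  excursion_sigma: float = 2.0) -> EventRaster:
    """Binary elevated-activity raster from fluorescence traces.

    Per cell: SNR = 99th percentile / mean of the raw trace; cells at or
    below ``snr_cutoff`` are dropped.  Retained traces are z-scored;
    every contiguous run above ``excursion_sigma`` is extended backward
    to the most recent crossing of the trace's median, and the union of
    the extended runs is marked as the event epochs.

    The event epochs of a retained cell are invariant to affine
    rescaling of its trace (z-scoring absorbs gain and offset); the SNR
    screen itself is gain-invariant but, like any percentile-over-mean
    ratio of raw fluorescence, depends on the baseline offset.
    """
    if rec.duration_s < 10.0:
        raise ConfigurationError("recording shorter than 10 s")
    n, f = rec.n_cells, rec.n_frames
    snr = np.full(n, np.nan)
    retained = np.zeros(n, dtype=bool)
    events = np.zeros((n, f), dtype=bool)
    for c in range(n):
        x = rec.traces[c]
        sd = x.std()
        if sd == 0:
            warnings.warn(f"cell {c}: constant trace, SNR undefined; "
                          "dropped")
            continue
        mu = x.mean()
        if mu <= 0:
            warnings.warn(f"cell {c}: non-positive mean fluorescence, "
                          "SNR undefined; dropped")
            continue
        snr[c] = np.percentile(x, 99) / mu
        if snr[c] <= snr_cutoff:
            continue
        retained[c] = True
        z = (x - mu) / sd
        med = np.median(z)
        above = z > excursion_sigma
        below_med = z <= med
        ev = above.copy()
        # extend each excursion backward to the last median crossing
        starts = np.nonzero(above & ~np.roll(above, 1))[0]
        if above[0]:
            starts = np.unique(np.concatenate(([0], starts)))
        cross = np.nonzero(below_med)[0]
        for s in starts:
            k = np.searchsorted(cross, s) - 1
            lo = cross[k] + 1 if k >= 0 else 0
            ev[lo:s] = True
        events[c] = ev
    return EventRaster(events, snr, retained, rec.frame_rate)


# ---------------------------------------------------------------------------
# inference

@dataclass
class InferredNetwork:
    weights: np.ndarray                # (n_cells, n_cells), row = source
    n_init: int
    frame_rate: float
    retained: np.ndarray | None = None

    def graph(self) -> WeightedDigraph:
        return WeightedDigraph(self.weights, kind="inferred")

    def threshold(self, percentile: float) -> WeightedDigraph:
        w = self.weights[self.weights > 0]
        if w.size == 0:
            raise ValueError("no non-zero inferred weights")
        cut = np.percentile(w, percentile)
        W = np.where(self.weights > cut, self.weights, 0.0)
        if not np.any(W):
            raise ValueError(f"thresholding at the {percentile}th "
                             "percentile leaves an empty graph")
        return WeightedDigraph(W, kind="inferred")


def _infer_once(X: np.ndarray, Y: np.ndarray, opportunities: np.ndarray,
                W0: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """One run of the explaining-away iteration.

    ``X`` (n_cells, n_lagframes) are parent-frame events; ``Y`` the
    target events one frame later.  For each target event the credit is
    split among its active parents in proportion to current weights;
    each weight is then the credited events per parent opportunity.
    """
    W = W0.copy()
    Xf = X.astype(float)
    Yf = Y.astype(float)
    inv_opp = np.divide(1.0, opportunities,
                        out=np.zeros_like(opportunities, dtype=float),
                        where=opportunities > 0)
    for _ in range(max_iter):
        # denom[j, f] = total weight of parents active before event (j, f)
        denom = W.T @ Xf
        resp = np.divide(Yf, denom, out=np.zeros_like(Yf),
                         where=denom > 0)
        credit = Xf @ resp.T           # credited events per (parent, target)
        W_new = W * credit * inv_opp[:, None]
        np.fill_diagonal(W_new, 0.0)
        delta = np.max(np.abs(W_new - W))
        W = W_new
        if delta < tol:
            break
    return W


def infer_functional_weights(events: EventRaster, n_init: int = 5,
                             rng_seed: int = 0, tol: float = 1e-6,
                             max_iter: int = 100) -> InferredNetwork:
    """Directed functional map from single-frame-lagged co-events.

    Runs the explaining-away iteration from ``n_init`` random positive
    initializations (scaled by the raw lagged co-activation counts so
    impossible edges start and stay at zero) and averages the final
    weight matrices.
    """
    E = events.events
    n = E.shape[0]
    if events.retained.sum() < 2:
        raise ValueError("need at least two retained cells")
    X = E[:, :-1]
    Y = E[:, 1:]
    co = X.astype(float) @ Y.T.astype(float)     # i active, j event next
    np.fill_diagonal(co, 0.0)
    if not np.any(co > 0):
        warnings.warn("no lag-1 co-events anywhere; returning an all-zero "
                      "network")
        return InferredNetwork(np.zeros((n, n)), n_init, events.frame_rate,
                               events.retained)
    opportunities = X.sum(axis=1).astype(float)
    rng = np.random.default_rng(rng_seed)
    acc = np.zeros((n, n))
    for _ in range(n_init):
        W0 = co * rng.uniform(0.5, 1.5, size=co.shape)
        acc += _infer_once(X, Y, opportunities, W0, tol, max_iter)
    return InferredNetwork(acc / n_init, n_init, events.frame_rate,
                           events.retained)


@dataclass
class BootstrapCensus:
    censuses: dict[str, np.ndarray]    # motif -> (n_boot,) mean coefficients
    point: dict[str, float]            # census of the thresholded graph
    n_boot: int
    fp_rate: float

    def ci(self, motif: str, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        x = self.censuses[motif]
        return float(np.quantile(x, a)), float(np.quantile(x, 1 - a))


def threshold_and_bootstrap(net: InferredNetwork, percentile: float,
                            fp_rate: float = 0.30, n_boot: int = 100,
                            rng_seed: int = 0) -> BootstrapCensus:
    """Motif-census distribution under false-positive edge redaction.

    Edges above the weight percentile are kept; each bootstrap draw
    removes ``fp_rate`` of the kept edges uniformly at random and
    recomputes the binary directed motif census.
    """
    if not 0 < percentile <= 100:
        raise ConfigurationError("percentile must be in (0, 100]")
    g = net.threshold(percentile)
    src, tgt = np.nonzero(g.weights)
    m = src.size
    if m < 10:
        raise ValueError(f"only {m} edges survive the threshold")
    point = directed_clustering(g, binary=True)
    rng = np.random.default_rng(rng_seed)
    n_drop = int(round(fp_rate * m))
    out = {mo: np.empty(n_boot) for mo in MOTIFS}
    for b in range(n_boot):
        W = g.weights.copy()
        if n_drop:
            drop = rng.choice(m, n_drop, replace=False)
            W[src[drop], tgt[drop]] = 0.0
        c = directed_clustering(WeightedDigraph(W, kind="inferred"),
                                binary=True)
        for mo in MOTIFS:
            out[mo][b] = c.mean_coefficient(mo)
    return BootstrapCensus(out, {mo: point.mean_coefficient(mo)
                                 for mo in MOTIFS}, n_boot, fp_rate)


# ---------------------------------------------------------------------------
# triplet cross-correlation and spatial statistics

def triplet_crosscorr(rec: FluorescenceRecording, triplets,
                      window_s: float = 2.0) -> tuple[np.ndarray,
                                                      np.ndarray]:
    """Presynaptic-product vs. postsynaptic trace correlogram.

    For each triplet (a, b, t) the z-scored traces of a and b are
    multiplied and correlated with t's z-scored trace at every lag in
    +-``window_s``; positive lags mean the product leads.  Returns
    (lags_s, correlogram averaged over triplets).  ``triplets`` is an
    iterable of (a, b, t) index triples.
    """
    lag_frames = int(round(window_s * rec.frame_rate))
    if 2 * lag_frames + 1 > rec.n_frames:
        raise ConfigurationError("window longer than the recording")
    tr = rec.traces
    sd = tr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (tr - tr.mean(axis=1, keepdims=True)) / sd
    lags = np.arange(-lag_frames, lag_frames + 1)
    triplets = list(triplets)
    if not triplets:
        raise ValueError("empty triplet list")
    acc = np.zeros(lags.size)
    for a, b, t in triplets:
        prod = z[a] * z[b]
        ps = prod.std()
        if ps == 0:
            continue
        prod = (prod - prod.mean()) / ps
        post = z[t]
        for k, lag in enumerate(lags):
            if lag >= 0:
                x, y = prod[:prod.size - lag], post[lag:]
            else:
                x, y = prod[-lag:], post[:post.size + lag]
            acc[k] += float(np.dot(x, y) / x.size)
    return lags / rec.frame_rate, acc / len(triplets)


@dataclass
class SpatialReport:
    connected_median_um: float
    random_median_um: float
    pair_p_value: float
    triangle_perimeter_um: float
    wedge_perimeter_um: float
    random_perimeter_um: float
    n_triangles: int
    n_wedges: int


def spatial_stats(positions: np.ndarray, net: InferredNetwork,
                  percentile: float = 95, n_random: int = 10000,
                  rng_seed: int = 0) -> SpatialReport:
    """Distances of strong functional pairs and triplets vs. chance.

    Compares the pairwise distances of supra-threshold edges against
    random cell pairs (two-sided rank-sum), and the triangle perimeters
    of fully-connected triplets against wedges (two connected pairs) and
    random triplets.  All distances in the units of ``positions``.
    """
    pos = np.asarray(positions, dtype=float)
    g = net.threshold(percentile)
    S = (g.weights > 0) | (g.weights.T > 0)
    n = pos.shape[0]
    rng = np.random.default_rng(rng_seed)

    def dist(i, j):
        return np.linalg.norm(pos[i] - pos[j], axis=-1)

    src, tgt = np.nonzero(np.triu(S, 1))
    if src.size == 0:
        raise ValueError("no supra-threshold edges")
    d_conn = dist(src, tgt)
    ri = rng.integers(0, n, n_random)
    rj = rng.integers(0, n, n_random)
    ok = ri != rj
    d_rand = dist(ri[ok], rj[ok])
    _, p_pair = mannwhitneyu(d_conn, d_rand, alternative="two-sided")

    tri_per, wed_per = [], []
    for i in range(n):
        nb = np.nonzero(S[i])[0]
        nb = nb[nb > i]
        for x in range(nb.size):
            for y in range(x + 1, nb.size):
                j, k = nb[x], nb[y]
                per = (dist(i, j) + dist(i, k) + dist(j, k))
                (tri_per if S[j, k] else wed_per).append(per)
    rt = rng.integers(0, n, (n_random, 3))
    rt = rt[(rt[:, 0] != rt[:, 1]) & (rt[:, 0] != rt[:, 2])
            & (rt[:, 1] != rt[:, 2])]
    rand_per = (dist(rt[:, 0], rt[:, 1]) + dist(rt[:, 0], rt[:, 2])
                + dist(rt[:, 1], rt[:, 2]))
    return SpatialReport(
        connected_median_um=float(np.median(d_conn)),
        random_median_um=float(np.median(d_rand)),
        pair_p_value=float(p_pair),
        triangle_perimeter_um=float(np.median(tri_per)) if tri_per else
        float("nan"),
        wedge_perimeter_um=float(np.median(wed_per)) if wed_per else
        float("nan"),
        random_perimeter_um=float(np.median(rand_per)),
        n_triangles=len(tri_per), n_wedges=len(wed_per))
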