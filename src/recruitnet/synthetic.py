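"""Synthetic data generators: surrogates, calcium recordings, fixtures.

Everything downstream of the simulator can be exercised with no
external data: rate-matched Poisson surrogates destroy interactions
while preserving per-neuron-per-trial rate profiles; the calcium
generator plants a known directed graph in a fluorescence recording so
inference can be scored against ground truth; toy fixtures provide
hand-enumerable graphs and rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import WeightedDigraph
from .imaging import EventRaster, FluorescenceRecording
from .params import ConfigurationError
from .raster import SpikeRaster


# ---------------------------------------------------------------------------
# Poisson surrogate

@dataclass
class SurrogateSpec:
    bin_width: float = 100.0           # ms
    seed: int = 0


def poisson_rate_matched(raster: SpikeRaster,
                         spec: SurrogateSpec) -> SpikeRaster:
    """Interaction-free surrogate matching per-bin expected counts.

    For every (neuron, trial, bin) the surrogate spike count is drawn
    Poisson with mean equal to the observed count in that bin; spike
    times are uniform within the bin.  Rates are matched
    neuron-by-neuron and trial-by-trial; all cross-neuron dependence is
    destroyed.
    """
    window = raster.record_duration
    n_bins = window / spec.bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ConfigurationError("bin width must divide the recording "
                                 "window")
    counts = raster.binned(spec.bin_width)     # trials x neurons x bins
    rng = np.random.default_rng(spec.seed)
    draws = rng.poisson(counts)
    tr, nrn, b = np.nonzero(draws)
    reps = draws[tr, nrn, b]
    tr = np.repeat(tr, reps)
    nrn = np.repeat(nrn, reps)
    b = np.repeat(b, reps)
    t0 = raster.record_window[0]
    times = t0 + (b + rng.random(b.size)) * spec.bin_width
    return SpikeRaster(tr, nrn, times, raster.n_trials, raster.n_neurons,
                       raster.record_window)


# ---------------------------------------------------------------------------
# calcium generator

@dataclass
class CalciumGenConfig:
    n_cells: int = 450
    frame_rate: float = 20.0           # Hz
    duration_s: float = 300.0
    rise_s: float = 0.05               # transient kernel rise
    decay_s: float = 0.6               # transient kernel decay
    noise_sigma: float = 0.06          # additive noise, amplitude units
    base_event_rate: float = 0.10      # events per second per cell
    burst_rate: float = 0.20           # population bursts per second
    burst_lift: float = 8.0            # event-rate multiplier in bursts
    coupling: float = 0.35             # lag-1 event-probability lift
    graph_density: float = 0.03        # planted ER density
    baseline: float = 1.0              # resting fluorescence level
    amplitude_mu: float = 0.0          # lognormal per-cell amplitude
    amplitude_sigma: float = 0.75      # spread targeting ~43% retention
    field_um: float = 300.0            # square field side
    distance_scale_um: float = 0.0     # 0 = no spatial kernel

    def __post_init__(self) -> None:
        if min(self.rise_s, self.decay_s) <= 0:
            raise ConfigurationError("kernel time constants must be > 0")
        if self.rise_s >= self.decay_s:
            raise ConfigurationError("rise must be faster than decay")


def transient_kernel(cfg: CalciumGenConfig) -> np.ndarray:
    """Peak-normalized difference-of-exponentials transient."""
    dt = 1.0 / cfg.frame_rate
    length = int(round(5 * cfg.decay_s / dt)) + 1
    t = np.arange(length) * dt
    k = np.exp(-t / cfg.decay_s) - np.exp(-t / cfg.rise_s)
    return k / k.max()


def generate_calcium(cfg: CalciumGenConfig, rng_seed: int = 0
                     ) -> tuple[FluorescenceRecording, EventRaster,
                                WeightedDigraph]:
    """Fluorescence recording with a planted directed ground truth.

    Event onsets are sparse per-cell Bernoulli processes modulated by
    shared population bursts; a directed edge i -> j lifts j's onset
    probability by ``coupling`` one frame after an i onset (scaled by a
    distance kernel when ``distance_scale_um`` > 0).  Each onset adds a
    per-cell-amplitude transient to the trace; Gaussian noise is added
    on top.  Returns (recording, planted onset raster, planted graph);
    the planted raster marks every cell retained since it is ground
    truth, not a detection.
    """
    rng = np.random.default_rng(rng_seed)
    n = cfg.n_cells
    f = int(round(cfg.duration_s * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate

    pos = rng.uniform(0, cfg.field_um, (n, 2))
    G = (rng.random((n, n)) < cfg.graph_density).astype(float)
    np.fill_diagonal(G, 0.0)
    if cfg.distance_scale_um > 0:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        keep = rng.random((n, n)) < np.exp(-d / cfg.distance_scale_um)
        G *= keep
    graph = WeightedDigraph(G, kind="synaptic", nodes=np.arange(n))

    # population burst envelope (shared rate modulation)
    burst = np.ones(f)
    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration_s)
    for _ in range(n_bursts):
        c = rng.integers(0, f)
        w = rng.integers(2, 7)          # 100-300 ms bursts
        burst[max(0, c - w):c + w] = cfg.burst_lift
    p_base = cfg.base_event_rate * dt

    onsets = np.zeros((n, f), dtype=bool)
    prev = np.zeros(n, dtype=bool)
    parents = G.T > 0                   # parents[j] = sources into j
    for t in range(f):
        p = np.full(n, p_base * burst[t])
        if prev.any():
            driven = parents[:, prev].any(axis=1)
            p[driven] = np.minimum(p[driven] + cfg.coupling, 0.95)
        now = rng.random(n) < p
        onsets[:, t] = now
        prev = now

    kernel = transient_kernel(cfg)
    amp = rng.lognormal(cfg.amplitude_mu, cfg.amplitude_sigma, n)
    traces = np.empty((n, f))
    for c in range(n):
        x = np.convolve(onsets[c].astype(float), kernel)[:f] * amp[c]
        traces[c] = cfg.baseline + x + rng.normal(0, cfg.noise_sigma, f)

    rec = FluorescenceRecording(traces, cfg.frame_rate, pos)
    truth = EventRaster(onsets, np.full(n, np.inf),
                        np.ones(n, dtype=bool), cfg.frame_rate)
    return rec, truth, graph


def event_recovery_fraction(truth: EventRaster, detected: EventRaster,
                            tol_frames: int = 1) -> float:
    """Fraction of planted onsets covered by detected events.

    An onset counts as recovered if the detected raster marks any frame
    within ``tol_frames`` of it.  Only cells retained by the detector
    are scored (detection is gated by the SNR screen).
    """
    cells = np.nonzero(truth.retained & detected.retained)[0]
    hit = tot = 0
    for c in cells:
        on = np.nonzero(truth.events[c])[0]
        det = detected.events[c]
        for t in on:
            lo, hi = max(0, t - tol_frames), min(det.size, t + tol_frames + 1)
            hit += bool(det[lo:hi].any())
            tot += 1
    return hit / tot if tot else float("nan")


# ---------------------------------------------------------------------------
# toy fixtures

@dataclass
class ToyFixtures:
    graphs: dict[str, WeightedDigraph]
    rasters: dict[str, SpikeRaster]
    # hand-enumerated per-node triangle counts for the labeled graphs
    censuses: dict[str, dict[str, list]]


def toy_fixtures() -> ToyFixtures:
    """Deterministic catalog of hand-checkable graphs and rasters.

    ``single_triangle`` is the graph {0->2, 1->2, 0->1}: by hand, node 2
    closes one fan-in triangle, node 0 one fan-out, node 1 one
    middleman, and there is no cycle.  ``er_seed7`` and ``er_seed20``
    are frozen Erdős-Rényi draws for oracle comparisons.
    """
    tri = np.zeros((3, 3))
    tri[0, 2] = tri[1, 2] = tri[0, 1] = 1.0
    graphs = {
        "single_triangle": WeightedDigraph(tri),
        "empty5": WeightedDigraph(np.zeros((5, 5))),
        "two_cycle": WeightedDigraph(
            np.array([[0., 1.], [1., 0.]])),
    }
    for name, (n, p, seed) in {"er_seed7": (7, 0.4, 7),
                               "er_seed20": (20, 0.25, 20)}.items():
        rng = np.random.default_rng(seed)
        A = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(A, 0.0)
        graphs[name] = WeightedDigraph(A)

    rasters = {
        "two_spikes": SpikeRaster(
            np.array([0, 0]), np.array([0, 1]), np.array([10.0, 12.0]),
            n_trials=1, n_neurons=3, record_window=(0.0, 100.0)),
        "silent": SpikeRaster(
            np.empty(0, int), np.empty(0, int), np.empty(0),
            n_trials=2, n_neurons=4, record_window=(0.0, 100.0)),
    }
    censuses = {
        "single_triangle": {
            "fan_in": [0, 0, 1], "fan_out": [1, 0, 0],
            "middleman": [0, 1, 0], "cycle": [0, 0, 0]},
        "empty5": {m: [0] * 5 for m in
                   ("fan_in", "fan_out", "middleman", "cycle")},
    }
    return ToyFixtures(graphs, rasters, censuses)
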