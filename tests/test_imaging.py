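"""Event detection, explaining-away inference, and imaging statistics."""

import numpy as np
import pytest

from recruitnet.imaging import (FluorescenceRecording, EventRaster,
                                InferredNetwork, detect_events,
                                infer_functional_weights, spatial_stats,
                                threshold_and_bootstrap,
                                triplet_crosscorr)
from recruitnet.synthetic import (CalciumGenConfig, generate_calcium,
                                  transient_kernel)

FRAME_RATE = 20.0


def _signal_trace(onsets, n_frames, amp=2.0, noise=0.02, seed=0,
                  baseline=1.0):
    cfg = CalciumGenConfig(frame_rate=FRAME_RATE)
    k = transient_kernel(cfg)
    rng = np.random.default_rng(seed)
    x = np.zeros(n_frames)
    x[list(onsets)] = 1.0
    return (baseline + amp * np.convolve(x, k)[:n_frames]
            + rng.normal(0, noise, n_frames))


def test_noise_cell_rejected_signal_cell_retained():
    n_frames = 600
    rng = np.random.default_rng(1)
    noise_only = 1.0 + rng.normal(0, 0.06, n_frames)
    signal = _signal_trace([100, 300, 500], n_frames)
    rec = FluorescenceRecording(np.vstack([noise_only, signal]),
                                FRAME_RATE)
    ev = detect_events(rec, snr_cutoff=1.55)
    assert not ev.retained[0]
    assert ev.retained[1]
    assert ev.snr[0] < 1.55 < ev.snr[1]
    assert not ev.events[0].any()
    assert ev.events[1].any()


def test_degenerate_traces_dropped_with_warning():
    n_frames = 400
    flat = np.full(n_frames, 1.0)
    negative = -1.0 + np.random.default_rng(0).normal(0, 0.01, n_frames)
    good = _signal_trace([200], n_frames)
    rec = FluorescenceRecording(np.vstack([flat, negative, good]),
                                FRAME_RATE)
    with pytest.warns(UserWarning):
        ev = detect_events(rec)
    assert list(ev.retained) == [False, False, True]


def test_event_onset_detected_within_one_frame():
    n_frames = 400
    onset = 150
    rec = FluorescenceRecording(
        _signal_trace([onset], n_frames, noise=0.01)[None, :], FRAME_RATE)
    ev = detect_events(rec)
    frames = np.nonzero(ev.events[0])[0]
    assert frames.size > 0
    assert abs(frames.min() - onset) <= 1


def test_event_epochs_invariant_to_affine_gain():
    n_frames = 600
    base = _signal_trace([50, 250, 450], n_frames)
    scaled = 3.0 * base + 0.5
    rec = FluorescenceRecording(np.vstack([base, scaled]), FRAME_RATE)
    ev = detect_events(rec, snr_cutoff=1.05)
    assert ev.retained.all()
    assert np.array_equal(ev.events[0], ev.events[1])


def _event_raster(events):
    events = np.asarray(events, dtype=bool)
    return EventRaster(events, np.full(events.shape[0], np.inf),
                       np.ones(events.shape[0], dtype=bool), FRAME_RATE)


def test_driver_pair_inferred_directionally():
    """Cell 0 events always followed one frame later by cell 1: the
    inferred weight 0 -> 1 saturates while 1 -> 0 is exactly zero."""
    n_frames = 300
    e = np.zeros((2, n_frames), dtype=bool)
    e[0, 5:n_frames - 1:10] = True
    e[1, 6:n_frames:10] = True
    net = infer_functional_weights(_event_raster(e))
    assert net.weights[0, 1] == pytest.approx(1.0, abs=1e-6)
    assert net.weights[1, 0] == 0.0


def test_explaining_away_suppresses_redundant_parent():
    """X drives Z on every X event; Y coincides with only half of the X
    events and never drives Z alone.  X must absorb the credit."""
    n_frames = 400
    e = np.zeros((3, n_frames), dtype=bool)
    x_frames = np.arange(5, n_frames - 1, 10)
    e[0, x_frames] = True                 # X
    e[1, x_frames[::2]] = True            # Y, a subset of X's frames
    e[2, x_frames + 1] = True             # Z follows X always
    net = infer_functional_weights(_event_raster(e))
    assert net.weights[0, 2] > 5 * net.weights[1, 2]


def test_inference_deterministic_given_seed():
    rng = np.random.default_rng(4)
    e = rng.random((6, 500)) < 0.05
    a = infer_functional_weights(_event_raster(e), rng_seed=9)
    b = infer_functional_weights(_event_raster(e), rng_seed=9)
    assert np.array_equal(a.weights, b.weights)


def test_no_coevents_yields_zero_network_with_warning():
    e = np.zeros((3, 200), dtype=bool)
    e[0, 10] = True                       # single isolated event
    with pytest.warns(UserWarning):
        net = infer_functional_weights(_event_raster(e))
    assert not net.weights.any()


def test_bootstrap_zero_fp_rate_is_degenerate():
    rng = np.random.default_rng(2)
    W = np.where(rng.random((30, 30)) < 0.2, rng.random((30, 30)), 0.0)
    np.fill_diagonal(W, 0.0)
    net = InferredNetwork(W, n_init=1, frame_rate=FRAME_RATE)
    bc = threshold_and_bootstrap(net, percentile=50, fp_rate=0.0,
                                 n_boot=10)
    for m, draws in bc.censuses.items():
        assert np.allclose(draws, bc.point[m])
        lo, hi = bc.ci(m)
        assert lo == pytest.approx(hi)


def test_threshold_errors_on_empty_or_sparse():
    net = InferredNetwork(np.zeros((5, 5)), 1, FRAME_RATE)
    with pytest.raises(ValueError):
        net.threshold(95)
    W = np.zeros((5, 5))
    W[0, 1] = W[1, 2] = 1.0
    with pytest.raises(ValueError):
        threshold_and_bootstrap(InferredNetwork(W, 1, FRAME_RATE), 10)


def test_planted_graph_recovered_above_chance():
    """End-to-end: generate calcium with a planted graph, detect events,
    infer, threshold at the planted density; precision must beat the
    planted density at least five-fold."""
    cfg = CalciumGenConfig(n_cells=80, duration_s=300.0,
                           graph_density=0.03, base_event_rate=0.08,
                           burst_lift=1.0, coupling=0.4,
                           amplitude_mu=0.5, amplitude_sigma=0.2,
                           noise_sigma=0.03)
    rec, truth, planted = generate_calcium(cfg, rng_seed=11)
    ev = detect_events(rec, snr_cutoff=1.05)
    assert ev.retention_fraction > 0.9    # clean generator settings
    net = infer_functional_weights(ev, rng_seed=0)
    thr = net.threshold(100 * (1 - cfg.graph_density))
    hits = np.count_nonzero((thr.weights > 0) & (planted.weights > 0))
    precision = hits / thr.n_edges
    assert precision > 5 * cfg.graph_density


def test_crosscorr_peak_at_imposed_lag():
    """Postsynaptic trace is the presynaptic product shifted by 5
    frames: the correlogram must peak at +0.25 s."""
    rng = np.random.default_rng(6)
    n_frames = 2000
    s = rng.normal(0, 1, n_frames)
    lag = 5
    post = np.roll(s ** 2, lag)
    rec = FluorescenceRecording(np.vstack([s, s, post]), FRAME_RATE)
    lags_s, cc = triplet_crosscorr(rec, [(0, 1, 2)], window_s=1.0)
    assert lags_s[np.argmax(cc)] == pytest.approx(lag / FRAME_RATE)
    assert cc.max() > 0.5


def test_crosscorr_flat_for_independent_traces():
    rng = np.random.default_rng(7)
    rec = FluorescenceRecording(rng.normal(0, 1, (3, 2000)), FRAME_RATE)
    _, cc = triplet_crosscorr(rec, [(0, 1, 2)], window_s=1.0)
    assert np.all(np.abs(cc) < 0.2)
    with pytest.raises(ValueError):
        triplet_crosscorr(rec, [])


def _spatial_net(n, edges, seed=0):
    # distinct weights so a low percentile keeps (almost) every edge
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for i, j in edges:
        W[i, j] = rng.uniform(0.5, 1.5)
    return InferredNetwork(W, 1, FRAME_RATE)


def test_spatial_coincident_cells_give_zero_distances():
    pos = np.zeros((10, 2))
    net = _spatial_net(10, [(i, (i + 1) % 10) for i in range(10)])
    rep = spatial_stats(pos, net, percentile=1, n_random=1000)
    assert rep.connected_median_um == 0.0
    assert rep.random_median_um == 0.0


def test_spatial_random_edges_indistinguishable_from_chance():
    rng = np.random.default_rng(8)
    n = 60
    pos = rng.uniform(0, 300, (n, 2))
    pairs = set()
    while len(pairs) < 150:
        i, j = rng.integers(0, n, 2)
        if i != j:
            pairs.add((int(i), int(j)))
    rep = spatial_stats(pos, _spatial_net(n, pairs), percentile=1,
                        n_random=5000, rng_seed=1)
    assert rep.pair_p_value > 0.01


def test_spatial_local_edges_are_shorter_than_chance():
    rng = np.random.default_rng(9)
    n = 60
    pos = rng.uniform(0, 300, (n, 2))
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    close = np.argwhere((d > 0) & (d < 60))
    edges = [tuple(e) for e in close[:150]]
    rep = spatial_stats(pos, _spatial_net(n, edges), percentile=1,
                        n_random=5000, rng_seed=1)
    assert rep.connected_median_um < rep.random_median_um
    assert rep.pair_p_value < 1e-4
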