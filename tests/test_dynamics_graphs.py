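"""Dynamics summary statistics and the generic digraph container."""

import numpy as np
import pytest

from recruitnet.dynamics import (EmptyRasterError, branching_coefficient,
                                 firing_rates, isi_cv2,
                                 mean_pairwise_correlation,
                                 participation, presyn_spike_counts,
                                 summarize_dynamics)
from recruitnet.graphs import (WeightedDigraph, from_networkx,
                               load_graphml)
from recruitnet.network import SynapticNetwork
from recruitnet.params import ConnectivityParams
from recruitnet.raster import SpikeRaster


def _raster(rows, n_trials=2, n_neurons=3, window=(0.0, 100.0)):
    tr, nr, tm = map(np.array, zip(*rows))
    return SpikeRaster(tr, nr, tm.astype(float), n_trials=n_trials,
                       n_neurons=n_neurons, record_window=window)


def test_firing_rates_exact():
    r = _raster([(0, 0, 10.0), (0, 0, 20.0), (1, 0, 30.0), (1, 1, 40.0)])
    rates = firing_rates(r)
    # 2 trials x 100 ms = 0.2 s of recording
    assert rates[0] == pytest.approx(15.0)
    assert rates[1] == pytest.approx(5.0)
    assert rates[2] == 0.0


def test_participation_per_epoch_and_overall():
    # epoch 0 = trials {0, 1}: neurons {0, 1}; epoch 1 = trial 2: {2}
    r = _raster([(0, 0, 10.0), (1, 1, 10.0), (2, 2, 10.0)], n_trials=4)
    per_epoch, overall = participation(r, trials_per_epoch=2)
    assert np.allclose(per_epoch, [2 / 3, 1 / 3])
    assert overall == pytest.approx(1.0)


def test_synchronous_neurons_are_perfectly_correlated():
    rows = [(0, j, t) for j in (0, 1) for t in (10.0, 30.0, 70.0)]
    r = _raster(rows, n_trials=1)
    assert mean_pairwise_correlation(r) == pytest.approx(1.0)


def test_disjoint_neurons_are_anticorrelated():
    rows = ([(0, 0, float(t)) for t in range(5, 50, 5)]
            + [(0, 1, float(t)) for t in range(55, 100, 5)])
    r = _raster(rows, n_trials=1)
    assert mean_pairwise_correlation(r) < 0.0


def test_isi_irregularity_regular_vs_poisson():
    regular = _raster([(0, 0, float(t)) for t in range(5, 100, 5)],
                      n_trials=1)
    assert isi_cv2(regular) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(0)
    times = np.cumsum(rng.exponential(5.0, 2000))
    times = times[times < 9999.0]
    poisson = _raster([(0, 0, t) for t in times], n_trials=1,
                      window=(0.0, 10000.0))
    assert isi_cv2(poisson) == pytest.approx(1.0, abs=0.1)


def test_branching_coefficient_doubling_and_steady():
    # counts per 10 ms bin: 1, 2, 4, 8 -> every ratio is 2
    rows = []
    k = 0
    for b, c in enumerate([1, 2, 4, 8]):
        for _ in range(c):
            rows.append((0, k % 3, b * 10.0 + 5.0 + 0.01 * k))
            k += 1
    assert branching_coefficient(_raster(rows, n_trials=1,
                                         window=(0.0, 40.0))) == 2.0
    steady = _raster([(0, 0, b * 10.0 + 5.0) for b in range(10)],
                     n_trials=1)
    assert branching_coefficient(steady) == 1.0


def test_presyn_spike_counts_hand_case():
    conn = ConnectivityParams(N_e=2, N_i=1, N_input=1)
    A = np.zeros((3, 3))
    A[0, 1] = 1.0                        # excitatory edge 0 -> 1
    net = SynapticNetwork(
        A, np.array(["excitatory", "excitatory", "inhibitory"],
                    dtype=object), conn)
    r = _raster([(0, 0, 10.0), (0, 1, 20.0), (0, 1, 50.0),
                 (1, 1, 20.0)], n_neurons=3)
    counts = presyn_spike_counts(net, r, window_ms=25.0)
    # spikes in raster order: (0,0,10): no presyn; (0,1,20): one spike of
    # neuron 0 within 10 ms; (0,1,50): neuron 0's spike 40 ms back, out
    # of window; (1,1,20): neuron 0 silent in trial 1
    assert list(counts) == [0, 1, 0, 0]


def test_empty_raster_statistics_raise():
    silent = SpikeRaster(np.empty(0, int), np.empty(0, int), np.empty(0),
                         n_trials=1, n_neurons=3,
                         record_window=(0.0, 100.0))
    for fn in (firing_rates, mean_pairwise_correlation, isi_cv2,
               branching_coefficient):
        with pytest.raises(EmptyRasterError):
            fn(silent)


def test_summarize_dynamics_fields_finite(small_sim):
    net, cfg, raster = small_sim
    s = summarize_dynamics(raster.subset_neurons(
        np.arange(net.n_excitatory)), cfg, net=net)
    assert 0 < s.firing_rate_mean < 100
    assert 0 < s.participation_overall <= 1
    assert s.participation_per_epoch <= s.participation_overall + 1e-12
    assert np.isfinite(s.isi_cv2) and np.isfinite(s.mean_pairwise_corr)
    assert s.branching_coeff_median > 0
    assert s.presyn_spikes_mean >= 0


def test_digraph_validation():
    with pytest.raises(ValueError):
        WeightedDigraph(np.zeros((2, 3)))
    with pytest.raises(ValueError):
        WeightedDigraph(-np.ones((2, 2)) + np.eye(2))
    with pytest.raises(ValueError):
        WeightedDigraph(np.ones((2, 2)))          # self-edges
    with pytest.raises(ValueError):
        WeightedDigraph(np.zeros((2, 2)), kind="mystery")
    with pytest.raises(ValueError):
        WeightedDigraph(2 * np.ones((2, 2)) - 2 * np.eye(2),
                        kind="functional")


def test_digraph_properties_and_subgraph():
    W = np.array([[0.0, 2.0, 0.0], [0.0, 0.0, 4.0], [0.0, 0.0, 0.0]])
    g = WeightedDigraph(W)
    assert g.n_edges == 2
    assert g.density == pytest.approx(2 / 6)
    assert np.array_equal(g.binary(), W > 0)
    assert np.allclose(g.symmetrized(), (W + W.T) / 2)
    sub = g.subgraph(np.array([1, 2]))
    assert sub.weights[0, 1] == 4.0
    assert list(sub.nodes) == [1, 2]


def test_graphml_and_networkx_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    W = np.where(rng.random((8, 8)) < 0.3, rng.random((8, 8)), 0.0)
    np.fill_diagonal(W, 0.0)
    g = WeightedDigraph(W, kind="functional")
    back = from_networkx(g.to_networkx(), kind="functional")
    assert np.allclose(back.weights, g.weights)
    path = tmp_path / "g.graphml"
    g.save_graphml(path)
    loaded = load_graphml(path, kind="functional")
    assert np.allclose(loaded.weights, g.weights)
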