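"""Pure-triplet enumeration and coincidence timing analyses."""

import numpy as np
import pytest

from recruitnet.graphs import WeightedDigraph
from recruitnet.mapping import functional_network, recruitment_network
from recruitnet.motif_timing import (TripletSet, coincidence_analysis,
                                     coincidence_rate_ratio,
                                     enumerate_pure_triplets,
                                     firing_rate_vs_clustering,
                                     sample_epoch_timing,
                                     shared_neighbor_comparison)
from recruitnet.network import SynapticNetwork, build_synaptic_network
from recruitnet.params import ConnectivityParams
from recruitnet.raster import SpikeRaster

from oracles import (all_digraphs, brute_force_coincidences,
                     brute_force_pure_triplets)


def _net_from_matrix(A):
    """Wrap an all-excitatory adjacency matrix as a SynapticNetwork."""
    n = A.shape[0]
    conn = ConnectivityParams(N_e=n, N_i=1, N_input=1)
    full = np.zeros((n + 1, n + 1))
    full[:n, :n] = A
    cls = np.array(["excitatory"] * n + ["inhibitory"], dtype=object)
    return SynapticNetwork(full, cls, conn)


def _as_tuples(ts: TripletSet):
    return sorted(zip(ts.a.tolist(), ts.b.tolist(), ts.post.tolist()))


def test_minimal_fan_in_triplet_found():
    A = np.zeros((3, 3))
    A[0, 2] = A[1, 2] = A[0, 1] = 1.0
    net = _net_from_matrix(A)
    fi = enumerate_pure_triplets(net, "fan-in")
    assert _as_tuples(fi) == [(0, 1, 2)]
    assert enumerate_pure_triplets(net, "convergence").n_triplets == 0


def test_extra_edge_disqualifies_triplet():
    A = np.zeros((3, 3))
    A[0, 2] = A[1, 2] = A[0, 1] = A[1, 0] = 1.0   # reciprocal presyn pair
    net = _net_from_matrix(A)
    assert enumerate_pure_triplets(net, "fan-in").n_triplets == 0


def test_enumeration_matches_brute_force_exhaustively_to_four_nodes():
    for n in (3, 4):
        for A in all_digraphs(n):
            net = _net_from_matrix(A)
            for cls in ("fan-in", "convergence"):
                got = _as_tuples(enumerate_pure_triplets(net, cls))
                assert got == brute_force_pure_triplets(A, cls), (A, cls)


def test_enumeration_matches_brute_force_random_graphs():
    rng = np.random.default_rng(0)
    for n, p in [(7, 0.3), (7, 0.6), (20, 0.2)]:
        A = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(A, 0.0)
        net = _net_from_matrix(A)
        for cls in ("fan-in", "convergence"):
            got = _as_tuples(enumerate_pure_triplets(net, cls))
            assert got == brute_force_pure_triplets(A, cls)


def test_er_count_matches_analytic_expectation():
    """Pure fan-in count in ER(n, p): n(n-1)(n-2) ordered triples times
    p^3 (1-p)^4."""
    n, p = 60, 0.1
    counts = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        A = (rng.random((n, n)) < p).astype(float)
        np.fill_diagonal(A, 0.0)
        counts.append(
            enumerate_pure_triplets(_net_from_matrix(A),
                                    "fan-in").n_triplets)
    expected = n * (n - 1) * (n - 2) * p ** 3 * (1 - p) ** 4
    mean = np.mean(counts)
    sem = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - expected) < 3 * max(sem, 1.0)


def _spikes(rows):
    tr, nr, tm = map(np.array, zip(*rows))
    return SpikeRaster(tr, nr, tm.astype(float), n_trials=2, n_neurons=4,
                       record_window=(0.0, 200.0))


def test_coincidence_detected_and_timed():
    """Post spike at 100; presyn a at 90, b at 96: one coincident epoch
    with interval t_b - t_a = 6 ms."""
    r = _spikes([(0, 0, 90.0), (0, 1, 96.0), (0, 2, 100.0)])
    ts = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    st = coincidence_analysis(r, ts, window=50.0)
    assert st.n_epochs == 1
    assert st.presyn_intervals[0] == pytest.approx(6.0)
    assert st.mean_abs_dt == pytest.approx(6.0)
    assert st.rate_per_triplet_per_trial == pytest.approx(0.5)


def test_presyn_outside_window_is_no_coincidence():
    r = _spikes([(0, 0, 60.0), (0, 1, 96.0), (0, 2, 100.0)])
    ts = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    assert coincidence_analysis(r, ts).n_epochs == 0


def test_nearest_presyn_spike_defines_timing():
    """With two a-spikes in the window, the one closest to the
    postsynaptic spike is used."""
    r = _spikes([(0, 0, 80.0), (0, 0, 95.0), (0, 1, 103.0),
                 (0, 2, 100.0)])
    ts = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    st = coincidence_analysis(r, ts)
    assert st.presyn_intervals[0] == pytest.approx(3.0 - (-5.0))


def test_coincidence_matches_brute_force(small_sim):
    net, cfg, raster = small_sim
    exc = raster.subset_neurons(np.arange(net.n_excitatory))
    fi = enumerate_pure_triplets(net, "fan-in").subsample(5, rng_seed=1)
    st = coincidence_analysis(exc, fi)
    times = {}
    for tr, nr, tm in zip(exc.trial, exc.neuron, exc.time):
        times.setdefault((int(tr), int(nr)), []).append(float(tm))
    total = 0
    for k in range(fi.n_triplets):
        trip = (int(fi.a[k]), int(fi.b[k]), int(fi.post[k]))
        total += len(brute_force_coincidences(times, trip, exc.n_trials))
    assert st.n_epochs == total


def test_coincidence_invariant_to_neuron_relabeling():
    rows = [(0, 0, 90.0), (0, 1, 96.0), (0, 2, 100.0), (1, 0, 20.0),
            (1, 1, 30.0), (1, 2, 41.0)]
    r = _spikes(rows)
    ts = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    st = coincidence_analysis(r, ts)
    # relabel neurons 0<->3 (3 is silent)
    relabeled = [(tr, {0: 3, 3: 0}.get(n, n), t) for tr, n, t in rows]
    r2 = _spikes(relabeled)
    ts2 = TripletSet(np.array([3]), np.array([1]), np.array([2]),
                     "fan-in")
    st2 = coincidence_analysis(r2, ts2)
    assert st.n_epochs == st2.n_epochs
    assert np.allclose(np.sort(st.presyn_intervals),
                       np.sort(st2.presyn_intervals))


def test_label_shuffled_intervals_are_symmetric():
    """If presynaptic labels carry no information, the t_b - t_a
    histogram is symmetric about zero."""
    rng = np.random.default_rng(3)
    rows = []
    for tr in range(2):
        for t_post in range(20, 200, 20):
            rows.append((tr, 2, float(t_post)))
            offs = rng.uniform(-20, 20, 2)
            rows.append((tr, 0, float(t_post + offs[0])))
            rows.append((tr, 1, float(t_post + offs[1])))
    r = SpikeRaster(*map(np.array, zip(*rows)), n_trials=2, n_neurons=4,
                    record_window=(0.0, 250.0))
    ts = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    st = coincidence_analysis(r, ts)
    assert st.n_epochs > 10
    assert abs(st.asymmetry()) < 0.5


def test_rate_ratio_and_sampling():
    r = _spikes([(0, 0, 90.0), (0, 1, 96.0), (0, 2, 100.0)])
    fi = TripletSet(np.array([0]), np.array([1]), np.array([2]), "fan-in")
    st = coincidence_analysis(r, fi)
    assert coincidence_rate_ratio(st, st) == pytest.approx(1.0)
    assert sample_epoch_timing(st, 5).size == 1
    with pytest.raises(ValueError):
        coincidence_analysis(r, TripletSet(np.empty(0, int),
                                           np.empty(0, int),
                                           np.empty(0, int), "fan-in"))


def test_firing_rate_vs_clustering_table():
    rates = np.array([1.0, 2.0, 3.0, 4.0])
    coefs = np.array([0.4, 0.3, 0.2, 0.1])
    tab = firing_rate_vs_clustering(rates, coefs, thresholds=(0, 50))
    assert list(tab["n_neurons"]) == [4, 2]
    # the top half by coefficient holds the two lowest rates
    assert tab["rate_median"].iloc[1] == pytest.approx(1.5)


def test_shared_neighbors_null_calibration(small_sim):
    """Random recruitment assignment: no shared-neighbor difference."""
    net, cfg, raster = small_sim
    rng = np.random.default_rng(0)
    A = net.excitatory_subgraph
    R = np.where(rng.random(A.shape) < 0.5, A > 0, False)
    rep = shared_neighbor_comparison(
        net, WeightedDigraph(R.astype(float), kind="recruitment",
                             nodes=np.arange(A.shape[0])),
        n_pairs=100, rng_seed=1)
    assert rep.p_value > 0.01
    assert rep.n_pairs == 100


def test_shared_neighbors_degenerate_partition(small_sim):
    net, cfg, raster = small_sim
    A = net.excitatory_subgraph
    with pytest.raises(ValueError):
        shared_neighbor_comparison(
            net, WeightedDigraph(np.minimum(A, 1.0), kind="recruitment"),
            n_pairs=10)
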