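"""Directed motif census, small-world scores, nulls and propensity."""

import itertools

import numpy as np
import pytest

from recruitnet.graph_stats import (DegenerateGraphError,
                                    characteristic_path,
                                    clustering_propensity,
                                    directed_clustering, generate_null,
                                    mean_local_clustering,
                                    small_world_scores,
                                    threshold_top_edges, transitivity)
from recruitnet.graphs import WeightedDigraph
from recruitnet.synthetic import toy_fixtures

from oracles import (all_digraphs, brute_force_census,
                     brute_force_clustering)


def _er(n, p, seed, weighted=False):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(float)
    if weighted:
        A *= rng.lognormal(0, 0.5, (n, n))
    np.fill_diagonal(A, 0.0)
    return WeightedDigraph(A)


def test_census_matches_brute_force_exhaustively_to_four_nodes():
    """Every simple digraph on up to 4 nodes: counts and coefficients
    equal the independent enumeration oracle exactly."""
    for n in (2, 3, 4):
        for A in all_digraphs(n):
            c = directed_clustering(WeightedDigraph(A), binary=True)
            bf = brute_force_census(A)
            for m in ("fan_in", "fan_out", "middleman", "cycle"):
                assert np.allclose(c.counts[m], bf["counts"][m]), (n, m, A)
                assert np.allclose(c.coefficients[m],
                                   bf["coefficients"][m]), (n, m, A)


def test_census_matches_brute_force_on_random_larger_graphs():
    for n, p, seed in [(7, 0.3, 0), (7, 0.6, 1), (7, 0.9, 2),
                       (20, 0.25, 3), (20, 0.5, 4)]:
        g = _er(n, p, seed)
        c = directed_clustering(g, binary=True)
        bf = brute_force_census(g.weights)
        for m in ("fan_in", "fan_out", "middleman", "cycle"):
            assert np.allclose(c.counts[m], bf["counts"][m])
            assert np.allclose(c.coefficients[m], bf["coefficients"][m])


def test_hand_enumerated_triangle_fixture():
    fx = toy_fixtures()
    c = directed_clustering(fx.graphs["single_triangle"], binary=True)
    for m, expected in fx.censuses["single_triangle"].items():
        assert np.allclose(c.counts[m], expected)
    c_empty = directed_clustering(fx.graphs["empty5"], binary=True)
    for m in ("fan_in", "fan_out", "middleman", "cycle"):
        assert np.all(c_empty.counts[m] == 0)


def test_census_totals_identities():
    """Each non-cyclic directed triangle appears once as a fan-in, once
    as a fan-out and once as a middleman (at its three corners); cycle
    totals are divisible by 3."""
    g = _er(30, 0.3, 9)
    c = directed_clustering(g, binary=True)
    assert c.total_count("fan_in") == c.total_count("fan_out")
    assert c.total_count("fan_in") == c.total_count("middleman")
    assert c.total_count("cycle") % 3 == 0


def test_binary_clustering_matches_oracle():
    for seed in (0, 1):
        g = _er(15, 0.3, seed)
        assert mean_local_clustering(g, binary=True) == pytest.approx(
            brute_force_clustering(g.weights))


def test_weighted_clustering_scale_invariant():
    g = _er(20, 0.3, 5, weighted=True)
    c1 = mean_local_clustering(g)
    c2 = mean_local_clustering(g.with_weights(g.weights * 7.3))
    assert c1 == pytest.approx(c2)


def test_characteristic_path_line_graph():
    """0 -> 1 -> 2: hop distances 1, 1, 2; only 3 of 6 pairs reachable."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 2] = 1.0
    L, unreach = characteristic_path(WeightedDigraph(W))
    assert L == pytest.approx(4.0 / 3.0)
    assert unreach == pytest.approx(0.5)
    # weighted costs: 1/w doubles when weights halve
    Lw, _ = characteristic_path(WeightedDigraph(W * 0.5), weighted=True)
    assert Lw == pytest.approx(2 * 4.0 / 3.0)


def test_null_preserves_density_and_weights():
    g = _er(40, 0.15, 6, weighted=True)
    for kind in ("erdos-renyi", "lattice"):
        null = generate_null(g, kind, 0)
        assert null.n_edges == g.n_edges
        assert np.allclose(np.sort(null.weight_multiset()),
                           np.sort(g.weight_multiset()))
        assert np.all(np.diag(null.weights) == 0)


def test_er_graph_self_normalizes_to_unity():
    """An ER graph scored against ER nulls: all three ratios near 1."""
    g = _er(300, 0.05, 7, weighted=True)
    rep = small_world_scores(g, n_null=8, rng_seed=1)
    assert rep.clustering_ratio == pytest.approx(1.0, abs=0.1)
    assert rep.path_ratio == pytest.approx(1.0, abs=0.05)
    assert rep.small_world_ratio == pytest.approx(1.0, abs=0.12)


def test_lattice_is_more_small_world_than_er():
    """A ring lattice has lattice-level clustering but long paths; its
    clustering ratio must far exceed 1."""
    g = _er(100, 0.08, 8)
    latt = generate_null(g, "lattice", 0)
    rep = small_world_scores(latt, n_null=5, rng_seed=2)
    assert rep.clustering_ratio > 2.0
    assert rep.path_ratio > 1.5


def test_propensity_anchors_zero_and_one():
    base = _er(120, 0.05, 10)
    er_score = clustering_propensity(base, motif="undirected", n_null=6,
                                     rng_seed=3)
    assert er_score.one_minus_deltaC == pytest.approx(0.0, abs=0.1)
    latt = generate_null(base, "lattice", 1)
    latt_score = clustering_propensity(latt, motif="undirected", n_null=6,
                                       rng_seed=4)
    assert latt_score.one_minus_deltaC == pytest.approx(1.0, abs=0.1)


def test_threshold_keeps_strongest_fraction():
    g = _er(50, 0.3, 11, weighted=True)
    thr = threshold_top_edges(g, 0.2)
    assert thr.n_edges == pytest.approx(0.2 * g.n_edges, rel=0.05)
    assert thr.weight_multiset().min() >= np.quantile(
        g.weight_multiset(), 0.8) - 1e-12


def test_degenerate_graphs_raise():
    with pytest.raises(DegenerateGraphError):
        small_world_scores(WeightedDigraph(np.zeros((5, 5))))
    with pytest.raises(DegenerateGraphError):
        characteristic_path(WeightedDigraph(np.zeros((4, 4))))


def test_transitivity_complete_graph():
    A = np.ones((5, 5)) - np.eye(5)
    assert transitivity(WeightedDigraph(A)) == pytest.approx(1.0)
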