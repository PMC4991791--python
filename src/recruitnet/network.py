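"""Construction and serialization of the random synaptic network.

Neurons are indexed 0..N_e-1 (excitatory) then N_e..N_e+N_i-1
(inhibitory).  The adjacency matrix ``A`` holds directed weights in
multiples of the leak conductance; ``A[i, j]`` is the weight of the
connection from presynaptic *i* onto postsynaptic *j*, zero meaning
absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ConnectivityParams


EXC = "excitatory"
INH = "inhibitory"


@dataclass
class SynapticNetwork:
    adjacency: np.ndarray            # (N, N) weights, row = presynaptic
    cell_class: np.ndarray           # (N,) strings, EXC or INH
    conn: ConnectivityParams

    def __post_init__(self) -> None:
        A = self.adjacency
        if A.shape[0] != A.shape[1] or A.shape[0] != self.cell_class.size:
            raise ValueError("adjacency and cell_class sizes disagree")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-edges are not allowed")
        if np.any(A < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_excitatory(self) -> int:
        return int(np.sum(self.cell_class == EXC))

    @property
    def excitatory_mask(self) -> np.ndarray:
        return self.cell_class == EXC

    @property
    def excitatory_subgraph(self) -> np.ndarray:
        """Weight matrix of the excitatory-to-excitatory subgraph."""
        m = self.excitatory_mask
        return self.adjacency[np.ix_(m, m)]

    def to_edge_list(self) -> list[tuple[int, int, float, str, str]]:
        src, tgt = np.nonzero(self.adjacency)
        return [
            (int(i), int(j), float(self.adjacency[i, j]),
             str(self.cell_class[i]), str(self.cell_class[j]))
            for i, j in zip(src, tgt)
        ]

    def save_edge_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight",
                             "source_class", "target_class"])
            writer.writerows(self.to_edge_list())

    def save_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for i, cls in enumerate(self.cell_class):
            g.add_node(int(i), cell_class=str(cls))
        for i, j, w, *_ in self.to_edge_list():
            g.add_edge(i, j, weight=w)
        nx.write_graphml(g, str(path))


def load_edge_csv(path: str | Path,
                  conn: ConnectivityParams | None = None) -> SynapticNetwork:
    """Read a network back from the edge-list CSV dialect."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((int(row["source"]), int(row["target"]),
                         float(row["weight"]), row["source_class"],
                         row["target_class"]))
    n = 1 + max(max(r[0] for r in rows), max(r[1] for r in rows))
    A = np.zeros((n, n))
    cls = np.array([EXC] * n, dtype=object)
    for i, j, w, ci, cj in rows:
        A[i, j] = w
        cls[i], cls[j] = ci, cj
    conn = conn or ConnectivityParams(N_e=int(np.sum(cls == EXC)),
                                      N_i=max(1, int(np.sum(cls == INH))))
    return SynapticNetwork(A, cls, conn)


def build_synaptic_network(conn: ConnectivityParams,
                           rng_seed: int) -> SynapticNetwork:
    """Draw a class-dependent Erdős-Rényi network with lognormal weights.

    Every ordered pair (i, j), i != j, is connected independently with
    the probability appropriate to the (class of i, class of j) pair.
    Present edges carry lognormal(mu, sigma) weights times the global
    ``weight_scale``; inhibitory-to-excitatory edges get an extra
    ``ie_scale`` multiplier.
    """
    rng = np.random.default_rng(rng_seed)
    N_e, N_i = conn.N_e, conn.N_i
    n = N_e + N_i
    cls = np.array([EXC] * N_e + [INH] * N_i, dtype=object)

    # p[source, target]; conn.p_xy is target <- source
    p = np.empty((n, n))
    e = slice(0, N_e)
    i = slice(N_e, n)
    p[e, e] = conn.p_ee      # E <- E
    p[i, e] = conn.p_ei      # E <- I  (row = inhibitory source)
    p[e, i] = conn.p_ie      # I <- E
    p[i, i] = conn.p_ii      # I <- I

    present = rng.random((n, n)) < p
    np.fill_diagonal(present, False)

    weights = rng.lognormal(conn.lognormal_mu, conn.lognormal_sigma,
                            size=(n, n))
    weights[i, e] *= conn.ie_scale
    A = np.where(present, weights * conn.weight_scale, 0.0)
    return SynapticNetwork(A, cls, conn)


def draw_input_projections(conn: ConnectivityParams,
                           rng: np.random.Generator) -> np.ndarray:
    """Weights from the Poisson input pool onto excitatory cells.

    Each of the ``N_input`` units projects onto each excitatory cell
    independently with probability ``p_input``; projection weights come
    from the same lognormal ensemble as recurrent excitatory synapses.
    Returns an (N_input, N_e) weight matrix.
    """
    present = rng.random((conn.N_input, conn.N_e)) < conn.p_input
    weights = rng.lognormal(conn.lognormal_mu, conn.lognormal_sigma,
                            size=(conn.N_input, conn.N_e))
    return np.where(present, weights * conn.weight_scale, 0.0)
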