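"""Generic weighted directed graph container.

One container serves every network kind in the pipeline — synaptic,
functional, active, recruitment, inferred, voltage-conditioned — with
``kind`` recording the semantics of the weights (synaptic conductance
multiples for structural graphs, conditional probabilities for
functional-family graphs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

KINDS = ("synaptic", "functional", "active", "recruitment", "inferred",
         "voltage-conditioned")


@dataclass
class WeightedDigraph:
    weights: np.ndarray                    # (n, n), row = source
    kind: str = "synaptic"
    nodes: np.ndarray | None = None        # original node labels

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-edges are not allowed")
        if self.kind not in KINDS:
            raise ValueError(f"unknown graph kind {self.kind!r}")
        if self.kind in ("functional", "recruitment") and np.any(W > 1):
            raise ValueError(f"{self.kind} weights are probabilities <= 1")
        self.weights = W
        if self.nodes is None:
            self.nodes = np.arange(W.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1)) if n > 1 else 0.0

    def binary(self) -> np.ndarray:
        return (self.weights > 0)

    def symmetrized(self) -> np.ndarray:
        """Undirected weight matrix, averaging reciprocal weights."""
        return (self.weights + self.weights.T) / 2.0

    def weight_multiset(self) -> np.ndarray:
        return self.weights[self.weights > 0]

    def with_weights(self, W: np.ndarray, kind: str | None = None
                     ) -> "WeightedDigraph":
        return WeightedDigraph(W, kind or self.kind, self.nodes)

    def subgraph(self, idx: np.ndarray) -> "WeightedDigraph":
        idx = np.asarray(idx)
        return WeightedDigraph(self.weights[np.ix_(idx, idx)], self.kind,
                               self.nodes[idx])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(kind=self.kind)
        g.add_nodes_from(int(v) for v in self.nodes)
        src, tgt = np.nonzero(self.weights)
        g.add_weighted_edges_from(
            (int(self.nodes[i]), int(self.nodes[j]),
             float(self.weights[i, j])) for i, j in zip(src, tgt))
        return g

    def save_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def save_edge_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            src, tgt = np.nonzero(self.weights)
            for i, j in zip(src, tgt):
                w.writerow([int(self.nodes[i]), int(self.nodes[j]),
                            float(self.weights[i, j])])


def from_networkx(g, kind: str = "synaptic") -> WeightedDigraph:
    import networkx as nx

    nodes = np.array(sorted(g.nodes()))
    index = {v: k for k, v in enumerate(nodes)}
    W = np.zeros((nodes.size, nodes.size))
    for u, v, data in g.edges(data=True):
        W[index[u], index[v]] = data.get("weight", 1.0)
    return WeightedDigraph(W, kind, nodes)


def load_graphml(path: str | Path, kind: str = "synaptic") -> WeightedDigraph:
    import networkx as nx

    g = nx.read_graphml(str(path))
    g = nx.relabel_nodes(g, {v: int(v) for v in g.nodes()})
    return from_networkx(nx.DiGraph(g), kind)
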