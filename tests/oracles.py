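"""Independent brute-force oracles for graph and triplet statistics.

These are deliberately naive O(n^3) implementations written from the
motif definitions alone, used only to validate the vectorized library
code.  They share no code with the library.
"""

from __future__ import annotations

import numpy as np


def brute_force_census(A: np.ndarray) -> dict:
    """Per-node directed triangle counts and coefficients by enumeration.

    For each reference node i, every ordered pair (j, k) of distinct
    other nodes is inspected:

    * fan-in:    j -> i, k -> i and j -> k
    * fan-out:   i -> j, i -> k and j -> k
    * middleman: j -> i, i -> k and j -> k
    * cycle:     i -> j, j -> k and k -> i

    Counting over ordered pairs makes a bidirectionally-connected
    presynaptic pair contribute twice to fan-in/fan-out, matching the
    convention that each direction of the closing edge is a distinct
    triangle.
    """
    A = (np.asarray(A) > 0)
    n = A.shape[0]
    counts = {m: np.zeros(n) for m in
              ("fan_in", "fan_out", "middleman", "cycle")}
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for k in range(n):
                if k == i or k == j:
                    continue
                if A[j, i] and A[k, i] and A[j, k]:
                    counts["fan_in"][i] += 1
                if A[i, j] and A[i, k] and A[j, k]:
                    counts["fan_out"][i] += 1
                if A[j, i] and A[i, k] and A[j, k]:
                    counts["middleman"][i] += 1
                if A[i, j] and A[j, k] and A[k, i]:
                    counts["cycle"][i] += 1
    d_in = A.sum(axis=0).astype(float)
    d_out = A.sum(axis=1).astype(float)
    d_bi = (A & A.T).sum(axis=1).astype(float)
    denoms = {"fan_in": d_in * (d_in - 1),
              "fan_out": d_out * (d_out - 1),
              "middleman": d_in * d_out - d_bi,
              "cycle": d_in * d_out - d_bi}
    coefs = {}
    for m, c in counts.items():
        d = denoms[m]
        coefs[m] = np.divide(c, d, out=np.zeros_like(c), where=d > 0)
    return {"counts": counts, "coefficients": coefs}


def brute_force_pure_triplets(A: np.ndarray, motif_class: str):
    """All pure triplets by checking every ordered node triple.

    fan-in: exactly the edges a->t, b->t, a->b among the three nodes;
    convergence: exactly a->t, b->t (with a < b).  Returns a sorted list
    of (a, b, t) tuples.
    """
    A = (np.asarray(A) > 0)
    n = A.shape[0]
    out = []
    for a in range(n):
        for b in range(n):
            if b == a:
                continue
            for t in range(n):
                if t == a or t == b:
                    continue
                base = (A[a, t] and A[b, t] and not A[t, a]
                        and not A[t, b] and not A[b, a])
                if not base:
                    continue
                if motif_class == "fan-in" and A[a, b]:
                    out.append((a, b, t))
                elif motif_class == "convergence" and not A[a, b] and a < b:
                    out.append((a, b, t))
    return sorted(out)


def brute_force_coincidences(spike_times: dict, triplet, n_trials: int,
                             window: float = 50.0):
    """Coincident epochs for one triplet by direct scanning.

    ``spike_times`` maps (trial, neuron) to a sorted list of times.
    Returns a list of (postsyn time, nearest a offset, nearest b offset)
    per coincident epoch.
    """
    a, b, t = triplet
    half = window / 2.0
    epochs = []
    for tr in range(n_trials):
        for ts in spike_times.get((tr, t), []):
            offs = []
            for nrn in (a, b):
                cand = [x - ts for x in spike_times.get((tr, nrn), [])
                        if -half <= x - ts < half]
                if not cand:
                    offs = None
                    break
                offs.append(min(cand, key=abs))
            if offs is not None:
                epochs.append((ts, offs[0], offs[1]))
    return epochs


def brute_force_clustering(A: np.ndarray) -> float:
    """Mean binary local clustering on the symmetrized graph."""
    A = (np.asarray(A) > 0)
    S = A | A.T
    n = A.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if S[i, j] and j != i]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for x in nb for y in nb if x != y and S[x, y])
        vals.append(links / (k * (k - 1)))
    return float(np.mean(vals))


def all_digraphs(n: int):
    """Yield every simple digraph adjacency matrix on n nodes."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for code in range(1 << len(pairs)):
        A = np.zeros((n, n))
        for bit, (i, j) in enumerate(pairs):
            if code >> bit & 1:
                A[i, j] = 1.0
        yield A
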