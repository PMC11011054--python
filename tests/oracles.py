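"""Independent reference computations used as test oracles.

Everything here is deliberately brute force (enumeration, direct sums,
explicit loops) and independent of the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def all_typed_partitions(graph):
    """Every partition of the graph's nodes that never mixes node types."""
    groups = [list(np.flatnonzero(graph.node_type == t)) for t in range(graph.n_types)]
    groups = [g for g in groups if g]
    for combo in itertools.product(*(set_partitions(g) for g in groups)):
        b = np.zeros(graph.n_nodes, dtype=int)
        nxt = 0
        for part in combo:
            for blk in part:
                for v in blk:
                    b[v] = nxt
                nxt += 1
        yield b


def entropy(labels) -> float:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_info_direct(a, b) -> float:
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    mi = 0.0
    for av in np.unique(a):
        for bv in np.unique(b):
            nij = np.sum((a == av) & (b == bv))
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((np.sum(a == av) / n) * (np.sum(b == bv) / n)))
    return mi


def nmi_direct(a, b) -> float:
    ha, hb = entropy(a), entropy(b)
    if ha == 0 or hb == 0:
        return 0.0
    return mutual_info_direct(a, b) / ((ha + hb) / 2)


def nmi_null_exhaustive(pred, true) -> float:
    """Exact NMI* by averaging over every permutation of the samples."""
    pred = list(pred)
    vals = [nmi_direct(list(p), true) for p in itertools.permutations(pred)]
    return float(np.mean(vals))


def hypergeom_tail_bruteforce(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by summing the exact pmf; pmf from binomial coefficients."""
    total = math.comb(N, n)
    s = 0
    for j in range(k, min(K, n) + 1):
        s += math.comb(K, j) * math.comb(N - K, n - j)
    return s / total


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-element urn."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def adaptive_n_reference(pc_cluster: np.ndarray, n_start: float = 3.0, step: float = 0.05):
    """Reference loop for the adaptive topic-assignment threshold.

    Returns (n, list of topic-index sets) or None if infeasible down to 0.
    """
    mu = pc_cluster.mean(axis=1)
    sigma = pc_cluster.std(axis=1)
    k = 0
    while True:
        n = round(n_start * 100 - k * round(step * 100)) / 100
        if n < 0:
            return None
        sets = [
            frozenset(np.flatnonzero(row > mu[i] + n * sigma[i]))
            for i, row in enumerate(pc_cluster)
        ]
        if all(len(s) for s in sets) and len(set(sets)) == len(sets):
            return n, sets
        k += 1
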