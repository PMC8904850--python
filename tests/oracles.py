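"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: sequence enumeration
for the slow-propagation order statistics, the rank-correlation formula
evaluated literally, networkx shortest paths for effective distances, and
exhaustive subset search for the resection optimizer.
"""

from itertools import combinations

import numpy as np


def enumerate_slow_orders(weights: np.ndarray, seed_pos) -> np.ndarray:
    """Exact expected activation step per node for single-node-per-step spreading.

    Enumerates every infection sequence with its probability (each step picks
    a susceptible node with probability proportional to its total weight to
    the infected set).  Exponential in n; use only for n <= ~7.
    """
    n = weights.shape[0]
    exp_step = np.zeros(n)

    def recurse(infected: frozenset, step: int, prob: float) -> None:
        pressure = {
            j: sum(weights[i, j] for i in infected)
            for j in range(n)
            if j not in infected
        }
        total = sum(p for p in pressure.values() if p > 0)
        if total <= 0:
            return
        for j, pj in pressure.items():
            if pj <= 0:
                continue
            pr = prob * pj / total
            exp_step[j] += pr * step
            recurse(infected | {j}, step + 1, pr)

    recurse(frozenset(int(s) for s in seed_pos), 1, 1.0)
    return exp_step


def rank_correlation_literal(a, b) -> float:
    """Eq.-style rank correlation: cov / (sigma * sigma), population moments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return cov / (a.std() * b.std())


def effective_distance_networkx(weights: np.ndarray, seed_pos) -> np.ndarray:
    """Multi-source shortest path on the d = 1 - ln(P) graph via networkx."""
    import networkx as nx

    n = weights.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    s = weights.sum(axis=1)
    for i in range(n):
        if s[i] <= 0:
            continue
        for j in range(n):
            if weights[i, j] > 0:
                g.add_edge(i, j, weight=1.0 - np.log(weights[i, j] / s[i]))
    dist = np.full(n, np.inf)
    for src in seed_pos:
        lengths = nx.single_source_dijkstra_path_length(g, int(src), weight="weight")
        for node, d in lengths.items():
            dist[node] = min(dist[node], d)
    dist[list(seed_pos)] = 0.0
    return dist


def exhaustive_best_subsets(objective, pool, size: int):
    """All size-``size`` subsets of ``pool`` ranked by ``objective`` (desc)."""
    scored = [(tuple(sorted(c)), objective(c)) for c in combinations(pool, size)]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored
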