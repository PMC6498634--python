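"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — alternating-scaling IPF, exhaustive
shortest-path enumeration, textbook IRLS, the rank-sum AUROC formula — and
shares no code with the implementation it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def alternating_ipf(X: np.ndarray, target: float = 1.0, tol: float = 1e-12,
                    max_iter: int = 200_000) -> np.ndarray:
    """Classic IPF: scale rows to the target, then columns, until both sets
    of marginals converge."""
    A = np.array(X, dtype=float)
    active = A.sum(axis=1) > 0
    for _ in range(max_iter):
        r = A.sum(axis=1)
        s = np.where(active, target / np.where(r > 0, r, 1.0), 1.0)
        A = A * s[:, None]
        c = A.sum(axis=0)
        s = np.where(active, target / np.where(c > 0, c, 1.0), 1.0)
        A = A * s[None, :]
        dev = max(np.abs(A.sum(axis=1)[active] - target).max(),
                  np.abs(A.sum(axis=0)[active] - target).max())
        if dev < tol:
            break
    return A


def brute_force_centralities(adjacency: dict) -> dict:
    """Exhaustive unweighted betweenness/closeness by enumerating every
    shortest path between every node pair.

    ``adjacency``: node -> set of neighbours. Returns
    {node: (degree, closeness, betweenness)} with closeness
    (n_reachable − 1)/Σd on the node's component and betweenness the sum over
    pairs of the fraction of shortest paths through the node.
    """
    nodes = sorted(adjacency)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS over the predecessor structure
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adjacency[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])

        extend([s])
        return [p for p in paths if p[-1] == t]

    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        reach = len(dist) - 1
        total = sum(dist.values())
        closeness[s] = reach / total if total > 0 else 0.0
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)
    return {v: (len(adjacency[v]), closeness[v], betweenness[v]) for v in nodes}


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 200) -> np.ndarray:
    """Textbook iteratively reweighted least squares for logistic MLE."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.abs(beta_new - beta).max() < tol:
            return beta_new
        beta = beta_new
    return beta


def rank_auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUROC by direct pair comparison (ties count one half)."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
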