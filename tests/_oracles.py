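"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, closed forms, third-party solvers) so they share no code with
the implementations they check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def random_signed_graph(rng, p, edge_prob=0.5, wmin=0.2, wmax=0.8, connected=False):
    """Random symmetric signed weight matrix; optionally resample until connected."""
    while True:
        W = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < edge_prob:
                    w = rng.uniform(wmin, wmax) * (1 if rng.random() < 0.5 else -1)
                    W[i, j] = W[j, i] = w
        if not connected:
            return W
        # BFS on support
        A = np.abs(W) > 0
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in np.flatnonzero(A[v]):
                if u not in seen:
                    seen.add(int(u))
                    frontier.append(int(u))
        if len(seen) == p:
            return W


def brute_shortest_paths(W):
    """Floyd-Warshall on 1/|w| lengths."""
    p = W.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] != 0:
                D[i, j] = 1.0 / abs(W[i, j])
    for k in range(p):
        for i in range(p):
            for j in range(p):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _all_paths(W, s, t):
    """Every simple path s -> t with its 1/|w| length."""
    p = W.shape[0]
    others = [v for v in range(p) if v not in (s, t)]
    out = []
    if W[s, t] != 0:
        out.append(([s, t], 1.0 / abs(W[s, t])))
    for r in range(1, len(others) + 1):
        for mid in permutations(others, r):
            path = [s, *mid, t]
            length = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if W[a, b] == 0:
                    ok = False
                    break
                length += 1.0 / abs(W[a, b])
            if ok:
                out.append((path, length))
    return out


def brute_betweenness(W, tol=1e-12):
    """Enumerate all shortest paths; fractional credit to interior nodes."""
    p = W.shape[0]
    b = np.zeros(p)
    for s, t in combinations(range(p), 2):
        paths = _all_paths(W, s, t)
        if not paths:
            continue
        dmin = min(length for _, length in paths)
        shortest = [pa for pa, length in paths if length <= dmin + tol]
        for pa in shortest:
            for v in pa[1:-1]:
                b[v] += 1.0 / len(shortest)
    return b


def brute_closeness(W):
    D = brute_shortest_paths(W)
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        finite = [D[i, j] for j in range(p) if j != i and np.isfinite(D[i, j])]
        if finite:
            out[i] = 1.0 / sum(finite)
    return out


def brute_balance(W):
    """Exhaustive signed triangle census: (n_triangles, n_balanced)."""
    p = W.shape[0]
    n_tri = n_bal = 0
    for i, j, k in combinations(range(p), 3):
        if W[i, j] != 0 and W[j, k] != 0 and W[i, k] != 0:
            n_tri += 1
            if np.sign(W[i, j]) * np.sign(W[j, k]) * np.sign(W[i, k]) > 0:
                n_bal += 1
    return n_tri, n_bal


def brute_transitivity(W):
    p = W.shape[0]
    A = (np.abs(W) > 0).astype(int)
    closed = triples = 0
    for i, j, k in combinations(range(p), 3):
        links = A[i, j] + A[j, k] + A[i, k]
        if links == 3:
            closed += 1
            triples += 3
        elif links == 2:
            triples += 1
    return 3.0 * closed / triples if triples else 0.0


def sklearn_glasso(R, lam, tol=1e-10, max_iter=2000):
    """Third-party LARS-based graphical lasso as an external oracle."""
    from sklearn.covariance import graphical_lasso

    _, K = graphical_lasso(np.asarray(R), alpha=float(lam), tol=tol,
                           max_iter=max_iter, mode="lars")
    return K


def edge_f1(W_est, W_true, eps=1e-12):
    te = np.triu(np.abs(W_true) > eps, 1)
    ee = np.triu(np.abs(W_est) > eps, 1)
    tp = int((te & ee).sum())
    fp = int((~te & ee).sum())
    fn = int((te & ~ee).sum())
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
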