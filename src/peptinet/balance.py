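"""Structural balance: signed triangle census.

A triangle is balanced iff the product of its three edge signs is positive
(all-positive, or exactly two negative edges).  Global structural balance is
the fraction of balanced triangles among all closed triangles on the sparse
edge support; high balance suggests a stable signed configuration, and the
unbalanced triangles are the candidate points of structural tension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import EDGE_EPS, MultilayerNetwork, SignedNetwork


@dataclass
class Triangle:
    nodes: tuple[str, str, str]
    signs: tuple[int, int, int]      # signs of edges (ij, jk, ik)
    weights: tuple[float, float, float]
    balanced: bool


@dataclass
class BalanceResult:
    n_triangles: int
    n_balanced: int
    balance_fraction: float | None   # None when there are no triangles
    unbalanced: list[Triangle] = field(default_factory=list)


def _base(net) -> SignedNetwork:
    return net.network if isinstance(net, MultilayerNetwork) else net


def is_balanced(sign_a: float, sign_b: float, sign_c: float) -> bool:
    """Product-of-signs rule; raises on a zero sign (absent edge)."""
    prod = np.sign(sign_a) * np.sign(sign_b) * np.sign(sign_c)
    if prod == 0:
        raise ValueError("a triangle cannot contain an absent (zero-sign) edge")
    return bool(prod > 0)


def enumerate_triangles(net) -> list[tuple[int, int, int]]:
    """Index triples whose three pairwise edges are all present."""
    W = _base(net).W
    A = np.abs(W) > EDGE_EPS
    np.fill_diagonal(A, False)
    p = A.shape[0]
    nbr = [np.flatnonzero(A[i]) for i in range(p)]
    out: list[tuple[int, int, int]] = []
    for i in range(p):
        ni = nbr[i]
        ni = ni[ni > i]
        for j in ni:
            common = np.intersect1d(ni, nbr[j], assume_unique=False)
            for k in common[common > j]:
                out.append((i, int(j), int(k)))
    return out


def _label(net, triple: tuple[int, int, int]) -> Triangle:
    base = _base(net)
    W = base.W
    i, j, k = triple
    ws = (float(W[i, j]), float(W[j, k]), float(W[i, k]))
    signs = tuple(int(np.sign(w)) for w in ws)
    return Triangle(
        nodes=(base.node_ids[i], base.node_ids[j], base.node_ids[k]),
        signs=signs,  # type: ignore[arg-type]
        weights=ws,
        balanced=is_balanced(*ws),
    )


def global_balance(net) -> BalanceResult:
    """Fraction of balanced triangles; keeps the unbalanced list for inspection."""
    triples = enumerate_triangles(net)
    if not triples:
        warnings.warn("network has no closed triangles; balance undefined")
        return BalanceResult(0, 0, None, [])
    labeled = [_label(net, t) for t in triples]
    unbalanced = [t for t in labeled if not t.balanced]
    n_bal = len(labeled) - len(unbalanced)
    return BalanceResult(
        n_triangles=len(labeled),
        n_balanced=n_bal,
        balance_fraction=n_bal / len(labeled),
        unbalanced=unbalanced,
    )


def triangles_containing(net, node_ids: Iterable[str]) -> list[Triangle]:
    """Labeled triangles touching at least one of the named nodes."""
    base = _base(net)
    wanted = set(node_ids)
    unknown = wanted - set(base.node_ids)
    if unknown:
        raise KeyError(f"unknown node ids: {sorted(unknown)}")
    idx_wanted = {i for i, n in enumerate(base.nodes) if n.node_id in wanted}
    return [
        _label(net, t) for t in enumerate_triangles(net) if idx_wanted.intersection(t)
    ]


def balance_report(result: BalanceResult) -> dict:
    return {
        "n_triangles": result.n_triangles,
        "n_balanced": result.n_balanced,
        "balance_fraction": result.balance_fraction,
        "unbalanced_triangles": [
            {"nodes": list(t.nodes), "signs": list(t.signs), "weights": list(t.weights)}
            for t in result.unbalanced
        ],
    }
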