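"""Node- and network-level topology of signed weighted networks.

Distances follow the usual psychometric-network convention: edge length is
the reciprocal of the absolute partial correlation, so strong conditional
dependencies are short paths.  Strength sums absolute weights; expected
influence keeps the signs and is the one-step signed analogue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import EDGE_EPS, MultilayerNetwork, SignedNetwork


def _base(net: MultilayerNetwork | SignedNetwork) -> SignedNetwork:
    return net.network if isinstance(net, MultilayerNetwork) else net


def strength(net) -> np.ndarray:
    """Sum of absolute edge weights per node."""
    return np.abs(_base(net).W).sum(axis=1)


def expected_influence(net) -> np.ndarray:
    """Signed one-step influence: sum of raw edge weights per node."""
    return _base(net).W.sum(axis=1)


def _length_matrix(W: np.ndarray) -> csr_matrix:
    A = np.abs(W).copy()
    A[A <= EDGE_EPS] = 0.0
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, 0.0)
    return csr_matrix(L)


def shortest_path_lengths(net) -> np.ndarray:
    """All-pairs Dijkstra distances on 1/|w| edge lengths (inf if unreachable)."""
    W = _base(net).W
    return dijkstra(_length_matrix(W), directed=False)


def closeness(net) -> np.ndarray:
    """c_i = 1 / sum of distances to the other nodes of i's component.

    Nodes in singleton components get 0.
    """
    W = _base(net).W
    D = shortest_path_lengths(net)
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        finite = np.isfinite(D[i]) & (np.arange(p) != i)
        if finite.any():
            out[i] = 1.0 / D[i, finite].sum()
    return out


def betweenness(net) -> np.ndarray:
    """Brandes betweenness on 1/|w| lengths; unordered pairs counted once."""
    import networkx as nx

    base = _base(net)
    W = base.W
    G = nx.Graph()
    G.add_nodes_from(range(base.p))
    ii, jj = np.nonzero(np.triu(np.abs(W) > EDGE_EPS, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(int(i), int(j), length=1.0 / abs(W[i, j]))
    b = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([b[i] for i in range(base.p)])


def identify_hubs(betweenness_vector: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Indices with betweenness above mean + k * sample SD (empty if SD = 0)."""
    b = np.asarray(betweenness_vector, dtype=float)
    if b.size < 3:
        raise ValueError("hub identification needs at least 3 nodes")
    sd = b.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(b > b.mean() + k * sd)


def global_connectivity(net) -> float:
    """Sum of absolute edge weights, each unordered pair once."""
    W = _base(net).W
    return float(np.abs(np.triu(W, k=1)).sum())


def interlayer_connectivity(net: MultilayerNetwork, layer_a: str, layer_b: str) -> float:
    """Sum of |w| over edges with one endpoint in each named layer.

    With layer_a == layer_b this is the intra-layer connectivity.
    """
    base = net.network
    layers = np.array([n.layer for n in base.nodes])
    for lay in (layer_a, layer_b):
        if lay not in layers:
            raise KeyError(f"layer {lay!r} has no nodes in this network")
    in_a = layers == layer_a
    in_b = layers == layer_b
    A = np.abs(np.triu(base.W, k=1))
    if layer_a == layer_b:
        return float(A[np.ix_(in_a, in_a)].sum())
    return float(A[np.ix_(in_a, in_b)].sum() + A[np.ix_(in_b, in_a)].sum())


def connectivity_by_layer_pair(net: MultilayerNetwork) -> dict[tuple[str, str], float]:
    """Connectivity for every unordered layer pair (including intra-layer)."""
    present = sorted({n.layer for n in net.network.nodes})
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(present):
        for b in present[i:]:
            out[(a, b)] = interlayer_connectivity(net, a, b)
    return out


def diameter(net, convention: str = "inverse_weight") -> float:
    """Largest finite shortest-path distance.

    convention="inverse_weight" uses 1/|w| lengths; "hops" counts unweighted
    steps on the edge support.
    """
    W = _base(net).W
    if convention == "inverse_weight":
        D = shortest_path_lengths(net)
    elif convention == "hops":
        A = (np.abs(W) > EDGE_EPS).astype(float)
        D = dijkstra(csr_matrix(A), directed=False, unweighted=True)
    else:
        raise ValueError(f"unknown length convention {convention!r}")
    finite = D[np.isfinite(D)]
    return float(finite.max()) if finite.size else 0.0


def centrality_table(net) -> pd.DataFrame:
    """Per-node strength, closeness, betweenness, expected influence, z-scores, hub flag."""
    base = _base(net)
    s = strength(net)
    c = closeness(net)
    b = betweenness(net)
    ei = expected_influence(net)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    hubs = set(identify_hubs(b)) if base.p >= 3 else set()
    return pd.DataFrame(
        {
            "node_id": base.node_ids,
            "layer": [n.layer for n in base.nodes],
            "strength": s,
            "closeness": c,
            "betweenness": b,
            "expected_influence": ei,
            "strength_z": z(s),
            "closeness_z": z(c),
            "betweenness_z": z(b),
            "expected_influence_z": z(ei),
            "hub": [i in hubs for i in range(base.p)],
        }
    )


def topology_summary(
    net: MultilayerNetwork,
    n_boot: int = 500,
    seed: int = 0,
    run_powerlaw: bool = True,
) -> dict:
    """Global connectivity, per-layer-pair connectivity, diameters, scale-free test."""
    from .powerlaw import powerlaw_ks_test

    out = {
        "global_connectivity": global_connectivity(net),
        "interlayer_connectivity": {
            f"{a}|{b}": v for (a, b), v in connectivity_by_layer_pair(net).items()
        },
        "diameter_inverse_weight": diameter(net, "inverse_weight"),
        "diameter_hops": diameter(net, "hops"),
    }
    if run_powerlaw:
        s = strength(net)
        s = s[s > 0]
        if s.size >= 10 and np.unique(s).size > 1:
            fit = powerlaw_ks_test(s, n_boot=n_boot, seed=seed)
            out.update(
                powerlaw_alpha=fit.alpha, ks_statistic=fit.ks_stat, ks_pvalue=fit.p_value
            )
    return out
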