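"""Signed community detection and module-level summaries.

Modules are found by simulated-annealing spinglass optimization of the
signed Reichardt-Bornholdt Hamiltonian, which rewards dense positive and
penalizes negative within-module connectivity against configuration-model
null expectations:

    H(sigma) = - sum_{i<j} [ w+_ij - g+ p+_ij ] delta(sigma_i, sigma_j)
               + sum_{i<j} [ w-_ij - g- p-_ij ] delta(sigma_i, sigma_j)

with w+/w- the positive/negative weight magnitudes, p+-_ij = s_i s_j / 2m
their configuration-model expectations and g+- resolution parameters.  The
optimization itself is delegated to igraph's negative-weight spinglass
implementation; this module seeds it, runs restarts, and scores partitions.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy import stats

from .core import EDGE_EPS, MultilayerNetwork, SignedNetwork

log = logging.getLogger(__name__)


@dataclass
class PartitionResult:
    assignment: dict[str, int]          # node_id -> module_id (1..K)
    K: int
    modularity: float                   # signed (Gomez) modularity
    modularity_positive: float          # Newman modularity of the positive part
    transitivity: float
    hamiltonian: float
    seed: int
    n_restarts: int
    restart_energies: list[float] = field(default_factory=list)

    def labels(self, node_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in node_ids])


def _base(net) -> SignedNetwork:
    return net.network if isinstance(net, MultilayerNetwork) else net


def _split_parts(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Wp = np.where(W > EDGE_EPS, W, 0.0)
    Wn = np.where(W < -EDGE_EPS, -W, 0.0)
    return Wp, Wn


def spinglass_hamiltonian(
    net, assignment: dict[str, int], gamma_pos: float = 1.0, gamma_neg: float = 1.0
) -> float:
    """Signed Reichardt-Bornholdt energy of a partition (lower is better)."""
    base = _base(net)
    W = base.W
    Wp, Wn = _split_parts(W)
    labels = np.array([assignment[n] for n in base.node_ids])
    same = labels[:, None] == labels[None, :]
    H = 0.0
    for part, g, sign in ((Wp, gamma_pos, -1.0), (Wn, gamma_neg, +1.0)):
        m2 = part.sum()  # = 2m
        if m2 <= 0:
            continue
        s = part.sum(axis=1)
        null = np.outer(s, s) / m2
        contrib = (part - g * null)[same].sum() - np.trace(part - g * null)
        H += sign * contrib / 2.0
    return float(H)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K by descending size, ties by smallest node index."""
    uniq = {}
    for lab in labels:
        uniq.setdefault(lab, [0, len(labels)])
    for idx, lab in enumerate(labels):
        uniq[lab][0] += 1
        uniq[lab][1] = min(uniq[lab][1], idx)
    order = sorted(uniq, key=lambda l: (-uniq[l][0], uniq[l][1]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def spinglass_partition(
    net,
    n_spins: int = 25,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
    seed: int = 0,
    n_restarts: int = 20,
) -> PartitionResult:
    """Best-of-restarts signed spinglass partition; deterministic given seed.

    The optimizer requires a connected graph: detection runs on the largest
    connected component of the edge support and every remaining component
    becomes its own module.
    """
    base = _base(net)
    W = base.W
    p = base.p
    if p < 3:
        raise ValueError("community detection needs at least 3 nodes")
    ii, jj = np.nonzero(np.triu(np.abs(W) > EDGE_EPS, k=1))
    if ii.size == 0:
        raise ValueError("network has no edges; nothing to partition")
    g = igraph.Graph(p, list(zip(ii.tolist(), jj.tolist())))
    weights = W[ii, jj].tolist()

    comps = g.connected_components()
    giant_idx = max(range(len(comps)), key=lambda k: len(comps[k]))
    giant_nodes = comps[giant_idx]
    # rebuild the component subgraph explicitly to keep edge/weight order aligned
    gmap = {v: k for k, v in enumerate(giant_nodes)}
    sub_edges, sub_w = [], []
    for (a, b), w in zip(zip(ii.tolist(), jj.tolist()), weights):
        if a in gmap and b in gmap:
            sub_edges.append((gmap[a], gmap[b]))
            sub_w.append(w)
    sub = igraph.Graph(len(giant_nodes), sub_edges)

    rng = random.Random(seed)
    best_energy = np.inf
    best_membership: list[int] | None = None
    energies: list[float] = []
    for _ in range(max(1, n_restarts)):
        random.seed(rng.randrange(2**31 - 1))  # igraph draws from Python's random
        cl = sub.community_spinglass(
            weights=sub_w,
            spins=min(n_spins, len(giant_nodes)),
            implementation="negative",
            gamma=gamma_pos,
            lambda_=gamma_neg,
        )
        membership = list(cl.membership)
        trial = {base.node_ids[v]: membership[gmap[v]] + 1 for v in giant_nodes}
        # complete the assignment for off-giant nodes so energy is comparable
        nxt = max(membership) + 2
        for k in range(len(comps)):
            if k == giant_idx:
                continue
            for v in comps[k]:
                trial[base.node_ids[v]] = nxt
            nxt += 1
        e = spinglass_hamiltonian(net, trial, gamma_pos, gamma_neg)
        energies.append(e)
        if e < best_energy:
            best_energy = e
            best_membership = [trial[n] for n in base.node_ids]
    assert best_membership is not None
    labels = _canonicalize(np.array(best_membership))
    assignment = {nid: int(l) for nid, l in zip(base.node_ids, labels)}
    Q_signed = signed_modularity(net, assignment)
    Wp, _ = _split_parts(W)
    Q_pos = _newman_modularity(Wp, labels) if Wp.sum() > 0 else 0.0
    return PartitionResult(
        assignment=assignment,
        K=int(labels.max()),
        modularity=Q_signed,
        modularity_positive=Q_pos,
        transitivity=transitivity(net),
        hamiltonian=best_energy,
        seed=seed,
        n_restarts=n_restarts,
        restart_energies=energies,
    )


def _newman_modularity(Wpart: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a nonnegative weight matrix."""
    m2 = Wpart.sum()
    if m2 <= 0:
        raise ValueError("no edges in this weight part")
    s = Wpart.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((Wpart - np.outer(s, s) / m2)[same]).sum() / m2)


def signed_modularity(net, assignment: dict[str, int]) -> float:
    """Gomez signed modularity: positive-part Q minus negative-part Q, weighted.

    Q = (2m+ / (2m+ + 2m-)) Q+  -  (2m- / (2m+ + 2m-)) Q-.
    """
    base = _base(net)
    missing = [n for n in base.node_ids if n not in assignment]
    if missing:
        raise ValueError(f"assignment is missing nodes: {missing[:5]}")
    labels = np.array([assignment[n] for n in base.node_ids])
    Wp, Wn = _split_parts(base.W)
    m2p, m2n = Wp.sum(), Wn.sum()
    if m2p + m2n <= 0:
        raise ValueError("network has no edges")
    Qp = _newman_modularity(Wp, labels) if m2p > 0 else 0.0
    Qn = _newman_modularity(Wn, labels) if m2n > 0 else 0.0
    return float(m2p / (m2p + m2n) * Qp - m2n / (m2p + m2n) * Qn)


def transitivity(net) -> float:
    """Global clustering coefficient on the unweighted edge support.

    3 * (closed triangles) / (connected triples); 0 with a warning when the
    network has no connected triples.
    """
    A = (np.abs(_base(net).W) > EDGE_EPS).astype(float)
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    triples = float((deg * (deg - 1)).sum() / 2.0)
    if triples == 0:
        warnings.warn("network has no connected triples; transitivity undefined, returning 0")
        return 0.0
    closed = float(np.trace(A @ A @ A) / 6.0)
    return 3.0 * closed / triples


def structural_equivalence(net, threshold: float = 0.95) -> list[tuple[str, str, float]]:
    """Node pairs whose edge-weight profiles to all third nodes correlate >= threshold."""
    base = _base(net)
    W = base.W
    p = base.p
    out: list[tuple[str, str, float]] = []
    for i in range(p):
        for j in range(i + 1, p):
            mask = np.ones(p, dtype=bool)
            mask[[i, j]] = False
            a, b = W[i, mask], W[j, mask]
            if a.std() == 0 or b.std() == 0:
                r = 1.0 if np.allclose(a, b) else 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            if r >= threshold:
                out.append((base.node_ids[i], base.node_ids[j], r))
    return out


def module_attribute_anova(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float, dict]:
    """One-way fixed-effects ANOVA of a per-node statistic across group labels.

    Groups with fewer than 2 members are dropped with a warning.  Returns
    (F, p, per-group means).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    buckets: dict = {}
    for v, gr in zip(values, groups):
        buckets.setdefault(gr, []).append(v)
    kept = {gr: np.array(v) for gr, v in buckets.items() if len(v) >= 2}
    dropped = sorted(set(buckets) - set(kept), key=str)
    if dropped:
        warnings.warn(f"dropping groups with < 2 members: {dropped}")
    if len(kept) < 2:
        raise ValueError("ANOVA needs at least 2 groups with >= 2 members each")
    F, pval = stats.f_oneway(*kept.values())
    means = {gr: float(v.mean()) for gr, v in kept.items()}
    return float(F), float(pval), means


def module_composition(net, attribute: str) -> pd.DataFrame:
    """Cross-tabulation of module membership x a node annotation."""
    base = _base(net)
    rows = [
        {"module": n.module_id, attribute: getattr(n, attribute) or "unknown"}
        for n in base.nodes
        if n.module_id is not None
    ]
    if not rows:
        raise ValueError("no nodes carry module assignments")
    df = pd.DataFrame(rows)
    return pd.crosstab(df["module"], df[attribute])


def apply_partition(net, result: PartitionResult) -> None:
    """Write module ids from a partition onto the node metadata in place."""
    for n in _base(net).nodes:
        n.module_id = result.assignment[n.node_id]
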