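"""Shared domain types for signed partial-correlation networks.

A network here is an undirected, weighted, signed graph whose edge weights
are partial correlations estimated from a Gaussian graphical model.  Nodes
carry biological metadata (layer membership, cell type, subcellular
localization, functional annotation) so that downstream stages can slice
the network by layer and summarize modules by annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Canonical layer names, in display order.
LAYERS = (
    "synaptic_peptide",
    "ppi_complex",
    "pathological_peptide",
    "cellular_pathology",
)

FUNCTION_TAGS = ("secretion", "trafficking", "other")
LOCALIZATIONS = ("cytosol", "plasma_membrane", "vesicle_membrane", "other")

#: Weights with absolute value at or below this are treated as absent edges.
EDGE_EPS = 1e-12


@dataclass
class NodeMeta:
    """Metadata for a single network node (one measured variable)."""

    node_id: str
    label: str
    layer: str
    function_tag: str | None = None
    cell_type: str | None = None
    localization: str | None = None
    module_id: int | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(
                f"unknown layer {self.layer!r} for node {self.node_id!r}; "
                f"expected one of {LAYERS}"
            )
        if self.module_id is not None and self.module_id < 1:
            raise ValueError(f"module_id must be a positive integer, got {self.module_id}")


@dataclass
class SignedNetwork:
    """Symmetric signed weighted network of partial correlations.

    ``W`` is a p x p matrix with zero diagonal; ``W[i, j]`` is the partial
    correlation between variables i and j given all others.  ``n_samples``
    records the effective sample size used at estimation time.
    """

    nodes: list[NodeMeta]
    W: np.ndarray
    n_samples: int = 0
    layout: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(
            nodes=[replace(n) for n in self.nodes],
            W=self.W.copy(),
            n_samples=self.n_samples,
            layout=dict(self.layout) if self.layout else None,
        )


@dataclass
class MultilayerNetwork:
    """A signed network whose nodes are partitioned into layers."""

    network: SignedNetwork

    @property
    def layer_of(self) -> dict[str, str]:
        return {n.node_id: n.layer for n in self.network.nodes}

    @property
    def layer_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for n in self.network.nodes:
            sizes[n.layer] = sizes.get(n.layer, 0) + 1
        return sizes


@dataclass
class SubjectTable:
    """Subject-by-variable measurements plus per-subject covariates.

    ``X`` columns are node ids; ``covariates`` is indexed like ``X`` and may
    hold age_at_death, sex, education, activity_counts, cognition_z and
    tangle_density.
    """

    X: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.X) == 0:
            raise ValueError("SubjectTable requires at least one subject")


@dataclass
class GGMFit:
    """A graphical-lasso regularization path with EBIC model selection."""

    lambda_grid: np.ndarray
    precisions: list[np.ndarray]
    ebic_values: np.ndarray
    selected_index: int
    gamma: float
    sample_correlation: np.ndarray
    n_effective: int

    @property
    def selected_precision(self) -> np.ndarray:
        return self.precisions[self.selected_index]

    @property
    def selected_lambda(self) -> float:
        return float(self.lambda_grid[self.selected_index])

    def path_summary(self) -> pd.DataFrame:
        """Per-lambda edge counts and EBIC values."""
        n_edges = [
            int(np.count_nonzero(np.triu(np.abs(t) > EDGE_EPS, k=1)))
            for t in self.precisions
        ]
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "n_edges": n_edges, "ebic": self.ebic_values}
        )


# ---------------------------------------------------------------------------
# validation / extraction

def validate_network(net: SignedNetwork) -> list[str]:
    """Check SignedNetwork invariants; returns one message per violation.

    Never raises: an empty list means the network is valid.
    """
    violations: list[str] = []
    W = net.W
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        violations.append(f"W is not square: shape {W.shape}")
        return violations
    if W.shape[0] != len(net.nodes):
        violations.append(
            f"matrix size {W.shape[0]} != number of nodes {len(net.nodes)}"
        )
    ids = [n.node_id for n in net.nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        violations.append(f"duplicate node ids: {dupes}")
    asym = np.argwhere(np.abs(W - W.T) > 1e-12)
    for i, j in asym:
        if i < j:
            violations.append(f"asymmetry at ({i},{j})")
    for i in np.flatnonzero(np.abs(np.diag(W)) > 1e-12):
        violations.append(f"nonzero diagonal at {i}")
    over = np.argwhere(np.abs(W) > 1 + 1e-12)
    for i, j in over:
        if i <= j:
            violations.append(f"|weight| > 1 at ({i},{j}): {W[i, j]:.6f}")
    if not np.all(np.isfinite(W)):
        violations.append("non-finite entries in W")
    return violations


def subnetwork(net: MultilayerNetwork | SignedNetwork, keep: Iterable[str]) -> SignedNetwork:
    """Extract the induced subnetwork on ``keep`` (weights copied, not re-estimated)."""
    base = net.network if isinstance(net, MultilayerNetwork) else net
    keep = list(keep)
    known = set(base.node_ids)
    for nid in keep:
        if nid not in known:
            raise KeyError(f"unknown node id {nid!r}")
    keep_set = set(keep)
    idx = [i for i, n in enumerate(base.nodes) if n.node_id in keep_set]
    nodes = [replace(base.nodes[i]) for i in idx]
    W = base.W[np.ix_(idx, idx)].copy()
    layout = None
    if base.layout:
        layout = {n.node_id: base.layout[n.node_id] for n in nodes if n.node_id in base.layout}
    return SignedNetwork(nodes=nodes, W=W, n_samples=base.n_samples, layout=layout)


@dataclass(frozen=True)
class Edge:
    i: str
    j: str
    weight: float
    kind: str  # "intra" or "inter"


def edge_list(net: MultilayerNetwork | SignedNetwork) -> list[Edge]:
    """All edges (|weight| > EDGE_EPS), each unordered pair once, tagged intra/inter.

    For a plain SignedNetwork the tag still reflects the node layers.
    """
    base = net.network if isinstance(net, MultilayerNetwork) else net
    W = base.W
    edges: list[Edge] = []
    ii, jj = np.nonzero(np.triu(np.abs(W) > EDGE_EPS, k=1))
    for i, j in zip(ii, jj):
        a, b = base.nodes[i], base.nodes[j]
        kind = "intra" if a.layer == b.layer else "inter"
        edges.append(Edge(a.node_id, b.node_id, float(W[i, j]), kind))
    return edges


# ---------------------------------------------------------------------------
# serialization

def to_networkx(net: MultilayerNetwork | SignedNetwork) -> nx.Graph:
    base = net.network if isinstance(net, MultilayerNetwork) else net
    G = nx.Graph()
    for n in base.nodes:
        attrs = {"label": n.label, "layer": n.layer}
        if n.module_id is not None:
            attrs["module"] = int(n.module_id)
        if base.layout and n.node_id in base.layout:
            attrs["x"], attrs["y"] = map(float, base.layout[n.node_id])
        G.add_node(n.node_id, **attrs)
    for e in edge_list(base):
        G.add_edge(e.i, e.j, weight=e.weight, kind=e.kind)
    return G


def write_graphml(net: MultilayerNetwork | SignedNetwork, path: str) -> None:
    nx.write_graphml(to_networkx(net), path)


def write_edge_csv(net: MultilayerNetwork | SignedNetwork, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "weight", "type"])
        for e in edge_list(net):
            w.writerow([e.i, e.j, f"{e.weight:.10g}", e.kind])


def read_node_meta(path: str) -> list[NodeMeta]:
    """Read node metadata TSV (node_id, label, layer, function_tag, cell_type, localization)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"node_id", "label", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"node metadata file missing columns: {sorted(missing)}")
    nodes = []
    for _, row in df.iterrows():
        nodes.append(
            NodeMeta(
                node_id=row["node_id"],
                label=row["label"] or row["node_id"],
                layer=row["layer"],
                function_tag=row.get("function_tag") or None,
                cell_type=row.get("cell_type") or None,
                localization=row.get("localization") or None,
            )
        )
    return nodes


def write_node_meta(nodes: Sequence[NodeMeta], path: str) -> None:
    rows = [
        {
            "node_id": n.node_id,
            "label": n.label,
            "layer": n.layer,
            "function_tag": n.function_tag or "",
            "cell_type": n.cell_type or "",
            "localization": n.localization or "",
        }
        for n in nodes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_network(
    nodes: Sequence[NodeMeta],
    W: np.ndarray,
    n_samples: int = 0,
    layout: Mapping[str, tuple[float, float]] | None = None,
) -> MultilayerNetwork:
    """Assemble and validate a MultilayerNetwork from metadata and weights."""
    net = SignedNetwork(
        nodes=list(nodes), W=np.asarray(W, float), n_samples=n_samples,
        layout=dict(layout) if layout else None,
    )
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(problems))
    return MultilayerNetwork(network=net)
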