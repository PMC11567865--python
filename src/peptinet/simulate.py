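"""Synthetic multilayer datasets with known ground truth.

The generator emulates the structure of a post mortem cohort dataset: a
four-layer variable set (48 synaptic peptides, 4 protein-protein
interaction measures, 14 pathological peptides, 5 cellular-pathology
densities; 71 variables), two activity-defined subject groups of 220, a
sparse signed conditional-dependence structure with synaptic modules and a
hub, non-normal monotone marginals, MCAR missingness, one group-specific
negative synaptic-to-p-tau edge, and phenotypes (cognition, tangle burden)
with planted linear and three-way interaction effects.

Ground truth is expressed as a target partial-correlation matrix W.  The
precision matrix realizing it is obtained by the fixed-point iteration
theta_ii = 1 + sum_j |theta_ij|, theta_ij = -w_ij sqrt(theta_ii theta_jj),
which converges whenever each row of |W| sums below 1 and yields a strictly
diagonally dominant (hence SPD) precision whose implied partial
correlations equal the designed ones essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import LAYERS, NodeMeta, SubjectTable

SYN, PPI, PATH, CELL = LAYERS


@dataclass
class PhenotypeSpec:
    """Planted regression effects; coefficient values mirror the magnitudes
    reported for the real cohort so recovery tests run at realistic signal."""

    cognition_weights: dict[int, float] = field(default_factory=lambda: {2: 1.7, 1: 0.5})
    cognition_sd: float = 1.0
    beta_ptau1: float = 1.08
    beta_ptau2: float = -0.97
    beta_module: float = -1.11
    beta_activity: float = -0.1
    beta3_ptau1: float = 0.65      # three-way ptau1 x module x activity
    beta3_ptau2: float = 0.0
    tangle_sd: float = 8.0
    activity_mean: float = 1.94    # daily actigraphy counts (x10^5), lognormal
    activity_sd: float = 1.14


@dataclass
class SyntheticConfig:
    n_per_group: int = 220
    layer_sizes: dict[str, int] = field(
        default_factory=lambda: {SYN: 48, PPI: 4, PATH: 14, CELL: 5}
    )
    # synaptic modules: (size, chord probability, ring weight range).
    # Each module is wired as a strong ring (every member two strong edges)
    # plus weaker chords: partial-correlation rows must stay below 1 in
    # absolute sum, so concentrating strength in few edges per node is what
    # keeps the planted structure both valid and detectable.
    module_spec: list[tuple[int, float, tuple[float, float]]] = field(
        default_factory=lambda: [
            (14, 0.08, (0.30, 0.42)),
            (10, 0.10, (0.30, 0.42)),
            (8, 0.12, (0.30, 0.42)),
            (7, 0.15, (0.30, 0.42)),
            (5, 0.20, (0.30, 0.42)),
            (4, 0.25, (0.30, 0.42)),
        ]
    )
    chord_weight_factor: float = 0.4   # chord weight = factor x ring draw
    n_negative_between: int = 10
    negative_between_range: tuple[float, float] = (0.08, 0.15)
    # per-layer block structure for the non-synaptic layers (same wiring rule)
    other_layer_specs: dict[str, list[tuple[int, float, tuple[float, float]]]] = field(
        default_factory=lambda: {
            PPI: [(4, 0.25, (0.25, 0.40))],
            PATH: [(8, 0.12, (0.25, 0.40)), (6, 0.15, (0.25, 0.40))],
            CELL: [(5, 0.20, (0.25, 0.40))],
        }
    )
    hub_degree: int = 7
    hub_weight_range: tuple[float, float] = (0.10, 0.14)
    # (layer_a, layer_b, count, sign, weight range)
    interlayer_edges: list[tuple[str, str, int, int, tuple[float, float]]] = field(
        default_factory=lambda: [
            (SYN, PPI, 6, +1, (0.08, 0.15)),
            (SYN, PATH, 3, -1, (0.08, 0.15)),
            (PATH, CELL, 4, +1, (0.12, 0.25)),
            (PPI, PATH, 2, -1, (0.05, 0.10)),
        ]
    )
    # (node_a, node_b, partial correlation) present in the LOW-activity group only
    group_unique_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("syn_25", "pp_02", -0.4)]
    )
    # marginal distortions: column -> "identity" | "exp" | "cube"
    marginal_transforms: dict[str, str] = field(default_factory=dict)
    n_exp_columns: int = 8
    n_cube_columns: int = 4
    missing_rate: float = 0.05
    max_row_partial_sum: float = 0.85
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    seed: int = 0

    # designated special nodes
    ptau1_node: str = "pp_01"
    ptau2_node: str = "pp_02"


def _node_ids(config: SyntheticConfig) -> dict[str, list[str]]:
    sizes = config.layer_sizes
    return {
        SYN: [f"syn_{i + 1:02d}" for i in range(sizes[SYN])],
        PPI: [f"ppi_{i + 1}" for i in range(sizes[PPI])],
        PATH: [f"pp_{i + 1:02d}" for i in range(sizes[PATH])],
        CELL: [f"cp_{i + 1}" for i in range(sizes[CELL])],
    }


def make_node_meta(config: SyntheticConfig) -> tuple[list[NodeMeta], dict[str, int]]:
    """Node metadata plus the planted synaptic module assignment.

    Annotation pattern mirrors the biology the generator emulates: the two
    largest synaptic modules are neuronal secretion machinery (module 1
    cytosolic, module 2 membrane-bound), later modules mix trafficking and
    other functions across cell types.
    """
    ids = _node_ids(config)
    meta: list[NodeMeta] = []
    modules: dict[str, int] = {}
    pos = 0
    func_by_module = {1: "secretion", 2: "secretion", 3: "trafficking",
                      4: "trafficking", 5: "other", 6: "other"}
    loc_by_module = {1: "cytosol", 2: "plasma_membrane", 3: "vesicle_membrane",
                     4: "cytosol", 5: "other", 6: "other"}
    for m, (size, _, _) in enumerate(config.module_spec, start=1):
        for _ in range(size):
            nid = ids[SYN][pos]
            modules[nid] = m
            meta.append(
                NodeMeta(
                    node_id=nid,
                    label=f"synaptic peptide {pos + 1} (synthetic)",
                    layer=SYN,
                    function_tag=func_by_module.get(m, "other"),
                    cell_type="neuron" if m <= 2 else ("astrocyte" if m == 5 else "mixed"),
                    localization=loc_by_module.get(m, "other"),
                )
            )
            pos += 1
    if pos != len(ids[SYN]):
        raise ValueError(
            f"module sizes sum to {pos}, but the synaptic layer has {len(ids[SYN])} nodes"
        )
    for nid in ids[PPI]:
        meta.append(NodeMeta(nid, f"SNARE interaction {nid[-1]} (synthetic)", PPI,
                             function_tag="secretion"))
    for k, nid in enumerate(ids[PATH]):
        label = {0: "p-tau proline-rich A (synthetic)", 1: "p-tau proline-rich B (synthetic)",
                 2: "p-tau MTBD (synthetic)"}.get(k, f"pathological peptide {k + 1} (synthetic)")
        meta.append(NodeMeta(nid, label, PATH))
    for k, nid in enumerate(ids[CELL]):
        label = ["diffuse plaques", "neuritic plaques", "tangles (silver)",
                 "tangle density (immuno)", "amyloid load"][k % 5]
        meta.append(NodeMeta(nid, f"{label} (synthetic)", CELL))
    return meta, modules


def _cap_rows(W: np.ndarray, max_row: np.ndarray | float, iters: int = 20) -> np.ndarray:
    """Scale edges so each row's absolute sum stays below its limit (signs kept)."""
    W = W.copy()
    limit = np.broadcast_to(np.asarray(max_row, dtype=float), (W.shape[0],))
    for _ in range(iters):
        rows = np.abs(W).sum(axis=1)
        if np.all(rows <= limit + 1e-12):
            break
        scale = np.minimum(1.0, limit / np.maximum(rows, 1e-12))
        S = np.minimum.outer(scale, scale)
        W = W * S
    return W


def _theta_from_partials(W_target: np.ndarray, iters: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Precision matrix whose implied partial correlations equal W_target."""
    p = W_target.shape[0]
    d = np.ones(p)
    for _ in range(iters):
        denom = np.sqrt(np.outer(d, d))
        off = -W_target * denom
        d_new = 1.0 + np.abs(off).sum(axis=1)
        if np.max(np.abs(d_new - d)) < tol:
            d = d_new
            break
        d = d_new
    Theta = -W_target * np.sqrt(np.outer(d, d))
    Theta[np.diag_indices(p)] = d
    # strict diagonal dominance => SPD; verify anyway
    np.linalg.cholesky(Theta)
    return Theta


def _available_pairs(idx_a, idx_b, used: set) -> list[tuple[int, int]]:
    return [
        (a, b) for a in idx_a for b in idx_b
        if a != b and (min(a, b), max(a, b)) not in used
    ]


def build_precision(
    config: SyntheticConfig, include_group_edges: bool = False
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Assemble the ground-truth precision / partial-correlation matrices.

    With ``include_group_edges`` the group-specific edges (the low-activity
    group's extra negative synaptic-to-p-tau connection) are added.
    Returns (Theta, W_true, metadata).
    """
    rng = np.random.default_rng(config.seed)
    meta, modules = make_node_meta(config)
    ids = [m.node_id for m in meta]
    index = {nid: k for k, nid in enumerate(ids)}
    p = len(ids)
    W = np.zeros((p, p))
    used: set[tuple[int, int]] = set()

    def add_edge(i: int, j: int, w: float) -> None:
        key = (min(i, j), max(i, j))
        if key in used:
            return
        used.add(key)
        W[i, j] = W[j, i] = w

    def fill_module(members: list[int], chord_prob: float, wrange, sign: int = +1) -> None:
        # strong ring backbone (chain for < 3 members), weaker chords
        if len(members) >= 3:
            cycle = list(zip(members, members[1:] + [members[0]]))
        else:
            cycle = list(zip(members[:-1], members[1:]))
        for a, b in cycle:
            add_edge(a, b, sign * rng.uniform(*wrange))
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = members[ai], members[bi]
                if (a, b) in used or rng.random() >= chord_prob:
                    continue
                add_edge(a, b, sign * config.chord_weight_factor * rng.uniform(*wrange))

    # synaptic modules; the first node of module 1 is reserved as the hub
    # (kept off the ring so its row budget goes to cross-module spokes)
    module_members: dict[int, list[int]] = {}
    pos = 0
    hub = 0 if (config.hub_degree > 0 and config.module_spec) else -1
    for m, (size, chord_prob, wrange) in enumerate(config.module_spec, start=1):
        members = list(range(pos, pos + size))
        module_members[m] = members
        ring = [v for v in members if v != hub]
        fill_module(ring, chord_prob, wrange)
        pos += size

    # sparse negative between-module edges within the synaptic layer, placed
    # among the large modules so the hub (below) stays the broker for the rest
    mod_ids = list(module_members)[: max(2, len(module_members) // 2)]
    placed = 0
    attempts = 0
    while placed < config.n_negative_between and attempts < 1000:
        attempts += 1
        ma, mb = rng.choice(mod_ids, size=2, replace=False)
        a = int(rng.choice(module_members[ma]))
        b = int(rng.choice(module_members[mb]))
        if (min(a, b), max(a, b)) in used:
            continue
        add_edge(a, b, -rng.uniform(*config.negative_between_range))
        placed += 1

    # hub spokes: one to each module in round-robin, so the small modules
    # (which get no negative bridges) reach the rest through the hub
    if hub >= 0:
        avail = sum(
            len([v for v in mem if v != hub]) for mem in module_members.values()
        )
        want = min(config.hub_degree, avail)
        targets = []
        k = 0
        while len(targets) < want:
            for m in module_members:
                mem = [v for v in module_members[m] if v != hub]
                if k < len(mem):
                    targets.append(mem[k])
                if len(targets) >= want:
                    break
            k += 1
        for t in targets:
            if (min(hub, t), max(hub, t)) not in used:
                add_edge(hub, t, rng.uniform(*config.hub_weight_range))

    # non-synaptic intra-layer blocks
    layer_index = {lay: [index[n] for n in nids] for lay, nids in _node_ids(config).items()}
    for lay, specs in config.other_layer_specs.items():
        start = 0
        nodes_lay = layer_index[lay]
        for size, chord_prob, wrange in specs:
            members = nodes_lay[start:start + size]
            if len(members) >= 2:
                fill_module(members, chord_prob, wrange)
            start += size

    # inter-layer edges
    for lay_a, lay_b, count, sign, wrange in config.interlayer_edges:
        pairs = _available_pairs(layer_index[lay_a], layer_index[lay_b], used)
        if count > len(pairs):
            raise ValueError(
                f"requested {count} edges between {lay_a} and {lay_b}, "
                f"only {len(pairs)} pairs available"
            )
        chosen = rng.choice(len(pairs), size=count, replace=False)
        for c in chosen:
            a, b = pairs[int(c)]
            add_edge(a, b, sign * rng.uniform(*wrange))

    # cap rows with budget reserved for the group-unique edges, then add those
    # edges afterwards so their planted magnitudes survive exactly
    limits = np.full(p, config.max_row_partial_sum)
    group_pairs = []
    for na, nb, w in config.group_unique_edges:
        i, j = index[na], index[nb]
        group_pairs.append((na, nb, w))
        limits[i] -= abs(w)
        limits[j] -= abs(w)
        W[i, j] = W[j, i] = 0.0
    if np.any(limits <= 0):
        raise ValueError("group-unique edge weights exceed the per-row partial budget")
    W = _cap_rows(W, limits)
    if include_group_edges:
        for na, nb, w in config.group_unique_edges:
            i, j = index[na], index[nb]
            W[i, j] = W[j, i] = w
    Theta = _theta_from_partials(W)
    W_true = W  # fixed point realizes the target partials exactly
    metadata = {
        "node_meta": meta,
        "node_ids": ids,
        "modules": modules,
        "hub_nodes": [ids[hub]] if hub >= 0 else [],
        "group_unique_edges": group_pairs,
        "layer_index": layer_index,
        "ptau1": config.ptau1_node,
        "ptau2": config.ptau2_node,
    }
    return Theta, W_true, metadata


def _default_transforms(config: SyntheticConfig, ids: list[str], rng) -> dict[str, str]:
    if config.marginal_transforms:
        return dict(config.marginal_transforms)
    picks = rng.choice(len(ids), size=config.n_exp_columns + config.n_cube_columns,
                       replace=False)
    tf = {ids[int(k)]: "exp" for k in picks[: config.n_exp_columns]}
    tf.update({ids[int(k)]: "cube" for k in picks[config.n_exp_columns:]})
    return tf


def _apply_transform(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "identity":
        return z
    if kind == "exp":
        return np.exp(z)
    if kind == "cube":
        return z ** 3
    raise ValueError(f"unknown marginal transform {kind!r}")


def sample_latent(Theta: np.ndarray, n: int, rng) -> np.ndarray:
    """n multivariate normal draws with covariance Theta^{-1}."""
    Sigma = np.linalg.inv(Theta)
    L = np.linalg.cholesky((Sigma + Sigma.T) / 2.0)
    return rng.standard_normal((n, Theta.shape[0])) @ L.T


def sample_group(
    Theta: np.ndarray,
    n: int,
    node_ids: list[str],
    marginal_transforms: dict[str, str] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SubjectTable:
    """Draw a group's observed table: Gaussian copula sample with monotone
    marginal distortions and MCAR missingness."""
    rng = np.random.default_rng(seed)
    Z = sample_latent(Theta, n, rng)
    X = Z.copy()
    tf = marginal_transforms or {}
    for c, nid in enumerate(node_ids):
        X[:, c] = _apply_transform(X[:, c], tf.get(nid, "identity"))
    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        X[mask] = np.nan
    df = pd.DataFrame(X, columns=node_ids)
    return SubjectTable(X=df)


@dataclass
class StudyTruth:
    """Everything the generator planted, for recovery checks."""

    Theta_high: np.ndarray
    Theta_low: np.ndarray
    W_high: np.ndarray
    W_low: np.ndarray
    modules: dict[str, int]
    hub_nodes: list[str]
    group_unique_edges: list[tuple[str, str, float]]
    phenotype: PhenotypeSpec
    node_meta: list[NodeMeta]
    seed: int


def generate_study(config: SyntheticConfig) -> tuple[SubjectTable, SubjectTable, StudyTruth]:
    """Generate the full two-group study: measurements, covariates, phenotypes.

    Activity counts are lognormal (moments matched to the cohort's mean 1.94,
    SD 1.14 daily counts); subjects above the sample median form the
    high-activity group.  The low-activity group's precision matrix carries
    the group-unique edges.  Cognition is a weighted sum of module means
    plus noise; tangle burden follows the planted linear-plus-three-way
    model on the latent (undistorted) scale.
    """
    rng = np.random.default_rng(config.seed)
    Theta_h, W_h, meta = build_precision(config, include_group_edges=False)
    Theta_l, W_l, _ = build_precision(config, include_group_edges=True)
    ids = meta["node_ids"]
    n = config.n_per_group
    ph = config.phenotype

    # lognormal activity with matched moments
    cv2 = (ph.activity_sd / ph.activity_mean) ** 2
    sig = np.sqrt(np.log1p(cv2))
    mu = np.log(ph.activity_mean) - sig**2 / 2
    activity = rng.lognormal(mean=mu, sigma=sig, size=2 * n)
    order = np.argsort(activity)
    low_idx, high_idx = order[:n], order[n:]

    tf = _default_transforms(config, ids, rng)

    def build_group(Theta: np.ndarray, act: np.ndarray, seed: int) -> SubjectTable:
        grng = np.random.default_rng(seed)
        Z = sample_latent(Theta, len(act), grng)
        Zs = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        mod_mean = {
            m: Zs[:, [ids.index(nid) for nid, mm in meta["modules"].items() if mm == m]].mean(axis=1)
            for m in sorted(set(meta["modules"].values()))
        }
        cognition = sum(
            w * mod_mean[m] for m, w in ph.cognition_weights.items()
        ) + grng.normal(0, ph.cognition_sd, len(act))
        p1 = Zs[:, ids.index(config.ptau1_node)]
        p2 = Zs[:, ids.index(config.ptau2_node)]
        mod2 = mod_mean[2]
        act_c = act - activity.mean()
        tangles = (
            ph.beta_ptau1 * p1
            + ph.beta_ptau2 * p2
            + ph.beta_module * mod2
            + ph.beta_activity * act_c
            + ph.beta3_ptau1 * p1 * mod2 * act_c
            + ph.beta3_ptau2 * p2 * mod2 * act_c
            + grng.normal(0, ph.tangle_sd, len(act))
        )
        X = Z.copy()
        for c, nid in enumerate(ids):
            X[:, c] = _apply_transform(X[:, c], tf.get(nid, "identity"))
        if config.missing_rate > 0:
            mask = grng.random(X.shape) < config.missing_rate
            X[mask] = np.nan
        cov = pd.DataFrame(
            {
                "age_at_death": grng.normal(90.0, 6.2, len(act)).clip(65, 110),
                "sex": grng.binomial(1, 0.27, len(act)).astype(float),
                "education": grng.normal(14.6, 2.8, len(act)).clip(5, 30),
                "activity_counts": act,
                "cognition_z": cognition,
                "tangle_density": tangles,
            }
        )
        return SubjectTable(X=pd.DataFrame(X, columns=ids), covariates=cov)

    sub_seed = int(rng.integers(2**31 - 1))
    high = build_group(Theta_h, activity[high_idx], sub_seed)
    low = build_group(Theta_l, activity[low_idx], sub_seed + 1)
    truth = StudyTruth(
        Theta_high=Theta_h,
        Theta_low=Theta_l,
        W_high=W_h,
        W_low=W_l,
        modules=meta["modules"],
        hub_nodes=meta["hub_nodes"],
        group_unique_edges=meta["group_unique_edges"],
        phenotype=ph,
        node_meta=[replace(m) for m in meta["node_meta"]],
        seed=config.seed,
    )
    return high, low, truth


def simulate_moderation(
    n: int = 440,
    beta3: float = 0.65,
    seed: int = 0,
    phenotype: PhenotypeSpec | None = None,
) -> pd.DataFrame:
    """Minimal generator for the three-way moderation model alone.

    Draws the two p-tau peptides and the module score from a correlated
    normal (pairwise r = 0.3), activity from the matched lognormal, and
    tangle burden from the planted linear model with three-way coefficient
    ``beta3`` on the ptau_1 x module x activity product.  Noise SD 8 puts
    the three-way coefficient's standard error near 0.33 at n = 440, the
    uncertainty scale of the reference analysis.
    """
    ph = phenotype or PhenotypeSpec(beta3_ptau1=beta3)
    ph = replace(ph, beta3_ptau1=beta3)
    rng = np.random.default_rng(seed)
    C = np.full((3, 3), 0.3)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, 3)) @ L.T
    p1, p2, mod = Z[:, 0], Z[:, 1], Z[:, 2]
    cv2 = (ph.activity_sd / ph.activity_mean) ** 2
    sig = np.sqrt(np.log1p(cv2))
    mu = np.log(ph.activity_mean) - sig**2 / 2
    act = rng.lognormal(mu, sig, n)
    act_c = act - act.mean()
    tangles = (
        ph.beta_ptau1 * p1
        + ph.beta_ptau2 * p2
        + ph.beta_module * mod
        + ph.beta_activity * act_c
        + ph.beta3_ptau1 * p1 * mod * act_c
        + ph.beta3_ptau2 * p2 * mod * act_c
        + rng.normal(0, ph.tangle_sd, n)
    )
    return pd.DataFrame(
        {"tangles": tangles, "ptau_1": p1, "ptau_2": p2, "module": mod, "activity": act}
    )
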