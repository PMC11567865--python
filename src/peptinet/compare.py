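"""Permutation-based comparison of two estimated networks.

Subjects are split into two groups (in the study design, above/below the
median of daily actigraphy counts), a network is estimated independently
per group, and the difference of every statistic of interest is referred to
its permutation distribution: group labels are reshuffled (group sizes
preserved) and the full estimation pipeline — Gaussianization,
pairwise-complete correlation, EBIC-glasso — is re-run for both pseudo
groups at every permutation.  Two-sided p-values use absolute differences
with the add-one correction p = (1 + #{perm >= obs}) / (n_perm + 1);
per-edge and per-node families are corrected by Holm-Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EDGE_EPS, MultilayerNetwork, NodeMeta

log = logging.getLogger(__name__)


def median_split(activity: pd.Series) -> tuple[list, list]:
    """Split subject ids at the median: strictly above -> high, at/below -> low."""
    act = activity.dropna()
    if len(act) < 2:
        raise ValueError("median split needs at least 2 subjects with activity data")
    if act.nunique() == 1:
        raise ValueError("all activity values are identical; no median split possible")
    med = act.median()
    high = act.index[act > med].tolist()
    low = act.index[act <= med].tolist()
    return high, low


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm rejections, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    order = np.argsort(p, kind="stable")
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


@dataclass
class ComparisonResult:
    """Observed statistics, permutation p-values and Holm decisions."""

    node_ids: list[str]
    global_connectivity: tuple[float, float]      # (group A, group B)
    global_connectivity_p: float
    edges: pd.DataFrame                           # i, j, w_a, w_b, diff, p, reject
    centrality: pd.DataFrame                      # node_id, s_a, s_b, diff, p, reject
    interlayer: pd.DataFrame                      # layer_a, layer_b, c_a, c_b, diff, p
    network_a: MultilayerNetwork = field(repr=False, default=None)
    network_b: MultilayerNetwork = field(repr=False, default=None)
    n_perm: int = 0
    seed: int = 0
    alpha: float = 0.05
    n_redrawn: int = 0

    def to_json(self) -> dict:
        return {
            "global_connectivity": {
                "group_a": self.global_connectivity[0],
                "group_b": self.global_connectivity[1],
                "difference": self.global_connectivity[0] - self.global_connectivity[1],
                "p_value": self.global_connectivity_p,
            },
            "edges": self.edges.to_dict(orient="records"),
            "centrality": self.centrality.to_dict(orient="records"),
            "interlayer_connectivity": self.interlayer.to_dict(orient="records"),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "n_redrawn_permutations": self.n_redrawn,
        }


def _to_network(W: np.ndarray, node_meta, n_eff: int) -> MultilayerNetwork:
    from .core import build_network

    return build_network(list(node_meta), W, n_samples=n_eff)


def _estimate_W(arr: np.ndarray, est_kwargs) -> tuple[np.ndarray, int]:
    """Raw array -> partial-correlation matrix via the full pipeline."""
    from .ggm import select_model, to_partial_correlations
    from .preprocess import nonparanormal_transform_array, pairwise_complete_correlation

    Z = nonparanormal_transform_array(arr)
    if np.isnan(Z).any():
        corr = pairwise_complete_correlation(pd.DataFrame(Z, copy=False))
        R, n_eff = corr.R, corr.n_effective
    else:
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(Z.T)
        if np.isnan(R).any():
            raise ValueError("correlation undefined (constant column)")
        n_eff = arr.shape[0]
    fit = select_model(R, n_eff, **est_kwargs)
    return to_partial_correlations(fit.selected_precision), n_eff


def _layer_pair_masks(node_meta) -> dict[tuple[str, str], np.ndarray]:
    layers = np.array([m.layer for m in node_meta])
    present = sorted(set(layers))
    masks = {}
    p = len(layers)
    triu = np.triu(np.ones((p, p), dtype=bool), k=1)
    for i, a in enumerate(present):
        for b in present[i:]:
            in_a, in_b = layers == a, layers == b
            block = np.outer(in_a, in_b) | np.outer(in_b, in_a)
            masks[(a, b)] = block & triu
    return masks


def _stats_W(W: np.ndarray, pairs: np.ndarray, masks) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    absW = np.abs(W)
    gc = float(np.triu(absW, k=1).sum())
    s = absW.sum(axis=1)
    inter = np.array([absW[m].sum() for m in masks.values()])
    ew = W[pairs[:, 0], pairs[:, 1]]
    return gc, s, inter, ew


def nct(
    Xa: pd.DataFrame,
    Xb: pd.DataFrame,
    node_meta: Sequence[NodeMeta],
    n_perm: int = 10000,
    alpha: float = 0.05,
    gamma: float = 0.5,
    seed: int = 0,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-5,
    min_group_n: int = 50,
) -> ComparisonResult:
    """Network comparison test between two subject groups.

    ``Xa``/``Xb`` are raw (pre-Gaussianization) subject-by-variable tables
    with identical columns matching ``node_meta``.  Edge differences are
    tested on the union support of the two observed networks.  Permutations
    whose estimation fails are redrawn; more than 1% failures aborts.
    """
    if list(Xa.columns) != list(Xb.columns):
        raise ValueError("both groups must share the same columns in the same order")
    if len(Xa) < min_group_n or len(Xb) < min_group_n:
        raise ValueError(f"each group needs at least {min_group_n} subjects")

    est_kwargs = dict(gamma=gamma, n_lambda=n_lambda,
                      lambda_min_ratio=lambda_min_ratio, tol=tol)
    arr_a = Xa.to_numpy(dtype=float)
    arr_b = Xb.to_numpy(dtype=float)
    Wa, na_eff = _estimate_W(arr_a, est_kwargs)
    Wb, nb_eff = _estimate_W(arr_b, est_kwargs)
    net_a = _to_network(Wa, node_meta, na_eff)
    net_b = _to_network(Wb, node_meta, nb_eff)

    union = np.triu((np.abs(Wa) > EDGE_EPS) | (np.abs(Wb) > EDGE_EPS), k=1)
    pairs = np.argwhere(union)
    masks = _layer_pair_masks(node_meta)
    layer_pairs = list(masks)
    gc_a, s_a, inter_a, ew_a = _stats_W(Wa, pairs, masks)
    gc_b, s_b, inter_b, ew_b = _stats_W(Wb, pairs, masks)

    obs_gc = abs(gc_a - gc_b)
    obs_edge = np.abs(ew_a - ew_b)
    obs_cent = np.abs(s_a - s_b)
    obs_inter = np.abs(inter_a - inter_b)

    pool = np.concatenate([arr_a, arr_b], axis=0)
    na = len(arr_a)
    rng = np.random.default_rng(seed)

    ge_gc = 0
    ge_edge = np.zeros(len(pairs), dtype=int)
    ge_cent = np.zeros(len(node_meta), dtype=int)
    ge_inter = np.zeros(len(layer_pairs), dtype=int)
    done = 0
    failures = 0
    max_failures = max(1, int(np.ceil(0.01 * n_perm)))
    while done < n_perm:
        idx = rng.permutation(len(pool))
        try:
            Wpa, _ = _estimate_W(pool[idx[:na]], est_kwargs)
            Wpb, _ = _estimate_W(pool[idx[na:]], est_kwargs)
        except Exception as exc:  # redraw this permutation
            failures += 1
            log.warning("permutation estimation failed (%s); redrawing", exc)
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 1% of permutations failed ({failures}); aborting"
                ) from exc
            continue
        gca, sa, ia, ea = _stats_W(Wpa, pairs, masks)
        gcb, sb, ib, eb = _stats_W(Wpb, pairs, masks)
        ge_gc += abs(gca - gcb) >= obs_gc
        ge_edge += np.abs(ea - eb) >= obs_edge
        ge_cent += np.abs(sa - sb) >= obs_cent
        ge_inter += np.abs(ia - ib) >= obs_inter
        done += 1
        if done % 100 == 0:
            log.info("permutation %d / %d", done, n_perm)

    denom = n_perm + 1
    p_gc = (1 + ge_gc) / denom
    p_edge = (1 + ge_edge) / denom
    p_cent = (1 + ge_cent) / denom
    p_inter = (1 + ge_inter) / denom

    ids = [m.node_id for m in node_meta]
    edges = pd.DataFrame(
        {
            "i": [ids[a] for a, _ in pairs],
            "j": [ids[b] for _, b in pairs],
            "w_a": ew_a,
            "w_b": ew_b,
            "diff": ew_a - ew_b,
            "p": p_edge,
            "reject": holm_bonferroni(p_edge, alpha) if len(pairs) else [],
        }
    )
    centrality = pd.DataFrame(
        {
            "node_id": ids,
            "strength_a": s_a,
            "strength_b": s_b,
            "diff": s_a - s_b,
            "p": p_cent,
            "reject": holm_bonferroni(p_cent, alpha),
        }
    )
    inter = pd.DataFrame(
        {
            "layer_a": [lp[0] for lp in layer_pairs],
            "layer_b": [lp[1] for lp in layer_pairs],
            "connectivity_a": inter_a,
            "connectivity_b": inter_b,
            "diff": inter_a - inter_b,
            "p": p_inter,
        }
    )
    return ComparisonResult(
        node_ids=ids,
        global_connectivity=(gc_a, gc_b),
        global_connectivity_p=float(p_gc),
        edges=edges,
        centrality=centrality,
        interlayer=inter,
        network_a=net_a,
        network_b=net_b,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        n_redrawn=failures,
    )
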