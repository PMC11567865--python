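"""Raw abundance tables -> analysis-ready matrix.

The targeted mass-spectrometry assay reports light:heavy peptide abundance
ratios, which are log2-transformed and median-centered per peptide.  Pairs
of peptides that target the same protein and are highly correlated are
averaged into one variable.  Before network estimation every column is
Gaussianized by a rank-based (nonparanormal) transform, and the correlation
matrix is computed on pairwise-complete observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class MergePlan:
    """Record of which highly correlated peptide pairs were averaged."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (a, b, merged_id)
    r_threshold: float = 0.8
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)


def log2_median_center(raw: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and center each column at its median.

    Missing entries are preserved; every non-missing entry must be positive.
    """
    arr = raw.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(arr) & (arr <= 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive ratio at row {raw.index[r]!r}, column {raw.columns[c]!r}: {arr[r, c]}"
        )
    logged = np.log2(arr)
    med = np.nanmedian(logged, axis=0)
    return pd.DataFrame(logged - med, index=raw.index, columns=raw.columns)


def merge_correlated_pairs(
    X: pd.DataFrame,
    candidate_pairs: list[tuple[str, str]],
    r_threshold: float = 0.8,
) -> tuple[pd.DataFrame, MergePlan]:
    """Average candidate column pairs whose pairwise-complete Pearson r >= threshold.

    The merged column is named ``"<a>+<b>"`` and replaces both inputs (at the
    position of the first); pairs below the threshold are left untouched.
    A column may appear in at most one candidate pair.
    """
    seen: set[str] = set()
    for a, b in candidate_pairs:
        for col in (a, b):
            if col not in X.columns:
                raise KeyError(f"candidate pair references unknown column {col!r}")
            if col in seen:
                raise ValueError(f"column {col!r} appears in more than one candidate pair")
            seen.add(col)

    plan = MergePlan(r_threshold=r_threshold)
    out = X.copy()
    for a, b in candidate_pairs:
        r = out[a].corr(out[b])  # pairwise-complete Pearson
        plan.correlations[(a, b)] = float(r) if np.isfinite(r) else np.nan
        if np.isfinite(r) and r >= r_threshold:
            merged_id = f"{a}+{b}"
            merged = pd.concat([out[a], out[b]], axis=1).mean(axis=1, skipna=True)
            pos = out.columns.get_loc(a)
            out = out.drop(columns=[a, b])
            out.insert(min(pos, out.shape[1]), merged_id, merged)
            plan.pairs.append((a, b, merged_id))
    return out, plan


def nonparanormal_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Columnwise rank-based Gaussianization (semiparametric copula estimate).

    A value with (average, tie-aware) rank k among m non-missing entries maps
    to the standard normal quantile of k/(m+1); the column is then rescaled
    to unit sample standard deviation.  The output is invariant to strictly
    monotone transforms of the input column.
    """
    arr = X.to_numpy(dtype=float)
    out = nonparanormal_transform_array(arr, columns=list(X.columns))
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def nonparanormal_transform_array(arr: np.ndarray, columns: list | None = None) -> np.ndarray:
    """Array-level nonparanormal transform (see nonparanormal_transform)."""
    names = columns or list(range(arr.shape[1]))
    if not np.isnan(arr).any():
        # complete data: one vectorized rank pass
        m = arr.shape[0]
        if m < 2:
            raise ValueError("need at least 2 rows")
        mins, maxs = arr.min(axis=0), arr.max(axis=0)
        if np.any(mins == maxs):
            c = int(np.argmax(mins == maxs))
            raise ValueError(f"constant or near-empty column {names[c]!r}")
        ranks = stats.rankdata(arr, method="average", axis=0)
        z = stats.norm.ppf(ranks / (m + 1))
        return z / z.std(axis=0, ddof=1)
    out = np.full(arr.shape, np.nan)
    for c in range(arr.shape[1]):
        col = arr[:, c]
        obs = ~np.isnan(col)
        vals = col[obs]
        if vals.size < 2 or np.nanmin(vals) == np.nanmax(vals):
            raise ValueError(f"constant or near-empty column {names[c]!r}")
        ranks = stats.rankdata(vals, method="average")
        z = stats.norm.ppf(ranks / (vals.size + 1))
        out[obs, c] = z / z.std(ddof=1)
    return out


@dataclass
class CorrelationResult:
    """Pairwise-complete correlation matrix with bookkeeping."""

    R: np.ndarray
    columns: list[str]
    n_pairwise: np.ndarray  # joint-observation counts per pair
    n_effective: int        # min pairwise-complete count
    psd_repaired: bool


def pairwise_complete_correlation(
    X: pd.DataFrame, min_joint: int = 10
) -> CorrelationResult:
    """Pearson correlations over jointly observed rows for every column pair.

    If the assembled matrix is indefinite (a routine consequence of pairwise
    deletion) it is repaired by clipping eigenvalues at 1e-8 and re-normalizing
    to unit diagonal; the repair is logged.
    """
    arr = X.to_numpy(dtype=float)
    p = X.shape[1]
    off = ~np.eye(p, dtype=bool)
    if not np.isnan(arr).any():
        # complete data: plain correlation, all counts equal n
        if arr.shape[0] < min_joint:
            raise ValueError(f"only {arr.shape[0]} rows (< {min_joint})")
        counts = np.full((p, p), arr.shape[0], dtype=int)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(arr.T) if p > 1 else np.ones((1, 1))
    else:
        obs = (~np.isnan(arr)).astype(float)
        counts = (obs.T @ obs).astype(int)
        if counts[off].min() < min_joint:
            i, j = np.argwhere((counts < min_joint) & off)[0]
            raise ValueError(
                f"columns {X.columns[i]!r} and {X.columns[j]!r} share only "
                f"{counts[i, j]} joint observations (< {min_joint})"
            )
        # vectorized pairwise-complete Pearson via masked cross-products
        X0 = np.nan_to_num(arr, nan=0.0)
        C = counts.astype(float)
        Sx = X0.T @ obs            # sum of x_i over rows where both i, j observed
        Sxx = (X0 * X0).T @ obs
        Sxy = X0.T @ X0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_x = Sx / C
            cov = Sxy / C - mean_x * mean_x.T
            var_x = Sxx / C - mean_x**2
            R = cov / np.sqrt(var_x * var_x.T)
        np.fill_diagonal(R, 1.0)
    if np.isnan(R).any():
        i, j = np.argwhere(np.isnan(R))[0]
        raise ValueError(
            f"correlation undefined for columns {X.columns[i]!r}, {X.columns[j]!r} "
            "(zero variance on the joint sample)"
        )
    repaired = False
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < 0:
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        repaired = True
        log.warning(
            "pairwise-complete correlation matrix was indefinite "
            "(min eigenvalue %.3e); repaired by eigenvalue clipping", eigmin
        )
    R = (R + R.T) / 2.0
    return CorrelationResult(
        R=R,
        columns=list(X.columns),
        n_pairwise=counts,
        n_effective=int(counts[off].min()) if p > 1 else int(counts[0, 0]),
        psd_repaired=repaired,
    )


def preprocess_report(plan: MergePlan, X: pd.DataFrame, corr: CorrelationResult) -> dict:
    """JSON-serializable summary of the preprocessing stage."""
    return {
        "merged_pairs": [list(t) for t in plan.pairs],
        "merge_r_threshold": plan.r_threshold,
        "missing_fraction_per_column": {
            c: float(X[c].isna().mean()) for c in X.columns
        },
        "n_effective": corr.n_effective,
        "psd_repaired": corr.psd_repaired,
    }
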