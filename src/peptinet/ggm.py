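"""Sparse Gaussian graphical model estimation.

The conditional-dependence network is estimated by the graphical lasso:
maximize  log det Theta - tr(R Theta) - lambda * sum_{i != j} |Theta_ij|
over symmetric positive-definite precision matrices Theta, with the L1
penalty on off-diagonal entries only.  The regularization level is chosen
by the extended Bayesian information criterion (EBIC) with gamma = 0.5,
and the selected precision matrix is converted to partial correlations

    w_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj).

The solver is ADMM with an eigendecomposition-based Theta-step, a
soft-threshold Z-step and adaptive penalty parameter; consecutive fits
along the lambda path are warm-started, which is what makes permutation
re-estimation of whole networks affordable.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

from .core import EDGE_EPS, GGMFit, MultilayerNetwork, NodeMeta, build_network
from .preprocess import pairwise_complete_correlation


class GlassoError(RuntimeError):
    pass


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-8:
        raise GlassoError(
            f"R is not positive semidefinite (min eigenvalue {eigmin:.3e}); "
            "repair it first (see pairwise_complete_correlation)"
        )
    return R


def glasso(
    R: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    rho: float = 1.0,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    return_state: bool = False,
    check: bool = True,
):
    """Solve the graphical lasso at a single penalty level.

    Parameters
    ----------
    R : correlation (or covariance) matrix, symmetric PSD.
    lam : L1 penalty on off-diagonal precision entries, >= 0.
    warm : optional (Z, U) pair from a previous solve for warm starting.
    return_state : also return (Z, U, rho) for warm-starting the next solve.
    check : validate R (symmetry, PSD); callers fitting a path validate once.

    Returns the precision estimate; off-diagonal zeros are exact (they come
    from the soft-threshold step).  At lam == 0 the penalty vanishes and the
    maximum-likelihood solution R^{-1} is returned directly.
    """
    if check:
        R = _check_corr(R)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = R.shape[0]
    if lam == 0:
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin <= 1e-10:
            raise GlassoError("R is singular; lambda = 0 requires positive definite R")
        Theta = np.linalg.inv(R)
        Theta = (Theta + Theta.T) / 2.0
        return (Theta, (Theta.copy(), np.zeros_like(R), rho)) if return_state else Theta

    if warm is not None:
        Z, U = warm[0].copy(), warm[1].copy()
    else:
        Z, U = np.eye(p), np.zeros((p, p))
    diag_idx = np.diag_indices(p)
    Theta = Z.copy()
    for _ in range(max_iter):
        # Theta-step: prox of -logdet + tr(R .) at rho
        w, V = np.linalg.eigh(rho * (Z - U) - R)
        ev = (w + np.sqrt(w * w + 4.0 * rho)) / (2.0 * rho)
        Theta = (V * ev) @ V.T
        # Z-step: soft-threshold off-diagonals
        Z_old = Z
        M = Theta + U
        Z = np.sign(M) * np.maximum(np.abs(M) - lam / rho, 0.0)
        Z[diag_idx] = M[diag_idx]
        U = U + Theta - Z
        r_norm = np.linalg.norm(Theta - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps_pri = p * 1e-12 + tol * max(np.linalg.norm(Theta), np.linalg.norm(Z))
        eps_dual = p * 1e-12 + tol * np.linalg.norm(rho * U)
        if r_norm <= eps_pri and s_norm <= max(eps_dual, tol):
            break
        # adaptive rho (Boyd et al. 3.4.1); rescale the scaled dual variable
        if r_norm > 10.0 * s_norm:
            rho *= 2.0
            U /= 2.0
        elif s_norm > 10.0 * r_norm:
            rho /= 2.0
            U *= 2.0
    else:
        raise GlassoError(
            f"glasso did not converge at lambda={lam:.6g} "
            f"(primal residual {r_norm:.3e}, tol {tol:g})"
        )
    Z = (Z + Z.T) / 2.0
    return (Z, (Z.copy(), U, rho)) if return_state else Z


def n_edges(Theta: np.ndarray, eps: float = EDGE_EPS) -> int:
    """Number of nonzero off-diagonal upper-triangle entries."""
    return int(np.count_nonzero(np.triu(np.abs(Theta) > eps, k=1)))


def ebic(Theta: np.ndarray, R: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC:  -2 L + |E| log n + 4 gamma |E| log p.

    L = (n/2)(log det Theta - tr(R Theta)) is the Gaussian profile
    log-likelihood; |E| counts the nonzero off-diagonal upper-triangle
    entries of Theta.  gamma = 0 recovers the ordinary BIC.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0 or not np.isfinite(logdet):
        raise GlassoError("Theta is not positive definite; EBIC undefined")
    p = Theta.shape[0]
    L = (n / 2.0) * (logdet - float(np.sum(R * Theta)))
    E = n_edges(Theta)
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def select_model(
    R: np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
) -> GGMFit:
    """Fit the glasso path and pick the EBIC-minimizing model.

    The lambda grid is log-spaced from lambda_max = max off-diagonal |R_ij|
    (the smallest penalty producing an empty graph) down to
    lambda_min_ratio * lambda_max.  Fits are warm-started from large to
    small lambda.
    """
    R = _check_corr(R)
    p = R.shape[0]
    lam_max = float(np.max(np.abs(R - np.diag(np.diag(R))))) if p > 1 else 1.0
    if lam_max <= 0:
        lam_max = 1e-3  # R is diagonal; any positive penalty gives the empty graph
    grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    precisions: list[np.ndarray] = []
    ebics = np.empty(n_lambda)
    state = None
    for k, lam in enumerate(grid):
        Theta, state = glasso(R, float(lam), tol=tol, warm=state[:2] if state else None,
                              rho=state[2] if state else 1.0, return_state=True,
                              check=False)
        sign, _ = np.linalg.slogdet(Theta)
        if sign <= 0:
            # soft-threshold iterate can be marginally indefinite before full
            # convergence; re-solve this lambda cold at tighter tolerance
            Theta, state = glasso(R, float(lam), tol=tol / 10, return_state=True,
                                  check=False)
        precisions.append(Theta)
        ebics[k] = ebic(Theta, R, n, gamma)
    best = int(np.argmin(ebics))
    return GGMFit(
        lambda_grid=grid,
        precisions=precisions,
        ebic_values=ebics,
        selected_index=best,
        gamma=gamma,
        sample_correlation=R,
        n_effective=n,
    )


def to_partial_correlations(Theta: np.ndarray) -> np.ndarray:
    """Precision matrix -> signed partial-correlation matrix (zero diagonal)."""
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    denom = np.sqrt(np.outer(d, d))
    W = -Theta / denom
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) <= EDGE_EPS] = 0.0
    return (W + W.T) / 2.0


def estimate_network(
    X_npn,
    node_meta: Sequence[NodeMeta],
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    layout_seed: int = 42,
    compute_layout: bool = True,
) -> tuple[MultilayerNetwork, GGMFit]:
    """Full estimation from a Gaussianized data table to a signed network.

    Pipeline: pairwise-complete correlation -> EBIC-glasso -> partial
    correlations; a seeded Fruchterman-Reingold layout on |W| is attached
    for plotting.
    """
    cols = list(X_npn.columns)
    ids = [m.node_id for m in node_meta]
    if cols != ids:
        raise ValueError("columns of the data table must match node metadata ids in order")
    corr = pairwise_complete_correlation(X_npn)
    fit = select_model(corr.R, corr.n_effective, gamma=gamma, n_lambda=n_lambda,
                       lambda_min_ratio=lambda_min_ratio, tol=tol)
    W = to_partial_correlations(fit.selected_precision)
    layout = None
    if compute_layout:
        layout = fruchterman_reingold_layout(W, ids, seed=layout_seed)
    net = build_network(node_meta, W, n_samples=corr.n_effective, layout=layout)
    return net, fit


# alias emphasizing the joint 4-layer use case
estimate_multilayer = estimate_network


def fruchterman_reingold_layout(
    W: np.ndarray, node_ids: Sequence[str], seed: int = 42
) -> dict[str, tuple[float, float]]:
    """Seeded force-directed coordinates using |W| as attraction weights."""
    G = nx.Graph()
    G.add_nodes_from(node_ids)
    ii, jj = np.nonzero(np.triu(np.abs(W) > EDGE_EPS, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(node_ids[i], node_ids[j], weight=float(abs(W[i, j])))
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    return {nid: (float(x), float(y)) for nid, (x, y) in pos.items()}
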