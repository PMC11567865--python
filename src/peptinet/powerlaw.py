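"""Continuous power-law fitting with a weighted KS goodness-of-fit bootstrap.

Implements the standard maximum-likelihood recipe for heavy-tailed data:
the exponent alpha is the continuous MLE above a lower cutoff x_min, x_min
is chosen to minimize the KS distance between the tail data and the fitted
power law, and the p-value comes from a semiparametric bootstrap in which
synthetic samples mix resampled body values with power-law tail draws.
Large p-values mean the data are consistent with a power law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PowerlawFit:
    alpha: float
    x_min: float
    ks_stat: float
    p_value: float
    n_tail: int


def _fit_tail(x_sorted: np.ndarray, x_min_candidates: np.ndarray) -> tuple[float, float, float]:
    """Best (alpha, x_min, ks) over the candidate cutoffs; x_sorted ascending."""
    best = (np.inf, np.nan, np.nan)  # (ks, alpha, x_min)
    n = x_sorted.size
    for xm in x_min_candidates:
        start = np.searchsorted(x_sorted, xm, side="left")
        tail = x_sorted[start:]
        m = tail.size
        if m < 2:
            continue
        logs = np.log(tail / xm)
        s = logs.sum()
        if s <= 0:
            continue
        alpha = 1.0 + m / s
        # KS distance between tail ECDF and fitted CDF 1 - (x/xm)^(1-alpha)
        cdf = 1.0 - (tail / xm) ** (1.0 - alpha)
        ecdf_hi = np.arange(1, m + 1) / m
        ecdf_lo = np.arange(0, m) / m
        ks = max(np.max(np.abs(cdf - ecdf_hi)), np.max(np.abs(cdf - ecdf_lo)))
        if ks < best[0]:
            best = (ks, alpha, float(xm))
    if not np.isfinite(best[0]):
        raise ValueError("could not fit a power-law tail (degenerate values)")
    return best[1], best[2], best[0]


def fit_powerlaw(values: np.ndarray, max_candidates: int = 60) -> tuple[float, float, float, int]:
    """MLE power-law fit with KS-minimizing x_min.

    Returns (alpha, x_min, ks_stat, n_tail).  Candidate cutoffs are the
    unique data values (subsampled evenly if there are many).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 10:
        raise ValueError("need at least 10 positive values")
    if np.any(x <= 0):
        raise ValueError("power-law fitting requires strictly positive values")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("all values are equal; no distribution to fit")
    cands = uniq[:-1]  # keep >= 2 tail points
    if cands.size > max_candidates:
        cands = cands[np.linspace(0, cands.size - 1, max_candidates).astype(int)]
    alpha, x_min, ks = _fit_tail(x, cands)
    n_tail = int((x >= x_min).sum())
    return alpha, x_min, ks, n_tail


def powerlaw_ks_test(values: np.ndarray, n_boot: int = 500, seed: int = 0) -> PowerlawFit:
    """Clauset-style goodness-of-fit test for a continuous power-law tail.

    p_value is the fraction of semiparametric bootstrap replicates whose
    refit KS distance is at least the observed one; large p means the
    power-law hypothesis is not rejected.
    """
    x = np.sort(np.asarray(values, dtype=float))
    alpha, x_min, ks_obs, n_tail = fit_powerlaw(x)
    rng = np.random.default_rng(seed)
    n = x.size
    body = x[x < x_min]
    p_tail = n_tail / n
    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(n) < p_tail
        m = int(take_tail.sum())
        synth = np.empty(n)
        # tail: inverse-CDF draws from the fitted power law
        u = rng.random(m)
        synth[:m] = x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))
        # body: resample the sub-threshold empirical values
        if n - m > 0:
            if body.size:
                synth[m:] = rng.choice(body, size=n - m, replace=True)
            else:
                u2 = rng.random(n - m)
                synth[m:] = x_min * (1.0 - u2) ** (-1.0 / (alpha - 1.0))
        try:
            _, _, ks_b, _ = fit_powerlaw(synth)
        except ValueError:
            continue
        if ks_b >= ks_obs:
            exceed += 1
    p_value = (exceed + 1) / (n_boot + 1)
    return PowerlawFit(alpha=alpha, x_min=x_min, ks_stat=ks_obs, p_value=p_value, n_tail=n_tail)
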