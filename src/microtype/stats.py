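"""Shared statistical utilities: FDR procedures and seeded PERMANOVA.

Benjamini–Hochberg comes from statsmodels.  Storey's q-value method is
implemented here (no installed package provides it): pi0 is estimated on a
lambda grid 0.05..0.95 smoothed with a cubic spline and evaluated at the
largest lambda, falling back to BH (pi0 = 1) when fewer than 50 p-values
are available — too few for a stable histogram.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

log = logging.getLogger("microtype")

STOREY_MIN_PVALUES = 50


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(pvalues, lambdas=None) -> float:
    """Storey's pi0: spline-smoothed proportion of nulls."""
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_at = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = CubicSpline(lambdas, pi0_at)
    pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 0.0, 1.0)) or 1e-8


def qvalues(pvalues) -> np.ndarray:
    """Storey q-values; BH fallback for sparse p-value vectors (logged)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be in [0, 1]")
    if p.size < STOREY_MIN_PVALUES:
        log.info("qvalues: %d p-values < %d, using BH fallback", p.size, STOREY_MIN_PVALUES)
        return bh_adjust(p)
    pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def permanova(dist: np.ndarray, labels, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA (Anderson's pseudo-F) with a seeded permutation test.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous term
    within each group; F = (SS_between/(k-1)) / (SS_within/(n-k));
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("labels length must match distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValidationError("every group needs >= 2 members")

    d2 = d ** 2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            idx = np.flatnonzero(assign == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf  # perfect separation
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)
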