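"""Phylogenetic beta diversity, principal coordinates, and vector fitting.

UniFrac (unweighted and weighted) is computed through scikit-bio.  PCoA is
a direct Gower double-centering + symmetric eigendecomposition so that the
negative-eigenvalue policy and the axis sign convention are explicit and
deterministic.  ``envfit_vectors`` superimposes covariates (food items,
metadata) on the first two ordination axes with a permutation test, in the
manner of vegan's envfit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity

from .core import FeatureTable, ValidationError


@dataclass
class OrdinationResult:
    """PCoA coordinates plus fitted covariate vectors.

    Eigenvalues are reported in descending order, negative ones included;
    coordinates only span the axes with positive eigenvalues.
    """

    coordinates: pd.DataFrame          # samples × PCo1..PCom (positive axes)
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues only
    fitted_vectors: pd.DataFrame | None = None


def unifrac(
    table: FeatureTable,
    tree: skbio.TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> pd.DataFrame:
    """UniFrac distance matrix between all sample pairs.

    Unweighted uses branch presence/absence (presence = count > 0, no
    rarefaction); weighted uses abundance-weighted branch differences,
    normalized by default.  Every feature must be a leaf of ``tree``.
    """
    leaves = {t.name for t in tree.tips()}
    missing = [f for f in table.feature_ids if f not in leaves]
    if missing:
        raise ValidationError(f"features absent from tree: {missing[:10]}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(
        metric,
        table.values(),
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree,
        **kwargs,
    )
    return pd.DataFrame(dm.data, index=table.sample_ids, columns=table.sample_ids)


def pcoa(dist: pd.DataFrame, eig_tol: float = 1e-9) -> OrdinationResult:
    """Principal coordinates analysis.

    Gower-centers -d^2/2 and eigendecomposes.  Coordinates on axis j are
    the eigenvector scaled by sqrt(eigenvalue); axes with eigenvalue below
    ``eig_tol`` (incl. negative ones) are reported but excluded from the
    coordinate matrix.  The sign of each axis is fixed so the coordinate
    with the largest magnitude is positive.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    pos = eigvals > eig_tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # deterministic sign: largest-|coordinate| entry positive on each axis
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PCo{j + 1}" for j in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def envfit_vectors(
    ordination: OrdinationResult,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    axes: tuple[int, int] = (0, 1),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit covariates as arrows onto two ordination axes.

    For each covariate y the least-squares fit on the axis scores gives
    direction cosines and R^2 (squared multiple correlation); the p-value
    permutes y over samples.  Constant covariates are flagged and skipped.
    The significance filter at ``alpha`` populates a display flag only —
    every covariate is retained in the output.
    """
    if ordination.coordinates.shape[1] < 2:
        raise ValidationError("envfit needs an ordination with >= 2 axes")
    X = ordination.coordinates.iloc[:, list(axes)].to_numpy()
    Xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in covariates.columns:
        y = covariates[name].to_numpy(dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < 3 or np.std(y[mask]) == 0:
            rows.append(
                {"covariate": name, "dx": np.nan, "dy": np.nan, "r2": np.nan,
                 "p": np.nan, "display": False, "note": "constant-or-missing"}
            )
            continue
        Xm, ym = Xc[mask], y[mask] - y[mask].mean()

        def r2_of(yv: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(Xm, yv, rcond=None)
            fitted = Xm @ beta
            denom = (yv ** 2).sum()
            return (float((fitted ** 2).sum() / denom) if denom > 0 else 0.0), beta

        r2, beta = r2_of(ym)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        exceed = sum(r2_of(rng.permutation(ym))[0] >= r2 for _ in range(n_perm))
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {"covariate": name, "dx": float(direction[0]), "dy": float(direction[1]),
             "r2": r2, "p": float(p), "display": p <= alpha, "note": ""}
        )
    out = pd.DataFrame(rows).set_index("covariate")
    ordination.fitted_vectors = out
    return out
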