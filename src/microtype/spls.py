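"""Sparse partial least squares (sPLS) regression for two-block integration.

Links a metatranscriptomic block X to a lipidomic block Y by extracting
pairs of latent components that maximize cross-block covariance, with an
optional L1-style sparsity constraint on the X loadings (soft-thresholding
to the keepX largest entries per component), deflating X and Y in
regression mode between components.  The alternating least-squares
(NIPALS-style) iteration is initialized from the leading singular vector
of X'Y, making the fit deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .core import FeatureTable, ValidationError


@dataclass
class SplsModel:
    x_loadings: pd.DataFrame     # features × components, unit norm, sparse
    y_loadings: pd.DataFrame
    x_scores: pd.DataFrame       # samples × components
    y_scores: pd.DataFrame
    explained_covariance: np.ndarray
    x_features: list[str] = field(default_factory=list)
    y_features: list[str] = field(default_factory=list)


def prevalence_filter_features(table: FeatureTable, threshold: float = 0.5) -> FeatureTable:
    """Keep features nonzero in >= ``threshold`` of samples (inclusive)."""
    vals = table.values()
    if vals.shape[1] == 0:
        raise ValidationError("empty feature table")
    prevalence = (vals > 0).mean(axis=0)
    keep = [f for f, p in zip(table.feature_ids, prevalence) if p >= threshold]
    if not keep:
        raise ValidationError("no features pass the prevalence filter")
    return table.subset_features(keep)


def _soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold v so only its ``keep`` largest-|.| entries stay nonzero."""
    if keep >= v.size:
        return v
    cutoff = np.sort(np.abs(v))[-(keep + 1)]
    out = np.sign(v) * np.maximum(np.abs(v) - cutoff, 0.0)
    return out


def spls_fit(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int = 2,
    keep_x: int | list[int] | None = None,
    scale: bool = True,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SplsModel:
    """Fit sPLS in regression mode (X explains Y).

    Blocks are centered (and unit-scaled when ``scale``).  Per component:
    alternate u ∝ soft(X' Y v), v ∝ Y' X u until the X loading moves less
    than ``tol``; deflate X by its score regression and Y by the X score
    (regression mode).  ``keep_x`` may be a single budget or one per
    component; None keeps every feature (dense PLS).
    """
    if list(X.index) != list(Y.index):
        raise ValidationError("X and Y must share samples, in order")
    n, p = X.shape
    q = Y.shape[1]
    if n_components > min(n - 1, p):
        raise ValidationError("n_components exceeds the usable rank")
    keeps = ([keep_x] * n_components if isinstance(keep_x, int) or keep_x is None
             else list(keep_x))
    if len(keeps) != n_components:
        raise ValidationError("keep_x must have one entry per component")

    Xw = X.to_numpy(dtype=float).copy()
    Yw = Y.to_numpy(dtype=float).copy()
    Xw -= Xw.mean(axis=0)
    Yw -= Yw.mean(axis=0)
    if scale:
        sx = Xw.std(axis=0, ddof=1)
        sy = Yw.std(axis=0, ddof=1)
        Xw /= np.where(sx > 0, sx, 1.0)
        Yw /= np.where(sy > 0, sy, 1.0)

    U = np.zeros((p, n_components))
    V = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    S = np.zeros((n, n_components))
    expl = np.zeros(n_components)

    for h in range(n_components):
        M = Xw.T @ Yw
        # deterministic start: leading singular pair of the cross-covariance
        uu, ss, vv = np.linalg.svd(M, full_matrices=False)
        u, v = uu[:, 0], vv[0]
        keep = keeps[h]
        for it in range(max_iter):
            u_new = M @ v
            if keep is not None:
                u_new = _soft_threshold_keep(u_new, keep)
            nrm = np.linalg.norm(u_new)
            if nrm == 0:
                raise ValidationError(f"component {h + 1}: X loading collapsed to zero")
            u_new /= nrm
            v_new = M.T @ u_new
            v_new /= np.linalg.norm(v_new)
            if np.linalg.norm(u_new - u) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        else:
            raise ValidationError(
                f"component {h + 1}: no convergence in {max_iter} iterations "
                f"(last delta {np.linalg.norm(u_new - u):.2e})"
            )
        # sign convention: largest-|.| X loading positive
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        t = Xw @ u
        s = Yw @ v
        U[:, h], V[:, h], T[:, h], S[:, h] = u, v, t, s
        expl[h] = float((t @ s) ** 2)
        # regression-mode deflation
        tt = t @ t
        if tt > 0:
            c = (Xw.T @ t) / tt
            Xw = Xw - np.outer(t, c)
            dvec = (Yw.T @ t) / tt
            Yw = Yw - np.outer(t, dvec)

    return SplsModel(
        x_loadings=pd.DataFrame(U, index=X.columns,
                                columns=[f"comp{h + 1}" for h in range(n_components)]),
        y_loadings=pd.DataFrame(V, index=Y.columns,
                                columns=[f"comp{h + 1}" for h in range(n_components)]),
        x_scores=pd.DataFrame(T, index=X.index,
                              columns=[f"comp{h + 1}" for h in range(n_components)]),
        y_scores=pd.DataFrame(S, index=Y.index,
                              columns=[f"comp{h + 1}" for h in range(n_components)]),
        explained_covariance=expl,
        x_features=list(X.columns),
        y_features=list(Y.columns),
    )


def association_matrix(model: SplsModel) -> pd.DataFrame:
    """Low-rank X↔Y association scores: sum_h u_h v_h' weighted by covariance."""
    U = model.x_loadings.to_numpy()
    V = model.y_loadings.to_numpy()
    w = np.sqrt(model.explained_covariance)
    A = (U * w) @ V.T
    return pd.DataFrame(A, index=model.x_loadings.index, columns=model.y_loadings.index)


def spls_cluster(model: SplsModel, signed: bool = True) -> dict:
    """Order the association heatmap by complete linkage on 1 - Pearson r.

    Distance between two X features (or two Y features) is 1 - r of their
    association-score profiles (1 - |r| when ``signed`` is False).  Returns
    the reordered matrix and both leaf orders.
    """
    A = association_matrix(model)

    def order(mat: np.ndarray) -> np.ndarray:
        k = mat.shape[0]
        if k < 3:
            return np.arange(k)
        r = np.corrcoef(mat)
        r = np.nan_to_num(r, nan=0.0)
        d = 1.0 - (r if signed else np.abs(r))
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        link = sch.linkage(d[np.triu_indices(k, 1)], method="complete")
        return sch.leaves_list(link)

    row_order = order(A.to_numpy())
    col_order = order(A.to_numpy().T)
    ordered = A.iloc[row_order, col_order]
    return {"matrix": ordered, "row_order": row_order, "col_order": col_order}


def top_association_pairs(model: SplsModel, n: int = 5) -> pd.DataFrame:
    """The n largest |association| (X feature, Y feature) pairs."""
    A = association_matrix(model)
    flat = A.stack().rename("score").reset_index()
    flat.columns = ["x_feature", "y_feature", "score"]
    flat["abs_score"] = flat["score"].abs()
    return flat.sort_values("abs_score", ascending=False).head(n).reset_index(drop=True)
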