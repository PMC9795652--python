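"""Dietary patterning from food-frequency questionnaires.

Samples are placed on the first axis of a correspondence analysis of the
FFQ table and split into dietary groups by 1-D Ward clustering.  The
Healthy Food Diversity index combines how many foods are eaten, how evenly
(Berry index), and how healthy they are (per-item health values in [0,1]).
Nutrient summaries use Atwater 4/4/9 kcal/g conversions and normalize
fiber to 1000 kcal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .core import FeatureTable, ValidationError

ANNOTATION_COLUMNS = ["kcal", "protein_g", "carb_g", "fat_g", "fiber_g", "health_value"]


@dataclass
class DietAssignment:
    labels: pd.Series            # sample -> 'D1'..'Dk', ordered by mean axis score
    axis_scores: pd.Series
    inertia_share: np.ndarray    # proportion of total inertia per axis
    hfd_by_group: pd.DataFrame | None = None


def correspondence_axis(ffq: FeatureTable) -> tuple[pd.Series, np.ndarray]:
    """Row (sample) principal coordinates on CA axis 1 plus inertia shares.

    Standardized-residual SVD of the correspondence matrix.  Axis sign is
    fixed so the food with the largest column mass has a non-negative
    column coordinate, making runs comparable.
    """
    X = ffq.values()
    total = X.sum()
    if total <= 0:
        raise ValidationError("FFQ grand total is zero")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValidationError("CA requires no all-zero rows or columns")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-zero dimensions
    keep = sv > 1e-12
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    if sv.size == 0:  # independence table: zero inertia
        scores = pd.Series(np.zeros(X.shape[0]), index=ffq.sample_ids, name="ca1")
        return scores, np.array([])
    # row principal coordinates: D_r^{-1/2} U S
    rows = (u / np.sqrt(r)[:, None]) * sv
    cols = (vt.T / np.sqrt(c)[:, None]) * sv
    if cols[np.argmax(c), 0] < 0:
        rows[:, 0] = -rows[:, 0]
        cols[:, 0] = -cols[:, 0]
    inertia = sv ** 2
    scores = pd.Series(rows[:, 0], index=ffq.sample_ids, name="ca1")
    return scores, inertia / inertia.sum()


def total_inertia(ffq: FeatureTable) -> float:
    """Total CA inertia; times the grand total this is the chi-square statistic."""
    X = ffq.values()
    total = X.sum()
    P = X / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    E = np.outer(r, c)
    return float((((P - E) ** 2) / E).sum())


def dietary_groups(axis_scores: pd.Series, k: int = 3) -> DietAssignment:
    """1-D Ward clustering of CA axis-1 scores into D1..Dk (ordered by mean)."""
    n = len(axis_scores)
    if k < 2:
        raise ValidationError("need k >= 2 dietary groups")
    if k > n:
        raise ValidationError(f"k={k} exceeds sample count {n}")
    x = axis_scores.to_numpy(dtype=float)[:, None]
    linkage = sch.linkage(x, method="ward", metric="euclidean")
    raw = sch.fcluster(linkage, k, criterion="maxclust")
    means = {g: axis_scores[raw == g].mean() for g in np.unique(raw)}
    order = sorted(means, key=means.get)
    rename = {g: f"D{i + 1}" for i, g in enumerate(order)}
    labels = pd.Series([rename[g] for g in raw], index=axis_scores.index, name="diet_group")
    return DietAssignment(labels=labels, axis_scores=axis_scores, inertia_share=np.array([]))


def hfd_index(ffq: FeatureTable, annotations: pd.DataFrame) -> pd.Series:
    """Healthy Food Diversity index per sample.

    shares s_i = consumption shares; Berry index BI = 1 - sum s_i^2;
    mean health value hv_bar = sum hv_i s_i; HFD = hv_bar * BI.
    Samples with zero total consumption are NaN (flagged, not dropped).
    """
    missing = [f for f in ffq.feature_ids if f not in annotations.index]
    if missing:
        raise ValidationError(f"foods without annotations: {missing}")
    hv = annotations.loc[ffq.feature_ids, "health_value"].to_numpy(dtype=float)
    if ((hv < 0) | (hv > 1)).any():
        raise ValidationError("health values must lie in [0, 1]")
    X = ffq.values()
    totals = X.sum(axis=1)
    out = np.full(len(totals), np.nan)
    ok = totals > 0
    shares = X[ok] / totals[ok, None]
    berry = 1.0 - (shares ** 2).sum(axis=1)
    hv_bar = shares @ hv
    out[ok] = hv_bar * berry
    return pd.Series(out, index=ffq.sample_ids, name="hfd")


def nutrient_summaries(ffq: FeatureTable, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample energy, fiber density (g / 1000 kcal), and macro shares.

    Macro energy shares use 4/4/9 kcal per gram of protein/carb/fat and are
    expressed as a percentage of macro energy.  Zero-energy samples get NaN
    fiber density and shares.
    """
    missing = [f for f in ffq.feature_ids if f not in annotations.index]
    if missing:
        raise ValidationError(f"foods without annotations: {missing}")
    ann = annotations.loc[ffq.feature_ids]
    X = ffq.values()
    kcal = X @ ann["kcal"].to_numpy(dtype=float)
    fiber = X @ ann["fiber_g"].to_numpy(dtype=float)
    prot = X @ ann["protein_g"].to_numpy(dtype=float)
    carb = X @ ann["carb_g"].to_numpy(dtype=float)
    fat = X @ ann["fat_g"].to_numpy(dtype=float)
    macro_kcal = 4 * prot + 4 * carb + 9 * fat
    with np.errstate(divide="ignore", invalid="ignore"):
        fiber_density = np.where(kcal > 0, fiber / (kcal / 1000.0), np.nan)
        prot_share = np.where(macro_kcal > 0, 100 * 4 * prot / macro_kcal, np.nan)
        carb_share = np.where(macro_kcal > 0, 100 * 4 * carb / macro_kcal, np.nan)
        fat_share = np.where(macro_kcal > 0, 100 * 9 * fat / macro_kcal, np.nan)
    return pd.DataFrame(
        {
            "energy_kcal": kcal,
            "fiber_g": fiber,
            "fiber_g_per_1000kcal": fiber_density,
            "protein_pct": prot_share,
            "carb_pct": carb_share,
            "fat_pct": fat_share,
        },
        index=ffq.sample_ids,
    )


def diet_cluster_crosstab(
    diet_labels: pd.Series, cluster_labels: pd.Series, strata: pd.Series | None = None
) -> pd.DataFrame:
    """Diet × microbiome-cluster counts and within-stratum percentages.

    Empty combinations are reported as zero rather than omitted.  When a
    ``strata`` series is given (e.g. weight group or YFAS behavior group),
    per-stratum tables are stacked alongside the overall one.
    """
    shared = diet_labels.index.intersection(cluster_labels.index)
    d = diet_labels.loc[shared]
    c = cluster_labels.loc[shared]
    diet_levels = sorted(d.unique())
    cluster_levels = sorted(c.unique())

    def one(mask: pd.Series, name: str) -> list[dict]:
        dd, cc = d[mask], c[mask]
        total = int(mask.sum())
        rows = []
        for dl in diet_levels:
            for cl in cluster_levels:
                count = int(((dd == dl) & (cc == cl)).sum())
                rows.append(
                    {"diet_group": dl, "cluster": cl, "count": count,
                     "pct": 100.0 * count / total if total else np.nan,
                     "stratum": name}
                )
        return rows

    rows = one(pd.Series(True, index=shared), "all")
    if strata is not None:
        s = strata.reindex(shared)
        for level in sorted(s.dropna().unique()):
            rows.extend(one(s == level, str(level)))
    return pd.DataFrame(rows)
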