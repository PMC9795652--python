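"""Microbiome steady-state typing.

Samples are clustered with Ward linkage on d = 1 - rho, where rho is the
Spearman correlation between their OTU proportion profiles (after a 20%
prevalence filter).  Clusters are validated by requiring that nearly all
within-cluster sample pairs show a BH-significant positive Spearman
correlation, and overall separation is tested with PERMANOVA on the same
distance matrix.  Alpha diversity (Shannon, observed features) and the
generic Kruskal–Wallis / pairwise-Wilcoxon group comparison used across
the pipeline also live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from sklearn.metrics import silhouette_score

from .core import FeatureTable, ValidationError
from .stats import bh_adjust, permanova


@dataclass
class ClusterAssignment:
    """Per-sample steady-state labels plus validity diagnostics."""

    labels: pd.Series                     # sample -> 'C1'..'Ck'
    k: int
    linkage: np.ndarray                   # scipy linkage matrix
    silhouette_by_k: dict[int, float]
    valid_pair_fraction: dict[str, float] | None = None
    cluster_valid: dict[str, bool] | None = None
    manova_f: float | None = None
    manova_p: float | None = None

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.labels.unique())


@dataclass
class AlphaDiversity:
    data: pd.DataFrame  # columns: shannon, observed_features


def prevalence_filter(table: FeatureTable, threshold: float = 0.20) -> FeatureTable:
    """Keep features present (count > 0) in >= ``threshold`` of samples.

    The boundary is inclusive; proportions are NOT re-closed afterwards, so
    retained values still reflect the original composition.
    """
    vals = table.values()
    prevalence = (vals > 0).mean(axis=0)
    keep = [f for f, p in zip(table.feature_ids, prevalence) if p >= threshold]
    if not keep:
        raise ValidationError(
            f"prevalence filter at {threshold} removed every feature; lower the threshold"
        )
    return table.subset_features(keep)


def spearman_matrix(table: FeatureTable) -> pd.DataFrame:
    """Sample × sample Spearman correlation of abundance profiles.

    Average ranks for ties; a constant profile has no rank variance and is
    rejected by name.
    """
    vals = table.values()
    if vals.shape[1] < 3:
        raise ValidationError("need >= 3 features for a meaningful Spearman matrix")
    const = vals.std(axis=1) == 0
    if const.any():
        bad = [s for s, c in zip(table.sample_ids, const) if c]
        raise ValidationError(f"constant abundance profile(s), correlation undefined: {bad}")
    ranks = np.apply_along_axis(ss.rankdata, 1, vals)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.sample_ids, columns=table.sample_ids)


def correlation_distance(corr: pd.DataFrame) -> np.ndarray:
    """d = 1 - rho, zeroed diagonal, symmetrized against roundoff."""
    d = 1.0 - corr.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def ward_cluster_samples(
    corr: pd.DataFrame, k: int | None = None, max_k: int = 8
) -> ClusterAssignment:
    """Ward-linkage clustering of samples on d = 1 - rho.

    When ``k`` is None the cut is chosen to maximize the mean silhouette on
    the same distance matrix over k = 2..max_k; the full linkage is kept so
    any other cut can be taken.  Labels are C1..Ck in order of first
    appearance along the sample list.
    """
    samples = list(corr.index)
    n = len(samples)
    if k is not None and k > n:
        raise ValidationError(f"k={k} exceeds sample count {n}")
    d = correlation_distance(corr)
    condensed = d[np.triu_indices(n, 1)]
    linkage = sch.linkage(condensed, method="ward")

    sil: dict[int, float] = {}
    for kk in range(2, min(max_k, n - 1) + 1):
        lab = sch.fcluster(linkage, kk, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[kk] = float(silhouette_score(d, lab, metric="precomputed"))
    chosen = k if k is not None else max(sil, key=sil.get)
    raw = sch.fcluster(linkage, chosen, criterion="maxclust")

    # stable C1..Ck naming: order of first appearance
    mapping: dict[int, str] = {}
    for r in raw:
        if r not in mapping:
            mapping[r] = f"C{len(mapping) + 1}"
    labels = pd.Series([mapping[r] for r in raw], index=samples, name="cluster")
    return ClusterAssignment(labels=labels, k=int(chosen), linkage=linkage, silhouette_by_k=sil)


def validate_clusters_bh(
    table: FeatureTable,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
    valid_fraction: float = 0.95,
) -> ClusterAssignment:
    """Within-cluster pairwise Spearman tests with joint BH correction.

    A cluster is flagged valid when >= ``valid_fraction`` of its sample
    pairs have BH-adjusted p <= alpha with rho > 0.  Singleton clusters are
    flagged (vacuously invalid) and excluded from testing.
    """
    vals = table.data
    pairs: list[tuple[str, int, float, float]] = []  # cluster, pair idx, rho, p
    for cl in assignment.cluster_ids:
        members = assignment.labels.index[assignment.labels == cl]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rho, p = ss.spearmanr(vals.loc[members[i]], vals.loc[members[j]])
                pairs.append((cl, len(pairs), float(rho), float(p)))
    if pairs:
        padj = bh_adjust([p for _, _, _, p in pairs])
    frac: dict[str, float] = {}
    valid: dict[str, bool] = {}
    for cl in assignment.cluster_ids:
        idx = [i for i, (c, _, _, _) in enumerate(pairs) if c == cl]
        if not idx:
            frac[cl] = 0.0
            valid[cl] = False
            continue
        ok = [(padj[i] <= alpha) and (pairs[i][2] > 0) for i in idx]
        frac[cl] = float(np.mean(ok))
        valid[cl] = frac[cl] >= valid_fraction
    assignment.valid_pair_fraction = frac
    assignment.cluster_valid = valid
    return assignment


def typing_permanova(
    corr: pd.DataFrame, assignment: ClusterAssignment, n_perm: int = 999, seed: int = 0
) -> ClusterAssignment:
    """PERMANOVA on the Spearman distance matrix against the cluster labels."""
    d = correlation_distance(corr)
    f, p = permanova(d, assignment.labels.loc[corr.index].to_numpy(), n_perm=n_perm, seed=seed)
    assignment.manova_f = f
    assignment.manova_p = p
    return assignment


def alpha_diversity(table: FeatureTable, log_base: float = 2.0) -> AlphaDiversity:
    """Shannon index (base-2 by default) and observed-feature counts."""
    vals = table.values()
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValidationError(f"all-zero sample(s): {bad}")
    p = vals / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(log_base)
    observed = (vals > 0).sum(axis=1)
    return AlphaDiversity(
        pd.DataFrame(
            {"shannon": shannon, "observed_features": observed}, index=table.sample_ids
        )
    )


def group_compare(values: pd.Series, groups: pd.Series, posthoc: bool = True) -> dict:
    """Kruskal–Wallis omnibus plus BH-adjusted pairwise Wilcoxon rank-sum.

    Complete-case: samples with missing values are dropped (N reported per
    group).  Wilcoxon uses the exact distribution for small tie-free
    samples (n <= 25 per group) and the continuity-corrected normal
    approximation otherwise.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValidationError("group_compare needs >= 2 groups")
    by_group = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in levels}
    for g, v in by_group.items():
        if v.size == 0:
            raise ValidationError(f"group {g!r} is empty")
    kw_stat, kw_p = ss.kruskal(*by_group.values())

    report: dict = {
        "n": {g: int(v.size) for g, v in by_group.items()},
        "median": {g: float(np.median(v)) for g, v in by_group.items()},
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": None,
    }
    if posthoc:
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a, b = by_group[levels[i]], by_group[levels[j]]
                small = max(a.size, b.size) <= 25
                ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
                method = "exact" if (small and not ties) else "asymptotic"
                res = ss.mannwhitneyu(a, b, alternative="two-sided", method=method)
                rows.append({"group_a": levels[i], "group_b": levels[j], "p": float(res.pvalue)})
        padj = bh_adjust([r["p"] for r in rows])
        for r, q in zip(rows, padj):
            r["p_adj"] = float(q)
        report["pairwise"] = pd.DataFrame(rows)
    return report
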