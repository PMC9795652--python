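"""Genus co-abundance groups (CAGs) and Wiggum-plot statistics.

Edges of the co-abundance network are positive Kendall tau-b correlations
between genus profiles that survive a q-value FDR gate; the CAG partition
itself comes from Ward clustering of 1 - Spearman rho between genus
profiles (the two metrics are deliberately kept distinct — edges via
Kendall, grouping via Spearman).  Each CAG is named for its most abundant
genus cohort-wide.  Disc sizes for the Wiggum rendering are per-cluster
over-abundance ratios relative to the cohort mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .core import FeatureTable, ValidationError
from .stats import qvalues


@dataclass
class CagPartition:
    genus_to_cag: dict[str, int]
    cag_names: dict[int, str]          # cag id -> dominant genus
    edges: pd.DataFrame                # genus_a, genus_b, tau, p, q (tau>0, q<=alpha)
    all_pairs: pd.DataFrame            # every tested pair, unfiltered
    disc_sizes: pd.DataFrame | None = None  # genus × cluster over-abundance


def genus_from_taxonomy(table: FeatureTable) -> FeatureTable:
    """Collapse an OTU table to genus level using its taxonomy strings.

    Genus is taken from the ``g__`` field of the lineage; OTUs without one
    are pooled under ``unclassified``.
    """
    if not table.taxonomy:
        raise ValidationError("OTU table has no taxonomy annotations")
    groups: dict[str, list[str]] = {}
    for otu in table.feature_ids:
        lineage = table.taxonomy.get(otu, "")
        genus = "unclassified"
        for field in lineage.split(";"):
            field = field.strip()
            if field.startswith("g__") and len(field) > 3:
                genus = field[3:]
        groups.setdefault(genus, []).append(otu)
    data = {g: table.data[cols].sum(axis=1) for g, cols in groups.items()}
    return FeatureTable(pd.DataFrame(data, index=table.sample_ids), level="genus")


def filter_genera(
    table: FeatureTable, rel_threshold: float = 0.001, min_samples: int = 2
) -> FeatureTable:
    """Keep genera exceeding ``rel_threshold`` (strict >) in >= min_samples samples."""
    rel = table if table.is_relative else table.relative()
    above = (rel.values() > rel_threshold).sum(axis=0)
    keep = [g for g, n in zip(rel.feature_ids, above) if n >= min_samples]
    if len(keep) < 3:
        raise ValidationError(
            f"only {len(keep)} genera pass the abundance filter; need >= 3"
        )
    return rel.subset_features(keep)


def kendall_network(table: FeatureTable, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Kendall tau-b with q-value FDR; returns (retained edges, all pairs).

    Retained edges satisfy tau > 0 and q <= alpha.  Pairs involving a
    constant genus are flagged undefined and never retained.
    """
    if table.n_samples < 4:
        raise ValidationError("Kendall network needs >= 4 samples")
    genera = table.feature_ids
    vals = table.values()
    const = vals.std(axis=0) == 0
    rows = []
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            if const[i] or const[j]:
                rows.append({"genus_a": genera[i], "genus_b": genera[j],
                             "tau": np.nan, "p": np.nan, "defined": False})
                continue
            tau, p = ss.kendalltau(vals[:, i], vals[:, j])
            rows.append({"genus_a": genera[i], "genus_b": genera[j],
                         "tau": float(tau), "p": float(p), "defined": True})
    pairs = pd.DataFrame(rows)
    defined = pairs["defined"].to_numpy()
    q = np.full(len(pairs), np.nan)
    if defined.any():
        q[defined] = qvalues(pairs.loc[defined, "p"].to_numpy())
    pairs["q"] = q
    edges = pairs[(pairs["tau"] > 0) & (pairs["q"] <= alpha) & pairs["defined"]].reset_index(
        drop=True
    )
    return edges, pairs


def assign_cags(
    table: FeatureTable, k: int = 5, alpha: float = 0.05,
    edges: pd.DataFrame | None = None, all_pairs: pd.DataFrame | None = None,
) -> CagPartition:
    """Partition genera into k CAGs by Ward linkage on 1 - Spearman rho.

    Each CAG is named after its member genus with the highest cohort-mean
    relative abundance.  Pass precomputed ``edges``/``all_pairs`` to skip
    re-running the Kendall stage.
    """
    genera = table.feature_ids
    if k > len(genera):
        raise ValidationError(f"k={k} exceeds genus count {len(genera)}")
    if edges is None or all_pairs is None:
        edges, all_pairs = kendall_network(table, alpha=alpha)
    rho, _ = ss.spearmanr(table.values())
    rho = np.atleast_2d(rho)
    d = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    condensed = (d + d.T)[np.triu_indices(len(genera), 1)] / 2.0
    linkage = sch.linkage(condensed, method="ward")
    raw = sch.fcluster(linkage, k, criterion="maxclust")

    mean_abund = table.values().mean(axis=0)
    cag_names: dict[int, str] = {}
    for cag_id in np.unique(raw):
        members = np.flatnonzero(raw == cag_id)
        dominant = genera[members[np.argmax(mean_abund[members])]]
        cag_names[int(cag_id)] = dominant
    genus_to_cag = {g: int(c) for g, c in zip(genera, raw)}
    return CagPartition(genus_to_cag=genus_to_cag, cag_names=cag_names,
                        edges=edges, all_pairs=all_pairs)


def wiggum_stats(
    table: FeatureTable, clusters: pd.Series, partition: CagPartition
) -> pd.DataFrame:
    """Per-(genus, cluster) disc size = cluster mean / cohort mean rel. abundance.

    Genera absent cohort-wide are excluded.  Disc = 1 when a cluster's mean
    matches the cohort's; 0 when the genus is absent from the cluster.
    """
    shared = [s for s in table.sample_ids if s in clusters.index]
    if not shared:
        raise ValidationError("no shared samples between table and cluster assignment")
    sub = table.data.loc[shared]
    labels = clusters.loc[shared]
    cohort_mean = sub.mean(axis=0)
    present = cohort_mean[cohort_mean > 0].index
    rows = {}
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        rows[cl] = sub.loc[members, present].mean(axis=0) / cohort_mean[present]
    disc = pd.DataFrame(rows)
    disc.index.name = "genus"
    partition.disc_sizes = disc
    return disc


def network_graphml(partition: CagPartition, path) -> None:
    """Export the FDR-gated positive-edge network with CAG annotations."""
    g = nx.Graph()
    for genus, cag_id in partition.genus_to_cag.items():
        g.add_node(genus, cag=cag_id, cag_name=partition.cag_names[cag_id])
    for _, row in partition.edges.iterrows():
        g.add_edge(row["genus_a"], row["genus_b"], tau=float(row["tau"]), q=float(row["q"]))
    nx.write_graphml(g, path)


def cag_permanova(table: FeatureTable, partition: CagPartition, n_perm: int = 999,
                  seed: int = 0) -> tuple[float, float]:
    """PERMANOVA over genera: Kendall distance (1 - tau) vs CAG labels."""
    from .stats import permanova

    genera = table.feature_ids
    vals = table.values()
    n = len(genera)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau, _ = ss.kendalltau(vals[:, i], vals[:, j])
            d[i, j] = d[j, i] = 1.0 - (tau if np.isfinite(tau) else 0.0)
    labels = np.array([partition.genus_to_cag[g] for g in genera])
    return permanova(d, labels, n_perm=n_perm, seed=seed)
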