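"""DNA-normalized transcription: RNA:DNA ratios and derived summaries.

Transcript abundances are divided by the matching gene (DNA) abundances so
expression is quantified independently of gene copy number.  Downstream:
per-cluster log2 over-abundance of each species-stratified feature, the
"active species" rule (log2 > 1 in at least a third of a metabolic
category's pathways), and cluster-vs-cohort mean ratios for a panel of key
KO gene families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from math import ceil

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .core import PairedOmicsTable, ValidationError

log = logging.getLogger("microtype")

#: KO gene families highlighted in the cluster heatmap (bile-salt hydrolase
#: K01442, 7alpha-HSDH K00076, cholesterol-associated K07007/K03778,
#: pyruvate:ferredoxin oxidoreductases K00170/K00172, tryptophanase K01667,
#: carboxylesterase K01046, ABC transporter K01995, glutamate decarboxylase K01580)
DEFAULT_KO_PANEL = (
    "K01442", "K00076", "K07007", "K03778", "K00170",
    "K00172", "K01667", "K01046", "K01995", "K01580",
)


@dataclass
class ActivityTable:
    """Per-(feature, sample) RNA:DNA ratios with the zero-DNA side table."""

    ratios: pd.DataFrame          # features × samples; NaN = undefined
    rna_only: pd.DataFrame        # rows where DNA = 0 but RNA > 0 (flagged)
    cluster_log2: pd.DataFrame | None = None
    active_counts: pd.DataFrame | None = None


def default_category_map() -> dict[str, str]:
    """Packaged pathway -> metabolic-category map (overridable)."""
    text = resources.files("microtype.data").joinpath("kegg_categories.tsv").read_text()
    out = {}
    for line in text.strip().splitlines()[1:]:
        pathway, category = line.split("\t")
        out[pathway] = category
    return out


def rna_dna_normalize(paired: PairedOmicsTable, pseudocount: float = 0.0) -> ActivityTable:
    """RNA:DNA ratio per (feature, sample).

    Policy: DNA = 0 and RNA = 0 -> undefined (NaN, excluded); DNA = 0 and
    RNA > 0 -> undefined but recorded in the ``rna_only`` side table; a
    smoothing pseudocount (added to both numerator and denominator) is off
    by default.
    """
    rna = paired.rna.data.T.to_numpy(dtype=float)   # features × samples
    dna = paired.dna.data.T.to_numpy(dtype=float)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount > 0:
        ratios = (rna + pseudocount) / (dna + pseudocount)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(dna > 0, rna / np.where(dna > 0, dna, 1.0), np.nan)
    keys = paired.keys
    samples = paired.rna.sample_ids
    ratio_df = pd.DataFrame(ratios, index=keys, columns=samples)

    flag = (dna == 0) & (rna > 0)
    rows = []
    for i, j in np.argwhere(flag):
        rows.append({"feature": keys[i], "sample": samples[j], "rna": rna[i, j]})
    rna_only = pd.DataFrame(rows, columns=["feature", "sample", "rna"])
    return ActivityTable(ratios=ratio_df, rna_only=rna_only)


def log2_overabundance(activity: ActivityTable, clusters: pd.Series) -> pd.DataFrame:
    """log2(cluster mean ratio / cohort mean ratio) per feature × cluster.

    Means ignore undefined ratios.  A pseudocount of half the smallest
    nonzero ratio is added to both terms so features silent in a cluster
    stay finite.
    """
    ratios = activity.ratios
    shared = [s for s in ratios.columns if s in clusters.index]
    ratios = ratios[shared]
    labels = clusters.loc[shared]
    cohort_mean = ratios.mean(axis=1, skipna=True)
    defined = cohort_mean.dropna()
    nonzero = ratios.to_numpy()
    nonzero = nonzero[np.isfinite(nonzero) & (nonzero > 0)]
    eps = 0.5 * nonzero.min() if nonzero.size else 1e-9
    out = {}
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        cl_mean = ratios[members].mean(axis=1, skipna=True)
        out[cl] = np.log2((cl_mean.loc[defined.index] + eps) / (defined + eps))
    result = pd.DataFrame(out)
    activity.cluster_log2 = result
    return result


def count_active_species(
    cluster_log2: pd.DataFrame, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Active-species counts per (cluster, metabolic category).

    A species is active in a category within a cluster when its log2
    over-abundance exceeds 1 (strict) in at least ceil(m/3) of the
    category's m pathways.  Features must be keyed ``pathway|species``;
    unstratified rows are ignored.  Rows with undefined log2 never count.
    """
    if category_map is None:
        category_map = default_category_map()
    records = []
    for key in cluster_log2.index:
        pathway, species = PairedOmicsTable.split_key(key)
        if species is None or pathway not in category_map:
            continue
        records.append((pathway, species, category_map[pathway], key))
    if not records:
        log.warning("count_active_species: no stratified features matched the category map")
        return pd.DataFrame()
    meta = pd.DataFrame(records, columns=["pathway", "species", "category", "key"])
    clusters = list(cluster_log2.columns)
    rows = []
    for category, sub in meta.groupby("category"):
        m = sub["pathway"].nunique()
        if m == 0:
            continue
        need = ceil(m / 3)
        for cl in clusters:
            active = 0
            for species, ssub in sub.groupby("species"):
                vals = cluster_log2.loc[ssub["key"], cl]
                n_over = int((vals > 1).sum())  # NaN never counts
                if n_over >= need:
                    active += 1
            rows.append({"cluster": cl, "category": category, "active_species": active,
                         "n_pathways": m, "threshold_pathways": need})
    return pd.DataFrame(rows)


def ko_panel_ratios(
    paired: PairedOmicsTable,
    clusters: pd.Series,
    panel: tuple[str, ...] = DEFAULT_KO_PANEL,
) -> pd.DataFrame:
    """Cluster mean RNA:DNA ratio over cohort mean, per (KO, species).

    Rows are ordered by Ward clustering on 1 - Spearman rho between the
    features' DNA-normalized transcript profiles.  KOs absent from the
    input are reported missing (logged), not fatal.
    """
    if not panel:
        log.warning("ko_panel_ratios: empty panel")
        return pd.DataFrame()
    activity = rna_dna_normalize(paired)
    ratios = activity.ratios
    keys = [k for k in ratios.index if PairedOmicsTable.split_key(k)[0] in panel
            and PairedOmicsTable.split_key(k)[1] is not None]
    found = {PairedOmicsTable.split_key(k)[0] for k in keys}
    missing = [ko for ko in panel if ko not in found]
    if missing:
        log.warning("ko_panel_ratios: panel ids absent from input: %s", missing)
    if not keys:
        return pd.DataFrame()
    shared = [s for s in ratios.columns if s in clusters.index]
    sub = ratios.loc[keys, shared]
    labels = clusters.loc[shared]
    cohort_mean = sub.mean(axis=1, skipna=True)
    out = {}
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[cl] = sub[members].mean(axis=1, skipna=True) / cohort_mean
    table = pd.DataFrame(out)

    if len(keys) > 2:
        rho = sub.fillna(0.0).T.corr(method="spearman").to_numpy()
        rho = np.nan_to_num(rho, nan=0.0)
        d = np.clip(1 - (rho + rho.T) / 2, 0, None)
        np.fill_diagonal(d, 0.0)
        link = sch.linkage(d[np.triu_indices(len(keys), 1)], method="ward")
        order = sch.leaves_list(link)
        table = table.iloc[order]
    return table
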