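"""End-to-end pipeline: chains every stage and writes one result directory.

Stage order: typing -> ordination -> CAG -> diet -> activity -> sPLS ->
associations.  All outputs are machine-readable TSV/JSON plus a run
manifest capturing the seed and thresholds.  Sample-id mismatches between
inputs are a hard error reporting the symmetric difference.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import assoc, cag, community, diet, ordination, spls
from .core import AnalysisConfig, FeatureTable, PairedOmicsTable, SampleMetadata
from .io import check_shared_samples, write_manifest

log = logging.getLogger("microtype")


def run_pipeline(
    config: AnalysisConfig,
    otu_table: FeatureTable,
    tree,
    metadata: SampleMetadata,
    out_dir: str | Path,
    genus: FeatureTable | None = None,
    ffq: FeatureTable | None = None,
    food_annotations: pd.DataFrame | None = None,
    lipids: FeatureTable | None = None,
    paired: PairedOmicsTable | None = None,
) -> dict:
    """Run all configured stages; returns the results bundle.

    Optional inputs (genus table, FFQ, lipids, paired RNA/DNA) switch their
    stages on; the typing and ordination stages always run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    required = [(otu_table, "otu_table"), (metadata, "metadata")]
    for tbl, name in ((genus, "genus"), (ffq, "ffq"), (lipids, "lipids")):
        if tbl is not None:
            required.append((tbl, name))
    if paired is not None:
        required.append((paired.rna, "rna"))
    check_shared_samples(*required)
    results: dict = {}
    seed = config.rng_seed

    # --- typing ---------------------------------------------------------
    rel = otu_table.relative()
    filtered = community.prevalence_filter(rel, config.prevalence_threshold)
    corr = community.spearman_matrix(filtered)
    assignment = community.ward_cluster_samples(corr, k=config.n_clusters,
                                                max_k=config.max_clusters)
    community.validate_clusters_bh(filtered, assignment, alpha=config.fdr_alpha,
                                   valid_fraction=config.bh_valid_pair_fraction)
    community.typing_permanova(corr, assignment, n_perm=config.n_permutations, seed=seed)
    alpha_div = community.alpha_diversity(otu_table, log_base=config.shannon_log_base)
    results["clusters"] = assignment
    results["alpha_diversity"] = alpha_div
    assignment.labels.rename("cluster").to_frame().to_csv(out / "cluster_assignments.tsv", sep="\t")
    alpha_div.data.to_csv(out / "alpha_diversity.tsv", sep="\t")
    (out / "permanova.json").write_text(json.dumps({
        "pseudo_F": assignment.manova_f, "p": assignment.manova_p,
        "k": assignment.k, "silhouette_by_k": assignment.silhouette_by_k,
        "valid_pair_fraction": assignment.valid_pair_fraction,
    }, indent=2))

    # --- ordination -----------------------------------------------------
    dm_u = ordination.unifrac(rel, tree, weighted=False)
    dm_w = ordination.unifrac(rel, tree, weighted=True,
                              normalized=config.weighted_unifrac_normalized)
    ord_res = ordination.pcoa(dm_u)
    results["unifrac_unweighted"] = dm_u
    results["unifrac_weighted"] = dm_w
    results["ordination"] = ord_res
    dm_u.to_csv(out / "unifrac_unweighted.tsv", sep="\t")
    dm_w.to_csv(out / "unifrac_weighted.tsv", sep="\t")
    ord_res.coordinates.to_csv(out / "pcoa_coords.tsv", sep="\t")
    pd.Series(ord_res.eigenvalues, name="eigenvalue").to_csv(out / "pcoa_eigs.tsv", sep="\t")
    if ffq is not None:
        env = ordination.envfit_vectors(ord_res, ffq.data, n_perm=config.n_permutations,
                                        seed=seed, alpha=config.fdr_alpha)
        env.to_csv(out / "envfit.tsv", sep="\t")
        results["envfit"] = env

    # --- CAG ------------------------------------------------------------
    if genus is None and otu_table.taxonomy:
        genus = cag.genus_from_taxonomy(otu_table)
    if genus is not None:
        gen_filtered = cag.filter_genera(genus, config.genus_rel_abund_threshold,
                                         config.genus_min_samples)
        partition = cag.assign_cags(gen_filtered, k=config.n_cags, alpha=config.fdr_alpha)
        disc = cag.wiggum_stats(gen_filtered, assignment.labels, partition)
        results["cags"] = partition
        pd.Series(partition.genus_to_cag, name="cag").to_frame().assign(
            cag_name=lambda d: d["cag"].map(partition.cag_names)
        ).to_csv(out / "cag_assignments.tsv", sep="\t")
        disc.to_csv(out / "wiggum_stats.tsv", sep="\t")
        cag.network_graphml(partition, out / "edges.graphml")

    # --- diet -----------------------------------------------------------
    if ffq is not None and food_annotations is not None:
        scores, inertia = diet.correspondence_axis(ffq)
        diet_assign = diet.dietary_groups(scores, k=config.n_diet_groups)
        diet_assign.inertia_share = inertia
        hfd = diet.hfd_index(ffq, food_annotations)
        nutrients = diet.nutrient_summaries(ffq, food_annotations)
        crosstab = diet.diet_cluster_crosstab(
            diet_assign.labels, assignment.labels,
            strata=metadata.data.get("weight_group"),
        )
        results["diet"] = diet_assign
        results["hfd"] = hfd
        results["nutrients"] = nutrients
        diet_assign.labels.to_frame().assign(ca1=scores).to_csv(out / "diet_groups.tsv", sep="\t")
        hfd.to_frame().to_csv(out / "hfd.tsv", sep="\t")
        nutrients.to_csv(out / "nutrients.tsv", sep="\t")
        crosstab.to_csv(out / "diet_cluster_crosstab.tsv", sep="\t", index=False)

    # --- activity -------------------------------------------------------
    if paired is not None:
        act = activity_mod.rna_dna_normalize(paired)
        log2 = activity_mod.log2_overabundance(act, assignment.labels)
        active = activity_mod.count_active_species(log2)
        panel = activity_mod.ko_panel_ratios(paired, assignment.labels)
        results["activity"] = act
        act.ratios.to_csv(out / "activity_ratios.tsv", sep="\t")
        log2.to_csv(out / "cluster_log2.tsv", sep="\t")
        if not active.empty:
            active.to_csv(out / "active_counts.tsv", sep="\t", index=False)
        if not panel.empty:
            panel.to_csv(out / "ko_panel.tsv", sep="\t")
        results["active_counts"] = active
        results["ko_panel"] = panel

    # --- sPLS -----------------------------------------------------------
    if paired is not None and lipids is not None:
        act = results["activity"]
        x_raw = FeatureTable(act.ratios.T.fillna(0.0), level="pathway")
        x_filtered = spls.prevalence_filter_features(x_raw, 0.5)
        # drop zero-variance features (constant after filtering)
        keep = x_filtered.data.std(axis=0) > 0
        X = x_filtered.data.loc[:, keep]
        model = spls.spls_fit(X, lipids.data, n_components=config.spls_n_components,
                              keep_x=config.spls_keep_x)
        heat = spls.spls_cluster(model)
        results["spls"] = model
        model.x_loadings.to_csv(out / "spls_loadings_x.tsv", sep="\t")
        model.y_loadings.to_csv(out / "spls_loadings_y.tsv", sep="\t")
        model.x_scores.to_csv(out / "spls_scores.tsv", sep="\t")
        heat["matrix"].to_csv(out / "spls_heatmap_order.tsv", sep="\t")

    # --- associations ---------------------------------------------------
    qa = assoc.quantile_assoc(
        metadata.data, results["ordination"].coordinates,
        variables=[v for v in ("bite_symptom", "tfeq_ue", "tfeq_cr", "tfeq_ee",
                               "bite_severity", "pss", "bmi")
                   if v in metadata.data.columns],
        alpha=config.fdr_alpha,
    )
    qa.to_csv(out / "associations.tsv", sep="\t", index=False)
    clinical = assoc.clinical_indices(metadata)
    clinical.to_csv(out / "derived_clinical.csv")
    results["associations"] = qa
    results["clinical"] = clinical

    cat_tests = {}
    if "weight_group" in metadata.data.columns:
        wt = metadata.data["weight_group"]
        table = pd.crosstab(wt, assignment.labels.loc[wt.index]).to_numpy()
        fisher = assoc.fisher_2xk(table, seed=seed)
        cat_tests["weight_by_cluster_fisher"] = fisher
        ir = clinical["insulin_resistant"].map({True: "IR", False: "IS"})
        ct = pd.crosstab(ir, wt)
        if ct.shape == (2, 2):
            cat_tests["ir_by_weight_cramers_v"] = assoc.cramers_v(ct.to_numpy())
        results["categorical_tests"] = cat_tests
        (out / "categorical_tests.json").write_text(json.dumps(cat_tests, indent=2))
    if {"yfas_symptoms", "yfas_diagnosis", "weight_group"} <= set(metadata.data.columns):
        behavior = assoc.yfas_stratify(metadata)
        behavior.to_frame().to_csv(out / "behavior_groups.tsv", sep="\t")
        results["behavior_groups"] = behavior

    write_manifest(out / "run_manifest.json", seed=seed,
                   config={k: v for k, v in vars(config).items() if k != "paths"})
    log.info("pipeline complete: %s", out)
    return results
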