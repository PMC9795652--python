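"""Ground-truth consistency of the synthetic cohort generator."""

import itertools

import numpy as np
import pytest
import scipy.stats as ss
from sklearn.metrics import adjusted_rand_score

from microtype.core import ValidationError
from microtype.diet import correspondence_axis, dietary_groups
from microtype.synth import (
    SynthConfig,
    _resolve_expression_multipliers,
    simulate_abundances,
    simulate_ffq,
    simulate_lipidome,
    simulate_metadata,
    simulate_transcriptome,
    simulate_tree,
)

SMALL = dict(n_genera=10, otus_per_genus=(2, 3), n_samples=40)


class TestTree:
    def test_leaf_count_matches_otu_map(self):
        tree, otu_genus = simulate_tree(SynthConfig(rng_seed=0, **SMALL))
        assert len(list(tree.tips())) == len(otu_genus)

    def test_genus_monophyly(self):
        tree, otu_genus = simulate_tree(SynthConfig(rng_seed=0, **SMALL))
        for genus in set(otu_genus.values()):
            otus = [o for o, g in otu_genus.items() if g == genus]
            lca = tree.lca(otus)
            clade = {t.name for t in lca.tips()}
            assert clade == set(otus), f"{genus} is not monophyletic"

    def test_same_seed_identical_newick(self):
        t1, _ = simulate_tree(SynthConfig(rng_seed=7, **SMALL))
        t2, _ = simulate_tree(SynthConfig(rng_seed=7, **SMALL))
        assert str(t1) == str(t2)


class TestAbundances:
    def test_zero_multiplier_silences_block(self, cohort, truth):
        rel = cohort["otu_table"].relative()
        bif_otus = [o for o, g in truth.otu_genus.items()
                    if truth.genus_block[g] == "Bifidobacterium"]
        c2 = truth.cluster.index[truth.cluster == "C2"]
        c1 = truth.cluster.index[truth.cluster == "C1"]
        mean_c2 = rel.data.loc[c2, bif_otus].to_numpy().sum(axis=1).mean()
        mean_c1 = rel.data.loc[c1, bif_otus].to_numpy().sum(axis=1).mean()
        assert mean_c2 < 0.05 * mean_c1

    def test_within_block_kendall_exceeds_between(self, cohort, truth):
        from microtype.synth import genus_table

        g = genus_table(cohort["otu_table"], truth.otu_genus)
        vals = g.values()
        genera = g.feature_ids
        within, between = [], []
        for i, j in itertools.combinations(range(len(genera)), 2):
            tau, _ = ss.kendalltau(vals[:, i], vals[:, j])
            same = truth.genus_block[genera[i]] == truth.genus_block[genera[j]]
            (within if same else between).append(tau)
        assert np.mean(within) > np.mean(between)

    def test_shannon_ordering_c1_above_c2(self, cohort, truth):
        from microtype.community import alpha_diversity

        sh = alpha_diversity(cohort["otu_table"]).data["shannon"]
        assert sh.groupby(truth.cluster).mean()["C1"] > sh.groupby(truth.cluster).mean()["C2"]


class TestMetadata:
    def test_diagnosis_requires_three_symptoms(self, cohort):
        md = cohort["metadata"].data
        assert not ((md["yfas_diagnosis"]) & (md["yfas_symptoms"] < 3)).any()

    def test_weight_groups_follow_cluster_probabilities(self, truth, cohort):
        md = cohort["metadata"].data
        nw_frac = (md["weight_group"] == "NW").groupby(truth.cluster).mean()
        # C1 planted at 48% NW, C2 at 28%: order should hold with n~30 each
        assert nw_frac["C1"] > nw_frac["C2"]

    def test_null_slope_gives_unrelated_scores(self):
        cfg = SynthConfig(rng_seed=3, ue_slope=0.0, bite_slope=0.0)
        from microtype.synth import simulate_cohort

        cohort = simulate_cohort(cfg)
        md = cohort["metadata"].data
        pco2 = cohort["ordination"].coordinates["PCo2"]
        r, p = ss.pearsonr(md["tfeq_ue"], pco2.loc[md.index])
        assert p > 0.01  # no planted association


class TestFfq:
    def test_zero_perturbation_recovers_archetypes_exactly(self):
        cfg = SynthConfig(rng_seed=5, ffq_concentration=np.inf)
        from microtype.synth import GroundTruth, simulate_abundances

        table, truth = simulate_abundances(cfg)
        ffq, _ = simulate_ffq(cfg, truth)
        scores, _ = correspondence_axis(ffq)
        assignment = dietary_groups(scores, k=3)
        assert adjusted_rand_score(truth.diet_archetype, assignment.labels) == 1.0

    def test_archetypes_recovered_at_default_noise(self, cohort, truth):
        scores, _ = correspondence_axis(cohort["ffq"])
        assignment = dietary_groups(scores, k=3)
        assert adjusted_rand_score(truth.diet_archetype, assignment.labels) >= 0.8

    def test_annotation_macro_kcal_identity(self, cohort):
        ann = cohort["food_annotations"]
        macro = 4 * ann["protein_g"] + 4 * ann["carb_g"] + 9 * ann["fat_g"]
        np.testing.assert_allclose(ann["kcal"], macro, rtol=1e-3)


class TestLipidome:
    def test_all_positive(self, cohort):
        assert (cohort["lipids"].values() > 0).all()

    def test_planted_scfa_contrast_detected(self, cohort, truth):
        from microtype.community import group_compare

        rep = group_compare(cohort["lipids"].data["butyrate"], truth.cluster)
        assert rep["kruskal_p"] < 0.05

    def test_null_effect_rate(self):
        # no planted effects: KW omnibus should reject at roughly alpha
        rejections = 0
        n_reps = 40
        for seed in range(n_reps):
            cfg = SynthConfig(
                rng_seed=seed, n_samples=60,
                lipid_effects={"acetate": {}, "butyrate": {}, "cholesterol": {}},
            )
            from microtype.synth import GroundTruth, simulate_abundances

            _, truth = simulate_abundances(cfg)
            lip = simulate_lipidome(cfg, truth)
            from microtype.community import group_compare

            rep = group_compare(lip.data["butyrate"], truth.cluster, posthoc=False)
            rejections += rep["kruskal_p"] <= 0.05
        assert rejections / n_reps < 0.25


class TestTranscriptome:
    def test_unit_multipliers_give_unit_ratios(self):
        cfg = SynthConfig(rng_seed=9, expression_targets={}, expression_noise_sd=0.0,
                          **SMALL)
        from microtype.synth import genus_table, simulate_abundances

        table, truth = simulate_abundances(cfg)
        g = genus_table(table, truth.otu_genus).relative()
        paired = simulate_transcriptome(cfg, truth, g)
        rna = paired.rna.values()
        dna = paired.dna.values()
        mask = dna > 0
        np.testing.assert_allclose(rna[mask] / dna[mask], 1.0, atol=1e-9)

    def test_zero_dna_rows_carried_through(self, cohort):
        dna = cohort["paired"].dna.values()
        assert (dna == 0).any()  # zeros present, not dropped

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            _resolve_expression_multipliers(
                {("sp", "p"): {"C2": 4.0, "C3": 4.0}}, (0.31, 0.33, 0.22, 0.14)
            )

    def test_targets_average_to_one(self):
        mult = _resolve_expression_multipliers(
            {("sp", "p"): {"C4": 4.0}}, (0.31, 0.33, 0.22, 0.14)
        )[("sp", "p")]
        weighted = sum(p * mult[c] for p, c in zip((0.31, 0.33, 0.22, 0.14),
                                                   ("C1", "C2", "C3", "C4")))
        assert weighted == pytest.approx(1.0)
        assert mult["C4"] == 4.0


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        from microtype.synth import simulate_cohort

        a = simulate_cohort(SynthConfig(rng_seed=11, **SMALL))
        b = simulate_cohort(SynthConfig(rng_seed=11, **SMALL))
        np.testing.assert_array_equal(a["otu_table"].values(), b["otu_table"].values())
        np.testing.assert_array_equal(a["lipids"].values(), b["lipids"].values())
        assert (a["metadata"].data == b["metadata"].data).all().all()
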