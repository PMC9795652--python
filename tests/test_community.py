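"""Community typing: filtering, correlation, clustering, validation, tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from sklearn.metrics import adjusted_rand_score

from microtype.community import (
    alpha_diversity,
    group_compare,
    prevalence_filter,
    spearman_matrix,
    validate_clusters_bh,
    ward_cluster_samples,
)
from microtype.core import ValidationError
from microtype.stats import bh_adjust, permanova

from conftest import make_table


class TestPrevalenceFilter:
    @pytest.mark.parametrize(
        "present_in,kept",
        [(2, True), (1, False)],  # 2/10 kept at inclusive 20% boundary; 1/10 dropped
    )
    def test_boundary(self, present_in, kept):
        vals = np.zeros((10, 2))
        vals[:, 0] = 1.0
        vals[:present_in, 1] = 1.0
        out = prevalence_filter(make_table(vals), 0.20)
        assert ("F1" in out.feature_ids) is kept

    def test_all_zero_feature_removed(self):
        vals = np.ones((5, 2))
        vals[:, 1] = 0.0
        assert prevalence_filter(make_table(vals), 0.01).feature_ids == ["F0"]

    def test_empty_result_is_error(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValidationError, match="lower the threshold"):
            prevalence_filter(make_table(vals), 1.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 3, size=(20, 30)))
        counts = [prevalence_filter(t, th).n_features for th in (0.1, 0.3, 0.5)]
        assert counts == sorted(counts, reverse=True)


class TestSpearmanMatrix:
    def test_duplicated_sample_rho_one(self):
        t = make_table([[1, 2, 3], [1, 2, 3], [3, 1, 2]])
        rho = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # profiles (1,2,3) vs (2,1,3): rho = 1 - 6*2/(3*8) = 0.5
        rho = spearman_matrix(make_table([[1, 2, 3], [2, 1, 3]]))
        assert rho.iloc[0, 1] == pytest.approx(0.5)

    def test_reversed_ranks(self):
        rho = spearman_matrix(make_table([[1, 2, 3], [3, 2, 1]]))
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValidationError, match="S1"):
            spearman_matrix(make_table([[1, 2, 3], [2, 2, 2]], samples=["S0", "S1"]))


class TestWardClustering:
    def test_two_duplicate_blocks(self):
        rng = np.random.default_rng(1)
        a = rng.random(50)
        b = rng.random(50)
        vals = np.vstack([a] * 5 + [b] * 5) + rng.normal(0, 1e-6, (10, 50))
        rho = spearman_matrix(make_table(vals))
        asn = ward_cluster_samples(rho)
        assert asn.k == 2
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, asn.labels) == 1.0

    def test_k_above_n_rejected(self, cohort):
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError):
            ward_cluster_samples(rho, k=5)

    def test_labels_cover_all_samples(self, cohort):
        from microtype.community import prevalence_filter, spearman_matrix

        rel = cohort["otu_table"].relative()
        rho = spearman_matrix(prevalence_filter(rel, 0.2))
        asn = ward_cluster_samples(rho)
        assert set(asn.labels.index) == set(rel.sample_ids)
        assert asn.k >= 2

    def test_invariant_to_sample_order(self, cohort):
        rel = cohort["otu_table"].relative()
        rho = spearman_matrix(prevalence_filter(rel, 0.2))
        asn1 = ward_cluster_samples(rho, k=4)
        perm = np.random.default_rng(0).permutation(len(rho))
        rho2 = rho.iloc[perm, perm]
        asn2 = ward_cluster_samples(rho2, k=4)
        joined = pd.concat([asn1.labels, asn2.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


class TestClusterValidation:
    def test_identical_samples_fully_valid(self):
        vals = np.tile([3.0, 1.0, 4.0, 1.0, 5.0], (6, 1))
        vals += np.random.default_rng(0).normal(0, 1e-9, vals.shape)
        t = make_table(vals)
        rho = spearman_matrix(t)
        asn = ward_cluster_samples(rho, k=2)
        asn = validate_clusters_bh(t, asn, alpha=0.05)
        assert all(f == 1.0 for f in asn.valid_pair_fraction.values())

    def test_random_profiles_invalid(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.random((8, 200)))
        rho = spearman_matrix(t)
        asn = ward_cluster_samples(rho, k=2)
        asn = validate_clusters_bh(t, asn, alpha=0.05)
        assert not any(asn.cluster_valid.values())

    def test_bh_step_up_hand_example(self):
        # (0.01, 0.02, 0.03, 0.04), m=4 -> all adjusted to 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


class TestPermanova:
    def test_perfect_separation_minimal_p(self):
        # groups of 10 so label permutations recreating the split are
        # vanishingly rare
        d = np.ones((20, 20))
        d[:10, :10] = 0.0
        d[10:, 10:] = 0.0
        np.fill_diagonal(d, 0.0)
        f, p = permanova(d, [0] * 10 + [1] * 10, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_single_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            permanova(d, [0, 0, 0, 0])

    def test_asymmetric_rejected(self):
        d = np.random.default_rng(0).random((4, 4))
        with pytest.raises(ValidationError, match="symmetric"):
            permanova(d, [0, 0, 1, 1])

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(7)
        pts = rng.random((12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        labels = [0, 1, 2] * 4
        f_obs, _ = permanova(d, labels, n_perm=99, seed=0)
        res = skbio_permanova(DistanceMatrix(d), [str(x) for x in labels], permutations=99)
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-9)

    def test_pseudo_f_invariant_to_relabeling(self):
        rng = np.random.default_rng(2)
        pts = rng.random((10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        f1, _ = permanova(d, labels, n_perm=99, seed=1)
        f2, _ = permanova(d, np.array(["x", "x", "x", "z", "z", "z", "y", "y", "y", "y"]),
                          n_perm=99, seed=1)
        assert f1 == pytest.approx(f2)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "profile,expected_h,expected_obs",
        [
            ([1, 1, 1, 1], 2.0, 4),
            ([7, 0, 0, 0], 0.0, 1),
            ([0.5, 0.25, 0.25, 0.0], 1.5, 3),
        ],
    )
    def test_closed_forms(self, profile, expected_h, expected_obs):
        ad = alpha_diversity(make_table([profile]))
        assert ad.data["shannon"].iloc[0] == pytest.approx(expected_h)
        assert ad.data["observed_features"].iloc[0] == expected_obs

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            alpha_diversity(make_table([[0.0, 0.0]]))

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(3)
        uniform = alpha_diversity(make_table([np.ones(16)])).data["shannon"].iloc[0]
        for _ in range(10):
            h = alpha_diversity(make_table([rng.random(16) + 1e-9])).data["shannon"].iloc[0]
            assert h <= uniform + 1e-12


class TestGroupCompare:
    def test_exact_minimum_p_for_3v3(self):
        values = pd.Series([1, 2, 3, 101, 102, 103], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        rep = group_compare(values, groups)
        assert rep["pairwise"]["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_large_p(self):
        values = pd.Series(list(range(10)) * 2, dtype=float)
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        rep = group_compare(values, groups)
        assert rep["kruskal_p"] > 0.9

    def test_empty_group_rejected(self):
        values = pd.Series([1.0, 2.0, np.nan])
        groups = pd.Series(["a", "a", "b"])
        with pytest.raises(ValidationError):
            group_compare(values, groups)

    def test_reports_per_group_n_and_median(self):
        values = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0])
        groups = pd.Series(["a", "a", "a", "b", "b"])
        rep = group_compare(values, groups, posthoc=False)
        assert rep["n"] == {"a": 3, "b": 2}
        assert rep["median"]["a"] == 2.0
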