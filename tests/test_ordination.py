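"""UniFrac (vs a brute-force branch-walk oracle), PCoA, and envfit."""

import numpy as np
import pandas as pd
import pytest
import skbio

from microtype.core import ValidationError
from microtype.ordination import envfit_vectors, pcoa, unifrac

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracle: explicit branch enumeration
# ---------------------------------------------------------------------------

def unifrac_oracle(tree, counts_a, counts_b, taxa, weighted, normalized=True):
    """Walk every branch and accumulate the UniFrac sums directly."""
    idx = {t: i for i, t in enumerate(taxa)}
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    ta, tb = a.sum(), b.sum()
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        in_a = sum(a[idx[x]] for x in leaves if x in idx)
        in_b = sum(b[idx[x]] for x in leaves if x in idx)
        if weighted:
            pa = in_a / ta if ta else 0.0
            pb = in_b / tb if tb else 0.0
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            pres_a, pres_b = in_a > 0, in_b > 0
            if pres_a != pres_b:
                num += length
            if pres_a or pres_b:
                den += length
    if weighted:
        return num / den if normalized else num
    return num / den if den else 0.0


def random_tree(rng, leaves):
    def build(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.1, 1.0):.6f}"
        k = int(rng.integers(1, len(names)))
        return f"({build(names[:k])},{build(names[k:])}):{rng.uniform(0.1, 1.0):.6f}"

    return skbio.TreeNode.read([f"({build(leaves)});"], convert_underscores=False)


class TestUnifrac:
    def test_identical_communities_zero(self):
        tree = skbio.TreeNode.read(["((A:1,B:1):1,C:2);"])
        t = make_table([[1, 2, 3], [1, 2, 3]], features=list("ABC"))
        for weighted in (False, True):
            d = unifrac(t, tree, weighted=weighted)
            assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_hand_value(self):
        # A={1,2} vs B={2,3}: unique branches A,C of 3 observed -> 2/3
        tree = skbio.TreeNode.read(["((A:1,B:1):0,C:1);"])
        t = make_table([[1, 1, 0], [0, 1, 1]], features=list("ABC"))
        d = unifrac(t, tree, weighted=False)
        assert d.iloc[0, 1] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(2024)
        taxa = [f"L{i}" for i in range(8)]
        for _ in range(30):
            tree = random_tree(rng, taxa)
            counts = rng.integers(0, 20, size=(2, 8))
            while (counts.sum(axis=1) == 0).any():
                counts = rng.integers(0, 20, size=(2, 8))
            t = make_table(counts, features=taxa)
            d = unifrac(t, tree, weighted=weighted, normalized=True)
            expected = unifrac_oracle(tree, counts[0], counts[1], taxa, weighted)
            assert d.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_missing_feature_error(self):
        tree = skbio.TreeNode.read(["(A:1,B:1);"])
        t = make_table([[1, 1, 1]], features=list("ABC"))
        with pytest.raises(ValidationError, match="C"):
            unifrac(t, tree)

    def test_bounds_and_symmetry(self, cohort):
        d = unifrac(cohort["otu_table"].relative(), cohort["tree"], weighted=False)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert arr.min() >= 0 and arr.max() <= 1


class TestPcoa:
    def test_collinear_points_recovered(self):
        # points at 0, 3, 4 on a line
        d = pd.DataFrame([[0, 3, 4], [3, 0, 1], [4, 1, 0]], dtype=float)
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.testing.assert_allclose(rec, d.to_numpy(), atol=1e-9)

    def test_duplicated_point_coincident(self):
        d = pd.DataFrame([[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
        res = pcoa(d)
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9
        )

    def test_euclidean_configs_reconstructed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.random((7, 3))
            d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None], axis=2))
            res = pcoa(d)
            coords = res.coordinates.to_numpy()
            rec = np.linalg.norm(coords[:, None] - coords[None], axis=2)
            np.testing.assert_allclose(rec, d.to_numpy(), atol=1e-9)
            # Euclidean input: no eigenvalue below -1e-9
            assert res.eigenvalues.min() > -1e-9

    def test_eigenvalues_descending_and_negatives_reported(self, cohort):
        from microtype.ordination import unifrac as uf

        d = uf(cohort["otu_table"].relative(), cohort["tree"], weighted=False)
        res = pcoa(d)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.coordinates.shape[1] == (res.eigenvalues > 1e-9).sum()

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        pts = rng.random((9, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        mine = pcoa(pd.DataFrame(d))
        ref = skbio_pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues)[::-1][:5],
            np.sort(ref.eigvals.to_numpy())[::-1][:5],
            atol=1e-9,
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            pcoa(pd.DataFrame(np.zeros((2, 3))))


class TestEnvfit:
    @pytest.fixture()
    def ordination(self):
        rng = np.random.default_rng(0)
        pts = rng.random((30, 4))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None], axis=2))
        return pcoa(d)

    def test_axis_aligned_covariate(self, ordination):
        cov = pd.DataFrame({"x": ordination.coordinates["PCo1"]})
        res = envfit_vectors(ordination, cov, n_perm=199, seed=0)
        assert res.loc["x", "r2"] == pytest.approx(1.0)
        assert res.loc["x", "p"] == pytest.approx(1 / 200)
        assert abs(res.loc["x", "dx"]) == pytest.approx(1.0)

    def test_negative_axis_two_sign(self, ordination):
        cov = pd.DataFrame({"y": -ordination.coordinates["PCo2"]})
        res = envfit_vectors(ordination, cov, n_perm=99, seed=0)
        np.testing.assert_allclose([res.loc["y", "dx"], res.loc["y", "dy"]],
                                   [0.0, -1.0], atol=1e-9)

    def test_constant_covariate_flagged(self, ordination):
        cov = pd.DataFrame({"c": np.ones(30)}, index=ordination.coordinates.index)
        res = envfit_vectors(ordination, cov, n_perm=99, seed=0)
        assert res.loc["c", "note"] == "constant-or-missing"
        assert np.isnan(res.loc["c", "r2"])

    def test_null_covariate_p_roughly_uniform(self, ordination):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            cov = pd.DataFrame({"z": rng.normal(size=30)},
                               index=ordination.coordinates.index)
            res = envfit_vectors(ordination, cov, n_perm=99, seed=i)
            hits += res.loc["z", "p"] <= 0.05
        assert 0.005 <= hits / n_rep <= 0.12
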