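import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from germcore.structure_analysis import (
    gower_distance,
    grm_pca,
    group_composition,
    hclust_phenotypes,
    ibs_distance,
    kinship_bins,
    kinship_matrix,
    modified_rogers_distance,
    nj_tree,
    pcoa,
)

from conftest import balding_nichols_panel, make_genotypes


class TestDistances:
    def test_ibs_identical_rows(self):
        geno = make_genotypes(np.tile([0, 1, 2, 1], (2, 1)))
        d = ibs_distance(geno)
        assert d.iloc[0, 1] == 0.0

    def test_ibs_opposite_homozygotes(self):
        geno = make_genotypes(np.array([[0, 0, 0], [2, 2, 2]]))
        assert ibs_distance(geno).iloc[0, 1] == 1.0

    def test_ibs_half_shared(self):
        geno = make_genotypes(np.array([[0.0], [1.0]]))
        assert ibs_distance(geno).iloc[0, 1] == 0.5

    def test_mrd_identical(self):
        geno = make_genotypes(np.tile([0, 2, 1], (2, 1)))
        assert modified_rogers_distance(geno).iloc[0, 1] == 0.0

    def test_mrd_opposite(self):
        geno = make_genotypes(np.array([[0, 0], [2, 2]]))
        assert modified_rogers_distance(geno).iloc[0, 1] == 1.0

    def test_mrd_hand_value(self):
        # one of two sites differs by one dosage: sqrt((1/4)/2)
        geno = make_genotypes(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert modified_rogers_distance(geno).iloc[0, 1] == pytest.approx(np.sqrt(0.125))

    @pytest.mark.parametrize("func", [ibs_distance, modified_rogers_distance])
    def test_symmetry_and_diagonal(self, func):
        rng = np.random.default_rng(31)
        dosages = rng.integers(0, 3, size=(12, 40)).astype(float)
        dosages[rng.random(dosages.shape) < 0.1] = np.nan
        d = func(make_genotypes(dosages)).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_no_shared_sites_errors(self):
        dosages = np.array([[0.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            ibs_distance(make_genotypes(dosages))


class TestPca:
    def test_separated_demes(self):
        geno, popmap, _ = balding_nichols_panel(25, 1000, 0.25, seed=32)
        coords, pct = grm_pca(geno, n_components=2)
        pc1 = coords["PC1"].to_numpy()
        g1, g2 = pc1[:25], pc1[25:]
        margin = abs(g1.mean() - g2.mean())
        spread = max(g1.std(), g2.std())
        assert margin > spread

    def test_identical_accessions_zero_eigenvalues(self):
        geno = make_genotypes(np.tile([0, 1, 2, 1, 0], (6, 1)))
        coords, pct = grm_pca(geno, n_components=3)
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-10)

    def test_variance_non_increasing(self):
        geno, _, _ = balding_nichols_panel(20, 500, 0.1, seed=33)
        _, pct = grm_pca(geno, n_components=5)
        assert (np.diff(pct) <= 1e-10).all()
        assert pct.sum() <= 100.0 + 1e-9

    def test_too_many_components_errors(self):
        geno, _, _ = balding_nichols_panel(5, 50, 0.1, seed=34)
        with pytest.raises(ValueError):
            grm_pca(geno, n_components=11)


def _procrustes_residual(X, Y):
    """Residual after optimally rotating/reflecting Y onto X (both centered)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc)
    R = U @ Vt
    return np.linalg.norm(Xc - Yc @ R.T)


class TestPcoa:
    def test_euclidean_exactness(self):
        rng = np.random.default_rng(35)
        points = rng.normal(size=(5, 2))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        coords, evals = pcoa(pd.DataFrame(D), n_components=2)
        assert _procrustes_residual(points, coords.to_numpy()) < 1e-8

    def test_two_points(self):
        coords, _ = pcoa(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]]), n_components=1)
        np.testing.assert_allclose(sorted(coords["Axis1"]), [-0.5, 0.5], atol=1e-12)

    def test_recovers_demes_from_ibs(self):
        geno, popmap, _ = balding_nichols_panel(20, 800, 0.25, seed=36)
        coords, _ = pcoa(ibs_distance(geno), n_components=1)
        ax = coords["Axis1"].to_numpy()
        assert abs(ax[:20].mean() - ax[20:].mean()) > max(ax[:20].std(), ax[20:].std())

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0.0, 1.0], [2.0, 0.0]]))

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(37)
        points = rng.normal(size=(8, 3))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        coords, _ = pcoa(pd.DataFrame(D), n_components=8)
        X = coords.to_numpy()
        D2 = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.testing.assert_allclose(D, D2, atol=1e-8)


def _tree_pdm(tree):
    """Leaf-to-leaf path lengths of a dendropy tree, as a dict."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        key = tuple(sorted((t1.label, t2.label)))
        out[key] = pdm.distance(t1, t2)
    return out


def _random_additive_matrix(n, seed):
    """Distances induced by a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=__import__("random").Random(seed),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = rng.uniform(0.1, 2.0)
    labels = [t.label for t in taxa]
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.distance(taxa[i], taxa[j])
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def _ls_topology_oracle_4taxa(D):
    """Enumerate the 3 unrooted 4-taxon topologies; least-squares fit each."""
    # topology encoded as the pair grouped together with taxon 0
    best = None
    for partner in (1, 2, 3):
        others = [k for k in (1, 2, 3) if k != partner]
        # params: 4 pendant edges + 1 internal edge
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            row = [0.0] * 5
            row[i] = row[j] = 1.0
            same_side = {i, j} in ({0, partner}, set(others))
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            y.append(D[i, j])
        coef, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = np.linalg.norm(np.array(rows) @ coef - np.array(y))
        if best is None or resid < best[0]:
            best = (resid, partner)
    return best[1]


class TestNjTree:
    @pytest.mark.parametrize("n,seed", [(4, 41), (5, 42), (6, 43)])
    def test_additive_matrix_exact_recovery(self, n, seed):
        D = _random_additive_matrix(n, seed)
        tree = nj_tree(D)
        pdm = _tree_pdm(tree)
        for (a, b), d in pdm.items():
            assert d == pytest.approx(D.loc[a, b], abs=1e-9)

    def test_four_taxon_topology_matches_enumeration(self):
        rng = np.random.default_rng(44)
        for seed in range(5):
            D = _random_additive_matrix(4, 100 + seed).to_numpy()
            D = D + rng.uniform(0, 0.01, size=D.shape)  # slight noise
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            partner = _ls_topology_oracle_4taxa(D)
            tree = nj_tree(pd.DataFrame(D, index=list("0123"), columns=list("0123")))
            # find taxon 0's sibling group in the NJ tree via the unique split
            pdm = _tree_pdm(tree)
            # four-point condition: 0's partner minimizes d(0,p) + d(q,r)
            sums = {
                p: pdm[tuple(sorted(("0", str(p))))]
                + pdm[tuple(sorted(tuple(str(k) for k in (1, 2, 3) if k != p)))]
                for p in (1, 2, 3)
            }
            nj_partner = min(sums, key=sums.get)
            assert nj_partner == partner

    def test_three_leaves_closed_form(self):
        D = pd.DataFrame(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = nj_tree(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_ultrametric_matches_single_linkage(self):
        # ultrametric distances: NJ groups must match the linkage dendrogram
        rng = np.random.default_rng(45)
        n = 6
        link = hierarchy.linkage(rng.normal(size=(n, 2)), method="single")
        D = np.zeros((n, n))
        coph = hierarchy.cophenet(link)
        from scipy.spatial.distance import squareform

        D = squareform(coph)
        labels = [f"L{i}" for i in range(n)]
        tree = nj_tree(pd.DataFrame(D, index=labels, columns=labels))
        pdm = _tree_pdm(tree)
        for (a, b), d in pdm.items():
            i, j = int(a[1:]), int(b[1:])
            assert d == pytest.approx(D[i, j], abs=1e-9)

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            nj_tree(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]]))

    def test_non_finite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(pd.DataFrame(D))


class TestHclust:
    def test_two_blobs(self):
        rng = np.random.default_rng(46)
        a = rng.normal(0, 0.1, size=(15, 4))
        b = rng.normal(5, 0.1, size=(15, 4))
        table = pd.DataFrame(np.vstack([a, b]), columns=list("wxyz"))
        labels = hclust_phenotypes(table, k=2)
        assert labels[:15].nunique() == 1
        assert labels[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n(self):
        rng = np.random.default_rng(47)
        table = pd.DataFrame(rng.normal(size=(6, 3)))
        labels = hclust_phenotypes(table, k=6)
        assert labels.nunique() == 6

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            hclust_phenotypes(pd.DataFrame(np.zeros((3, 2))), k=5)

    def test_identical_rows_single_cluster(self):
        table = pd.DataFrame(np.tile([1.0, 2.0], (5, 1)))
        labels = hclust_phenotypes(table, k=2)
        # zero-height merges: cutting cannot separate identical rows cleanly,
        # but every row must land somewhere
        assert len(labels) == 5


class TestKinship:
    def test_diagonal_one(self):
        rng = np.random.default_rng(48)
        geno = make_genotypes(rng.integers(0, 3, size=(8, 100)).astype(float))
        K = kinship_matrix(geno)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_duplicated_accession(self):
        rng = np.random.default_rng(49)
        dosages = rng.integers(0, 3, size=(5, 200)).astype(float)
        dosages[1] = dosages[0]
        K = kinship_matrix(make_genotypes(dosages))
        assert K.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_accessions_low_correlation(self):
        rng = np.random.default_rng(50)
        p = np.full(10_000, 0.5)
        dosages = rng.binomial(2, p, size=(2, 10_000)).astype(float)
        K = kinship_matrix(make_genotypes(dosages))
        assert abs(K.iloc[0, 1]) < 0.05

    def test_bins(self):
        K = pd.DataFrame(np.ones((4, 4)))
        bins = kinship_bins(K)
        assert bins.loc[bins["bin"] == ">0.5", "percent"].iloc[0] == 100.0
        assert bins["n_pairs"].sum() == 6  # C(4,2)

    def test_bin_percentages_sum(self):
        rng = np.random.default_rng(51)
        K = np.corrcoef(rng.normal(size=(10, 50)))
        bins = kinship_bins(pd.DataFrame(K))
        assert bins["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert bins["n_pairs"].sum() == 45


class TestGroupComposition:
    def test_published_split_percentages(self):
        a = pd.Series(["G2"] * 152, index=range(152))
        b = pd.Series(["C1"] * 69 + ["C2"] * 72 + ["C4"] * 11, index=range(152))
        counts, pct = group_composition(a, b)
        assert counts.loc["G2"].sum() == 152
        assert round(pct.loc["G2", "C1"], 2) == 45.39
        assert round(pct.loc["G2", "C2"], 2) == 47.37
        assert round(pct.loc["G2", "C4"], 2) == 7.24

    def test_identical_labelings_diagonal(self):
        a = pd.Series(["x", "y", "x"], index=range(3))
        counts, _ = group_composition(a, a)
        assert counts.loc["x", "x"] == 2
        assert counts.loc["y", "y"] == 1
        assert counts.to_numpy().sum() == 3


def test_gower_distance_range():
    rng = np.random.default_rng(52)
    table = pd.DataFrame(rng.normal(size=(10, 4)))
    d = gower_distance(table).to_numpy()
    assert (d >= 0).all() and (d <= 1 + 1e-12).all()
    np.testing.assert_allclose(d, d.T)
    np.testing.assert_allclose(np.diag(d), 0.0)
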