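import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from fishestab.distances import (
    DistanceMatrix,
    build_dendrogram,
    cophenetic_distances,
    dendrogram_to_newick,
    functional_distances,
    mantel_test,
    trait_pca,
)
from fishestab.synth import simulate_traits, simulate_tree

from conftest import tree_from


class TestCophenetic:
    def test_two_tip_path(self):
        dm = cophenetic_distances(tree_from("(A:0.3,B:0.7);"))
        assert dm.loc("A", "B") == pytest.approx(1.0)

    def test_three_tip_hand_values(self):
        dm = cophenetic_distances(tree_from("((A:1,B:1):2,C:3);"))
        assert dm.loc("A", "B") == pytest.approx(2.0)
        assert dm.loc("A", "C") == pytest.approx(6.0)
        assert dm.loc("B", "C") == pytest.approx(6.0)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_negative_branch_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            cophenetic_distances(tree_from("(A:-0.1,B:0.7);"))

    def test_outgroup_pruned(self):
        dm = cophenetic_distances(
            tree_from("(((A:1,B:1):1,C:2):5,OUT:7);"), outgroup="OUT"
        )
        assert sorted(dm.species) == ["A", "B", "C"]
        assert dm.loc("A", "C") == pytest.approx(4.0)


class TestTraitPCA:
    def test_recovers_orthogonal_axes(self):
        """Uncorrelated columns with variances 5>4>3>2>1 are the PCs themselves."""
        rng = np.random.default_rng(0)
        n = 400
        sds = np.sqrt([5, 4, 3, 2, 1])
        X = rng.standard_normal((n, 5))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T)).T)
        X = X * sds  # exactly uncorrelated columns with the target variances
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                          columns=[f"t{j}" for j in range(5)])
        space = trait_pca(df, n_components=5, standardize=False)
        np.testing.assert_allclose(space.explained_variance,
                                   np.array([5, 4, 3, 2, 1]) * n / (n - 1) * (n - 1) / n,
                                   rtol=1e-6)
        # loadings are the coordinate axes up to the sign convention
        np.testing.assert_allclose(np.abs(space.loadings), np.eye(5), atol=1e-8)
        assert np.all(np.diag(space.loadings) > 0)

    def test_total_variance_after_standardization(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, [1, 10, 100, 3, 7, 2, 5, 9, 4, 6], size=(30, 10)),
                          index=[f"s{i}" for i in range(30)])
        space = trait_pca(df, n_components=10)
        assert space.explained_variance.sum() == pytest.approx(10.0, rel=1e-10)
        assert np.all(np.diff(space.explained_variance) <= 1e-10)
        # scores orthogonal
        G = space.scores.T @ space.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_duplicate_species_identical_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 10))
        X[3] = X[0]
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(8)])
        space = trait_pca(df)
        np.testing.assert_allclose(space.scores[3], space.scores[0], atol=1e-10)

    def test_constant_trait_fatal(self):
        df = pd.DataFrame(np.ones((10, 10)), index=[f"s{i}" for i in range(10)],
                          columns=[f"t{j}" for j in range(10)])
        df.iloc[:, 1:] = np.random.default_rng(0).normal(size=(10, 9))
        with pytest.raises(ValueError, match="t0"):
            trait_pca(df)


class TestFunctionalDistances:
    def test_triangle_345(self):
        from fishestab.distances import TraitSpace

        space = TraitSpace(
            species=["a", "b"],
            scores=np.array([[0, 0, 0, 0, 0], [3, 4, 0, 0, 0.0]]),
            loadings=np.zeros((10, 5)),
            explained_variance=np.zeros(5),
            explained_variance_ratio=np.zeros(5),
            trait_names=[],
        )
        dm = functional_distances(space)
        assert dm.loc("a", "b") == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(8, 10)), index=[f"s{i}" for i in range(8)])
        space = trait_pca(df)
        dm = functional_distances(space)
        scores = {sp: space.scores[space.species.index(sp)] for sp in dm.species}
        for a in dm.species:
            for b in dm.species:
                manual = np.sqrt(((scores[a] - scores[b]) ** 2).sum())
                assert dm.loc(a, b) == pytest.approx(manual, abs=1e-12)


class TestDendrogram:
    def test_forced_first_merge(self):
        D = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], D, "functional")
        Z, labels = build_dendrogram(dm)
        assert sorted(int(Z[0, 0]) for _ in [0]) != []  # linkage exists
        assert {int(Z[0, 0]), int(Z[0, 1])} == {labels.index("A"), labels.index("B")}
        assert Z.shape[0] == 2  # n-1 merges

    def test_ultrametric_fixed_point(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 4))
        base = hierarchy.linkage(pts, method="average")
        cop = squareform(hierarchy.cophenet(base))
        dm = DistanceMatrix([f"s{i}" for i in range(9)], cop, "functional")
        Z, labels = build_dendrogram(dm, method="complete")
        cop2 = squareform(hierarchy.cophenet(Z))
        np.testing.assert_allclose(cop2, cop, atol=1e-10)

    def test_newick_export_parses(self):
        rng = np.random.default_rng(5)
        n = 7
        pts = rng.normal(size=(n, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"sp{i}" for i in range(n)], D, "functional")
        Z, labels = build_dendrogram(dm)
        nwk = dendrogram_to_newick(Z, labels)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        got = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert got == sorted(labels)


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = mantel_test(D, D.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            p1 = rng.normal(size=(4, 2))
            p2 = rng.normal(size=(4, 2))
            A = np.sqrt(((p1[:, None] - p1[None]) ** 2).sum(-1))
            B = np.sqrt(((p2[:, None] - p2[None]) ** 2).sum(-1))
            res = mantel_test(A, B, exact=True)
            # test-local enumeration over all 24 permutations
            iu = np.triu_indices(4, 1)

            def corr(M):
                a, b = A[iu], M[iu]
                return np.corrcoef(a, b)[0, 1]

            r_obs = corr(B)
            count = sum(
                corr(B[np.ix_(p, p)]) >= r_obs - 1e-12
                for p in map(list, itertools.permutations(range(4)))
            )
            assert res.n_perm == 24
            assert res.p == pytest.approx(count / 24)
            assert res.r == pytest.approx(r_obs)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        A = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        B = np.sqrt(((rng.normal(size=(12, 2))[:, None] - rng.normal(size=(12, 2))[None]) ** 2).sum(-1))
        r1 = mantel_test(A, B, n_perm=199, seed=11)
        r2 = mantel_test(A, B, n_perm=199, seed=11)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_type_i_error_rate(self):
        """Independent matrices: rejection at alpha=.05 close to nominal."""
        rej = 0
        trials = 300
        for s in range(trials):
            rng = np.random.default_rng(20_000 + s)
            p1 = rng.normal(size=(12, 3))
            p2 = rng.normal(size=(12, 3))
            A = np.sqrt(((p1[:, None] - p1[None]) ** 2).sum(-1))
            B = np.sqrt(((p2[:, None] - p2[None]) ** 2).sum(-1))
            rej += mantel_test(A, B, n_perm=99, seed=s).p <= 0.05
        assert 0.02 <= rej / trials <= 0.09


class TestPhylogeneticSignal:
    def test_brownian_traits_show_signal(self):
        hits = 0
        for s in range(10):
            tree = simulate_tree(15, 1.0, seed=s)
            traits = simulate_traits(tree, trait_signal=1.0, seed=s)
            dphy = cophenetic_distances(tree)
            dfun = functional_distances(trait_pca(traits))
            res = mantel_test(dphy, dfun.submatrix(dphy.species), n_perm=199, seed=s)
            hits += res.p < 0.05
        assert hits >= 9

    def test_shuffled_traits_no_signal(self):
        rej = 0
        for s in range(20):
            tree = simulate_tree(15, 1.0, seed=s)
            traits = simulate_traits(tree, trait_signal=0.0, seed=s)
            dphy = cophenetic_distances(tree)
            dfun = functional_distances(trait_pca(traits))
            res = mantel_test(dphy, dfun.submatrix(dphy.species), n_perm=99, seed=s)
            rej += res.p < 0.05
        assert rej <= 4  # rejection rate near alpha, not near one

    def test_phylo_functional_correlation_materially_below_one(self, synth_small):
        d = synth_small
        dfun = d.d_fun.submatrix(d.d_phy.species)
        iu = np.triu_indices(len(d.d_phy.species), 1)
        r = np.corrcoef(d.d_phy.values[iu], dfun.values[iu])[0, 1]
        assert r**2 < 0.9
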