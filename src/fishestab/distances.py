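"""Species-by-species distance matrices: phylogenetic and functional.

The phylogenetic matrix holds cophenetic (tip-to-tip patristic) distances
from a rooted, branch-length-bearing tree.  The functional matrix holds
Euclidean distances in a trait space built from the first five principal
components of ten standardized morphological traits.  A Mantel test
quantifies phylogenetic signal, i.e. whether functionally similar species
are also close on the tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "DistanceMatrix",
    "TraitSpace",
    "cophenetic_distances",
    "trait_pca",
    "functional_distances",
    "build_dendrogram",
    "dendrogram_to_newick",
    "mantel_test",
    "MantelResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative species x species distance matrix."""

    species: list[str]
    values: np.ndarray
    kind: str  # "phylogenetic" | "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("nonzero diagonal")
        self._index = {s: i for i, s in enumerate(self.species)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, species: list[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in species]
        return DistanceMatrix(list(species), self.values[np.ix_(idx, idx)], self.kind)

    def indices(self, species) -> np.ndarray:
        return np.array([self._index[s] for s in species], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, kind: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.values, kind)


@dataclass
class TraitSpace:
    """Principal-component scores of the standardized trait table."""

    species: list[str]
    scores: np.ndarray                # n_species x n_components
    loadings: np.ndarray              # n_traits x n_components
    explained_variance: np.ndarray    # per retained component
    explained_variance_ratio: np.ndarray
    trait_names: list[str]


def cophenetic_distances(
    tree: dendropy.Tree, outgroup: str | None = None
) -> DistanceMatrix:
    """Pairwise sum of branch lengths along tip-to-tip paths.

    The optional outgroup tip is pruned before any distances are computed
    so it never inflates ingroup path lengths through the root.
    """
    tree = tree.clone(depth=1)
    if outgroup is not None:
        taxon = tree.taxon_namespace.get_taxon(outgroup)
        if taxon is None:
            raise ValueError(f"outgroup {outgroup!r} not found among tips")
        tree.prune_taxa([taxon])
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    pdm = tree.phylogenetic_distance_matrix()
    species = sorted(labels)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(species)
    D = np.zeros((n, n))
    for i, a in enumerate(species):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[species[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(species, D, "phylogenetic")


def trait_pca(
    traits: pd.DataFrame,
    n_components: int = 5,
    standardize: bool = True,
) -> TraitSpace:
    """PCA of the trait table (correlation-matrix PCA by default).

    Traits are z-scored column-wise (sample SD) before the decomposition,
    so each trait contributes unit variance regardless of its measurement
    scale.  A deterministic sign convention is applied: within each
    component the largest-magnitude loading is made positive.
    """
    X = traits.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("trait table contains non-finite values")
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} species for {n_components} PCs")
    sd = X.std(axis=0, ddof=1)
    if standardize:
        if np.any(sd == 0):
            bad = [c for c, s in zip(traits.columns, sd) if s == 0]
            raise ValueError(f"constant trait column(s): {bad}")
        X = (X - X.mean(axis=0)) / sd
    k = min(n_components, p, n - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # p x k
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return TraitSpace(
        species=list(traits.index),
        scores=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        trait_names=list(traits.columns),
    )


def functional_distances(space: TraitSpace) -> DistanceMatrix:
    """Euclidean distances between species in the PC-score space."""
    order = np.argsort(np.asarray(space.species, dtype=object))
    species = [space.species[i] for i in order]
    D = squareform(pdist(space.scores[order], metric="euclidean"))
    return DistanceMatrix(species, D, "functional")


def build_dendrogram(
    dm: DistanceMatrix, method: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the distance matrix.

    Species are sorted lexicographically first so merge order is
    deterministic under ties.  Returns the scipy linkage matrix and the
    leaf labels in input order.
    """
    if method not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    species = sorted(dm.species)
    sub = dm.submatrix(species)
    Z = hierarchy.linkage(squareform(sub.values, checks=False), method=method)
    return Z, species


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Export a linkage matrix as Newick with merge heights as node depths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.10g}"

    body = rec(tree, tree.dist)
    # root edge length is meaningless; strip it
    body = body.rsplit(":", 1)[0]
    return body + ";"


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    exact: bool


def _upper(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def mantel_test(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix correlation with an upper-tail permutation p.

    Pearson r is computed on the upper triangles.  Under permutation the
    rows and columns of the second matrix are permuted jointly.  With
    ``exact=True`` all n! permutations are enumerated (identity included)
    and p is the exact fraction with permuted r >= observed; otherwise p =
    (1 + #{r_perm >= r_obs}) / (n_perm + 1) over sampled permutations.
    """
    A = d1.values if isinstance(d1, DistanceMatrix) else np.asarray(d1, dtype=float)
    B = d2.values if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if d1.species != d2.species:
            raise ValueError("species orderings differ between matrices")
    if A.shape != B.shape:
        raise ValueError("matrix shapes differ")
    n = A.shape[0]
    a = _upper(A)
    if a.std() == 0 or _upper(B).std() == 0:
        raise ValueError("zero variance in a distance triangle")

    a_c = (a - a.mean()) / a.std()

    def corr(mat: np.ndarray) -> float:
        b = _upper(mat)
        return float(np.mean(a_c * (b - b.mean()) / b.std()))

    r_obs = corr(B)
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            p_idx = np.array(perm)
            if corr(B[np.ix_(p_idx, p_idx)]) >= r_obs - 1e-12:
                count += 1
        return MantelResult(r=r_obs, p=count / total, n_perm=total, exact=True)

    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        if corr(B[np.ix_(p_idx, p_idx)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm, exact=False)
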