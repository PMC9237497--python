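"""Multivariate population profiling.

Populations (treatment groups) are summarized by their trait-mean vectors;
pairwise Euclidean distances over those vectors give the inter-population
proximity matrix; average-linkage (UPGMA) clustering builds the dendrogram
and flat cluster profiles; correlation-matrix PCA yields variance fractions,
variable cos2 (quality of representation) and contributions.

Distances default to *raw* trait means — mixed units and all — because that
is the convention the trial's printed proximity extremes follow;
standardized (z-scored) distances remain available via a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin


def population_means(
    table: pd.DataFrame, variety: str, generation: str
) -> pd.DataFrame:
    """Treatment-by-trait matrix of cell means for one variety/generation."""
    sub = table[(table["variety"] == variety) & (table["generation"] == generation)]
    if sub.empty:
        raise ValueError(f"no rows for ({variety!r}, {generation!r})")
    m = sub.groupby(["treatment", "trait"])["value"].mean().unstack("trait")
    # preserve first-appearance order of treatments and traits
    m = m.loc[list(dict.fromkeys(sub["treatment"])), list(dict.fromkeys(sub["trait"]))]
    if m.isna().any().any():
        missing = [
            (str(i), str(c))
            for i in m.index for c in m.columns
            if pd.isna(m.loc[i, c])
        ]
        raise ValueError(f"missing (treatment, trait) cells: {missing}")
    return m


def euclidean_matrix(means: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Pairwise Euclidean distances between population mean vectors."""
    X = means.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = [str(c) for c, s in zip(means.columns, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance traits cannot be standardized: {zero}")
        X = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(d, index=means.index, columns=means.index)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` lists n-1 rows (id_a, id_b, height, size) in scipy convention:
    leaves are 0..n-1 in ``leaf_labels`` order, the i-th merge creates node
    n+i.  Heights are non-decreasing (UPGMA monotonicity).
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def cut(self, k: int) -> pd.Series:
        """Flat cluster memberships for ``k`` clusters (cut after n-k merges).

        Clusters are numbered 1..k in order of their smallest leaf label.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, (a, b, _h, _s) in enumerate(self.merges[: n - k]):
            node = n + i
            parent[find(a)] = node
            parent[find(b)] = node
        groups: dict[int, list[str]] = {}
        for leaf, lab in enumerate(self.leaf_labels):
            groups.setdefault(find(leaf), []).append(lab)
        ordered = sorted(groups.values(), key=lambda labs: min(labs))
        membership = {}
        for cid, labs in enumerate(ordered, start=1):
            for lab in labs:
                membership[lab] = cid
        return pd.Series(membership, name="cluster").loc[list(self.leaf_labels)]

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (height / 2 to leaves)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.leaf_labels[i] for i in range(n)}
        for i, (a, b, h, _s) in enumerate(self.merges):
            node = n + i
            la, lb = h / 2 - height[a] / 2, h / 2 - height[b] / 2
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[node] = h
        return text[2 * n - 2] + ";"


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the closest pair of clusters merges; the distance from the
    merged cluster to any other is the unweighted average of the member-pair
    distances.  Ties are broken by the smallest (lexicographic) pair of
    member labels, so the output is deterministic.
    """
    labels = [str(x) for x in distance.index]
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 populations")
    D = distance.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    # active clusters: node id -> (leaf set, size); distances in a dict
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            key = (
                d,
                min(labels[x] for x in active[i] + active[j]),
                sorted(labels[x] for x in active[i] + active[j]),
            )
            if best is None or key < best[0]:
                best = (key, i, j, d)
        _, i, j, h = best
        merges.append((i, j, h, sizes[i] + sizes[j]))
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dnew
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active[next_id] = active.pop(i) + active.pop(j)
        sizes[next_id] = sizes[i] + sizes[j]
        next_id += 1
    return Dendrogram(leaf_labels=tuple(labels), merges=tuple(merges))


class UPGMAClusterer(BaseEstimator, ClusterMixin):
    """Average-linkage clustering of population mean vectors.

    scikit-learn style: ``fit(X)`` with X a populations-by-traits DataFrame
    (or, with ``metric="precomputed"``, a square distance matrix) builds the
    UPGMA dendrogram and cuts it into ``n_clusters`` flat clusters.

    Attributes: ``dendrogram_``, ``labels_`` (1-based cluster ids aligned to
    rows), ``distance_matrix_``, ``linkage_matrix_``.
    """

    def __init__(self, n_clusters: int = 5, metric: str = "euclidean",
                 standardize: bool = False):
        self.n_clusters = n_clusters
        self.metric = metric
        self.standardize = standardize

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if self.metric == "precomputed":
            d = X.copy()
        elif self.metric == "euclidean":
            d = euclidean_matrix(X, standardize=self.standardize)
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.distance_matrix_ = d
        self.dendrogram_ = upgma(d)
        self.linkage_matrix_ = self.dendrogram_.to_linkage()
        members = self.dendrogram_.cut(self.n_clusters)
        self.labels_ = members.to_numpy()
        self.members_ = members
        return self


def cluster_profiles(
    dendrogram: Dendrogram,
    k: int,
    means: pd.DataFrame,
    distance: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Flat clusters with per-cluster trait means and inter-cluster distances.

    Returns (membership, profiles, intercluster): membership maps population
    -> cluster id; profiles averages the member rows of ``means`` per
    cluster; intercluster averages member-pair distances between clusters
    (diagonal: mean within-cluster pair distance, 0 for singletons).
    """
    membership = dendrogram.cut(k)
    profiles = means.groupby(membership).mean()
    profiles.index.name = "cluster"
    ids = sorted(membership.unique())
    inter = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        for b in ids:
            rows = membership.index[membership == a]
            cols = membership.index[membership == b]
            block = distance.loc[rows, cols].to_numpy()
            if a == b:
                m = len(rows)
                inter.loc[a, b] = (
                    block[np.triu_indices(m, k=1)].mean() if m > 1 else 0.0
                )
            else:
                inter.loc[a, b] = block.mean()
    return membership, profiles, inter


class PopulationPCA(BaseEstimator, TransformerMixin):
    """PCA of the population-by-trait mean matrix.

    By default the eigendecomposition is of the trait *correlation* matrix
    (standardized data), the natural choice for traits on mixed scales and
    the mode in which the cos2 identities hold exactly.  Component signs are
    fixed so the variable with the largest |loading| loads positively,
    making outputs platform-reproducible.

    Attributes (after fit)
    ----------------------
    eigenvalues_ : ndarray, descending; sums to the number of traits in
        correlation mode
    explained_pct_ : per-component percent of total variance
    scores_ : DataFrame, population coordinates
    loadings_ : DataFrame, variable coordinates (eigvec * sqrt(eigenvalue))
    cos2_ : DataFrame, squared variable-component correlations; each
        variable's row sums to 1 in correlation mode
    contributions_ : DataFrame, percent contribution of each variable to
        each component (columns sum to 100)
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("PCA needs >= 2 populations and >= 2 traits")
        V = X.to_numpy(dtype=float)
        self.mean_ = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        if self.standardize:
            zero = [str(c) for c, s in zip(X.columns, sd) if s == 0]
            if zero:
                raise ValueError(
                    f"zero-variance traits break correlation PCA: {zero}"
                )
            self.scale_ = sd
        else:
            self.scale_ = np.ones_like(sd)
        Z = (V - self.mean_) / self.scale_
        C = np.cov(Z, rowvar=False, ddof=1)
        eigval, eigvec = np.linalg.eigh(C)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        # deterministic sign: largest-|loading| variable positive
        for k in range(eigvec.shape[1]):
            pivot = int(np.argmax(np.abs(eigvec[:, k])))
            if eigvec[pivot, k] < 0:
                eigvec[:, k] = -eigvec[:, k]
        comps = [f"PC{i + 1}" for i in range(len(eigval))]
        loadings = eigvec * np.sqrt(eigval)[np.newaxis, :]
        self.eigenvalues_ = eigval
        self.components_ = pd.DataFrame(eigvec, index=X.columns, columns=comps)
        self.explained_pct_ = pd.Series(
            100.0 * eigval / eigval.sum(), index=comps, name="explained_pct"
        )
        self.scores_ = pd.DataFrame(Z @ eigvec, index=X.index, columns=comps)
        self.loadings_ = pd.DataFrame(loadings, index=X.columns, columns=comps)
        if self.standardize:
            cos2 = loadings**2
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                cos2 = (loadings / sd[:, np.newaxis]) ** 2
        self.cos2_ = pd.DataFrame(cos2, index=X.columns, columns=comps)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = 100.0 * (eigvec**2)
        self.contributions_ = pd.DataFrame(contrib, index=X.columns, columns=comps)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        Z = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(
            Z @ self.components_.to_numpy(), index=X.index,
            columns=self.components_.columns,
        )


def pca(means: pd.DataFrame, standardize: bool = True) -> PopulationPCA:
    """Thin wrapper: fit a :class:`PopulationPCA` on a mean matrix."""
    return PopulationPCA(standardize=standardize).fit(means)
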