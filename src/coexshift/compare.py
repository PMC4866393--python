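"""Global transcriptome comparison: PCA, profile and coexpression-structure clustering.

Two clustering substrates are supported: per-(region, window) average
expression profiles, and whole coexpression matrices compared entry-wise on
their strict upper triangles.  Both use 1 - Pearson R as the distance and
average-linkage (UPGMA) agglomeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, split_samples

__all__ = [
    "PCAResult",
    "DistanceMatrix",
    "Dendrogram",
    "pca_scores",
    "factor_association",
    "average_profiles",
    "correlation_distance_matrix",
    "average_linkage_cluster",
    "top_split",
    "stratum_coexpression_matrices",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    variance_fraction: np.ndarray

    def __post_init__(self):
        total = self.variance_fraction.sum()
        if not np.isclose(total, 1.0):
            raise ValueError(f"variance fractions sum to {total}, expected 1")


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Average-linkage merge history in scipy linkage encoding."""

    labels: list
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node):
            if node.is_leaf():
                return str(self.labels[node.id])
            left, right = render(node.left), render(node.right)
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return render(tree) + ";"


def pca_scores(E: ExpressionMatrix, scale: bool = False) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    Data are centered per gene; set ``scale=True`` to also divide by the
    per-gene standard deviation.  Component signs are fixed by forcing the
    largest-magnitude gene loading positive.
    """
    if E.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = E.values.T.astype(float)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S[None, :]
    var = S**2
    total = var.sum()
    if total == 0:
        raise ValueError("all samples identical: PCA undefined")
    return PCAResult(scores=scores, variance_fraction=var / total)


def factor_association(scores_pc1, grouping):
    """Kruskal-Wallis H (tie-corrected) of a score vector against group labels.

    Returns ``(H, p)`` with p from the chi-square approximation.  All-tied
    input returns ``(0.0, 1.0)`` with a warning instead of dividing by zero.
    """
    scores_pc1 = np.asarray(scores_pc1, dtype=float)
    grouping = np.asarray(grouping)
    levels = pd.unique(grouping)
    if len(levels) < 2:
        raise ValueError("factor_association needs at least 2 groups")
    groups = [scores_pc1[grouping == lv] for lv in levels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.all(scores_pc1 == scores_pc1[0]):
        warnings.warn("all scores identical; returning H=0", RuntimeWarning)
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def average_profiles(E: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean expression in each (region, window) stratum.

    Columns are labelled ``"<region>:<window>"``; one column per stratum.
    """
    frames = {}
    for label, sub in split_samples(E, "region_window"):
        frames[label] = sub.values.mean(axis=1)
    return pd.DataFrame(frames, index=E.gene_ids)


def _flatten(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T):
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]
    return arr.ravel()


def correlation_distance_matrix(arrays, labels=None) -> DistanceMatrix:
    """Pairwise 1 - Pearson R distance between equal-shape arrays.

    Symmetric square arrays are compared on their strict upper triangle
    (the unit diagonal carries no information); anything else is flattened
    in C order.  A constant input array makes the correlation undefined and
    raises, naming the offending entry.
    """
    arrays = list(arrays)
    if len(arrays) < 2:
        raise ValueError("need at least 2 arrays")
    if labels is None:
        labels = list(range(len(arrays)))
    flats = []
    for lab, arr in zip(labels, arrays):
        flat = _flatten(arr)
        if np.ptp(flat) == 0:
            raise ValueError(f"constant input array for {lab!r}: correlation undefined")
        flats.append(flat)
    shapes = {f.shape for f in flats}
    if len(shapes) != 1:
        raise ValueError("arrays must share a common shape")
    stack = np.vstack(flats)
    R = np.corrcoef(stack)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return DistanceMatrix(list(labels), D)


def average_linkage_cluster(D: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a distance matrix."""
    if len(D.labels) < 2:
        raise ValueError("clustering needs at least 2 leaves")
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="average")
    return Dendrogram(list(D.labels), Z)


def top_split(dend: Dendrogram):
    """Leaf sets of the two subtrees joined by the final merge."""
    if dend.n_leaves < 2:
        raise ValueError("top_split needs at least 2 leaves")
    assignments = hierarchy.cut_tree(dend.linkage, n_clusters=2).ravel()
    a = frozenset(l for l, c in zip(dend.labels, assignments) if c == 0)
    b = frozenset(l for l, c in zip(dend.labels, assignments) if c == 1)
    return a, b


def stratum_coexpression_matrices(E: ExpressionMatrix):
    """One gene-gene Pearson matrix per (region, window) stratum.

    Genes constant in *any* stratum are dropped globally so every matrix
    covers the same gene set (required for entry-wise matrix comparison);
    the dropped ids are returned for reporting.

    Returns
    -------
    (labels, matrices, dropped_genes)
    """
    strata = split_samples(E, "region_window")
    valid = np.ones(E.n_genes, dtype=bool)
    for _, sub in strata:
        valid &= sub.values.std(axis=1) > 0
    dropped = [g for g, v in zip(E.gene_ids, valid) if not v]
    labels, mats = [], []
    for label, sub in strata:
        labels.append(label)
        mats.append(np.corrcoef(sub.values[valid]))
    return labels, mats, dropped
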