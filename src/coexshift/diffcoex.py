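"""Differential coexpression: adjacency difference, TOM, module detection, rewiring tests.

The pipeline follows the weighted-network differential-coexpression recipe:
per-condition Pearson matrices, a soft-thresholded adjacency difference

    d_ij = ( 0.5 * | sign(c1_ij) c1_ij^2  -  sign(c2_ij) c2_ij^2 | ) ** (beta / 2)

(the 1/2 keeps d in [0, 1]; beta defaults to 6), topological overlap of D,
average-linkage clustering of 1 - TOM, an adaptive tree cut with a minimum
module size, eigengene-based module merging, and a per-module change in
average correlation whose significance comes from permuting the condition
labels of the pooled samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .compare import Dendrogram, DistanceMatrix, average_linkage_cluster
from .io import ExpressionMatrix

__all__ = [
    "ModuleAssignment",
    "EigengeneSet",
    "ModuleRewiringStat",
    "coexpression",
    "adjacency_difference",
    "scale_free_fit",
    "topological_overlap",
    "tom_dendrogram",
    "cut_modules",
    "module_eigengenes",
    "merge_modules",
    "rewiring_statistic",
    "rewiring_permutation_test",
]


@dataclass
class ModuleAssignment:
    """Gene -> module id; 0 means unassigned."""

    gene_ids: list
    labels: np.ndarray
    min_module_size: int = 100

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("labels length must match gene_ids")
        for m, size in self.sizes().items():
            if size < self.min_module_size:
                raise ValueError(f"module {m} smaller than the size floor")

    def sizes(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def module_ids(self) -> list:
        return sorted(self.sizes())

    def genes_of(self, module_id: int) -> list:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module_id]

    def relabel_by_size(self) -> "ModuleAssignment":
        """Renumber modules 1..k by decreasing size (ties by old id)."""
        order = sorted(self.sizes().items(), key=lambda kv: (-kv[1], kv[0]))
        remap = {old: new for new, (old, _) in enumerate(order, start=1)}
        new_labels = np.array([remap.get(l, 0) for l in self.labels])
        return ModuleAssignment(self.gene_ids, new_labels, self.min_module_size)


@dataclass
class EigengeneSet:
    """Module id -> per-sample eigengene (first PC of standardized expression)."""

    eigengenes: dict
    variance_explained: dict = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return np.vstack([self.eigengenes[m] for m in sorted(self.eigengenes)])


@dataclass
class ModuleRewiringStat:
    module_id: int
    n_genes: int
    mean_r_pre: float
    mean_r_post: float
    delta: float
    p: float = np.nan


def coexpression(E_stratum: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Pearson correlation matrix for one stratum.

    Genes constant within the stratum get correlation 0 with everything
    (and 1 on the diagonal) and trigger a warning.
    """
    if E_stratum.n_samples < 3:
        raise ValueError("coexpression needs >= 3 samples")
    X = E_stratum.values
    flat = X.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} genes constant within stratum; correlations set to 0",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    if flat.any():
        C[flat, :] = 0.0
        C[:, flat] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return C


def adjacency_difference(C_pre: np.ndarray, C_post: np.ndarray, beta: int = 6) -> np.ndarray:
    """Soft-thresholded absolute difference of signed squared correlations."""
    C_pre = np.asarray(C_pre, dtype=float)
    C_post = np.asarray(C_post, dtype=float)
    if C_pre.shape != C_post.shape or C_pre.shape[0] != C_pre.shape[1]:
        raise ValueError("condition matrices must be square and same shape")
    if beta < 1 or beta % 2:
        raise ValueError("beta must be an even positive integer")
    signed_sq = lambda c: np.sign(c) * c**2
    D = (0.5 * np.abs(signed_sq(C_pre) - signed_sq(C_post))) ** (beta / 2)
    np.fill_diagonal(D, 0.0)
    return D


def scale_free_fit(D: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) ~ log10(mean connectivity) over equal-width bins.

    Connectivity is the row sum of D.  Used to check that the chosen soft
    threshold yields an approximately scale-free degree distribution.
    """
    k = np.asarray(D, dtype=float).sum(axis=1)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical: fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(mask.mean()))
    if len(log_k) < 2:
        raise ValueError("fewer than 2 occupied bins: fit undefined")
    log_k, log_f = np.array(log_k), np.array(log_f)
    if np.ptp(log_k) == 0:
        raise ValueError("degenerate bin layout: fit undefined")
    r = np.corrcoef(log_k, log_f)[0, 1]
    return float(r**2)


def topological_overlap(D: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of an adjacency with zero diagonal.

    TOM_ij = (sum_u d_iu d_uj + d_ij) / (min(k_i, k_j) + 1 - d_ij), TOM_ii = 1.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("adjacency must be square")
    L = D @ D  # d_ii = 0 makes the u = i, j terms vanish
    k = D.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    tom = (L + D) / (kmin + 1.0 - D)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def tom_dendrogram(tom: np.ndarray, gene_ids) -> Dendrogram:
    """Average-linkage dendrogram of the 1 - TOM dissimilarity."""
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    return average_linkage_cluster(DistanceMatrix(list(gene_ids), diss))


def _qualifying(labels: np.ndarray, min_size: int):
    ids, counts = np.unique(labels, return_counts=True)
    return [c for c, n in zip(ids, counts) if n >= min_size]


def _tree_arrays(Z: np.ndarray, n: int):
    """Sizes, heights and parents for all 2n-1 dendrogram nodes."""
    total = 2 * n - 1
    size = np.ones(total, dtype=int)
    height = np.zeros(total)
    parent = np.full(total, -1, dtype=int)
    left = np.full(total, -1, dtype=int)
    right = np.full(total, -1, dtype=int)
    for i in range(n - 1):
        node = n + i
        a, b = int(Z[i, 0]), int(Z[i, 1])
        left[node], right[node] = a, b
        parent[a] = parent[b] = node
        size[node] = size[a] + size[b]
        height[node] = Z[i, 2]
    return size, height, parent, left, right


def _leaves_under(node: int, n: int, left, right) -> list:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.extend((left[v], right[v]))
    return out


def cut_modules(
    dend: Dendrogram,
    min_module_size: int = 100,
    deep_split: bool = True,
    cut_height_frac: float = 0.99,
    extension_frac: float = 0.5,
) -> ModuleAssignment:
    """Adaptive branch decomposition of the dendrogram into modules.

    A *core* is a minimal dendrogram node whose subtree first reaches
    ``min_module_size`` leaves, restricted to merge heights at or below
    ``cut_height_frac`` of the top merge (near the root, weakly connected
    leftover genes agglomerate into spurious size-qualifying branches).
    Each core is then extended upward to the largest ancestor whose subtree
    contains no other core, so peripheral genes that join a branch before
    it meets any other module are included.  Extension stops at
    ``extension_frac`` of the way from the core's own height to the
    ceiling: genes merging far above a core are loose background, not
    periphery.  Remaining genes are unassigned (module 0).

    ``deep_split`` keeps nested cores as separate modules; switching it off
    adds a coarsening pass that fuses sibling cores whenever their common
    branch (below the ceiling) carries fewer than ``min_module_size``
    additional genes.
    """
    n = dend.n_leaves
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; all genes unassigned")
        return ModuleAssignment(dend.labels, np.zeros(n, dtype=int), min_module_size)
    Z = dend.linkage
    size, height, parent, left, right = _tree_arrays(Z, n)
    ceiling = cut_height_frac * height[-1]

    cores = [
        node
        for node in range(n, 2 * n - 1)
        if height[node] <= ceiling
        and size[node] >= min_module_size
        and size[left[node]] < min_module_size
        and size[right[node]] < min_module_size
    ]
    if not cores:
        return ModuleAssignment(dend.labels, np.zeros(n, dtype=int), min_module_size)

    if not deep_split and len(cores) > 1:
        cores = _coarsen_cores(cores, size, height, parent, ceiling, min_module_size)

    # per-node count of cores in the subtree, bottom-up
    core_count = np.zeros(2 * n - 1, dtype=int)
    core_count[cores] = 1
    for node in range(n, 2 * n - 1):
        core_count[node] += core_count[left[node]] + core_count[right[node]]

    labels = np.zeros(n, dtype=int)
    for module_id, core in enumerate(sorted(cores), start=1):
        top = core
        reach = height[core] + extension_frac * (ceiling - height[core])
        while True:
            up = parent[top]
            if up == -1 or height[up] > reach or core_count[up] != 1:
                break
            top = up
        labels[_leaves_under(top, n, left, right)] = module_id
    assign = ModuleAssignment(dend.labels, labels, min_module_size)
    return assign.relabel_by_size()


def _coarsen_cores(cores, size, height, parent, ceiling, min_size):
    """Fuse sibling cores whose joining branch adds < min_size extra genes."""
    cores = set(cores)
    changed = True
    while changed and len(cores) > 1:
        changed = False
        # lowest common ancestors reachable below the ceiling
        for core in sorted(cores):
            node, under = core, {core}
            while True:
                up = parent[node]
                if up == -1 or height[up] > ceiling:
                    break
                node = up
                inside = {c for c in cores if _is_descendant(c, node, parent)}
                if len(inside) > 1:
                    extra = size[node] - sum(size[c] for c in inside)
                    if extra < min_size:
                        cores -= inside
                        cores.add(node)
                        changed = True
                    break
            if changed:
                break
    return sorted(cores)


def _is_descendant(node, ancestor, parent):
    while node != -1:
        if node == ancestor:
            return True
        node = parent[node]
    return False


def module_eigengenes(E_all: ExpressionMatrix, assign: ModuleAssignment) -> EigengeneSet:
    """First principal component of each module's gene-standardized expression.

    The eigengene sign is oriented to correlate positively with the
    module's mean standardized profile; variance explained is the first
    singular value's share.
    """
    eig, varex = {}, {}
    for m in assign.module_ids():
        idx = E_all.gene_index(assign.genes_of(m))
        if len(idx) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        X = E_all.values[idx]
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"module {m} contains constant genes")
        Z = (X - mu) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        e = Vt[0]
        mean_profile = Z.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eig[m] = e
        varex[m] = float(S[0] ** 2 / (S**2).sum())
    return EigengeneSet(eig, varex)


def merge_modules(
    E_all: ExpressionMatrix,
    assign: ModuleAssignment,
    r_threshold: float = 0.9,
) -> ModuleAssignment:
    """Iteratively merge the most-correlated eigengene pair above threshold.

    After each merge the combined module's eigengene is recomputed; the loop
    stops when no pair of eigengenes correlates above ``r_threshold``.
    """
    labels = assign.labels.copy()
    current = ModuleAssignment(assign.gene_ids, labels, assign.min_module_size)
    while True:
        ids = current.module_ids()
        if len(ids) < 2:
            break
        eig = module_eigengenes(E_all, current)
        M = np.vstack([eig.eigengenes[m] for m in ids])
        R = np.corrcoef(M)
        np.fill_diagonal(R, -np.inf)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] <= r_threshold:
            break
        keep, drop = sorted((ids[i], ids[j]))
        labels = current.labels.copy()
        labels[labels == drop] = keep
        current = ModuleAssignment(assign.gene_ids, labels, assign.min_module_size)
    return current.relabel_by_size()


def _mean_upper_corr(X: np.ndarray) -> float:
    C = np.corrcoef(X)
    iu = np.triu_indices(C.shape[0], k=1)
    return float(C[iu].mean())


def rewiring_statistic(
    E_pre: ExpressionMatrix, E_post: ExpressionMatrix, module_genes, module_id: int = 0
) -> ModuleRewiringStat:
    """Change in a module's mean pairwise correlation across the boundary."""
    genes = list(module_genes)
    if len(genes) < 2:
        raise ValueError("module must have >= 2 genes")
    if E_pre.n_samples < 3 or E_post.n_samples < 3:
        raise ValueError("each stratum needs >= 3 samples")
    pre = _mean_upper_corr(E_pre.values[E_pre.gene_index(genes)])
    post = _mean_upper_corr(E_post.values[E_post.gene_index(genes)])
    return ModuleRewiringStat(
        module_id=module_id,
        n_genes=len(genes),
        mean_r_pre=pre,
        mean_r_post=post,
        delta=post - pre,
    )


def rewiring_permutation_test(
    E_both: ExpressionMatrix,
    module_genes,
    n_perm: int = 1000,
    seed: int = 0,
    module_id: int = 0,
    mode: str = "label",
) -> ModuleRewiringStat:
    """Permutation significance of a module's correlation change.

    The default null permutes the window labels of the pooled samples,
    preserving both stratum sizes and each gene's marginal distribution;
    ``mode="shuffle"`` instead shuffles each gene's values independently
    across samples (exposed for comparison, not the default).  Two-sided:
    p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("label", "shuffle"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    genes = list(module_genes)
    if len(genes) < 2:
        raise ValueError("module must have >= 2 genes")
    idx = E_both.gene_index(genes)
    X = E_both.values[idx]
    is_post = (E_both.samples["window"] == E_both.windows[-1]).to_numpy()
    n_pre, n_post = int((~is_post).sum()), int(is_post.sum())
    if n_pre < 3 or n_post < 3:
        raise ValueError("each stratum needs >= 3 samples")

    def delta_of(post_mask, M):
        return _mean_upper_corr(M[:, post_mask]) - _mean_upper_corr(M[:, ~post_mask])

    obs = delta_of(is_post, X)
    rng = np.random.default_rng(seed)
    n_samples = X.shape[1]
    hits = 0
    for _ in range(n_perm):
        if mode == "label":
            perm = rng.permutation(n_samples)
            mask = np.zeros(n_samples, dtype=bool)
            mask[perm[:n_post]] = True
            M = X
        else:
            M = np.take_along_axis(
                X, rng.permuted(np.tile(np.arange(n_samples), (X.shape[0], 1)), axis=1), axis=1
            )
            mask = is_post
        if abs(delta_of(mask, M)) >= abs(obs):
            hits += 1
    stat = rewiring_statistic(
        E_both.subset_samples(~is_post), E_both.subset_samples(is_post), genes, module_id
    )
    stat.p = (1 + hits) / (n_perm + 1)
    return stat
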