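"""Module-wise gene-set enrichment with resampling and closed-form nulls.

Two routes are provided for term over-representation within a module: a
Z-score test whose null mean/sd are estimated from equally-sized random
gene samples drawn without replacement from the background, and an
upper-tail hypergeometric test.  Both adjust p values by Benjamini-Hochberg
within the module (each module is its own family) and flag significance
only when the term is over-represented by more than one gene.

Also here: the motif-exclusivity permutation test, pairwise enriched-set
overlap counts, and a Welch-t two-group differential-expression screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "benjamini_hochberg",
    "zscore_enrichment",
    "hypergeom_enrichment",
    "targeted_term_query",
    "tf_exclusivity_test",
    "overlap_counts",
    "differential_expression",
    "ExclusivityResult",
]

ENRICHMENT_COLUMNS = [
    "module",
    "term_id",
    "term_name",
    "term_size",
    "observed",
    "expected_mean",
    "expected_sd",
    "z",
    "p",
    "fdr",
    "significant",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _null_sample_counts(incidence, n_background, module_size, n_samples, seed, replace):
    """Per-term overlap counts of random module-sized draws from the background.

    Draws are generated in chunks via row-wise argpartition of uniform noise
    (an exact without-replacement sample) to keep memory bounded.
    """
    rng = np.random.default_rng(seed)
    n_terms = incidence.shape[0]
    counts = np.empty((n_samples, n_terms), dtype=np.int32)
    chunk = max(1, int(1e7 // max(n_background, 1)))  # ~80 MB of uniform noise
    done = 0
    while done < n_samples:
        take = min(chunk, n_samples - done)
        if replace:
            draws = rng.integers(0, n_background, size=(take, module_size))
        else:
            noise = rng.random((take, n_background))
            draws = np.argpartition(noise, module_size - 1, axis=1)[:, :module_size]
        for t in range(n_terms):
            counts[done : done + take, t] = incidence[t][draws].sum(axis=1)
        done += take
    return counts


def zscore_enrichment(
    module_genes,
    terms: GeneSetCollection,
    n_samples: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    module_id=0,
    replace: bool = False,
    term_ids=None,
) -> pd.DataFrame:
    """Z-score over-representation test with a numerically estimated null.

    For each retained term, the expected overlap mean and sd come from
    ``n_samples`` random gene sets of the module's size drawn from the
    background (without replacement by default).  p is two-sided normal from
    z; BH is applied across the module's terms; a term is significant iff
    fdr < alpha AND observed - expected_mean > 1.  Terms with zero null sd
    are flagged degenerate (fdr = NaN) and excluded from BH.
    """
    module = frozenset(module_genes)
    if not module <= terms.background:
        raise ValueError("module genes must lie within the annotation background")
    universe = sorted(terms.background)
    gene_pos = {g: i for i, g in enumerate(universe)}
    use = terms.retained() if term_ids is None else {
        t: terms.sets[t] for t in term_ids if t in terms.sets
    }
    tids = sorted(use)
    incidence = np.zeros((len(tids), len(universe)), dtype=bool)
    for r, t in enumerate(tids):
        for g in use[t][1]:
            incidence[r, gene_pos[g]] = True
    counts = _null_sample_counts(
        incidence, len(universe), len(module), n_samples, seed, replace
    )
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    observed = np.array([len(module & set(use[t][1])) for t in tids], dtype=float)
    degenerate = sd == 0
    z = np.full(len(tids), np.nan)
    p = np.full(len(tids), np.nan)
    ok = ~degenerate
    z[ok] = (observed[ok] - mean[ok]) / sd[ok]
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    fdr = np.full(len(tids), np.nan)
    fdr[ok] = benjamini_hochberg(p[ok])
    significant = ok & (fdr < alpha) & (observed - mean > 1.0)
    return pd.DataFrame(
        {
            "module": module_id,
            "term_id": tids,
            "term_name": [use[t][0] for t in tids],
            "term_size": [len(use[t][1]) for t in tids],
            "observed": observed.astype(int),
            "expected_mean": mean,
            "expected_sd": sd,
            "z": z,
            "p": p,
            "fdr": fdr,
            "significant": significant,
        },
        columns=ENRICHMENT_COLUMNS,
    )


def hypergeom_enrichment(
    module_genes,
    terms: GeneSetCollection,
    alpha: float = 0.05,
    module_id=0,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test, BH-adjusted."""
    module = frozenset(module_genes)
    if not module <= terms.background:
        raise ValueError("module genes must lie within the annotation background")
    N = len(terms.background)
    n = len(module)
    use = terms.retained()
    tids = sorted(use)
    rows = []
    for t in tids:
        members = set(use[t][1])
        K = len(members)
        if K > N:
            raise ValueError(f"term {t} larger than background")
        obs = len(module & members)
        expected = n * K / N
        p = float(stats.hypergeom.sf(obs - 1, N, K, n))
        rows.append((t, use[t][0], K, obs, expected, p))
    p_vec = np.array([r[5] for r in rows]) if rows else np.array([])
    fdr = benjamini_hochberg(p_vec)
    frame = pd.DataFrame(
        {
            "module": module_id,
            "term_id": [r[0] for r in rows],
            "term_name": [r[1] for r in rows],
            "term_size": [r[2] for r in rows],
            "observed": [r[3] for r in rows],
            "expected_mean": [r[4] for r in rows],
            "expected_sd": np.nan,
            "z": np.nan,
            "p": p_vec,
            "fdr": fdr,
            "significant": [
                (f < alpha) and (r[3] - r[4] > 1.0) for f, r in zip(fdr, rows)
            ],
        },
        columns=ENRICHMENT_COLUMNS,
    )
    return frame


def targeted_term_query(
    genes,
    terms: GeneSetCollection,
    term_ids,
    n_samples: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Z-score enrichment restricted to an explicit term id list.

    Missing ids are reported rather than fatal; BH spans only the found
    terms.  Returns ``(table, missing_ids)``.
    """
    term_ids = list(term_ids)
    if not term_ids:
        raise ValueError("empty query list")
    missing = [t for t in term_ids if t not in terms.sets]
    found = [t for t in term_ids if t in terms.sets]
    if not found:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS), missing
    table = zscore_enrichment(
        genes, terms, n_samples=n_samples, alpha=alpha, seed=seed, term_ids=found
    )
    return table, missing


class ExclusivityResult:
    def __init__(self, observed, perm_mean, perm_sd, p, n_perm):
        self.observed = observed
        self.perm_mean = perm_mean
        self.perm_sd = perm_sd
        self.p = p
        self.n_perm = n_perm

    def as_dict(self) -> dict:
        return {
            "observed_exclusive": int(self.observed),
            "perm_mean": float(self.perm_mean),
            "perm_sd": float(self.perm_sd),
            "p": float(self.p),
            "n_perm": int(self.n_perm),
        }


def _exclusive_count(sets_by_module) -> int:
    tally = {}
    for s in sets_by_module:
        for motif in s:
            tally[motif] = tally.get(motif, 0) + 1
    return sum(1 for c in tally.values() if c == 1)


def tf_exclusivity_test(
    enriched: dict,
    motif_universe,
    n_perm: int = 10000,
    seed: int = 0,
    null: str = "size",
) -> ExclusivityResult:
    """Are enriched motifs more module-exclusive than chance?

    ``observed`` counts motifs enriched in exactly one module.  The default
    null keeps each module's enriched-set size and resamples members
    uniformly without replacement from ``motif_universe``; ``null="swap"``
    additionally preserves each motif's total enrichment count by shuffling
    the module-motif bipartite edges with random pair swaps.  Upper-tail
    p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    universe = sorted(set(motif_universe))
    if not universe:
        raise ValueError("empty motif universe")
    module_ids = sorted(enriched)
    sets = [frozenset(enriched[m]) for m in module_ids]
    for m, s in zip(module_ids, sets):
        if not s <= set(universe):
            raise ValueError(f"module {m} has motifs outside the universe")
    observed = _exclusive_count(sets)
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    n_universe = len(universe)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    if null == "size":
        for it in range(n_perm):
            perm_sets = [
                rng.choice(n_universe, size=sz, replace=False) for sz in sizes
            ]
            perm_counts[it] = _exclusive_count([set(s.tolist()) for s in perm_sets])
    elif null == "swap":
        edges = [
            (mi, motif) for mi, s in enumerate(sets) for motif in sorted(s)
        ]
        for it in range(n_perm):
            shuffled = list(edges)
            for _ in range(10 * len(edges)):
                a, b = rng.integers(0, len(shuffled), size=2)
                (ma, fa), (mb, fb) = shuffled[a], shuffled[b]
                if ma == mb:
                    continue
                if (ma, fb) in shuffled or (mb, fa) in shuffled:
                    continue
                shuffled[a], shuffled[b] = (ma, fb), (mb, fa)
            perm_sets = [set() for _ in sets]
            for mi, motif in shuffled:
                perm_sets[mi].add(motif)
            perm_counts[it] = _exclusive_count(perm_sets)
    else:
        raise ValueError(f"unknown null {null!r}")
    p = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    return ExclusivityResult(
        observed, perm_counts.mean(), perm_counts.std(ddof=1), p, n_perm
    )


def overlap_counts(enriched: dict):
    """Pairwise motif-set overlap matrix and per-module exclusive counts."""
    module_ids = sorted(enriched)
    sets = {m: frozenset(enriched[m]) for m in module_ids}
    mat = pd.DataFrame(0, index=module_ids, columns=module_ids, dtype=int)
    for a in module_ids:
        for b in module_ids:
            mat.loc[a, b] = len(sets[a] & sets[b]) if a != b else len(sets[a])
    others = {
        m: frozenset().union(*(sets[o] for o in module_ids if o != m))
        if len(module_ids) > 1
        else frozenset()
        for m in module_ids
    }
    exclusive = {m: len(sets[m] - others[m]) for m in module_ids}
    return mat, exclusive


def differential_expression(
    E_pre: ExpressionMatrix, E_post: ExpressionMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Welch t test between the two windows with BH adjustment.

    Genes with zero variance in both groups cannot be tested and are
    flagged ``excluded`` (statistics NaN, never DE).
    """
    if E_pre.n_samples < 3 or E_post.n_samples < 3:
        raise ValueError("each window needs >= 3 samples")
    if E_pre.gene_ids != E_post.gene_ids:
        raise ValueError("gene universes differ between windows")
    A, B = E_pre.values, E_post.values
    both_flat = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    t[both_flat] = np.nan
    p[both_flat] = np.nan
    ok = ~both_flat & np.isfinite(p)
    fdr = np.full(len(t), np.nan)
    fdr[ok] = benjamini_hochberg(p[ok])
    return pd.DataFrame(
        {
            "gene_id": E_pre.gene_ids,
            "t": t,
            "p": p,
            "fdr": fdr,
            "de": ok & (fdr < alpha),
            "excluded": both_flat,
        }
    )
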