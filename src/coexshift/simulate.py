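"""Synthetic two-condition expression generator with planted coexpression modules.

Each module is driven by one latent factor drawn i.i.d. per sample; the
factor loading may differ between the two condition windows, which plants
gain-, loss- and swap-style rewiring of within-module correlation.  A
per-(gene, region) additive offset gives profile clustering a recoverable
region signal, and an optional per-(gene, region) loading jitter makes the
coexpression *structure* region-specific when rewiring is absent.

Expression is emitted on a log-like scale (values may be negative); pass
``exponentiate=True`` for RPKM-like nonnegative output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ModuleSpec",
    "GroundTruth",
    "simulate_expression",
    "simulate_annotations",
    "default_module_specs",
    "PRENATAL_AGES",
    "POSTNATAL_AGES",
    "REGION_NAMES",
]

PRENATAL_AGES = ["12pcw", "13pcw", "16pcw", "17pcw", "21pcw", "24pcw", "37pcw"]
POSTNATAL_AGES = ["4mo", "1yr", "2yr", "3yr", "8yr", "11yr", "13yr"]
REGION_NAMES = ["DFC", "IPC", "MFC", "OFC", "S1C", "STC", "V1C", "VFC"]

REWIRING_TYPES = ("gain", "loss", "swap", "stable", "background")


@dataclass
class ModuleSpec:
    """One planted module: size, per-window loadings, residual noise.

    ``loading_pre``/``loading_post`` may be scalars (shared by every member
    gene) or per-gene arrays of length ``size``; a swap module uses per-gene
    loadings whose dominant window differs between its two halves.
    """

    module_id: int
    size: int
    rewiring_type: str
    loading_pre: object = 0.0
    loading_post: object = 0.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.rewiring_type not in REWIRING_TYPES:
            raise ValueError(f"unknown rewiring_type {self.rewiring_type!r}")
        self.loading_pre = self._expand(self.loading_pre)
        self.loading_post = self._expand(self.loading_post)
        if self.rewiring_type == "stable" and not np.array_equal(
            self.loading_pre, self.loading_post
        ):
            raise ValueError("stable modules must have equal loadings")
        if self.rewiring_type == "background" and (
            np.any(self.loading_pre) or np.any(self.loading_post)
        ):
            raise ValueError("background modules must have zero loadings")

    def _expand(self, loading) -> np.ndarray:
        arr = np.asarray(loading, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.size, float(arr))
        if arr.shape != (self.size,):
            raise ValueError("loading length must equal module size")
        return arr


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a simulated matrix."""

    module_of_gene: dict
    rewiring_type: dict
    rewired_labels: dict = field(default_factory=dict)
    planted_terms: list = field(default_factory=list)
    de_genes: list = field(default_factory=list)
    factor_trajectories: dict = field(default_factory=dict)

    def labels(self, gene_ids, rewired_only: bool = False) -> np.ndarray:
        src = self.rewired_labels if rewired_only else self.module_of_gene
        return np.array([src.get(g, 0) for g in gene_ids], dtype=int)

    def to_json(self, path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "rewiring_type": {str(k): v for k, v in self.rewiring_type.items()},
            "rewired_labels": self.rewired_labels,
            "planted_terms": self.planted_terms,
            "de_genes": self.de_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_of_gene=payload["module_of_gene"],
            rewiring_type={int(k): v for k, v in payload["rewiring_type"].items()},
            rewired_labels=payload.get("rewired_labels", {}),
            planted_terms=[tuple(t) for t in payload.get("planted_terms", [])],
            de_genes=payload.get("de_genes", []),
        )


def default_module_specs(
    n_gain: int = 2,
    n_loss: int = 1,
    n_swap: int = 1,
    n_stable: int = 1,
    module_size: int = 150,
    n_background: int = 1250,
    loading: float = 1.0,
    noise_sd: float = 0.3,
) -> list:
    """Archetypal module roster mirroring the gain/loss/swap/stable design.

    A swap module is split into two halves: the first loses the factor
    across the boundary while the second gains it, with a sign flip keeping
    the two halves coupled through their cross-correlations.
    """
    specs, mid = [], 0
    for _ in range(n_gain):
        mid += 1
        specs.append(ModuleSpec(mid, module_size, "gain", 0.0, loading, noise_sd))
    for _ in range(n_loss):
        mid += 1
        specs.append(ModuleSpec(mid, module_size, "loss", loading, 0.0, noise_sd))
    for _ in range(n_swap):
        mid += 1
        half = module_size // 2
        rest = module_size - half
        pre = np.r_[np.full(half, loading), np.full(rest, -0.35 * loading)]
        post = np.r_[np.full(half, 0.35 * loading), np.full(rest, loading)]
        specs.append(ModuleSpec(mid, module_size, "swap", pre, post, noise_sd))
    for _ in range(n_stable):
        mid += 1
        specs.append(ModuleSpec(mid, module_size, "stable", loading, loading, noise_sd))
    if n_background:
        mid += 1
        specs.append(ModuleSpec(mid, n_background, "background", 0.0, 0.0, noise_sd))
    return specs


def _sample_metadata(n_regions, n_timepoints):
    regions = (
        REGION_NAMES[:n_regions]
        if n_regions <= len(REGION_NAMES)
        else [f"R{i+1:02d}" for i in range(n_regions)]
    )
    if n_timepoints == 7:
        ages = {"prenatal": PRENATAL_AGES, "postnatal": POSTNATAL_AGES}
    else:
        ages = {
            w: [f"{w[:4]}_t{i+1}" for i in range(n_timepoints)]
            for w in ("prenatal", "postnatal")
        }
    rows = []
    for window in ("prenatal", "postnatal"):
        for region in regions:
            for age in ages[window]:
                rows.append(
                    {
                        "sample_id": f"{region}_{age}",
                        "region": region,
                        "age": age,
                        "window": window,
                    }
                )
    return pd.DataFrame(rows), regions


def simulate_expression(
    specs,
    n_regions: int = 8,
    n_timepoints_per_window: int = 7,
    region_effect_sd: float = 0.0,
    region_loading_sd: float = 0.0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
    n_de_genes: int = 0,
    de_effect: float = 0.0,
    exponentiate: bool = False,
    seed: int = 0,
):
    """Draw a two-window, multi-region expression matrix with planted modules.

    Model per gene g and sample s::

        x[g, s] = mu_g + r[g, region(s)]
                  + (lambda_g(window(s)) + eta[g, region(s)]) * f_m(s)
                  + eps,   eps ~ Normal(0, noise_sd^2)

    where ``f_m`` is the module's latent factor, standard normal i.i.d. per
    sample, ``r`` is the per-(gene, region) offset (sd ``region_effect_sd``)
    and ``eta`` an optional per-(gene, region) loading jitter
    (sd ``region_loading_sd``) identical in both windows.  Deterministic
    given ``seed``.

    Returns
    -------
    (ExpressionMatrix, GroundTruth)
    """
    if n_regions < 1 or n_timepoints_per_window < 1:
        raise ValueError("counts must be >= 1")
    if not specs:
        raise ValueError("at least one ModuleSpec required")
    rng = np.random.default_rng(seed)
    meta, regions = _sample_metadata(n_regions, n_timepoints_per_window)
    n_samples = len(meta)
    region_idx = meta["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    is_post = (meta["window"] == "postnatal").to_numpy()

    n_genes = sum(s.size for s in specs)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = np.tile(mu[:, None], (1, n_samples))
    if region_effect_sd > 0:
        r_offsets = rng.normal(0.0, region_effect_sd, size=(n_genes, n_regions))
        values += r_offsets[:, region_idx]

    truth = GroundTruth(module_of_gene={}, rewiring_type={})
    row = 0
    next_rewired = 1
    for spec in specs:
        genes = gene_ids[row : row + spec.size]
        truth.rewiring_type[spec.module_id] = spec.rewiring_type
        for g in genes:
            truth.module_of_gene[g] = spec.module_id
        factor = rng.standard_normal(n_samples)
        lam = np.where(is_post[None, :], spec.loading_post[:, None], spec.loading_pre[:, None])
        if region_loading_sd > 0 and spec.rewiring_type != "background":
            eta = rng.normal(0.0, region_loading_sd, size=(spec.size, n_regions))
            lam = lam + eta[:, region_idx]
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.size, n_samples))
        values[row : row + spec.size] += lam * factor[None, :] + noise
        truth.factor_trajectories[spec.module_id] = factor
        if spec.rewiring_type in ("gain", "loss", "swap"):
            for g in genes:
                truth.rewired_labels[g] = next_rewired
            next_rewired += 1
        row += spec.size

    if n_de_genes:
        if de_effect == 0.0:
            raise ValueError("n_de_genes > 0 requires a nonzero de_effect")
        de_idx = rng.choice(n_genes, size=n_de_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de_genes)
        values[de_idx[:, None], np.flatnonzero(is_post)[None, :]] += (
            signs[:, None] * de_effect
        )
        truth.de_genes = [gene_ids[i] for i in sorted(de_idx)]

    if exponentiate:
        values = np.exp2(values / 2.0)
    E = ExpressionMatrix(gene_ids, values, meta)
    return E, truth


def simulate_annotations(
    truth: GroundTruth,
    gene_ids,
    n_terms: int,
    frac_planted: float,
    term_size_range=(150, 300),
    inside_fraction: float = 0.9,
    seed: int = 0,
) -> GeneSetCollection:
    """Emit a GMT-style collection with planted enriched terms plus decoys.

    A planted term draws ``inside_fraction`` of its members from one rewired
    module and the rest from the background universe; decoys are uniform
    draws from the universe.  Planted (module, term) pairs are appended to
    ``truth.planted_terms``.
    """
    if not 0.0 <= frac_planted <= 1.0:
        raise ValueError("frac_planted must lie in [0, 1]")
    lo, hi = term_size_range
    universe = list(gene_ids)
    if lo < 1 or hi > len(universe):
        raise ValueError("term sizes must be >= 1 and <= universe size")
    rng = np.random.default_rng(seed)
    by_module = {}
    for g in universe:
        m = truth.module_of_gene.get(g)
        if m is not None and truth.rewiring_type.get(m) in ("gain", "loss", "swap", "stable"):
            by_module.setdefault(m, []).append(g)
    module_ids = sorted(by_module)
    n_planted = int(round(frac_planted * n_terms))
    sets = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term_id = f"SYNT:{t:04d}"
        if t < n_planted and module_ids:
            module = module_ids[t % len(module_ids)]
            pool = by_module[module]
            n_in = min(int(round(inside_fraction * size)), len(pool))
            inside = list(rng.choice(pool, size=n_in, replace=False))
            rest_pool = [g for g in universe if g not in set(inside)]
            outside = list(rng.choice(rest_pool, size=size - n_in, replace=False))
            members = inside + outside
            truth.planted_terms.append((module, term_id))
            name = f"planted module {module}"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            name = "decoy"
        sets[term_id] = (name, tuple(members))
    return GeneSetCollection(sets, frozenset(universe), min_term_size=min(lo, 150))
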