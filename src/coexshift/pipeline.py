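"""Stage orchestration: run the analysis end to end and write artifacts.

Every stage writes plain-text outputs (TSV/JSON/GraphML/Newick) into the
output directory; ``run_pipeline`` records parameters, package versions and
per-file SHA-256 checksums in ``manifest.json`` so a rerun with the same
config and seed can be verified byte-for-byte.  Failures leave partial
outputs behind alongside a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, diffcoex, enrich, graph
from .io import (
    ExpressionMatrix,
    filter_zero_variance,
    read_expression,
    read_gmt,
    split_samples,
)

log = logging.getLogger("coexshift")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run (defaults = study values)."""

    expression: str = ""
    metadata: str = ""
    go_gmt: str = ""
    tf_gmt: str = ""
    out_dir: str = "coexshift_out"
    beta: int = 6
    min_module_size: int = 100
    merge_r: float = 0.9
    edge_threshold: float = 0.95
    n_perm_module: int = 1000
    n_samples_enrichment: int = 10000
    n_perm_exclusivity: int = 10000
    min_term_size: int = 150
    alpha: float = 0.05
    seed: int = 0
    pca_scale: bool = False
    stages: list = field(
        default_factory=lambda: ["profiles", "structure", "diffcoex", "enrich", "rewire"]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "coexshift": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def stage_profiles(E: ExpressionMatrix, out: Path, cfg: RunConfig) -> dict:
    pca = compare.pca_scores(E, scale=cfg.pca_scale)
    h_window, p_window = compare.factor_association(
        pca.scores[:, 0], E.samples["window"].to_numpy()
    )
    h_region, p_region = compare.factor_association(
        pca.scores[:, 0], E.samples["region"].to_numpy()
    )
    profiles = compare.average_profiles(E)
    profiles.to_csv(out / "average_profiles.tsv", sep="\t")
    dist = compare.correlation_distance_matrix(
        [profiles[c].to_numpy() for c in profiles.columns], list(profiles.columns)
    )
    dist.to_frame().to_csv(out / "profile_distance.tsv", sep="\t")
    dend = compare.average_linkage_cluster(dist)
    (out / "profile_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    split_a, split_b = compare.top_split(dend)
    summary = {
        "variance_fraction_pc1": float(pca.variance_fraction[0]),
        "variance_fraction_pc1_pc2": float(pca.variance_fraction[:2].sum()),
        "kruskal_window": {"H": h_window, "p": p_window},
        "kruskal_region": {"H": h_region, "p": p_region},
        "profile_top_split": [sorted(split_a), sorted(split_b)],
    }
    (out / "profiles_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def stage_structure(E: ExpressionMatrix, out: Path, cfg: RunConfig) -> dict:
    labels, mats, dropped = compare.stratum_coexpression_matrices(E)
    dist = compare.correlation_distance_matrix(mats, labels)
    dist.to_frame().to_csv(out / "structure_distance.tsv", sep="\t")
    dend = compare.average_linkage_cluster(dist)
    (out / "structure_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    split_a, split_b = compare.top_split(dend)
    summary = {
        "n_strata": len(labels),
        "n_genes_dropped_within_stratum": len(dropped),
        "structure_top_split": [sorted(split_a), sorted(split_b)],
    }
    (out / "structure_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def stage_diffcoex(E: ExpressionMatrix, out: Path, cfg: RunConfig):
    (label_pre, E_pre), (label_post, E_post) = split_samples(E, "window")
    log.info("diffcoex strata: %s=%d, %s=%d samples",
             label_pre, E_pre.n_samples, label_post, E_post.n_samples)
    C_pre = diffcoex.coexpression(E_pre)
    C_post = diffcoex.coexpression(E_post)
    D = diffcoex.adjacency_difference(C_pre, C_post, beta=cfg.beta)
    r2 = diffcoex.scale_free_fit(D)
    tom = diffcoex.topological_overlap(D)
    dend = diffcoex.tom_dendrogram(tom, E.gene_ids)
    assign = diffcoex.cut_modules(dend, min_module_size=cfg.min_module_size)
    n_before = len(assign.module_ids())
    merged = diffcoex.merge_modules(E, assign, r_threshold=cfg.merge_r)
    eig = diffcoex.module_eigengenes(E, merged) if merged.module_ids() else None
    log.info("modules: %d detected, %d after merge", n_before, len(merged.module_ids()))

    pd.DataFrame({"gene_id": merged.gene_ids, "module": merged.labels}).to_csv(
        out / "module_assignment.tsv", sep="\t", index=False
    )
    if eig is not None:
        eig_frame = pd.DataFrame(
            {f"M{m}": eig.eigengenes[m] for m in sorted(eig.eigengenes)},
            index=E.samples["sample_id"],
        )
        eig_frame.to_csv(out / "eigengenes.tsv", sep="\t")

    stats_rows = []
    for m in merged.module_ids():
        sub_seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(m,))
        stat = diffcoex.rewiring_permutation_test(
            E,
            merged.genes_of(m),
            n_perm=cfg.n_perm_module,
            seed=sub_seed,
            module_id=m,
        )
        stats_rows.append(
            {
                "module": m,
                "n_genes": stat.n_genes,
                "mean_r_pre": stat.mean_r_pre,
                "mean_r_post": stat.mean_r_post,
                "delta": stat.delta,
                "p": stat.p,
            }
        )
    stats = pd.DataFrame(
        stats_rows,
        columns=["module", "n_genes", "mean_r_pre", "mean_r_post", "delta", "p"],
    )
    stats.to_csv(out / "rewiring_stats.tsv", sep="\t", index=False)
    summary = {
        "scale_free_r2": r2,
        "n_modules_before_merge": n_before,
        "n_modules": len(merged.module_ids()),
        "module_sizes": merged.sizes(),
    }
    (out / "diffcoex_summary.json").write_text(json.dumps(summary, indent=1))
    return merged, C_pre, C_post, summary


def stage_enrich(E: ExpressionMatrix, merged, out: Path, cfg: RunConfig) -> dict:
    background = set(E.gene_ids)
    summary = {}
    enriched_tf = {}
    if cfg.go_gmt:
        go = read_gmt(cfg.go_gmt, background, min_term_size=cfg.min_term_size)
        tables = []
        for m in merged.module_ids():
            tables.append(
                enrich.zscore_enrichment(
                    merged.genes_of(m),
                    go,
                    n_samples=cfg.n_samples_enrichment,
                    alpha=cfg.alpha,
                    seed=cfg.seed + 1000 + m,
                    module_id=m,
                )
            )
        table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        if len(table):
            summary["n_modules_go_enriched"] = int(
                table[table["significant"]]["module"].nunique()
            )
    if cfg.tf_gmt:
        tf = read_gmt(cfg.tf_gmt, background, min_term_size=1)
        tables = []
        for m in merged.module_ids():
            t = enrich.hypergeom_enrichment(
                merged.genes_of(m), tf, alpha=cfg.alpha, module_id=m
            )
            tables.append(t)
            enriched_tf[m] = set(t[t["significant"]]["term_id"])
        table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        table.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False)
        if enriched_tf:
            universe = set(tf.sets)
            result = enrich.tf_exclusivity_test(
                enriched_tf,
                universe,
                n_perm=cfg.n_perm_exclusivity,
                seed=cfg.seed + 2000,
            )
            (out / "tf_exclusivity.json").write_text(
                json.dumps(result.as_dict(), indent=1)
            )
            mat, exclusive = enrich.overlap_counts(enriched_tf)
            mat.to_csv(out / "tf_overlap_counts.tsv", sep="\t")
            summary["tf_exclusivity"] = result.as_dict()
            summary["tf_exclusive_per_module"] = {
                str(k): v for k, v in exclusive.items()
            }
    (out / "enrich_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def stage_rewire(merged, C_pre, C_post, gene_ids, out: Path, cfg: RunConfig) -> dict:
    summary = {}
    for m in merged.module_ids():
        edges = graph.classify_edges(
            C_pre, C_post, merged.genes_of(m), gene_ids, threshold=cfg.edge_threshold
        )
        graph.export_graph(edges, out / f"module_{m}_edges.graphml", fmt="graphml")
        graph.export_graph(edges, out / f"module_{m}_edges.tsv", fmt="tsv")
        table, means = graph.degree_summary(edges)
        table.to_csv(out / f"module_{m}_degrees.tsv", sep="\t", index=False)
        summary[str(m)] = {
            "n_edges": len(edges.edges),
            "prenatal_only": edges.count("prenatal_only"),
            "postnatal_only": edges.count("postnatal_only"),
            "constant": edges.count("constant"),
            **means,
        }
    (out / "rewire_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages, writing artifacts plus a checksum manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        E = read_expression(cfg.expression, cfg.metadata, require_nonnegative=False)
        n_raw = E.n_genes
        E = filter_zero_variance(E)
        log.info("loaded %d genes (%d constant removed), %d samples",
                 E.n_genes, n_raw - E.n_genes, E.n_samples)
        results = {"n_genes": E.n_genes, "n_samples": E.n_samples}
        merged = C_pre = C_post = None
        if "profiles" in cfg.stages:
            stage = "profiles"
            results["profiles"] = stage_profiles(E, out, cfg)
        if "structure" in cfg.stages:
            stage = "structure"
            results["structure"] = stage_structure(E, out, cfg)
        if "diffcoex" in cfg.stages:
            stage = "diffcoex"
            merged, C_pre, C_post, results["diffcoex"] = stage_diffcoex(E, out, cfg)
        if "enrich" in cfg.stages:
            stage = "enrich"
            if merged is None:
                raise ValueError("enrich stage requires diffcoex")
            if cfg.go_gmt and not Path(cfg.go_gmt).exists():
                raise FileNotFoundError(f"GO GMT not found: {cfg.go_gmt}")
            if cfg.tf_gmt and not Path(cfg.tf_gmt).exists():
                raise FileNotFoundError(f"TF GMT not found: {cfg.tf_gmt}")
            results["enrich"] = stage_enrich(E, merged, out, cfg)
        if "rewire" in cfg.stages:
            stage = "rewire"
            if merged is None:
                raise ValueError("rewire stage requires diffcoex")
            results["rewire"] = stage_rewire(
                merged, C_pre, C_post, E.gene_ids, out, cfg
            )
        stage = "manifest"
        manifest = {
            "config": asdict(cfg),
            "versions": _versions(),
            "results": results,
            "checksums": {
                p.name: _sha256(p)
                for p in sorted(out.iterdir())
                if p.is_file() and p.name not in ("manifest.json", "FAILED")
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out
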