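"""Condition-specific high-correlation edges within a module.

A gene pair becomes an edge when its correlation exceeds the threshold in
either condition; the class records which condition carries it
(``prenatal_only``, ``postnatal_only``, or ``constant`` for both).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["EdgeSet", "classify_edges", "degree_summary", "export_graph"]

EDGE_CLASSES = ("prenatal_only", "postnatal_only", "constant")


@dataclass
class EdgeSet:
    """Canonically ordered classified edges plus the threshold that made them."""

    genes: list
    edges: list  # (gene_a, gene_b, class), gene_a < gene_b
    threshold: float

    def __post_init__(self):
        seen = set()
        for a, b, cls in self.edges:
            if not a < b:
                raise ValueError(f"edge ({a}, {b}) not in canonical order")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            if cls not in EDGE_CLASSES:
                raise ValueError(f"unknown edge class {cls!r}")
            seen.add((a, b))

    def count(self, cls: str) -> int:
        return sum(1 for _, _, c in self.edges if c == cls)


def classify_edges(
    C_pre: np.ndarray,
    C_post: np.ndarray,
    module_genes,
    gene_ids,
    threshold: float = 0.95,
    use_abs: bool = False,
) -> EdgeSet:
    """Classify gene pairs by which condition carries a high correlation.

    A pair enters the edge set when r > threshold prenatally or postnatally
    (signed r by default; ``use_abs`` thresholds |r| instead).  Present in
    both conditions means class ``constant``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    genes = sorted(module_genes)
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise KeyError(f"module genes absent from matrices: {missing[:5]}")
    idx = np.array([pos[g] for g in genes])
    sub_pre = np.asarray(C_pre)[np.ix_(idx, idx)]
    sub_post = np.asarray(C_post)[np.ix_(idx, idx)]
    if use_abs:
        sub_pre, sub_post = np.abs(sub_pre), np.abs(sub_post)
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            hit_pre = sub_pre[i, j] > threshold
            hit_post = sub_post[i, j] > threshold
            if hit_pre and hit_post:
                edges.append((genes[i], genes[j], "constant"))
            elif hit_pre:
                edges.append((genes[i], genes[j], "prenatal_only"))
            elif hit_post:
                edges.append((genes[i], genes[j], "postnatal_only"))
    return EdgeSet(genes, edges, threshold)


def degree_summary(edges: EdgeSet):
    """Per-gene and mean degree in each condition.

    Prenatal degree counts prenatal_only plus constant edges; likewise
    postnatal.  Means are taken over all module genes (isolated genes
    count as degree 0).
    """
    pre = {g: 0 for g in edges.genes}
    post = {g: 0 for g in edges.genes}
    for a, b, cls in edges.edges:
        if cls in ("prenatal_only", "constant"):
            pre[a] += 1
            pre[b] += 1
        if cls in ("postnatal_only", "constant"):
            post[a] += 1
            post[b] += 1
    table = pd.DataFrame(
        {
            "gene_id": edges.genes,
            "degree_pre": [pre[g] for g in edges.genes],
            "degree_post": [post[g] for g in edges.genes],
        }
    )
    means = {
        "mean_degree_pre": float(np.mean(table["degree_pre"])) if len(table) else 0.0,
        "mean_degree_post": float(np.mean(table["degree_post"])) if len(table) else 0.0,
    }
    return table, means


def export_graph(edges: EdgeSet, path, fmt: str = "graphml") -> None:
    """Write the classified edge graph as GraphML or a TSV edge list."""
    if fmt == "graphml":
        G = nx.Graph(threshold=edges.threshold)
        G.add_nodes_from(edges.genes)
        for a, b, cls in edges.edges:
            G.add_edge(a, b, **{"class": cls})
        nx.write_graphml(G, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tclass\n")
            for a, b, cls in edges.edges:
                fh.write(f"{a}\t{b}\t{cls}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
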