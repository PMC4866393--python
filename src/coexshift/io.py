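"""Expression matrix, sample metadata, and GMT gene-set input/output.

The expression format is plain TSV: genes in rows, samples in columns, a
header row of sample ids, and the gene id in the first column.  Metadata is
a TSV with columns ``sample_id``, ``region``, ``age``, ``window``; the
``window`` column must be a two-level factor (e.g. prenatal/postnatal).
Gene sets use the standard GMT dialect
(``term<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "FormatError",
    "read_expression",
    "write_expression",
    "filter_zero_variance",
    "split_samples",
    "read_gmt",
    "write_gmt",
]

METADATA_COLUMNS = ("sample_id", "region", "age", "window")


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``values``.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``region``, ``age``,
        ``window``; row order matches the columns of ``values``.
    """

    gene_ids: list
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.samples.shape[0] != self.values.shape[1]:
            raise FormatError(
                f"{self.samples.shape[0]} metadata rows but "
                f"{self.values.shape[1]} sample columns"
            )
        missing = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        windows = sorted(set(self.samples["window"]))
        if self.samples["window"].isna().any() or "" in windows:
            raise FormatError("every sample needs a window label")
        if len(windows) > 2:
            raise FormatError(
                f"window must be a two-level factor, got {windows}"
            )
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def windows(self) -> list:
        """Window labels in canonical order (prenatal first when present)."""
        levels = sorted(set(self.samples["window"]))
        if set(levels) == {"prenatal", "postnatal"}:
            return ["prenatal", "postnatal"]
        return levels

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(list(gene_ids), self.values[idx], self.samples.copy())

    def subset_samples(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            self.gene_ids,
            self.values[:, idx],
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.samples["sample_id"]
        )


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a background universe.

    ``sets`` maps term id -> (term name, tuple of member genes found in the
    background).  Terms whose post-intersection size falls below
    ``min_term_size`` are kept in ``sets`` but listed in ``excluded``.
    """

    sets: dict
    background: frozenset
    min_term_size: int = 150
    excluded: set = field(default_factory=set)

    def __post_init__(self):
        self.background = frozenset(self.background)
        for term_id, (name, members) in self.sets.items():
            members = tuple(m for m in members)
            if not set(members) <= self.background:
                raise FormatError(
                    f"term {term_id} has members outside the background"
                )
            self.sets[term_id] = (name, members)

    def retained(self) -> dict:
        """Term id -> (name, members) for terms meeting the size floor."""
        return {t: v for t, v in self.sets.items() if t not in self.excluded}

    def members(self, term_id) -> frozenset:
        return frozenset(self.sets[term_id][1])

    def __len__(self) -> int:
        return len(self.sets)


def read_expression(matrix_path, metadata_path, require_nonnegative: bool = True) -> ExpressionMatrix:
    """Read an expression TSV plus its sample metadata TSV.

    Sample order follows the metadata row order; the matrix columns are
    re-ordered to match.  Raises :class:`FormatError` when the two files
    disagree on sample ids or a cell is not numeric.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing columns: {missing_cols}")
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    matrix_ids = list(raw.columns)
    meta_ids = list(meta["sample_id"])
    only_matrix = sorted(set(matrix_ids) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(matrix_ids))
    if only_matrix or only_meta:
        raise FormatError(
            "sample ids disagree between matrix and metadata: "
            f"matrix-only={only_matrix} metadata-only={only_meta}"
        )
    raw = raw[meta_ids]
    for j, col in enumerate(raw.columns):
        if not np.issubdtype(raw[col].dtype, np.number):
            bad = raw[col].apply(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            row = raw.index[bad.to_numpy().argmax()]
            raise FormatError(f"non-numeric value at gene {row!r}, sample {col!r}")
    values = raw.to_numpy(dtype=float)
    if require_nonnegative and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(list(raw.index), values, meta)


def write_expression(E: ExpressionMatrix, matrix_path, metadata_path) -> None:
    """Write the matrix and metadata as TSV (full ``repr`` float precision)."""
    frame = E.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    E.samples.to_csv(metadata_path, sep="\t", index=False)


def filter_zero_variance(E: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose value is constant across all samples.

    Variance is taken jointly over every sample (both windows, all regions);
    per-stratum constancy is handled downstream.  Idempotent.
    """
    if E.n_genes == 0:
        raise FormatError("empty expression matrix")
    keep = E.values.max(axis=1) > E.values.min(axis=1)
    if not keep.any():
        raise FormatError("no genes survive variance filter")
    return ExpressionMatrix(
        [g for g, k in zip(E.gene_ids, keep) if k], E.values[keep], E.samples.copy()
    )


def split_samples(E: ExpressionMatrix, by: str):
    """Partition samples into disjoint groups.

    Parameters
    ----------
    by : {'window', 'region', 'region_window'}
        Grouping key.  ``region_window`` yields one group per
        (region, window) pair, labelled ``"<region>:<window>"``.

    Returns
    -------
    list of (label, ExpressionMatrix)
        Deterministically ordered: windows in canonical order, regions
        sorted lexicographically.
    """
    meta = E.samples
    if by == "window":
        keys = [(w,) for w in E.windows]
        label_of = lambda k: k[0]
        col = lambda k: meta["window"] == k[0]
    elif by == "region":
        keys = [(r,) for r in sorted(set(meta["region"]))]
        label_of = lambda k: k[0]
        col = lambda k: meta["region"] == k[0]
    elif by in ("region_window", "region×window"):
        keys = [
            (r, w)
            for r in sorted(set(meta["region"]))
            for w in E.windows
        ]
        label_of = lambda k: f"{k[0]}:{k[1]}"
        col = lambda k: (meta["region"] == k[0]) & (meta["window"] == k[1])
    else:
        raise ValueError(f"unknown grouping key {by!r}")
    groups = []
    for key in keys:
        mask = col(key).to_numpy()
        if not mask.any():
            raise FormatError(f"empty sample group {label_of(key)!r}")
        groups.append((label_of(key), E.subset_samples(mask)))
    return groups


def read_gmt(path, background, min_term_size: int = 150) -> GeneSetCollection:
    """Read a GMT file and intersect each term with ``background``.

    Terms whose post-intersection size is below ``min_term_size`` are
    retained but flagged excluded (the enrichment stage skips them).
    """
    background = frozenset(background)
    sets, excluded = {}, set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            term_id, name, members = parts[0], parts[1], parts[2:]
            if term_id in sets:
                raise FormatError(f"duplicate term id {term_id!r}")
            kept = tuple(g for g in members if g in background)
            sets[term_id] = (name, kept)
            if len(kept) < min_term_size:
                excluded.add(term_id)
    if n_lines == 0:
        raise FormatError(f"empty GMT file: {path}")
    return GeneSetCollection(sets, background, min_term_size, excluded)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in collection.sets.items():
            fh.write("\t".join([term_id, name, *members]) + "\n")
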