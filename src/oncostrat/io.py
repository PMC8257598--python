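"""Readers, writers and merging for the pipeline's three text formats.

Expression matrices are tab-separated (genes in rows, first column the gene
symbol, header row of sample ids), gene sets are GMT, and clinical tables are
CSV with a ``sample_id`` column.  All gene symbols are uppercased at load so
that cohorts annotated with mixed-case symbols intersect correctly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_DIRECTIONS = ("up", "down", "unsigned")


@dataclass
class ExpressionMatrix:
    """log2-scale gene-by-sample expression values.

    ``values`` is a DataFrame indexed by uppercased, unique gene symbols with
    sample ids as columns.  ``dataset_of`` optionally maps each sample to the
    source dataset it came from (populated by :func:`merge_datasets` and by
    the cohort simulator when batches are requested).
    """

    values: pd.DataFrame
    dataset_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index.astype(str).str.upper()
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids after uppercasing: {dupes[:5]}")
        self.values.index = idx
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 genes and 2 samples, got {self.values.shape}"
            )
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValidationError("missing values must be dropped before construction")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols with an optional direction."""

    name: str
    genes: frozenset[str]
    direction: str = "unsigned"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if self.direction not in VALID_DIRECTIONS:
            raise ValidationError(f"direction must be one of {VALID_DIRECTIONS}")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, optionally with survival fields.

    ``data`` is indexed by unique sample id.  ``schema`` maps column names to
    one of ``continuous | binary | categorical``; columns absent from the
    schema are carried along untyped.
    """

    data: pd.DataFrame
    schema: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        for col, kind in self.schema.items():
            if kind not in ("continuous", "binary", "categorical"):
                raise ValidationError(f"unknown column type {kind!r} for {col!r}")
            if col not in self.data.columns:
                continue
            if kind == "binary":
                vals = self.data[col].dropna().unique()
                if not set(vals) <= {0, 1}:
                    raise ValidationError(f"binary column {col!r} has values {vals}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def missing_counts(self) -> pd.Series:
        return self.data.isna().sum()


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, transform: str = "none") -> ExpressionMatrix:
    """Read a tab-separated genes-by-samples matrix.

    Rows with any missing/non-numeric value are dropped (count logged);
    duplicate symbols keep the row with the highest mean expression.  With
    ``transform="log2p1"`` values become ``log2(x + 1)``.
    """
    if transform not in ("none", "log2p1"):
        raise ValidationError(f"unknown transform {transform!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise FormatError("header must contain a gene column and >=2 samples")
        sample_ids = header[1:]
        symbols: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            symbols.append(fields[0])
            rows.append(fields[1:])
    df = pd.DataFrame(rows, index=symbols, columns=sample_ids)
    df = df.apply(pd.to_numeric, errors="coerce")
    n_dropped = int(df.isna().any(axis=1).sum())
    if n_dropped:
        logger.warning("dropping %d gene rows with missing values", n_dropped)
        df = df.dropna()
    df.index = df.index.astype(str).str.upper()
    if any(s != s.upper() for s in symbols):
        logger.warning("mixed-case gene symbols were uppercased")
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.warning("resolving %d duplicate gene symbols by max mean", n_dup)
        order = pd.Series(range(len(df)), index=df.index)
        means = df.mean(axis=1)
        keep = (
            pd.DataFrame({"mean": means.values, "pos": order.values}, index=df.index)
            .reset_index(names="gene")
            .sort_values(["gene", "mean"], kind="stable")
            .groupby("gene", sort=False)
            .tail(1)
            .sort_values("pos")["pos"]
            .values
        )
        df = df.iloc[keep]
    if transform == "log2p1":
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT lines need >=3 fields")
            name = fields[0]
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"line {lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, genes))
    return sets


def write_gmt(sets: list[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical(path, schema: dict[str, str] | None = None) -> ClinicalTable:
    """Read a clinical CSV keyed by ``sample_id``.

    Missingness is reported per column; rows with missing survival time are
    retained here (survival analyses exclude them downstream).
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("clinical CSV must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in clinical file")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    schema = dict(schema or {})
    for col, kind in schema.items():
        if col not in df.columns:
            continue
        if kind in ("continuous", "binary"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(f"non-numeric value in {kind} column {col!r}, row {row!r}")
            df[col] = coerced
    missing = df.isna().sum()
    for col, n in missing.items():
        if n:
            logger.info("clinical column %r: %d missing values", col, int(n))
    return ClinicalTable(df, schema)


def write_clinical(tab: ClinicalTable, path) -> None:
    tab.data.to_csv(path, index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# merging cohorts


def merge_datasets(
    matrices: list[ExpressionMatrix],
    adjust: str = "none",
    names: list[str] | None = None,
) -> ExpressionMatrix:
    """Merge cohorts onto the intersection of their gene symbols.

    Genes are matched by uppercased symbol and the merged order is sorted for
    determinism.  With ``adjust="center"`` every gene is median-centered
    within each source dataset, a simple location-only batch adjustment;
    centering is idempotent.
    """
    if adjust not in ("none", "center"):
        raise ValidationError(f"unknown adjust mode {adjust!r}")
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to merge")
    common: set[str] = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValidationError("gene intersection across datasets is empty")
    genes = sorted(common)
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.samples)
    if len(set(all_samples)) != len(all_samples):
        raise ValidationError("duplicate sample ids across datasets")
    if names is None:
        names = []
        for i, m in enumerate(matrices):
            tags = set((m.dataset_of or {}).values())
            names.append(tags.pop() if len(tags) == 1 else f"dataset{i + 1}")
    blocks = []
    dataset_of: dict[str, str] = {}
    for m, tag in zip(matrices, names):
        block = m.values.loc[genes]
        tags = pd.Series([(m.dataset_of or {}).get(s, tag) for s in m.samples],
                         index=block.columns)
        if adjust == "center":
            parts = []
            for t in tags.unique():
                cols = tags.index[tags == t]
                sub = block[cols]
                parts.append(sub.sub(sub.median(axis=1), axis=0))
            block = pd.concat(parts, axis=1)[block.columns]
        blocks.append(block)
        dataset_of.update(tags.to_dict())
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(merged, dataset_of=dataset_of)
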