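"""Tabular input/output: expression matrices, gene annotation, clinical tables.

Expression tables are tab-delimited with a probe/gene identifier in the first
column and sample identifiers in the header; annotation is BED-like with
1-based inclusive coordinates plus a cytoband column; clinical data is CSV.
All readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRADE_LEVELS = ("low", "intermediate", "high")

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "cytoband"]

CLINICAL_COLUMNS = [
    "sample_id",
    "time",
    "event",
    "age",
    "tumor_size",
    "grade",
    "node_negative",
    "her2",
    "er",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a batch label per sample.

    ``values`` is a float DataFrame indexed by gene (or probe) identifiers with
    sample identifiers as columns. ``batches`` maps each sample to its batch
    label and is index-aligned with the columns.
    """

    values: pd.DataFrame
    batches: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.batches = pd.Series(self.batches)
        missing = [s for s in self.values.columns if s not in self.batches.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing}")
        self.batches = self.batches.loc[self.values.columns]
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def batch_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.batches:
            seen.setdefault(b, None)
        return list(seen)

    def batch_columns(self, batch: str) -> list[str]:
        return [s for s in self.values.columns if self.batches[s] == batch]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_table(path, batch_label: str) -> ExpressionMatrix:
    """Read a tab-delimited genes-x-samples table, labelling all samples with one batch.

    The first column holds probe/gene identifiers; the header row holds sample
    identifiers. Empty cells are recorded as missing (NaN); any other
    non-numeric cell raises with its row/column coordinates.
    """
    header = pd.read_csv(path, sep="\t", header=None, nrows=1, dtype=str).iloc[0]
    sample_ids = pd.Index(header.iloc[1:])
    if sample_ids.has_duplicates:  # pandas would silently mangle these to S1.1 etc.
        dups = sample_ids[sample_ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in header of {path}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene/probe ids in {path}: {dups}")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        parsed = np.empty(raw.shape[0])
        for i, cell in enumerate(raw[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(cell)  # exact repr round-trip, unlike pd.to_numeric
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at row {raw.index[i]!r}, column {col!r} in {path}"
                ) from None
        values[col] = parsed
    batches = pd.Series(batch_label, index=values.columns)
    return ExpressionMatrix(values=values, batches=batches)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the dialect :func:`read_expression_table` reads.

    Uses ``repr`` round-trip float formatting so read-after-write reproduces
    values bit-for-bit.
    """
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format=lambda x: repr(float(x)))


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene, keeping the probe with the
    highest median expression across samples (missing values excluded from the
    median; ties broken toward the lexicographically smaller probe id)."""
    unmapped = [p for p in matrix.values.index if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes absent from probe map: {unmapped}")
    medians = matrix.values.median(axis=1, skipna=True)
    best: dict[str, str] = {}
    for probe in matrix.values.index:
        gene = probe_map[probe]
        cur = best.get(gene)
        if cur is None:
            best[gene] = probe
        else:
            m_new, m_cur = medians[probe], medians[cur]
            if (m_new > m_cur) or (m_new == m_cur and probe < cur):
                best[gene] = probe
    genes = list(best)
    values = matrix.values.loc[[best[g] for g in genes]].copy()
    values.index = pd.Index(genes, name=matrix.values.index.name)
    return ExpressionMatrix(values=values, batches=matrix.batches.copy())


def merge_batches(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts over samples, restricting to genes present in every
    batch (platform intersection). Batch labels are preserved; sample id
    collisions across batches raise."""
    if not matrices:
        raise ValueError("need at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index, sort=False)
    # keep first batch's gene order for determinism
    common = [g for g in matrices[0].values.index if g in set(common)]
    seen: set[str] = set()
    for m in matrices:
        collide = seen.intersection(m.values.columns)
        if collide:
            raise ValueError(f"sample id collision across batches: {sorted(collide)}")
        seen.update(m.values.columns)
    values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    batches = pd.concat([m.batches for m in matrices])
    return ExpressionMatrix(values=values, batches=batches)


def drop_sparse_genes(matrix: ExpressionMatrix, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Drop genes missing in more than ``max_missing_frac`` of samples in any
    batch, logging what was removed."""
    keep = pd.Series(True, index=matrix.values.index)
    for batch in matrix.batch_names:
        cols = matrix.batch_columns(batch)
        frac = matrix.values[cols].isna().mean(axis=1)
        keep &= frac <= max_missing_frac
    dropped = matrix.values.index[~keep].tolist()
    if dropped:
        logger.warning("dropping %d genes with >%d%% missing values in some batch: %s",
                       len(dropped), int(max_missing_frac * 100), dropped[:10])
    return ExpressionMatrix(values=matrix.values.loc[keep].copy(), batches=matrix.batches.copy())


def read_gene_annotation(path) -> pd.DataFrame:
    """Read BED-like gene annotation (gene_id, chrom, start, end, cytoband).

    Coordinates are 1-based inclusive, as printed in cytogenetic tables; use
    :func:`to_bed` for 0-based half-open export. The result is validated and
    sorted by (chrom, start); thousands separators in coordinates are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {missing}")
    if df.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS).astype({"start": int, "end": int})
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ("start", "end"):
        df[col] = df[col].str.replace(",", "", regex=False).astype(int)
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValueError(f"start > end for genes: {df.loc[bad, 'gene_id'].tolist()}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"duplicate gene ids in annotation: "
                         f"{df.loc[df['gene_id'].duplicated(), 'gene_id'].tolist()}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def to_bed(annotation: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive annotation to BED's 0-based half-open convention."""
    bed = annotation[["chrom", "start", "end", "gene_id"]].copy()
    bed["start"] = bed["start"] - 1
    return bed.rename(columns={"gene_id": "name"})


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical_table(path) -> pd.DataFrame:
    """Read the clinical CSV (sample_id, time, event, age, tumor_size, grade,
    node_negative, her2, er). Missing covariates stay missing (no imputation);
    unknown grade labels and negative times raise."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "time", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} missing columns: {missing}")
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    df["time"] = df["time"].astype(float)
    if (df["time"] < 0).any():
        raise ValueError("negative follow-up times in clinical table")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    if "grade" in df.columns:
        known = df["grade"].dropna()
        bad = ~known.isin(GRADE_LEVELS)
        if bad.any():
            raise ValueError(f"unknown grade labels: {sorted(known[bad].unique())}")
    return df.set_index("sample_id", drop=False)


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
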