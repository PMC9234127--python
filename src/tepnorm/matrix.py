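"""Gene-by-sample count and expression matrices.

The pipeline consumes a processed RNA-seq count matrix (genes as rows,
samples as columns) together with a sample sheet that assigns each sample
a condition label (e.g. ``normal`` vs. a tumor subtype) and, optionally,
the number of intron-spanning reads used as a per-sample quality metric.
Expression is quantified as log2 counts-per-million with a pseudo-count:

    log2CPM(g, s) = log2( count(g, s) / libsize(s) * 1e6 + prior )

where ``libsize(s)`` is the column sum of the (sample-filtered) matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "log2cpm",
]


def _sniff_sep(path: Path) -> str:
    """Infer the delimiter from the header line (TSV or CSV)."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file or blank header line")
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,;").delimiter
    except csv.Error:
        # single-column file; delimiter is irrelevant
        return "\t"


@dataclass
class CountMatrix:
    """Raw RNA-seq counts with per-sample group labels.

    Attributes
    ----------
    counts : DataFrame, genes (rows) x samples (columns), non-negative ints.
    groups : Series mapping sample id -> condition label.
    intron_spanning_reads : Series mapping sample id -> read total, or None.
    """

    counts: pd.DataFrame
    groups: pd.Series
    intron_spanning_reads: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count(s) present")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.intron_spanning_reads is not None:
            self.intron_spanning_reads = self.intron_spanning_reads.reindex(
                self.counts.columns
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        isr = None
        if self.intron_spanning_reads is not None:
            isr = self.intron_spanning_reads.loc[sample_ids]
        return CountMatrix(self.counts.loc[:, sample_ids], self.groups.loc[sample_ids], isr)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids], self.groups, self.intron_spanning_reads
        )


@dataclass
class ExpressionMatrix:
    """log2CPM expression on the same gene/sample axes as its source counts."""

    values: pd.DataFrame
    groups: pd.Series
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite expression value(s)")
        self.groups = self.groups.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a delimited count matrix plus its sample sheet.

    The matrix has gene ids in the first column and sample ids in the
    header; the sample sheet has columns ``sample_id``, ``group`` and
    optionally ``intron_spanning_reads``. Every sample in the matrix must
    appear in the sheet.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns = raw.columns.astype(str)

    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: empty cell at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative count(s) present")
    counts = numeric.round().astype(np.int64)

    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path))
    for required in ("sample_id", "group"):
        if required not in meta.columns:
            raise ParseError(f"{metadata_path}: missing column {required!r}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{metadata_path}: duplicate sample_id rows")
    meta = meta.set_index("sample_id")
    uncovered = [s for s in counts.columns if s not in meta.index]
    if uncovered:
        raise ValidationError(
            f"samples present in {path} but absent from {metadata_path}: {uncovered}"
        )
    groups = meta["group"].astype(str)
    isr = None
    if "intron_spanning_reads" in meta.columns:
        isr = pd.to_numeric(meta["intron_spanning_reads"])
        if (isr.dropna() < 0).any():
            raise ValidationError("negative intron_spanning_reads")
    return CountMatrix(counts, groups, isr)


def write_counts(cm: CountMatrix, path, metadata_path) -> None:
    """Write matrix and sample sheet in the dialect implied by the extension."""
    path, metadata_path = Path(path), Path(metadata_path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)
    meta = pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.groups.to_numpy()})
    if cm.intron_spanning_reads is not None:
        meta["intron_spanning_reads"] = cm.intron_spanning_reads.to_numpy()
    msep = "," if metadata_path.suffix.lower() == ".csv" else "\t"
    meta.to_csv(metadata_path, sep=msep, index=False)


def log2cpm(cm: CountMatrix, prior: float = 1.0) -> ExpressionMatrix:
    """Library-size-normalize to CPM and take log2 with a pseudo-count.

    Library size is the column sum of the matrix as given (i.e. after any
    sample filtering, before gene filtering downstream of this call).
    """
    if prior <= 0:
        raise ValidationError(f"prior must be positive, got {prior}")
    libsize = cm.counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = cm.counts.div(libsize.astype(float), axis=1) * 1e6
    values = np.log2(cpm + prior)
    return ExpressionMatrix(
        values,
        cm.groups,
        transform_params={"prior": prior, "library_sizes": libsize.to_dict()},
    )
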