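"""Cycle-threshold (Ct) panels.

A Ct panel holds RT-qPCR cycle-threshold measurements for a set of
candidate genes over samples, with replicate structure, per-sample group
labels and an assumed amplification efficiency E (E=2 means perfect
doubling per cycle). Data are stored long:

    sample_id  group  gene  replicate  ct

Missing measurements are NaN. Files may be this long layout or a wide
genes-by-samples table accompanied by a sample sheet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

LONG_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]

__all__ = ["CtPanel", "read_ct", "write_ct"]


@dataclass
class CtPanel:
    data: pd.DataFrame
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct panel missing column(s): {missing}")
        self.data = self.data.loc[:, LONG_COLUMNS].reset_index(drop=True)
        ct = self.data["ct"]
        if (ct.dropna() <= 0).any():
            raise ValidationError("Ct values must be positive where present")
        if self.data.duplicated(["gene", "sample_id", "replicate"]).any():
            raise ValidationError("duplicate (gene, sample, replicate) measurement")
        per_sample = self.data.groupby("sample_id", sort=False)["group"].nunique()
        if (per_sample > 1).any():
            bad = per_sample.index[per_sample > 1].tolist()
            raise ValidationError(f"conflicting group labels for sample(s): {bad}")
        if self.efficiency <= 1:
            raise ValidationError(f"efficiency must exceed 1, got {self.efficiency}")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def groups(self) -> pd.Series:
        """Sample id -> group label, in first-appearance order."""
        return self.data.drop_duplicates("sample_id").set_index("sample_id")["group"]

    @property
    def is_collapsed(self) -> bool:
        return not self.data.duplicated(["gene", "sample_id"]).any()

    def to_wide(self) -> pd.DataFrame:
        """Genes x samples Ct matrix; requires one measurement per cell."""
        if not self.is_collapsed:
            raise ValidationError(
                "panel has replicate structure; collapse replicates first"
            )
        wide = self.data.pivot(index="gene", columns="sample_id", values="ct")
        return wide.reindex(index=self.genes, columns=self.sample_ids)

    @classmethod
    def from_wide(
        cls, ct: pd.DataFrame, groups: pd.Series, efficiency: float = 2.0
    ) -> "CtPanel":
        missing = [s for s in ct.columns if s not in groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        long = ct.stack(future_stack=True).rename("ct").reset_index()
        long.columns = ["gene", "sample_id", "ct"]
        long["group"] = long["sample_id"].map(groups)
        long["replicate"] = 1
        return cls(long[LONG_COLUMNS], efficiency=efficiency)

    def with_data(self, data: pd.DataFrame) -> "CtPanel":
        return replace(self, data=data)


def _sep_of(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_ct(path, metadata_path=None, efficiency: float = 2.0) -> CtPanel:
    """Read a Ct panel, auto-detecting long vs. wide layout from the header."""
    path = Path(path)
    sep = _sep_of(path)
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(sep)]
    if {"sample_id", "gene", "ct"}.issubset(header):
        df = pd.read_csv(path, sep=sep)
        if "replicate" not in df.columns:
            df["replicate"] = 1
        if "group" not in df.columns:
            if metadata_path is None:
                raise ParseError(f"{path}: long layout lacks 'group'; provide a sample sheet")
            meta = pd.read_csv(metadata_path, sep=_sep_of(Path(metadata_path)))
            df["group"] = df["sample_id"].astype(str).map(
                meta.set_index(meta["sample_id"].astype(str))["group"]
            )
        df["sample_id"] = df["sample_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        return CtPanel(df[LONG_COLUMNS], efficiency=efficiency)
    # wide: first column gene ids, remaining columns samples
    if metadata_path is None:
        raise ParseError(f"{path}: wide layout requires a sample sheet for group labels")
    wide = pd.read_csv(path, sep=sep, index_col=0)
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep=_sep_of(Path(metadata_path)))
    meta["sample_id"] = meta["sample_id"].astype(str)
    groups = meta.set_index("sample_id")["group"].astype(str)
    return CtPanel.from_wide(wide, groups, efficiency=efficiency)


def write_ct(panel: CtPanel, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    panel.data.to_csv(path, sep=sep, index=False)
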