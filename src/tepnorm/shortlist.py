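"""Shortlisting of candidate reference genes from a count matrix.

The cascade nominates genes that are highly and stably expressed across
healthy and tumor platelet samples:

1. drop low-quality samples (fewer than ``min_reads`` intron-spanning reads);
2. drop genes with zero counts in more than ``max_zero_frac`` of samples;
3. transform to log2CPM and compute per-group (normal vs. pooled tumor)
   mean, SD and CV = SD/mean;
4. keep genes satisfying, simultaneously on one gene universe:
   (1) balanced means  — both mean ratios < ``fold_max``;
   (2) high expression — top ``top_frac`` by mean in both groups;
   (3) low variability — CV < ``cv_max`` in both groups;
5. refine: mean > ``mean_min`` and CV < ``cv_max_refine`` in both groups;
6. intersect with a curated list of known reference genes.

All cutpoints follow strict-inequality semantics: a sample at exactly the
read threshold is retained, a gene at exactly the zero-fraction threshold
is retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ShortlistConfig
from .errors import ConfigError, ValidationError
from .matrix import CountMatrix, ExpressionMatrix, log2cpm

__all__ = [
    "GroupStats",
    "FilterReport",
    "CandidateSet",
    "filter_samples_by_depth",
    "filter_genes_by_zero_fraction",
    "group_stats",
    "stability_criteria_filter",
    "refine_filter",
    "intersect_known",
    "load_known_list",
    "normalize_gene_id",
    "run_shortlist",
    "ShortlistResult",
]


@dataclass
class GroupStats:
    """Per-gene mean/SD/CV for the normal and (pooled) tumor group.

    ``mean``, ``sd`` and ``cv`` are DataFrames indexed by gene with columns
    ``normal`` and ``tumor``; SD uses the n-1 denominator and CV is NaN
    (undefined) wherever the group mean is not positive.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    cv: pd.DataFrame
    normal_label: str = "normal"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class FilterReport:
    """Per-stage attrition and per-gene pass/fail provenance."""

    stages: list[dict] = field(default_factory=list)
    gene_flags: pd.DataFrame | None = None
    sample_counts: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": name, "entering": n_in, "surviving": n_out,
                            "removed": n_in - n_out})

    def attrition_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def summary(self) -> dict:
        return {"stages": self.stages, "sample_counts": self.sample_counts}


@dataclass
class CandidateSet:
    """Ordered candidate gene list with filter provenance."""

    genes: list[str]
    report: FilterReport | None = None
    known_list_name: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene id(s) in candidate set")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def filter_samples_by_depth(
    cm: CountMatrix, min_reads: int = 400_000, policy: str = "strict"
) -> CountMatrix:
    """Remove samples with strictly fewer than ``min_reads`` intron-spanning reads."""
    isr = cm.intron_spanning_reads
    if isr is None or isr.isna().any():
        if policy == "strict":
            raise ValidationError(
                "intron_spanning_reads metadata missing; set depth_policy='lenient' "
                "to pass samples through unfiltered"
            )
        warnings.warn("intron-spanning read totals missing; sample depth filter skipped")
        if isr is None:
            return cm
        keep = (isr.isna() | (isr >= min_reads))
    else:
        keep = isr >= min_reads
    kept = [s for s, k in zip(cm.sample_ids, keep) if k]
    out = cm.subset_samples(kept)
    groups = set(out.groups)
    if len(groups) < 2:
        raise ValidationError(
            f"sample depth filter left fewer than two groups (remaining: {sorted(groups)})"
        )
    return out


def filter_genes_by_zero_fraction(
    cm: CountMatrix, max_zero_frac: float = 0.70
) -> tuple[CountMatrix, pd.Series]:
    """Remove genes whose zero-count fraction exceeds ``max_zero_frac`` (strict).

    Returns the filtered matrix and the per-gene boolean keep flags.
    """
    zero_frac = (cm.counts == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    return cm.subset_genes(cm.counts.index[keep]), keep


def group_stats(em: ExpressionMatrix, normal_label: str = "normal") -> GroupStats:
    """Per-gene mean/SD/CV in the normal group and the pooled tumor group."""
    is_normal = (em.groups == normal_label).to_numpy()
    out = {}
    for side, mask in (("normal", is_normal), ("tumor", ~is_normal)):
        if mask.sum() < 2:
            raise ValidationError(
                f"group {side!r} has {int(mask.sum())} sample(s); need at least 2"
            )
        sub = em.values.loc[:, em.values.columns[mask]]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = pd.Series(np.where(mean > 0, sd / mean, np.nan), index=mean.index)
        out[side] = (mean, sd, cv)
    mean = pd.DataFrame({s: out[s][0] for s in ("normal", "tumor")})
    sd = pd.DataFrame({s: out[s][1] for s in ("normal", "tumor")})
    cv = pd.DataFrame({s: out[s][2] for s in ("normal", "tumor")})
    return GroupStats(mean, sd, cv, normal_label)


def stability_criteria_filter(
    gs: GroupStats,
    fold_max: float = 1.2,
    top_frac: float = 0.10,
    cv_max: float = 0.10,
    fold_means: pd.DataFrame | None = None,
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the three simultaneous criteria on one gene universe.

    ``fold_means`` optionally supplies alternative means (e.g. linear-scale
    CPM) for the fold criterion; ranking and CV always use ``gs``.
    Returns (survivor index, per-gene flag DataFrame).
    """
    fm = gs.mean if fold_means is None else fold_means
    mn, mt = fm["normal"], fm["tumor"]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_ok = (mn > 0) & (mt > 0) & (mn / mt < fold_max) & (mt / mn < fold_max)

    G = len(gs.mean)
    k = math.ceil(top_frac * G)
    # rank 1 = largest mean; ties at the boundary are all kept (method="min")
    rank_n = gs.mean["normal"].rank(ascending=False, method="min")
    rank_t = gs.mean["tumor"].rank(ascending=False, method="min")
    top_ok = (rank_n <= k) & (rank_t <= k)

    cv_ok = (gs.cv["normal"] < cv_max) & (gs.cv["tumor"] < cv_max)
    cv_ok &= gs.cv["normal"].notna() & gs.cv["tumor"].notna()

    flags = pd.DataFrame(
        {"fold_ok": fold_ok, "top_ok": top_ok, "cv_ok": cv_ok}
    )
    flags["pass_all"] = flags.all(axis=1)
    return gs.mean.index[flags["pass_all"]], flags


def refine_filter(
    gs: GroupStats,
    genes,
    mean_min: float = 1.0,
    cv_max_refine: float = 0.01,
) -> pd.Index:
    """Keep genes with mean > ``mean_min`` and CV < ``cv_max_refine`` in both groups."""
    genes = pd.Index(genes)
    mean_ok = (gs.mean.loc[genes] > mean_min).all(axis=1)
    cv = gs.cv.loc[genes]
    cv_ok = (cv < cv_max_refine).all(axis=1) & cv.notna().all(axis=1)
    return genes[mean_ok & cv_ok]


def normalize_gene_id(gid: str) -> str:
    """Canonical form for intersection: trimmed, uppercased, Ensembl version-stripped."""
    gid = gid.strip().upper()
    if gid.startswith("ENS") and "." in gid:
        gid = gid.split(".", 1)[0]
    return gid


def load_known_list(path) -> list[str]:
    """Plain-text known-reference list: one id per line, '#' comments allowed."""
    genes: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            norm = normalize_gene_id(line)
            if norm not in seen:
                seen.add(norm)
                genes.append(norm)
    return genes


def intersect_known(
    candidates: CandidateSet, known: list[str], known_list_name: str = "known"
) -> CandidateSet:
    """Intersect candidates with the known-reference list, preserving candidate order."""
    if not known:
        raise ConfigError("known reference-gene list is empty")
    known_norm = {normalize_gene_id(g) for g in known}
    kept = [g for g in candidates.genes if normalize_gene_id(g) in known_norm]
    if not kept:
        warnings.warn(
            f"no candidate gene found in known list {known_list_name!r} "
            f"({len(known_norm)} ids)"
        )
    out = CandidateSet(kept, report=candidates.report, known_list_name=known_list_name)
    if out.report is not None:
        out.report.add_stage(f"intersect:{known_list_name}", len(candidates), len(kept))
    return out


@dataclass
class ShortlistResult:
    candidates: CandidateSet          # after the known-list intersection
    pre_intersection: list[str]       # survivors of the refinement step
    pre_refinement: list[str]         # survivors of criteria 1-3
    report: FilterReport
    expression: ExpressionMatrix
    stats: GroupStats


def run_shortlist(cm: CountMatrix, config: ShortlistConfig | None = None) -> ShortlistResult:
    """Execute the full cascade and record attrition at every stage."""
    config = config or ShortlistConfig()
    known_path = config.resolved_known_list()
    known = load_known_list(known_path)  # validated before any computation
    if not known:
        raise ConfigError(f"known reference-gene list {known_path} is empty")

    report = FilterReport()
    n0 = cm.n_samples
    cm = filter_samples_by_depth(cm, config.min_reads, config.depth_policy)
    report.sample_counts = {"entering": n0, "surviving": cm.n_samples}

    n_genes0 = cm.n_genes
    cm, zero_keep = filter_genes_by_zero_fraction(cm, config.max_zero_frac)
    report.add_stage("zero_fraction", n_genes0, cm.n_genes)

    em = log2cpm(cm, config.prior)
    gs = group_stats(em, config.normal_label)

    fold_means = None
    if config.use_linear_means:
        libsize = cm.counts.sum(axis=0).astype(float)
        cpm = cm.counts.div(libsize, axis=1) * 1e6
        is_normal = (em.groups == config.normal_label).to_numpy()
        fold_means = pd.DataFrame(
            {
                "normal": cpm.loc[:, cpm.columns[is_normal]].mean(axis=1),
                "tumor": cpm.loc[:, cpm.columns[~is_normal]].mean(axis=1),
            }
        )

    survivors, flags = stability_criteria_filter(
        gs, config.fold_max, config.top_frac, config.cv_max, fold_means
    )
    report.add_stage("stability_criteria", cm.n_genes, len(survivors))

    refined = refine_filter(gs, survivors, config.mean_min, config.cv_max_refine)
    report.add_stage("refinement", len(survivors), len(refined))

    gene_flags = flags.copy()
    gene_flags["refine_ok"] = gene_flags.index.isin(refined)
    report.gene_flags = gene_flags

    candidates = CandidateSet(list(refined), report=report)
    final = intersect_known(candidates, known, known_list_name=known_path.name)
    return ShortlistResult(
        candidates=final,
        pre_intersection=list(refined),
        pre_refinement=list(survivors),
        report=report,
        expression=em,
        stats=gs,
    )
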