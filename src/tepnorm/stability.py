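"""Expression-stability statistics for candidate reference genes.

Four classical algorithms are implemented on collapsed Ct panels, plus a
comprehensive rank aggregation:

comparative ΔCt
    For every gene pair, the SD over samples of the per-sample Ct
    difference; a gene's statistic is the mean of its pairwise SDs.
    A gene that co-varies with every other gene (stable up to shared
    loading effects) has a small value.

geNorm
    On log2 relative quantities, the gene-stability measure M(i) is the
    mean SD of a gene's pairwise log-ratios. The gene with the largest M
    is removed iteratively until the two most stable genes remain; the
    pairwise-variation series V(n/n+1) compares normalization factors
    (geometric means of the top-n genes' relative quantities).

NormFinder-style model-based estimate
    After centering each sample across genes, a gene's stability value
    combines its shrunken between-group bias with its within-group
    variability, weighted by group size. Lower is more stable.

BestKeeper
    Descriptive statistics on the raw Ct scale — here "SD" is the mean
    absolute deviation (MAD) around the arithmetic Ct mean, CV% its ratio
    to the mean — plus each gene's Pearson correlation with the
    BestKeeper index (per-sample geometric mean Ct across genes).

All ranks are ascending in the stability value (rank 1 = most stable),
with average ranks on ties; geNorm's final pair shares rank 1.5. The
comprehensive rank orders genes by the geometric mean of their per-method
ranks, ties broken alphabetically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ct import CtPanel
from .errors import ValidationError

__all__ = [
    "prepare_log_quantities",
    "delta_ct_stability",
    "genorm",
    "normfinder",
    "bestkeeper",
    "aggregate_ranks",
    "rank_stability",
    "DeltaCtResult",
    "GeNormTrace",
    "NormFinderResult",
    "BestKeeperResult",
    "StabilityTable",
]


def _wide(panel: CtPanel) -> pd.DataFrame:
    wide = panel.to_wide()
    all_missing = wide.index[wide.isna().all(axis=1)]
    if len(all_missing):
        warnings.warn(f"dropping gene(s) with no Ct values: {list(all_missing)}")
        wide = wide.drop(index=all_missing)
    return wide


def _complete_cases(wide: pd.DataFrame, drop_gene_first: bool = False) -> pd.DataFrame:
    """Samples with a value for every retained gene.

    With ``drop_gene_first``, genes missing in more than half the samples
    are dropped before samples are, rescuing panels where one gene would
    otherwise wipe out most samples.
    """
    if drop_gene_first:
        frac = wide.isna().mean(axis=1)
        wide = wide.loc[frac <= 0.5]
    return wide.loc[:, wide.notna().all(axis=0)]


def prepare_log_quantities(panel: CtPanel) -> pd.DataFrame:
    """Per-gene calibrated log2 relative quantities.

    a(g, s) = (Ct_cal(g) - Ct(g, s)) * log2(E), calibrated per gene to its
    least-expressed sample (highest Ct) so quantities are >= 1. The
    calibration constant affects no pairwise difference, SD or ratio of
    normalization factors downstream.
    """
    wide = _wide(panel)
    scale = math.log2(panel.efficiency)
    return wide.rsub(wide.max(axis=1), axis=0) * scale


@dataclass
class DeltaCtResult:
    values: pd.Series   # mean pairwise SD of ΔCt, cycles
    ranks: pd.Series
    pairwise_sd: pd.DataFrame


def _avg_ranks(values: pd.Series) -> pd.Series:
    return pd.Series(sps.rankdata(values.to_numpy(), method="average"),
                     index=values.index)


def delta_ct_stability(panel: CtPanel, pair_policy: str = "error") -> DeltaCtResult:
    """Comparative ΔCt statistic on pairwise-complete samples.

    ``pair_policy``: "error" (default) fails when a gene pair shares fewer
    than 3 samples; "drop" omits such pairs from the mean.
    """
    wide = _wide(panel)
    genes = list(wide.index)
    if len(genes) < 3:
        raise ValidationError("comparative ΔCt requires at least three genes")
    sd = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gi in enumerate(genes):
        for gk in genes[i + 1:]:
            diff = (wide.loc[gi] - wide.loc[gk]).dropna()
            if len(diff) < 3:
                if pair_policy == "error":
                    raise ValidationError(
                        f"gene pair ({gi}, {gk}) has {len(diff)} complete samples; "
                        "need at least 3 (or set pair_policy='drop')"
                    )
                continue
            sd.loc[gi, gk] = sd.loc[gk, gi] = diff.std(ddof=1)
    values = sd.mean(axis=1, skipna=True)
    if values.isna().any():
        raise ValidationError(
            f"no usable gene pair for gene(s): {list(values.index[values.isna()])}"
        )
    return DeltaCtResult(values.rename("delta_ct"), _avg_ranks(values), sd)


@dataclass
class GeNormTrace:
    steps: list[dict]                 # [{"m_values": {gene: M}, "removed": gene|None}]
    final_pair: tuple[str, str]
    ranks: pd.Series                  # final pair at 1.5, else reverse removal order
    m_at_elimination: pd.Series       # gene's M when removed (pair: mutual SD)
    v_series: dict[str, float] = field(default_factory=dict)   # "V2/3": value
    normalization_factors: dict[int, pd.Series] = field(default_factory=dict)
    ranking_order: list[str] = field(default_factory=list)     # most stable first


def _pairwise_sd_matrix(a: pd.DataFrame) -> pd.DataFrame:
    genes = list(a.index)
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gi in enumerate(genes):
        for gk in genes[i + 1:]:
            v = (a.loc[gi] - a.loc[gk]).std(ddof=1)
            out.loc[gi, gk] = out.loc[gk, gi] = v
    return out


def genorm(panel: CtPanel, drop_gene_first: bool = False) -> GeNormTrace:
    """Stepwise geNorm elimination with M trace, V series and NF factors."""
    a = _complete_cases(prepare_log_quantities(panel), drop_gene_first)
    genes = list(a.index)
    if len(genes) < 3:
        raise ValidationError("geNorm requires at least three genes")
    if a.shape[1] < 3:
        raise ValidationError(
            f"geNorm requires at least three complete-case samples, found {a.shape[1]}"
        )

    remaining = list(genes)
    steps: list[dict] = []
    removal_order: list[str] = []
    m_at_elim: dict[str, float] = {}
    while len(remaining) >= 2:
        sub = a.loc[remaining]
        sd = _pairwise_sd_matrix(sub)
        M = sd.mean(axis=1, skipna=True)
        if len(remaining) == 2:
            steps.append({"m_values": M.to_dict(), "removed": None})
            for g in remaining:
                m_at_elim[g] = float(M[g])
            break
        worst_val = M.max()
        # deterministic tie-break: lexicographically last gene id
        worst = max(g for g in remaining if M[g] == worst_val)
        steps.append({"m_values": M.to_dict(), "removed": worst})
        m_at_elim[worst] = float(M[worst])
        remaining.remove(worst)
        removal_order.append(worst)

    final_pair = tuple(remaining)
    ranks = pd.Series(index=genes, dtype=float)
    ranks[list(final_pair)] = 1.5
    for pos, g in enumerate(reversed(removal_order)):
        ranks[g] = 3 + pos
    ranking_order = list(final_pair) + list(reversed(removal_order))

    # normalization factors: geometric mean of relative quantities of top-n genes
    q_log = a  # log2 of relative quantities
    nf: dict[int, pd.Series] = {}
    for n in range(2, len(genes) + 1):
        top = ranking_order[:n]
        nf[n] = np.exp2(q_log.loc[top].mean(axis=0)).rename(f"NF{n}")
    v_series: dict[str, float] = {}
    for n in range(2, len(genes)):
        ratio = np.log2(nf[n] / nf[n + 1])
        v_series[f"V{n}/{n + 1}"] = float(ratio.std(ddof=1))

    return GeNormTrace(
        steps=steps,
        final_pair=final_pair,
        ranks=ranks,
        m_at_elimination=pd.Series(m_at_elim).reindex(genes).rename("genorm_M"),
        v_series=v_series,
        normalization_factors=nf,
        ranking_order=ranking_order,
    )


@dataclass
class NormFinderResult:
    rho: pd.Series
    ranks: pd.Series
    group_bias: pd.DataFrame | None = None     # shrunken |d| per gene x group
    group_variance: pd.DataFrame | None = None


def normfinder(panel: CtPanel, drop_gene_first: bool = False) -> NormFinderResult:
    """Model-based stability value combining group bias and within-group noise."""
    a = _complete_cases(prepare_log_quantities(panel), drop_gene_first)
    genes = list(a.index)
    if len(genes) < 3:
        raise ValidationError("the model-based estimator requires at least three genes")
    groups = panel.groups.reindex(a.columns)
    labels = list(dict.fromkeys(groups))
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise ValidationError(f"group(s) with fewer than two samples: {bad}")

    x = a - a.mean(axis=0)  # center each sample across genes

    if len(labels) == 1:
        rho = x.std(axis=1, ddof=1)
        return NormFinderResult(rho.rename("normfinder_rho"), _avg_ranks(rho))

    N = len(groups)
    m = pd.DataFrame(index=genes, columns=labels, dtype=float)
    v = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for lab in labels:
        cols = groups.index[groups == lab]
        m[lab] = x[cols].mean(axis=1)
        v[lab] = x[cols].var(axis=1, ddof=1)
    overall = sum(m[lab] * sizes[lab] for lab in labels) / N
    rho = pd.Series(0.0, index=genes)
    bias = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for lab in labels:
        n_g = sizes[lab]
        d = m[lab] - overall
        d2_shrunk = np.maximum(d**2 - v[lab] / n_g, 0.0)
        bias[lab] = np.sqrt(d2_shrunk)
        rho += (n_g / N) * (np.sqrt(d2_shrunk) + np.sqrt(v[lab] / n_g))
    return NormFinderResult(
        rho.rename("normfinder_rho"), _avg_ranks(rho), bias, v
    )


@dataclass
class BestKeeperResult:
    table: pd.DataFrame          # n, geo_mean, arith_mean, min, max, sd, cv_pct, ...
    index: pd.Series             # BestKeeper index per complete-case sample
    ranks: pd.Series             # ascending SD (MAD)


def bestkeeper(
    panel: CtPanel,
    sd_flag_cutoff: float = 1.0,
    classic_sd: bool = False,
) -> BestKeeperResult:
    """BestKeeper descriptive statistics on the raw Ct scale.

    "SD" is the mean absolute deviation around the arithmetic Ct mean
    (the original tool's descriptive convention); ``classic_sd`` switches
    to the n-1 standard deviation. Genes whose SD exceeds
    ``sd_flag_cutoff`` cycles are flagged inconsistent.
    """
    wide = _wide(panel)
    if len(wide.index) < 2:
        raise ValidationError("BestKeeper requires at least two genes")

    rows = []
    for g in wide.index:
        ct = wide.loc[g].dropna()
        am = ct.mean()
        if classic_sd:
            disp = ct.std(ddof=1)
        else:
            disp = (ct - am).abs().mean()
        rows.append(
            {
                "gene": g,
                "n": len(ct),
                "geo_mean": float(np.exp(np.log(ct).mean())),
                "arith_mean": float(am),
                "min": float(ct.min()),
                "max": float(ct.max()),
                "sd": float(disp),
                "cv_pct": float(100.0 * disp / am),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["inconsistent"] = table["sd"] > sd_flag_cutoff

    cc = _complete_cases(wide)
    index = pd.Series(np.exp(np.log(cc).mean(axis=0)), index=cc.columns, name="bki")
    r_vals, p_vals = {}, {}
    for g in wide.index:
        ct = wide.loc[g, cc.columns]
        if ct.nunique() < 2 or index.nunique() < 2 or len(cc.columns) < 3:
            r_vals[g], p_vals[g] = np.nan, np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = sps.pearsonr(ct, index)
        r_vals[g], p_vals[g] = float(r), float(p)
    table["r"] = pd.Series(r_vals)
    table["p"] = pd.Series(p_vals)

    ranks = _avg_ranks(table["sd"])
    return BestKeeperResult(table, index, ranks)


def aggregate_ranks(method_ranks: dict[str, pd.Series]) -> pd.DataFrame:
    """Comprehensive ranking: geometric mean of per-method ranks.

    Every supplied method must rank every gene; ties in the aggregate
    score are broken alphabetically by gene id so the comprehensive rank
    is a strict permutation.
    """
    if len(method_ranks) < 2:
        raise ValidationError("rank aggregation requires at least two methods")
    methods = list(method_ranks)
    base = set(method_ranks[methods[0]].index)
    for name in methods[1:]:
        if set(method_ranks[name].index) != base:
            raise ValidationError(
                f"method {name!r} ranks a different gene set; no partial aggregation"
            )
    genes = list(method_ranks[methods[0]].index)
    out = pd.DataFrame({name: method_ranks[name].reindex(genes) for name in methods})
    if out.isna().any().any():
        raise ValidationError("missing rank(s) in aggregation input")
    out["aggregate_score"] = np.exp(np.log(out[methods]).mean(axis=1))
    order = sorted(genes, key=lambda g: (out.loc[g, "aggregate_score"], g))
    out["comprehensive_rank"] = pd.Series(
        {g: i + 1 for i, g in enumerate(order)}, dtype=float
    )
    return out


@dataclass
class StabilityTable:
    """Per-gene values and ranks for all four methods plus the aggregate."""

    table: pd.DataFrame
    genorm_trace: GeNormTrace
    bestkeeper: BestKeeperResult


def rank_stability(
    panel: CtPanel,
    pair_policy: str = "error",
    drop_gene_first: bool = False,
    sd_flag_cutoff: float = 1.0,
    classic_sd: bool = False,
) -> StabilityTable:
    """Run all four stability algorithms and aggregate their rankings."""
    dct = delta_ct_stability(panel, pair_policy=pair_policy)
    gn = genorm(panel, drop_gene_first=drop_gene_first)
    nf = normfinder(panel, drop_gene_first=drop_gene_first)
    bk = bestkeeper(panel, sd_flag_cutoff=sd_flag_cutoff, classic_sd=classic_sd)

    agg = aggregate_ranks(
        {
            "delta_ct": dct.ranks,
            "genorm": gn.ranks,
            "normfinder": nf.ranks,
            "bestkeeper": bk.ranks,
        }
    )
    table = pd.DataFrame(
        {
            "delta_ct_value": dct.values,
            "delta_ct_rank": dct.ranks,
            "genorm_M": gn.m_at_elimination,
            "genorm_rank": gn.ranks,
            "normfinder_rho": nf.rho,
            "normfinder_rank": nf.ranks,
            "bestkeeper_sd": bk.table["sd"],
            "bestkeeper_cv": bk.table["cv_pct"],
            "bestkeeper_r": bk.table["r"],
            "bestkeeper_rank": bk.ranks,
            "aggregate_score": agg["aggregate_score"],
            "comprehensive_rank": agg["comprehensive_rank"],
        }
    ).sort_values("comprehensive_rank")
    return StabilityTable(table, gn, bk)
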