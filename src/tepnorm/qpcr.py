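"""Ct preprocessing and reference-gene application.

Preprocessing follows standard RT-qPCR practice: measurements at or above
a cycle-threshold ceiling (default 35) are treated as unreliable and set
missing, then technical/biological replicates are averaged per gene and
sample. The application step quantifies a target gene relative to the
chosen reference gene by the ΔΔCt method:

    ΔCt(s)   = Ct_target(s) - Ct_reference(s)
    fold(s)  = 2^-(ΔCt(s) - mean ΔCt over the control group)

so the control group's fold changes have geometric mean 1, and the
two-group difference is tested by a two-sided Student's t-test on the
ΔCt values (Welch's variant behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ct import CtPanel, LONG_COLUMNS
from .errors import ValidationError

__all__ = [
    "apply_ct_inclusion",
    "collapse_replicates",
    "relative_expression",
    "RelativeExpressionResult",
]


def apply_ct_inclusion(panel: CtPanel, max_ct: float = 35.0) -> CtPanel:
    """Set measurements with Ct >= max_ct to missing (strictly 'less than' kept)."""
    data = panel.data.copy()
    excluded = data["ct"] >= max_ct
    if excluded.any():
        per_gene = data.loc[excluded].groupby("gene").size()
        warnings.warn(
            "Ct inclusion rule removed measurements per gene: "
            + ", ".join(f"{g}={n}" for g, n in per_gene.items())
        )
    data.loc[excluded, "ct"] = np.nan
    return panel.with_data(data)


def collapse_replicates(panel: CtPanel, min_reps: int = 2) -> CtPanel:
    """Average surviving replicates per (gene, sample); too few -> missing."""
    data = panel.data
    grouped = data.groupby(["gene", "sample_id"], sort=False)
    agg = grouped.agg(
        group=("group", "first"), ct_mean=("ct", "mean"), n_reps=("ct", "count")
    ).reset_index()
    agg.loc[agg["n_reps"] < min_reps, "ct_mean"] = np.nan
    agg["replicate"] = 1
    agg = agg.rename(columns={"ct_mean": "ct"})
    return panel.with_data(agg[LONG_COLUMNS])


@dataclass
class RelativeExpressionResult:
    per_sample: pd.DataFrame      # sample_id, group, delta_ct, fold_change
    delta_ct_means: dict          # group -> mean ΔCt
    delta_ct_sds: dict            # group -> SD of ΔCt (n-1)
    fold_change_geomean: dict     # group -> geometric mean fold change
    t: float
    p: float
    degenerate: bool              # zero variance in both groups


def relative_expression(
    panel: CtPanel,
    target: str,
    reference: str,
    case_group: str,
    control_group: str,
    equal_var: bool = True,
) -> RelativeExpressionResult:
    """ΔΔCt quantification of ``target`` against ``reference`` with a t-test."""
    if not panel.is_collapsed:
        panel = collapse_replicates(panel)
    wide = panel.to_wide()
    for g in (target, reference):
        if g not in wide.index:
            raise ValidationError(f"gene {g!r} not present in the panel")
    groups = panel.groups
    for lab in (case_group, control_group):
        if lab not in set(groups):
            raise ValidationError(f"group {lab!r} not present in the panel")

    rows = []
    for s in wide.columns:
        if groups[s] not in (case_group, control_group):
            continue
        ct_t, ct_r = wide.loc[target, s], wide.loc[reference, s]
        if pd.isna(ct_r):
            warnings.warn(f"reference gene missing in sample {s}; sample dropped")
            continue
        if pd.isna(ct_t):
            continue
        rows.append({"sample_id": s, "group": groups[s], "delta_ct": ct_t - ct_r})
    df = pd.DataFrame(rows)
    for lab in (case_group, control_group):
        n = (df["group"] == lab).sum() if len(df) else 0
        if n < 3:
            raise ValidationError(
                f"group {lab!r} has {n} usable samples; need at least 3"
            )

    control_mean = df.loc[df["group"] == control_group, "delta_ct"].mean()
    df["fold_change"] = np.exp2(-(df["delta_ct"] - control_mean))

    case = df.loc[df["group"] == case_group, "delta_ct"].to_numpy()
    ctrl = df.loc[df["group"] == control_group, "delta_ct"].to_numpy()
    degenerate = case.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0
    if degenerate and case.mean() == ctrl.mean():
        t, p = 0.0, float("nan")  # identical constant groups: nothing to test
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = sps.ttest_ind(case, ctrl, equal_var=equal_var)
        t, p = float(t), float(p)

    means = df.groupby("group")["delta_ct"].mean().to_dict()
    sds = df.groupby("group")["delta_ct"].std(ddof=1).to_dict()
    geo = df.groupby("group")["fold_change"].apply(
        lambda x: float(np.exp(np.log(x).mean()))
    ).to_dict()
    return RelativeExpressionResult(
        per_sample=df.reset_index(drop=True),
        delta_ct_means=means,
        delta_ct_sds=sds,
        fold_change_geomean=geo,
        t=t,
        p=p,
        degenerate=bool(degenerate),
    )
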