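"""Synthetic count matrices and Ct panels with planted ground truth.

The count generator emulates the statistical structure the shortlist
cascade screens for: a small set of housekeeping genes with top-decile
expression, balanced group means and low dispersion, surrounded by
decoys — genes with genuine group fold changes, genes with inflated
biological noise, and zero-heavy low-expression genes. Counts are drawn
from a negative binomial (the standard overdispersed RNA-seq model) with
log-normal library sizes around one million reads.

The Ct generator emulates the RT-qPCR panels used for stability
assessment: an additive normal model on the Ct scale,

    Ct(g, s, rep) = baseline(g) + shift(g, group(s)) + b(s) + eps

with a shared per-sample loading effect b(s) ~ N(0, sample_effect_sd^2)
— exactly the nuisance the ΔCt family of methods cancels — per-gene
replicate noise eps ~ N(0, noise_sd(g)^2), and missingness completely at
random. Every draw is controlled by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct import CtPanel, LONG_COLUMNS
from .errors import ValidationError
from .matrix import CountMatrix

__all__ = [
    "SyntheticTruth",
    "CtGeneSpec",
    "simulate_counts",
    "simulate_ct",
    "reference_panel_specs",
    "validation_panel_specs",
]


@dataclass
class SyntheticTruth:
    """Per-gene ground truth plus the generator's seed and parameters.

    ``samples`` carries per-sample nuisance truth (true library size for
    count matrices, the shared loading effect for Ct panels).
    """

    genes: pd.DataFrame
    seed: int | None
    params: dict = field(default_factory=dict)
    samples: pd.DataFrame | None = None

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.genes.index[self.genes["role"] == role])

    @property
    def housekeeping_genes(self) -> list[str]:
        return self.genes_with_role("housekeeping")


DISPERSION_BY_ROLE = {"housekeeping": 1e4, "shifted": 1e4, "noisy": 0.4, "low": 0.5}
# relative displacement of one group's mean log2CPM for shifted genes;
# 0.35 puts the group mean ratio at 1/0.65 ~ 1.54, safely beyond the
# 1.2-fold balance criterion
FOLD_CHANGE_BY_ROLE = {"housekeeping": 0.0, "shifted": 0.35, "noisy": 0.0, "low": 0.0}


def simulate_counts(
    n_genes: int = 500,
    n_normal: int = 50,
    n_tumor: int = 50,
    frac_housekeeping: float = 0.02,
    frac_shifted: float = 0.30,
    frac_noisy: float = 0.30,
    mean_log2cpm_range: tuple[float, float] = (2.0, 10.0),
    housekeeping_log2cpm_range: tuple[float, float] = (11.0, 12.0),
    dispersion_by_role: dict | None = None,
    fold_change_by_role: dict | None = None,
    library_size_mean: float = 1e6,
    library_size_sigma: float = 0.25,
    seed: int | None = None,
    hk_gene_names: list[str] | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial count matrix with planted gene roles.

    Roles partition the genes: ``housekeeping`` (top-decile mean, no
    group effect, near-Poisson dispersion), ``shifted`` (group fold
    change beyond the balance criterion), ``noisy`` (dispersion inflating
    group CV past 10%), and ``low`` (zero-heavy; the remainder).
    """
    if not (0 < frac_housekeeping < 1):
        raise ValidationError("frac_housekeeping must be in (0, 1)")
    disp = {**DISPERSION_BY_ROLE, **(dispersion_by_role or {})}
    fc = {**FOLD_CHANGE_BY_ROLE, **(fold_change_by_role or {})}

    n_hk = max(1, round(frac_housekeeping * n_genes))
    n_shift = round(frac_shifted * n_genes)
    n_noisy = round(frac_noisy * n_genes)
    n_low = n_genes - n_hk - n_shift - n_noisy
    if n_low < 0:
        raise ValidationError("role fractions exceed 1")
    n_expressed = n_hk + n_shift + n_noisy
    if n_hk > 0.10 * n_expressed:
        raise ValidationError(
            f"frac_housekeeping too large: {n_hk} housekeeping genes cannot all "
            f"fit the top decile of {n_expressed} expressed genes"
        )

    rng = np.random.default_rng(seed)
    roles = (
        ["housekeeping"] * n_hk + ["shifted"] * n_shift
        + ["noisy"] * n_noisy + ["low"] * n_low
    )
    width = len(str(n_genes))
    gene_ids = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    if hk_gene_names:
        if len(hk_gene_names) > n_hk:
            raise ValidationError("more hk_gene_names than housekeeping genes")
        for i, name in enumerate(hk_gene_names):
            gene_ids[i] = name

    sample_ids = [f"N{i + 1:03d}" for i in range(n_normal)] + [
        f"T{i + 1:03d}" for i in range(n_tumor)
    ]
    group = pd.Series(
        ["normal"] * n_normal + ["tumor"] * n_tumor, index=sample_ids, name="group"
    )
    libsize = rng.lognormal(np.log(library_size_mean), library_size_sigma, len(sample_ids))

    lo, hi = mean_log2cpm_range
    base = np.empty(n_genes)
    mean_normal = np.empty(n_genes)
    mean_tumor = np.empty(n_genes)
    for i, role in enumerate(roles):
        if role == "housekeeping":
            base[i] = rng.uniform(*housekeeping_log2cpm_range)
        elif role == "low":
            base[i] = np.nan  # parameterized by mean count below
        else:
            base[i] = rng.uniform(lo, hi)
        mean_normal[i] = mean_tumor[i] = base[i]
        if role == "shifted":
            # lower one group's mean so the mean ratio lands beyond the
            # balance criterion while neither group invades the
            # housekeeping expression band
            drop = fc["shifted"] * base[i]
            if rng.random() < 0.5:
                mean_tumor[i] = base[i] - drop
            else:
                mean_normal[i] = base[i] - drop
    log2fc = mean_tumor - mean_normal

    is_tumor = (group == "tumor").to_numpy()
    counts = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
    for i, role in enumerate(roles):
        if role == "low":
            mu = rng.uniform(0.01, 0.2) * libsize / library_size_mean
        else:
            m = np.where(is_tumor, mean_tumor[i], mean_normal[i])
            mu = np.exp2(m) / 1e6 * libsize
        size = disp[role]
        counts[i] = rng.negative_binomial(size, size / (size + mu))

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        group,
        intron_spanning_reads=pd.Series(
            np.round(libsize).astype(np.int64),
            index=sample_ids,
            name="intron_spanning_reads",
        ),
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "role": roles,
                "base_log2cpm": base,
                "log2fc": log2fc,
                "dispersion": [disp[r] for r in roles],
            },
            index=gene_ids,
        ),
        seed=seed,
        params={
            "n_genes": n_genes, "n_normal": n_normal, "n_tumor": n_tumor,
            "frac_housekeeping": frac_housekeeping, "frac_shifted": frac_shifted,
            "frac_noisy": frac_noisy, "mean_log2cpm_range": mean_log2cpm_range,
            "library_size_mean": library_size_mean,
            "library_size_sigma": library_size_sigma,
        },
        samples=pd.DataFrame(
            {"group": group, "library_size": libsize}, index=sample_ids
        ),
    )
    return cm, truth


@dataclass
class CtGeneSpec:
    """Ground-truth parameters for one gene of a simulated Ct panel."""

    baseline: float                       # cycles, plausible range 10-40
    shifts: dict[str, float] = field(default_factory=dict)  # group -> cycles
    noise_sd: float = 0.2                 # replicate noise, cycles

    def shift(self, group: str) -> float:
        return self.shifts.get(group, 0.0)

    @property
    def max_abs_shift(self) -> float:
        return max((abs(v) for v in self.shifts.values()), default=0.0)


DEFAULT_GROUPS = ("HC", "NSCLC", "CRC", "HBC", "BrCa")


def reference_panel_specs(groups: tuple[str, ...] = DEFAULT_GROUPS) -> dict[str, CtGeneSpec]:
    """A 7-gene stability panel: one stable gene among shifted and noisy decoys.

    The stable gene has no group effect and 0.1-cycle noise; the decoys
    carry group shifts of at least one cycle or replicate noise of at
    least 0.8 cycles.
    """
    g = list(groups)
    others = g[1:]

    def shifts(vals):
        return dict(zip(others, vals))

    return {
        "STB1": CtGeneSpec(20.0, {}, 0.1),
        "UPA1": CtGeneSpec(22.0, shifts([1.0, -1.2, 1.5, -1.0][: len(others)]), 0.3),
        "UPA2": CtGeneSpec(24.0, shifts([-1.5, 1.0, -1.0, 1.2][: len(others)]), 0.3),
        "UPA3": CtGeneSpec(21.0, shifts([2.0, 1.6, -1.4, 1.0][: len(others)]), 0.3),
        "NSY1": CtGeneSpec(19.0, {}, 0.8),
        "NSY2": CtGeneSpec(25.0, {}, 1.0),
        "NSY3": CtGeneSpec(23.0, {}, 1.2),
    }


def validation_panel_specs(
    delta: float = -1.5, noise_sd: float = 0.5, case_group: str = "LC"
) -> dict[str, CtGeneSpec]:
    """Two-gene target/reference panel with a planted case-group ΔCt shift."""
    return {
        "REF": CtGeneSpec(20.0, {}, 0.1),
        "TARGET": CtGeneSpec(24.0, {case_group: delta}, noise_sd),
    }


def simulate_ct(
    gene_specs: dict[str, CtGeneSpec] | None = None,
    group_sizes: dict[str, int] | None = None,
    n_replicates: int = 3,
    sample_effect_sd: float = 0.5,
    missing_rate: float = 0.0,
    efficiency: float = 2.0,
    seed: int | None = None,
) -> tuple[CtPanel, SyntheticTruth]:
    """Simulate a Ct panel under the additive loading-effect model."""
    group_sizes = group_sizes or {g: 6 for g in DEFAULT_GROUPS}
    gene_specs = gene_specs or reference_panel_specs(tuple(group_sizes))
    if any(n < 2 for n in group_sizes.values()):
        raise ValidationError("every group needs at least two samples")
    for gid, spec in gene_specs.items():
        if not (10.0 <= spec.baseline <= 40.0):
            raise ValidationError(
                f"gene {gid!r}: baseline Ct {spec.baseline} outside the plausible 10-40 range"
            )
    if not (0.0 <= missing_rate < 1.0):
        raise ValidationError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    samples = [
        (f"{grp}{i + 1:02d}", grp)
        for grp, n in group_sizes.items()
        for i in range(n)
    ]
    loading = {sid: rng.normal(0.0, sample_effect_sd) for sid, _ in samples}

    rows = []
    for gid, spec in gene_specs.items():
        for sid, grp in samples:
            mean_ct = spec.baseline + spec.shift(grp) + loading[sid]
            for rep in range(1, n_replicates + 1):
                ct = mean_ct + rng.normal(0.0, spec.noise_sd)
                if missing_rate and rng.random() < missing_rate:
                    ct = np.nan
                rows.append((sid, grp, gid, rep, ct))
    panel = CtPanel(
        pd.DataFrame(rows, columns=LONG_COLUMNS), efficiency=efficiency
    )

    truth_df = pd.DataFrame(
        {
            "baseline_ct": {g: s.baseline for g, s in gene_specs.items()},
            "max_abs_shift": {g: s.max_abs_shift for g, s in gene_specs.items()},
            "noise_sd": {g: s.noise_sd for g, s in gene_specs.items()},
        }
    )
    # stability ordering implied by (|shift|, noise): smaller is more stable
    order = truth_df.sort_values(["max_abs_shift", "noise_sd"]).index
    truth_df["expected_stability_rank"] = pd.Series(
        {g: i + 1 for i, g in enumerate(order)}
    )
    truth = SyntheticTruth(
        genes=truth_df,
        seed=seed,
        params={
            "group_sizes": dict(group_sizes),
            "n_replicates": n_replicates,
            "sample_effect_sd": sample_effect_sd,
            "missing_rate": missing_rate,
            "efficiency": efficiency,
        },
        samples=pd.DataFrame(
            {"group": dict(samples).values(), "loading_effect": loading.values()},
            index=[sid for sid, _ in samples],
        ),
    )
    return panel, truth
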