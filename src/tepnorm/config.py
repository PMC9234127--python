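"""Configuration for the shortlisting cascade.

Every threshold of the filter cascade is exposed so that sensitivity
analyses can be run; defaults are the published study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ShortlistConfig"]


@dataclass
class ShortlistConfig:
    """Thresholds and options for :func:`tepnorm.shortlist.run_shortlist`.

    min_reads            sample kept iff intron-spanning reads >= this (strict
                         "less than" exclusion), reads.
    max_zero_frac        gene removed iff its zero-count fraction is strictly
                         greater than this.
    fold_max             criterion 1: both mean ratios (normal/tumor and
                         tumor/normal) must be < fold_max.
    top_frac             criterion 2: gene must rank within the top fraction
                         by group mean in BOTH groups.
    cv_max               criterion 3: per-group CV (SD/mean) must be < cv_max.
    mean_min             refinement: group mean log2CPM must exceed this.
    cv_max_refine        refinement: per-group CV must be below this (0.01 =
                         1 percent).
    prior                pseudo-count for the log2CPM transform.
    known_list_path      plain-text known-reference-gene list; None = the
                         curated list shipped with the package.
    normal_label         group label treated as the healthy/control arm; all
                         other labels are pooled as "tumor".
    depth_policy         "strict": missing intron-spanning-read metadata is an
                         error; "lenient": pass samples through with a warning.
    use_linear_means     evaluate criterion 1 on linear-scale CPM means
                         instead of means of log2CPM.
    """

    min_reads: int = 400_000
    max_zero_frac: float = 0.70
    fold_max: float = 1.2
    top_frac: float = 0.10
    cv_max: float = 0.10
    mean_min: float = 1.0
    cv_max_refine: float = 0.01
    prior: float = 1.0
    known_list_path: str | None = None
    normal_label: str = "normal"
    depth_policy: str = "strict"
    use_linear_means: bool = False

    def __post_init__(self) -> None:
        if self.depth_policy not in ("strict", "lenient"):
            raise ConfigError(f"depth_policy must be strict|lenient, got {self.depth_policy!r}")
        for name in ("max_zero_frac", "top_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.fold_max <= 1:
            raise ConfigError(f"fold_max must exceed 1, got {self.fold_max}")
        if self.prior <= 0:
            raise ConfigError(f"prior must be positive, got {self.prior}")

    @classmethod
    def from_dict(cls, d: dict) -> "ShortlistConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ShortlistConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def resolved_known_list(self) -> Path:
        if self.known_list_path is not None:
            return Path(self.known_list_path)
        from importlib.resources import files

        return Path(str(files("tepnorm").joinpath("data/known_reference_genes.txt")))
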