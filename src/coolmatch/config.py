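"""Declarative pipeline configuration.

Every analysis choice the method leaves open is surfaced here with its
default: exposure handling for missing feeding data, propensity trimming,
pH banding for the exact strata, the replication count, the variance
combination rule, and the preplanned sensitivity-analysis toggles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .derive import OUTCOME_COLUMNS

BINARY_SET = set(OUTCOME_COLUMNS[:6])


@dataclass
class PipelineConfig:
    infants_csv: str | None = None
    infant_days_csv: str | None = None
    covariates: tuple[str, ...] | None = None  # registry names; None = full registry
    exposure_policy: str = "missing_as_unfed"  # or drop_missing (sensitivity 2)
    trim_caps: tuple[float, float] = (0.01, 0.99)
    trim_common_support: bool = True
    ph_banding: str = "with_missing"  # 16 cells; 'strict12' drops missing-pH babies
    R: int = 25
    master_seed: int = 0
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS
    bonferroni_m: int = 12
    restrict_years_from: int | None = None  # 2012 for sensitivity 1
    add_pn_day1_covariate: bool = False  # sensitivity 3
    mask_small_counts: bool = False

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.exposure_policy not in ("missing_as_unfed", "drop_missing"):
            raise ValueError(f"unknown exposure_policy {self.exposure_policy!r}")
        if self.ph_banding not in ("with_missing", "strict12"):
            raise ValueError(f"unknown ph_banding {self.ph_banding!r}")
        unknown = set(self.outcomes) - set(OUTCOME_COLUMNS)
        if unknown:
            raise ValueError(f"unknown outcome(s): {sorted(unknown)}")
        if self.covariates is not None:
            from .registry import DEFAULT_REGISTRY

            known = {c.name for c in DEFAULT_REGISTRY}
            unknown = set(self.covariates) - known
            if unknown:
                raise ValueError(f"unknown covariate(s): {sorted(unknown)}")
        lo, hi = self.trim_caps
        if not (0 <= lo < hi <= 1):
            raise ValueError("trim_caps must satisfy 0 <= lo < hi <= 1")

    def outcome_scale(self, outcome: str) -> str:
        return "binary" if outcome in BINARY_SET else "continuous"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trim_caps"] = list(self.trim_caps)
        d["outcomes"] = list(self.outcomes)
        if self.covariates is not None:
            d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "trim_caps" in d:
            d["trim_caps"] = tuple(d["trim_caps"])
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        if d.get("covariates") is not None:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
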