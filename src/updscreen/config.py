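"""Run configuration: filter, classification, window and cohort parameters.

All shipped defaults are the screen's operating values; a YAML file with the
same nesting overrides any subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .genotype_store import FilterConfig
from .upd_core import ClassifyThresholds


@dataclass(frozen=True)
class WindowConfig:
    """Segmental-scan parameters: 5 Mb error-anchored windows, >= 50
    Mendelian errors, <= 10% heterozygosity at informative sites, and a
    strict 0.9 coverage-ratio cut separating deletions from partial UPD."""

    window_size: int = 5_000_000
    min_errors: int = 50
    het_max_pct: float = 10.0
    ratio_min: float = 0.9


@dataclass(frozen=True)
class OutlierConfig:
    """Cohort boxplot outlier rule (advisory, visualization support).

    Fence: Q1 - max(iqr_mult * IQR, min_fence) for the AB percentage (low
    tail only) and both tails for heterozygosity.  ``min_fence`` (percentage
    points) guards against a degenerate zero IQR at desk-scale site counts,
    where a single miscalled site would otherwise be flagged.
    """

    iqr_mult: float = 1.5
    min_fence: float = 5.0


@dataclass
class RunConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    windows: WindowConfig = field(default_factory=WindowConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    af_source: str = "AF"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "filters": dataclasses.asdict(self.filters),
            "thresholds": dataclasses.asdict(self.thresholds),
            "windows": dataclasses.asdict(self.windows),
            "outliers": dataclasses.asdict(self.outliers),
            "af_source": self.af_source,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        return cls(
            filters=FilterConfig(**raw.get("filters", {})),
            thresholds=ClassifyThresholds(**raw.get("thresholds", {})),
            windows=WindowConfig(**raw.get("windows", {})),
            outliers=OutlierConfig(**raw.get("outliers", {})),
            af_source=raw.get("af_source", "AF"),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
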