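"""Analysis configuration: every threshold of the filter chain, event
calling, sharing rule and clonality logic in one place, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .segments import EventThresholds
from .variants import DEFAULT_DRIVER_PANEL, DEFAULT_IMPACTFUL, DriverPanel


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the clonality pipeline.

    max_population_af
        gnomAD frequency above which a variant is considered a germline
        polymorphism (strict >).
    contamination_rate
        estimated cross-sample contamination; calls with VAF strictly below
        it are dropped.
    impactful_consequences
        consequence classes counted as functional coding impact.
    thresholds
        arm-level event-calling cutoffs (log2 +/-0.3, LOH MAF <= 0.40,
        >= 50% of the arm).
    min_reciprocal_overlap
        two lesions share a CNV feature when their event footprints overlap
        reciprocally by at least this fraction of each footprint.
    min_shared_drivers
        number of truncal driver features required to call a patient
        monoclonal.
    concordance_tolerance
        absolute difference under which the VAF- and MAF-based clonal
        fractions are flagged concordant.
    maf_model
        "allelic_imbalance" (c = 1 - 2*MAF, copy-neutral LOH) or "deletion"
        (c = (1 - 2*MAF)/(1 - MAF), hemizygous loss).
    """

    max_population_af: float = 0.01
    contamination_rate: float = 0.0
    impactful_consequences: frozenset[str] = DEFAULT_IMPACTFUL
    thresholds: EventThresholds = field(default_factory=EventThresholds)
    min_reciprocal_overlap: float = 0.5
    min_shared_drivers: int = 1
    concordance_tolerance: float = 0.10
    maf_model: str = "allelic_imbalance"
    include_outgroup: bool = True
    outgroup_label: str = "germline"
    panel: DriverPanel = DEFAULT_DRIVER_PANEL

    def __post_init__(self) -> None:
        if self.maf_model not in ("allelic_imbalance", "deletion"):
            raise ValueError(f"unknown maf_model {self.maf_model!r}")
        if not 0.0 <= self.max_population_af <= 1.0:
            raise ValueError("max_population_af must be in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.min_shared_drivers < 1:
            raise ValueError("min_shared_drivers must be >= 1")

    def to_dict(self) -> dict:
        return {
            "max_population_af": self.max_population_af,
            "contamination_rate": self.contamination_rate,
            "impactful_consequences": sorted(self.impactful_consequences),
            "thresholds": {
                "deletion_log2": self.thresholds.deletion_log2,
                "amplification_log2": self.thresholds.amplification_log2,
                "loh_maf": self.thresholds.loh_maf,
                "min_arm_fraction": self.thresholds.min_arm_fraction,
            },
            "min_reciprocal_overlap": self.min_reciprocal_overlap,
            "min_shared_drivers": self.min_shared_drivers,
            "concordance_tolerance": self.concordance_tolerance,
            "maf_model": self.maf_model,
            "include_outgroup": self.include_outgroup,
            "outgroup_label": self.outgroup_label,
            "panel": list(self.panel.genes),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        kwargs: dict = {}
        if "thresholds" in data:
            kwargs["thresholds"] = EventThresholds(**data.pop("thresholds"))
        if "impactful_consequences" in data:
            kwargs["impactful_consequences"] = frozenset(
                data.pop("impactful_consequences"))
        if "panel" in data:
            kwargs["panel"] = DriverPanel(tuple(data.pop("panel")))
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
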