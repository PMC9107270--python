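"""Molecular subtyping, clonal-origin classification, and clonal-fraction
estimation.

Subtype rule: a tumour with a somatic NF2 mutation and/or a chromosome 22
deletion is "NF2-loss"; tumours with other drivers are "non-NF2".

Clonal-origin rule: a patient's tumours are *monoclonal* when at least
``min_shared_drivers`` driver features (an identical driver-panel SNV/INDEL,
or a CNV/LOH event shared under the reciprocal-overlap rule) are present in
every lesion; otherwise the tumours are of *independent* origin.  This is the
minimal rule consistent with shared-truncal-event reasoning: a somatic driver
identical in all lesions is vanishingly unlikely to arise twice.

Clonal fractions (fraction c of tumour cells carrying an event):

* from the VAF v of a point mutation —
  heterozygous diploid locus:  c = 2 v;
  copy-neutral LOH (mutation on the duplicated allele):  c = v;
  hemizygous locus (mutation on the retained single copy):  c = 2 v / (1 + v);
* from the minor-allele fraction m of an LOH segment —
  copy-neutral allelic imbalance (default):  c = 1 - 2 m;
  hemizygous deletion:  c = (1 - 2 m) / (1 - m).

Estimates are clipped to [0, 1]; clipping is flagged in the comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .case import LesionProfile, PatientCase
from .config import AnalysisConfig
from .features import (
    CaseFeatures,
    extract_case_features,
    filter_lesion_variants,
    shared_private_partition,
    snv_display_name,
)
from .segments import call_events
from .variants import DriverPanel

COPY_STATES = ("het_diploid", "hemizygous", "cn_loh")


@dataclass(frozen=True)
class SubtypeCall:
    lesion_id: str
    subtype: str                      # "NF2-loss" | "non-NF2"
    evidence: tuple[str, ...] = ()


@dataclass
class ClonalityCall:
    patient_id: str
    verdict: str                      # "monoclonal" | "independent"
    shared_driver_evidence: tuple[str, ...] = ()
    clonal_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        monoclonal = bool(self.shared_driver_evidence)
        if (self.verdict == "monoclonal") != monoclonal:
            raise ValueError(
                "verdict must be monoclonal iff shared driver evidence "
                "is non-empty")


def classify_subtype(profile: LesionProfile,
                     config: AnalysisConfig | None = None) -> SubtypeCall:
    """NF2-loss iff the filtered profile carries an NF2 SNV/INDEL or a
    chromosome 22 deletion event; non-NF2 otherwise."""
    config = config or AnalysisConfig()
    filtered, _ = filter_lesion_variants(profile, config)
    events = call_events(profile.segments, config.thresholds)
    evidence: list[str] = []
    for v in filtered:
        if v.gene == "NF2":
            evidence.append(snv_display_name(v))
    for ev in events:
        if ev.kind == "deletion" and ev.chrom == "22":
            evidence.append(ev.key)
    subtype = "NF2-loss" if evidence else "non-NF2"
    return SubtypeCall(profile.lesion_id, subtype, tuple(sorted(evidence)))


def classify_patient_clonality(case: PatientCase,
                               config: AnalysisConfig | None = None,
                               features: CaseFeatures | None = None,
                               ) -> ClonalityCall:
    """Monoclonal iff >= ``min_shared_drivers`` driver features are shared
    by every tumour lesion of the patient."""
    config = config or AnalysisConfig()
    if len(case.lesions) < 2:
        raise ValueError(
            f"clonality classification needs >= 2 lesions "
            f"(patient {case.patient_id!r})")
    features = features or extract_case_features(case, config)
    partition = shared_private_partition(case, config, features)
    shared_drivers = sorted(partition.shared_by_all & features.drivers)
    if len(shared_drivers) >= config.min_shared_drivers:
        return ClonalityCall(case.patient_id, "monoclonal",
                             tuple(shared_drivers))
    return ClonalityCall(case.patient_id, "independent", ())


def clonal_fraction_from_vaf(vaf: float, copy_state: str = "het_diploid",
                             clip: bool = True) -> float:
    """Fraction of tumour cells carrying a point mutation, from its VAF."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf outside [0, 1]: {vaf}")
    if copy_state == "het_diploid":
        c = 2.0 * vaf
    elif copy_state == "cn_loh":
        c = vaf
    elif copy_state == "hemizygous":
        c = 2.0 * vaf / (1.0 + vaf)
    else:
        raise ValueError(f"unknown copy_state {copy_state!r}")
    return min(max(c, 0.0), 1.0) if clip else c


def clonal_fraction_from_maf(maf: float, model: str = "allelic_imbalance",
                             clip: bool = True) -> float:
    """Fraction of tumour cells with LOH, from the minor-allele fraction of
    the affected segment (0.5 = balanced, 0 = complete imbalance)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf outside [0, 0.5]: {maf}")
    if model == "allelic_imbalance":
        c = 1.0 - 2.0 * maf
    elif model == "deletion":
        c = (1.0 - 2.0 * maf) / (1.0 - maf)
    else:
        raise ValueError(f"unknown maf model {model!r}")
    return min(max(c, 0.0), 1.0) if clip else c


def compare_event_clonality(case: PatientCase,
                            config: AnalysisConfig | None = None,
                            features: CaseFeatures | None = None,
                            ) -> pd.DataFrame:
    """Per lesion, the MAF-based clonal fraction of each LOH event and the
    VAF-based clonal fraction of each driver-panel mutation, with a
    concordance flag when the two agree within the configured tolerance.

    Lesions lacking one of the two estimates get a row with the other
    estimate and a missing value; the concordance flag is then NA.
    """
    config = config or AnalysisConfig()
    features = features or extract_case_features(case, config)
    rows: list[dict] = []
    for profile in case.lesions:
        lesion = profile.lesion_id
        loh_events = [ev for ev in features.events[lesion]
                      if ev.kind == "loh"]
        panel_snvs = [v for v in features.filtered_variants[lesion]
                      if v.gene in config.panel]
        maf_estimates: list[tuple[str, float | None, float]] = []
        for ev in loh_events:
            segs = [s for s in profile.segments if s.maf is not None
                    and s.chrom == ev.chrom
                    and s.maf <= config.thresholds.loh_maf]
            if not segs:
                continue
            # length-weighted MAF over the event's qualifying segments
            total = sum(s.length for s in segs)
            maf = sum(s.maf * s.length for s in segs) / total
            maf_estimates.append((ev.key, maf, clonal_fraction_from_maf(
                maf, config.maf_model)))
        vaf_estimates = [
            (snv_display_name(v), v.vaf,
             clonal_fraction_from_vaf(v.vaf, "het_diploid"))
            for v in panel_snvs]
        if not maf_estimates:
            maf_estimates = [(None, None, None)]
        if not vaf_estimates:
            vaf_estimates = [(None, None, None)]
        for loh_key, maf, c_maf in maf_estimates:
            for snv_key, vaf, c_vaf in vaf_estimates:
                concordant = (
                    abs(c_maf - c_vaf) <= config.concordance_tolerance
                    if c_maf is not None and c_vaf is not None else None)
                clipped = any(
                    raw is not None and not 0.0 <= raw <= 1.0
                    for raw in (
                        None if maf is None else clonal_fraction_from_maf(
                            maf, config.maf_model, clip=False),
                        None if vaf is None else clonal_fraction_from_vaf(
                            vaf, clip=False)))
                rows.append({
                    "patient_id": case.patient_id, "lesion_id": lesion,
                    "loh_event": loh_key, "maf": maf,
                    "clonal_fraction_maf": c_maf,
                    "snv": snv_key, "vaf": vaf,
                    "clonal_fraction_vaf": c_vaf,
                    "concordant": concordant, "clipped": clipped,
                })
    return pd.DataFrame(rows, columns=[
        "patient_id", "lesion_id", "loh_event", "maf",
        "clonal_fraction_maf", "snv", "vaf", "clonal_fraction_vaf",
        "concordant", "clipped"])
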