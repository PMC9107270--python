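"""Feature extraction across the lesions of one patient.

A *feature* is a somatic alteration comparable between lesions:

* SNV/INDEL features are keyed by (chrom, pos, ref, alt) — the same genomic
  change in two lesions is the same feature regardless of annotation;
* CNV/LOH features are arm- or chromosome-level events; events of the same
  (label, kind) in different lesions are the same feature when their
  footprints overlap reciprocally (>= ``min_reciprocal_overlap`` of each),
  clustered by single linkage.

The shared/private partition classifies every feature of a patient as
shared-by-all (truncal), partially shared, or private to one lesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .case import LesionProfile, PatientCase
from .config import AnalysisConfig
from .segments import CNVEvent, call_events, overlap_length
from .variants import (
    SomaticVariant,
    filter_contamination,
    filter_functional_impact,
    filter_population_af,
    restrict_to_driver_panel,
)

logger = logging.getLogger(__name__)


def snv_feature_key(variant: SomaticVariant) -> str:
    return f"{variant.chrom}:{variant.pos}:{variant.ref}>{variant.alt}"


def snv_display_name(variant: SomaticVariant) -> str:
    return f"{variant.gene}:{snv_feature_key(variant)}"


@dataclass
class FilterStats:
    """Per-lesion audit of the filter chain."""

    lesion_id: str
    n_input: int
    n_after_population_af: int
    n_after_functional: int
    n_after_contamination: int


def filter_lesion_variants(
        profile: LesionProfile, config: AnalysisConfig,
) -> tuple[list[SomaticVariant], FilterStats]:
    """Apply the population-AF, functional-impact and contamination filters
    in order, recording counts at each stage."""
    v0 = profile.variants
    v1 = filter_population_af(v0, config.max_population_af)
    v2 = filter_functional_impact(v1, config.impactful_consequences)
    v3 = filter_contamination(v2, config.contamination_rate)
    stats = FilterStats(profile.lesion_id, len(v0), len(v1), len(v2), len(v3))
    return v3, stats


def _reciprocal_overlap(a: CNVEvent, b: CNVEvent, min_fraction: float) -> bool:
    shared = overlap_length(a.footprint, b.footprint)
    return (shared >= min_fraction * a.footprint_length
            and shared >= min_fraction * b.footprint_length)


def cluster_cnv_events(events_by_lesion: dict[str, list[CNVEvent]],
                       min_reciprocal_overlap: float,
                       ) -> dict[str, dict[str, CNVEvent]]:
    """Group per-lesion events into cross-lesion features.

    Returns feature key -> {lesion_id -> event}. Events sharing (label,
    kind) are single-linkage clustered by reciprocal footprint overlap;
    additional clusters under the same label get a ``#i`` suffix (ordered by
    leftmost footprint start) so distinct same-arm events stay distinct.
    """
    by_key: dict[str, list[CNVEvent]] = {}
    for events in events_by_lesion.values():
        for ev in events:
            by_key.setdefault(ev.key, []).append(ev)

    features: dict[str, dict[str, CNVEvent]] = {}
    for key, events in sorted(by_key.items()):
        # single-linkage clustering on reciprocal overlap
        clusters: list[list[CNVEvent]] = []
        for ev in sorted(events, key=lambda e: (e.footprint, e.lesion_id)):
            linked = [c for c in clusters if any(
                _reciprocal_overlap(ev, other, min_reciprocal_overlap)
                for other in c)]
            if not linked:
                clusters.append([ev])
            else:
                merged = [ev]
                for c in linked:
                    merged.extend(c)
                    clusters.remove(c)
                clusters.append(merged)
        clusters.sort(key=lambda c: min(e.footprint[0][0] for e in c))
        for i, cluster in enumerate(clusters):
            name = key if len(clusters) == 1 else f"{key}#{i + 1}"
            features[name] = {ev.lesion_id: ev for ev in cluster}
    return features


@dataclass
class CaseFeatures:
    """Resolved feature table for one patient.

    ``presence`` maps lesion id -> set of feature keys; ``kinds`` maps key ->
    "snv" | "cnv"; ``drivers`` is the subset of keys that count as driver
    evidence for the clonality call (driver-panel SNVs and all CNV/LOH
    events); ``display`` holds human-readable names.
    """

    presence: dict[str, set[str]]
    kinds: dict[str, str]
    drivers: set[str]
    display: dict[str, str]
    filter_stats: list[FilterStats] = field(default_factory=list)
    filtered_variants: dict[str, list[SomaticVariant]] = field(
        default_factory=dict)
    events: dict[str, list[CNVEvent]] = field(default_factory=dict)

    @property
    def feature_keys(self) -> list[str]:
        return sorted(self.kinds)


def extract_case_features(case: PatientCase,
                          config: AnalysisConfig | None = None,
                          panel_only_snvs: bool = False) -> CaseFeatures:
    """Filter variants, call events and resolve cross-lesion features for
    every tumour lesion of a patient.

    With ``panel_only_snvs`` SNV features are restricted to driver-panel
    genes (the binary-matrix convention); otherwise all filtered SNVs
    contribute (the shared/private census convention).
    """
    config = config or AnalysisConfig()
    presence: dict[str, set[str]] = {}
    kinds: dict[str, str] = {}
    drivers: set[str] = set()
    display: dict[str, str] = {}
    all_stats: list[FilterStats] = []
    filtered_by_lesion: dict[str, list[SomaticVariant]] = {}
    events_by_lesion: dict[str, list[CNVEvent]] = {}

    for profile in case.lesions:
        filtered, stats = filter_lesion_variants(profile, config)
        all_stats.append(stats)
        filtered_by_lesion[profile.lesion_id] = filtered
        events_by_lesion[profile.lesion_id] = call_events(
            profile.segments, config.thresholds)
        presence[profile.lesion_id] = set()

    for lesion_id, filtered in filtered_by_lesion.items():
        snvs = (restrict_to_driver_panel(filtered, config.panel)
                if panel_only_snvs else filtered)
        for v in snvs:
            key = snv_feature_key(v)
            presence[lesion_id].add(key)
            kinds[key] = "snv"
            display.setdefault(key, snv_display_name(v))
            if v.gene in config.panel:
                drivers.add(key)

    cnv_features = cluster_cnv_events(
        events_by_lesion, config.min_reciprocal_overlap)
    for key, members in cnv_features.items():
        kinds[key] = "cnv"
        display[key] = key
        drivers.add(key)
        for lesion_id in members:
            presence[lesion_id].add(key)

    return CaseFeatures(presence=presence, kinds=kinds, drivers=drivers,
                        display=display, filter_stats=all_stats,
                        filtered_variants=filtered_by_lesion,
                        events=events_by_lesion)


@dataclass
class SharedPrivatePartition:
    """Partition of a patient's features into truncal and non-truncal sets."""

    patient_id: str
    shared_by_all: set[str]
    partially_shared: set[str]
    private: set[str]
    per_lesion_counts: dict[str, dict[str, int]]

    def category_of(self, key: str) -> str:
        if key in self.shared_by_all:
            return "shared_by_all"
        if key in self.partially_shared:
            return "partially_shared"
        return "private"


def shared_private_partition(case: PatientCase,
                             config: AnalysisConfig | None = None,
                             features: CaseFeatures | None = None,
                             ) -> SharedPrivatePartition:
    """Classify every feature of a patient as shared-by-all, partially
    shared, or private to one lesion.

    A single-lesion case degenerates: everything is trivially shared by all
    lesions, which is flagged with a warning.
    """
    features = features or extract_case_features(case, config)
    n = len(case.lesions)
    if n == 1:
        logger.warning(
            "patient %s has a single lesion; shared/private partition is "
            "degenerate", case.patient_id)
    counts: dict[str, int] = {}
    for present in features.presence.values():
        for key in present:
            counts[key] = counts.get(key, 0) + 1
    shared = {k for k, c in counts.items() if c == n}
    private = {k for k, c in counts.items() if c == 1 and n > 1}
    partial = set(counts) - shared - private

    per_lesion: dict[str, dict[str, int]] = {}
    for lesion_id, present in features.presence.items():
        per_lesion[lesion_id] = {
            "shared_by_all": sum(1 for k in present if k in shared),
            "partially_shared": sum(1 for k in present if k in partial),
            "private": sum(1 for k in present if k in private),
        }
    return SharedPrivatePartition(
        patient_id=case.patient_id, shared_by_all=shared,
        partially_shared=partial, private=private,
        per_lesion_counts=per_lesion)
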