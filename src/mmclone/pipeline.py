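"""Patient manifests and the end-to-end analysis pipeline.

Stage order per patient: filter variants → call arm/chromosome events →
shared/private partition → molecular subtype per lesion → clonal-origin
verdict → binary feature matrix → Manhattan distances → neighbor-joining
tree.  A failure in one patient is recorded and does not abort the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .case import LesionProfile, PatientCase
from .clonality import (
    ClonalityCall,
    SubtypeCall,
    classify_patient_clonality,
    classify_subtype,
    compare_event_clonality,
)
from .config import AnalysisConfig
from .features import (
    extract_case_features,
    filter_lesion_variants,
    shared_private_partition,
)
from .phylogeny import (
    build_feature_matrix,
    manhattan_distance_matrix,
    neighbor_joining,
    to_newick,
)
from .segments import call_events, read_segments
from .variants import read_variant_table, restrict_to_driver_panel

logger = logging.getLogger(__name__)


class ManifestError(ValueError):
    """Raised when a patient manifest is malformed."""


@dataclass(frozen=True)
class LesionEntry:
    lesion_id: str
    variants: Path
    segments: Path


@dataclass(frozen=True)
class PatientManifest:
    patient_id: str
    lesions: tuple[LesionEntry, ...]
    normal: LesionEntry | None = None

    def __post_init__(self) -> None:
        if not self.lesions:
            raise ManifestError(
                f"patient {self.patient_id!r} lists no lesions")
        ids = [e.lesion_id for e in self.lesions]
        if len(set(ids)) != len(ids):
            raise ManifestError(
                f"duplicate lesion ids for patient {self.patient_id!r}")


def _entry(data: dict, base: Path) -> LesionEntry:
    try:
        return LesionEntry(
            lesion_id=str(data["lesion_id"]),
            variants=base / data["variants"],
            segments=base / data["segments"])
    except KeyError as exc:
        raise ManifestError(f"manifest lesion entry missing {exc}") from exc


def load_manifest(path: str | Path) -> list[PatientManifest]:
    """Read a cohort or single-patient manifest (YAML or JSON).

    A cohort manifest is ``{"patients": [...]}`` where each element is
    either an inline patient mapping or a path to a per-patient manifest;
    a per-patient manifest is ``{"patient_id", "lesions": [...], "normal"}``
    with file paths relative to the manifest location.
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ManifestError(f"{path}: manifest must be a mapping")
    if "patients" in data:
        entries = data["patients"]
        if not entries:
            raise ManifestError(f"{path}: empty cohort manifest")
        manifests: list[PatientManifest] = []
        for item in entries:
            if isinstance(item, str):
                manifests.extend(load_manifest(path.parent / item))
            else:
                manifests.append(_patient_manifest(item, path.parent))
        return manifests
    return [_patient_manifest(data, path.parent)]


def _patient_manifest(data: dict, base: Path) -> PatientManifest:
    if "patient_id" not in data or "lesions" not in data:
        raise ManifestError(
            "patient manifest requires 'patient_id' and 'lesions'")
    normal = data.get("normal")
    return PatientManifest(
        patient_id=str(data["patient_id"]),
        lesions=tuple(_entry(e, base) for e in data["lesions"]),
        normal=_entry(normal, base) if normal else None)


def load_case(manifest: PatientManifest) -> PatientCase:
    """Read the variant and segment tables named by a manifest."""

    def profile(entry: LesionEntry) -> LesionProfile:
        for p in (entry.variants, entry.segments):
            if not Path(p).exists():
                raise ManifestError(f"input file not found: {p}")
        return LesionProfile(
            lesion_id=entry.lesion_id,
            variants=read_variant_table(entry.variants),
            segments=read_segments(entry.segments))

    return PatientCase(
        patient_id=manifest.patient_id,
        lesions=[profile(e) for e in manifest.lesions],
        normal=profile(manifest.normal) if manifest.normal else None)


@dataclass
class PatientReport:
    patient_id: str
    subtype_calls: list[SubtypeCall]
    clonality: ClonalityCall | None
    partition_counts: dict[str, dict[str, int]]
    clonal_fraction_table: list[dict]
    newick: str | None
    filter_stats: list[dict]
    normal_panel_features: int | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "subtypes": {c.lesion_id: {"subtype": c.subtype,
                                       "evidence": list(c.evidence)}
                         for c in self.subtype_calls},
            "clonality": None if self.clonality is None else {
                "verdict": self.clonality.verdict,
                "shared_driver_evidence":
                    list(self.clonality.shared_driver_evidence),
            },
            "shared_private_counts": self.partition_counts,
            "clonal_fractions": self.clonal_fraction_table,
            "newick": self.newick,
            "filter_stats": self.filter_stats,
            "normal_panel_features": self.normal_panel_features,
            "notes": self.notes,
        }


@dataclass
class CohortReport:
    patients: list[PatientReport]
    errors: dict[str, str]
    config: dict

    def to_dict(self) -> dict:
        payload = {
            "config": self.config,
            "version": __version__,
            "patients": [p.to_dict() for p in self.patients],
            "errors": self.errors,
        }
        payload["summary"] = summarize_cohort(self)
        payload["config_hash"] = hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16]
        return payload


def run_case(case: PatientCase,
             config: AnalysisConfig | None = None) -> PatientReport:
    """Run every analysis stage for one patient."""
    config = config or AnalysisConfig()
    notes: list[str] = []
    features = extract_case_features(case, config)
    partition = shared_private_partition(case, config, features)
    subtype_calls = [classify_subtype(p, config) for p in case.lesions]

    clonality: ClonalityCall | None = None
    if len(case.lesions) >= 2:
        clonality = classify_patient_clonality(case, config, features)
    else:
        notes.append("single lesion: clonal-origin classification skipped")

    table = compare_event_clonality(case, config, features)

    newick: str | None = None
    try:
        matrix = build_feature_matrix(
            case, config, extract_case_features(
                case, config, panel_only_snvs=True))
        if len(matrix) >= 3:
            dist = manhattan_distance_matrix(matrix)
            tree = neighbor_joining(
                dist, outgroup=config.outgroup_label
                if config.include_outgroup else None)
            newick = to_newick(tree)
        else:
            notes.append(
                "fewer than 3 matrix rows: no tree estimated")
    except ValueError as exc:
        notes.append(f"phylogeny skipped: {exc}")

    normal_panel_features: int | None = None
    if case.normal is not None:
        filtered, _ = filter_lesion_variants(case.normal, config)
        events = call_events(case.normal.segments, config.thresholds)
        normal_panel_features = (
            len(restrict_to_driver_panel(filtered, config.panel))
            + len(events))
        if normal_panel_features:
            notes.append(
                f"normal/dura profile carries {normal_panel_features} "
                "panel features; outgroup assumption violated")

    return PatientReport(
        patient_id=case.patient_id,
        subtype_calls=subtype_calls,
        clonality=clonality,
        partition_counts=partition.per_lesion_counts,
        clonal_fraction_table=table.to_dict(orient="records"),
        newick=newick,
        filter_stats=[vars(s) for s in features.filter_stats],
        normal_panel_features=normal_panel_features,
        notes=notes)


def run_pipeline(cases_or_manifests,
                 config: AnalysisConfig | None = None) -> CohortReport:
    """Run the pipeline over PatientCase objects or PatientManifests;
    per-patient failures are collected, not raised."""
    config = config or AnalysisConfig()
    reports: list[PatientReport] = []
    errors: dict[str, str] = {}
    for item in cases_or_manifests:
        case = item
        try:
            if isinstance(item, PatientManifest):
                case = load_case(item)
            reports.append(run_case(case, config))
        except Exception as exc:  # noqa: BLE001 — collected per patient
            pid = getattr(item, "patient_id", "<unknown>")
            logger.error("patient %s failed: %s", pid, exc)
            errors[pid] = str(exc)
    return CohortReport(patients=reports, errors=errors,
                        config=config.to_dict())


def summarize_cohort(report: CohortReport) -> dict:
    """Cohort-level counts: subtype and clonal-origin tallies plus
    shared/private feature fractions per lesion."""
    subtype_counts = {"NF2-loss": 0, "non-NF2": 0}
    verdict_counts = {"monoclonal": 0, "independent": 0}
    fractions: dict[str, dict[str, float]] = {}
    for patient in report.patients:
        for call in patient.subtype_calls:
            subtype_counts[call.subtype] += 1
        if patient.clonality is not None:
            verdict_counts[patient.clonality.verdict] += 1
        for lesion, counts in patient.partition_counts.items():
            total = sum(counts.values())
            fractions[lesion] = {
                k: (v / total if total else 0.0) for k, v in counts.items()}
    return {
        "n_patients": len(report.patients),
        "n_tumors": sum(len(p.subtype_calls) for p in report.patients),
        "subtype_counts": subtype_counts,
        "clonality_counts": verdict_counts,
        "shared_private_fractions": fractions,
        "n_failed_patients": len(report.errors),
    }


def write_report(report: CohortReport, outdir: str | Path) -> Path:
    """Write report.json, per-patient Newick files and a subtype/clonality
    TSV; returns the JSON path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2,
                                    sort_keys=True) + "\n")
    lines = ["patient_id\tlesion_id\tsubtype\tverdict"]
    for patient in report.patients:
        verdict = (patient.clonality.verdict
                   if patient.clonality is not None else "NA")
        for call in patient.subtype_calls:
            lines.append(f"{patient.patient_id}\t{call.lesion_id}"
                         f"\t{call.subtype}\t{verdict}")
        if patient.newick:
            (outdir / f"{patient.patient_id}.nwk").write_text(
                patient.newick + "\n")
    (outdir / "calls.tsv").write_text("\n".join(lines) + "\n")
    return json_path
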