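"""Copy-number / allelic segments: SEG I/O, interval algebra and arm-level
event calling.

Coordinates are 0-based half-open internally (BED semantics); the SEG dialect
on disk is 1-based inclusive and converted at the boundary.  Each lesion's
segments must form a partition per chromosome (no overlaps) — that is what
an allele-fraction segmentation produces, and it is what makes the shared-
segment intersection well defined.

Arm-level events are called when the fraction of an arm in a given state
(deletion: log2 copy ratio at or below a cut; amplification: at or above;
LOH: minor-allele fraction at or below a cut, irrespective of copy ratio)
reaches a minimum arm fraction.  When every arm of a chromosome carries the
same event the arms coalesce into a single chromosome-level event
("chr22"), matching how whole-chromosome losses are usually described.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .genome import arm_intervals, normalize_chrom

Interval = tuple[int, int]

EVENT_KINDS = ("deletion", "amplification", "loh")


class SegmentTableError(ValueError):
    """Raised for malformed or overlapping segment input."""


@dataclass(frozen=True)
class CNVSegment:
    """Genomic interval with log2 copy ratio and optional minor-allele
    fraction; (start, end) 0-based half-open."""

    chrom: str
    start: int
    end: int
    log2_copy_ratio: float
    maf: float | None = None
    lesion_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not 0 <= self.start < self.end:
            raise SegmentTableError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise SegmentTableError(
                f"maf outside [0, 0.5] at {self.chrom}:{self.start}: {self.maf}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVEvent:
    """Arm- or chromosome-level copy-number/LOH event.

    ``label`` is an arm ("1p") or a whole chromosome ("chr22");
    ``footprint`` is the merged set of intervals that support the call,
    used for the reciprocal-overlap sharing rule across lesions.
    """

    label: str
    kind: str
    covered_fraction: float
    lesion_id: str
    chrom: str
    footprint: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 < self.covered_fraction <= 1.0:
            raise ValueError("covered_fraction must be in (0, 1]")

    @property
    def key(self) -> str:
        return f"{self.label}:{self.kind}"

    @property
    def footprint_length(self) -> int:
        return sum(e - s for s, e in self.footprint)


@dataclass(frozen=True)
class EventThresholds:
    """Cutoffs for arm-level event calling (field-standard defaults; all
    configurable — segmentation pipelines do not fix them)."""

    deletion_log2: float = -0.3
    amplification_log2: float = 0.3
    loh_maf: float = 0.40
    min_arm_fraction: float = 0.5


SEG_COLUMNS = ("sample", "chrom", "start", "end", "log2_copy_ratio", "maf")


def _validate_partition(segments: Sequence[CNVSegment], source: str) -> None:
    by_key: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.lesion_id, seg.chrom), []).append(seg)
    for (lesion, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise SegmentTableError(
                    f"{source}: overlapping segments on {chrom} in lesion "
                    f"{lesion!r}: {a.start}-{a.end} and {b.start}-{b.end}")


def read_segments(path: str | Path) -> list[CNVSegment]:
    """Read a SEG-dialect table (1-based inclusive on disk) and convert to
    internal 0-based half-open coordinates; per-lesion segments must not
    overlap within a chromosome."""
    path = Path(path)
    segments: list[CNVSegment] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SegmentTableError(f"{path}: empty file, header expected")
        missing = set(SEG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SegmentTableError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                maf_raw = row["maf"]
                maf = (None if maf_raw is None
                       or maf_raw.strip() in ("", "NA", "na", ".")
                       else float(maf_raw))
                segments.append(CNVSegment(
                    chrom=row["chrom"],
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    log2_copy_ratio=float(row["log2_copy_ratio"]),
                    maf=maf,
                    lesion_id=row["sample"],
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise SegmentTableError(
                    f"{path}: line {lineno}: {exc}") from exc
    _validate_partition(segments, str(path))
    return segments


def write_segments(segments: Iterable[CNVSegment], path: str | Path) -> Path:
    """Write segments in the SEG dialect (1-based inclusive)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEG_COLUMNS)
        for seg in segments:
            writer.writerow([
                seg.lesion_id, seg.chrom, seg.start + 1, seg.end,
                repr(seg.log2_copy_ratio),
                "NA" if seg.maf is None else repr(seg.maf),
            ])
    return path


# -- interval algebra (inputs are sorted, disjoint interval lists) ----------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, returned sorted and disjoint (adjacent merged)."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def intersect_interval_lists(a: Sequence[Interval],
                             b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists (two-pointer)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intersect_interval_lists(
        merge_intervals(a), merge_intervals(b)))


def intersect_shared_segments(
        segments_by_lesion: Mapping[str, Sequence[CNVSegment]],
        predicate: Callable[[CNVSegment], bool],
) -> list[tuple[str, int, int]]:
    """Maximal intervals on which ``predicate`` holds in every lesion.

    The multi-lesion analogue of a bedtools intersect across per-lesion
    state intervals; output is disjoint and sorted by (chrom, start).
    """
    if len(segments_by_lesion) < 2:
        raise ValueError("shared-segment intersection needs >= 2 lesions")
    per_lesion: list[dict[str, list[Interval]]] = []
    for segs in segments_by_lesion.values():
        by_chrom: dict[str, list[Interval]] = {}
        for seg in segs:
            if predicate(seg):
                by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
        per_lesion.append({c: merge_intervals(iv) for c, iv in by_chrom.items()})
    shared_chroms = set(per_lesion[0])
    for d in per_lesion[1:]:
        shared_chroms &= set(d)
    out: list[tuple[str, int, int]] = []
    for chrom in shared_chroms:
        current = per_lesion[0][chrom]
        for d in per_lesion[1:]:
            current = intersect_interval_lists(current, d[chrom])
        out.extend((chrom, s, e) for s, e in current)
    out.sort(key=lambda t: (_chrom_sort_key(t[0]), t[1]))
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):02d}") if chrom.isdigit() else (1, chrom)


# -- arm-level event calling -------------------------------------------------

def _state_predicates(thresholds: EventThresholds) -> dict[str, Callable]:
    return {
        "deletion": lambda s: s.log2_copy_ratio <= thresholds.deletion_log2,
        "amplification":
            lambda s: s.log2_copy_ratio >= thresholds.amplification_log2,
        "loh": lambda s: s.maf is not None and s.maf <= thresholds.loh_maf,
    }


def call_events(segments: Sequence[CNVSegment],
                thresholds: EventThresholds = EventThresholds(),
                ) -> list[CNVEvent]:
    """Call arm/chromosome-level CNV and LOH events for one lesion.

    Arms where every arm of the chromosome shows the same event kind are
    coalesced into one chromosome-level event.
    """
    lesions = {s.lesion_id for s in segments}
    if len(lesions) > 1:
        raise ValueError(f"call_events expects one lesion, got {sorted(lesions)}")
    lesion_id = next(iter(lesions)) if lesions else ""
    _validate_partition(segments, "call_events")

    by_chrom: dict[str, list[CNVSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    predicates = _state_predicates(thresholds)
    events: list[CNVEvent] = []
    for chrom, segs in sorted(by_chrom.items(),
                              key=lambda kv: _chrom_sort_key(kv[0])):
        arms = arm_intervals(chrom)
        for kind, pred in predicates.items():
            qualifying = merge_intervals(
                (s.start, s.end) for s in segs if pred(s))
            if not qualifying:
                continue
            arm_hits: dict[str, tuple[float, list[Interval]]] = {}
            for arm, (arm_start, arm_end) in arms.items():
                covered = intersect_interval_lists(
                    qualifying, [(arm_start, arm_end)])
                frac = sum(e - s for s, e in covered) / (arm_end - arm_start)
                if frac >= thresholds.min_arm_fraction:
                    arm_hits[arm] = (frac, covered)
            if not arm_hits:
                continue
            if set(arm_hits) == set(arms):
                total_len = sum(e - s for s, e in arms.values())
                covered_all = merge_intervals(
                    iv for _, ivs in arm_hits.values() for iv in ivs)
                events.append(CNVEvent(
                    label=f"chr{chrom}", kind=kind,
                    covered_fraction=sum(
                        e - s for s, e in covered_all) / total_len,
                    lesion_id=lesion_id, chrom=chrom,
                    footprint=tuple(covered_all)))
            else:
                for arm, (frac, covered) in sorted(arm_hits.items()):
                    events.append(CNVEvent(
                        label=arm, kind=kind, covered_fraction=frac,
                        lesion_id=lesion_id, chrom=chrom,
                        footprint=tuple(covered)))
    return events
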