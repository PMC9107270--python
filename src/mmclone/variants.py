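"""Somatic SNV/INDEL records, the tab-delimited variant table dialect, and the
post-calling filter chain.

Three filters mirror the usual somatic post-processing of a tumour/normal
exome callset:

* a population-frequency filter that drops variants common in gnomAD
  (strictly greater than the threshold; missing frequencies are kept, since a
  variant absent from the population database cannot be declared common);
* a functional-impact filter that keeps protein-altering consequences;
* a contamination filter that drops calls whose VAF falls below the estimated
  cross-sample contamination rate (strictly below; equality is kept).

All filters are pure subset operations: they never reorder or mutate records,
so they are idempotent and commute with one another.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome import normalize_chrom

logger = logging.getLogger(__name__)

#: controlled vocabulary of variant consequences understood by the filters
CONSEQUENCE_TERMS = frozenset({
    "missense", "nonsense", "frameshift", "in_frame_indel", "splice_site",
    "start_lost", "stop_lost", "synonymous", "intronic", "utr",
})

#: consequences treated as having a functional coding impact
DEFAULT_IMPACTFUL = frozenset({
    "missense", "nonsense", "frameshift", "in_frame_indel", "splice_site",
    "start_lost", "stop_lost",
})

VARIANT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "consequence", "vaf", "gnomad_af",
)


class VariantTableError(ValueError):
    """Raised when a variant table row cannot be parsed or validated."""


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic SNV/INDEL call in one lesion.

    ``pos`` is 1-based. ``gnomad_af`` is ``None`` when the variant is absent
    from the population database (kept distinct from 0.0).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    vaf: float
    gnomad_af: float | None = None
    lesion_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise VariantTableError(f"pos must be >= 1 (got {self.pos})")
        if self.ref == self.alt:
            raise VariantTableError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise VariantTableError(
                f"vaf outside [0, 1] at {self.chrom}:{self.pos}: {self.vaf}")
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise VariantTableError(
                f"gnomad_af outside [0, 1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant across lesions: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DriverPanel:
    """Ordered set of driver gene symbols used for phylogeny features and
    subtype calls."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("driver panel must not be empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("driver panel genes must be unique")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(self.genes)


#: meningioma driver genes used for the binary alteration matrix
DEFAULT_DRIVER_PANEL = DriverPanel((
    "NF2", "TRAF7", "AKT1", "KLF4", "PIK3CA", "PIK3R1", "SMO", "SUFU",
    "POLR2A", "SMARCB1", "PRKAR1A",
))


def _parse_optional_af(raw: str) -> float | None:
    if raw is None or raw.strip() in ("", "NA", "na", ".", "None"):
        return None
    return float(raw)


def read_variant_table(path: str | Path) -> list[SomaticVariant]:
    """Read a tab-delimited variant table (one lesion per file).

    Columns: chrom, pos (1-based), ref, alt, gene, consequence, vaf,
    gnomad_af (blank/NA/. for missing). The lesion id is taken from the file
    stem unless a ``lesion_id`` column is present.
    """
    path = Path(path)
    variants: list[SomaticVariant] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise VariantTableError(f"{path}: empty file, header expected")
        missing = set(VARIANT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise VariantTableError(
                f"{path}: missing columns {sorted(missing)}")
        default_lesion = path.stem.replace(".variants", "")
        seen: set[tuple] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                variant = SomaticVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    consequence=row["consequence"],
                    vaf=float(row["vaf"]),
                    gnomad_af=_parse_optional_af(row["gnomad_af"]),
                    lesion_id=row.get("lesion_id") or default_lesion,
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise VariantTableError(
                    f"{path}: line {lineno}: {exc}") from exc
            if variant.key in seen:
                raise VariantTableError(
                    f"{path}: line {lineno}: duplicate variant "
                    f"{variant.chrom}:{variant.pos}:{variant.ref}>{variant.alt}")
            seen.add(variant.key)
            variants.append(variant)
    return variants


def write_variant_table(variants: Iterable[SomaticVariant],
                        path: str | Path) -> Path:
    """Write variants in the tab-delimited dialect read by
    :func:`read_variant_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS + ("lesion_id",))
        for v in variants:
            writer.writerow([
                v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence,
                repr(v.vaf),
                "NA" if v.gnomad_af is None else repr(v.gnomad_af),
                v.lesion_id,
            ])
    return path


def filter_population_af(variants: Sequence[SomaticVariant],
                         threshold: float = 0.01) -> list[SomaticVariant]:
    """Drop variants with population allele frequency strictly greater than
    ``threshold``; variants with no recorded frequency are kept."""
    return [v for v in variants
            if v.gnomad_af is None or v.gnomad_af <= threshold]


def filter_functional_impact(
        variants: Sequence[SomaticVariant],
        impactful: frozenset[str] | set[str] = DEFAULT_IMPACTFUL,
) -> list[SomaticVariant]:
    """Keep variants whose consequence is in the functional-impact set.

    Consequence terms outside the controlled vocabulary are excluded with a
    logged warning rather than raising, so one oddly annotated row cannot
    abort a whole lesion.
    """
    if not impactful:
        raise ValueError("impactful consequence set must not be empty")
    kept: list[SomaticVariant] = []
    for v in variants:
        if v.consequence not in CONSEQUENCE_TERMS:
            logger.warning(
                "unknown consequence %r at %s:%d — excluded",
                v.consequence, v.chrom, v.pos)
            continue
        if v.consequence in impactful:
            kept.append(v)
    return kept


def filter_contamination(variants: Sequence[SomaticVariant],
                         contamination_rate: float) -> list[SomaticVariant]:
    """Drop variants with VAF strictly below the contamination rate."""
    if not 0.0 <= contamination_rate <= 1.0:
        raise ValueError("contamination_rate must be in [0, 1]")
    return [v for v in variants if v.vaf >= contamination_rate]


def restrict_to_driver_panel(
        variants: Sequence[SomaticVariant],
        panel: DriverPanel = DEFAULT_DRIVER_PANEL) -> list[SomaticVariant]:
    """Keep variants in driver-panel genes (used for phylogeny features)."""
    return [v for v in variants if v.gene in panel]
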