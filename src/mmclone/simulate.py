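"""Synthetic multi-lesion somatic call sets with known ground truth.

The generator emulates the two clonal architectures seen in multi-lesion
tumour cohorts:

* ``monoclonal_branched`` — all lesions descend from one founding clone:
  they share a truncal set of SNVs and CNV/LOH events and then diverge by
  acquiring private alterations (branched evolution);
* ``independent`` — each lesion arises separately: no somatic alteration is
  shared, and each lesion carries its own founder alterations.

Every simulated SNV carries an observed VAF drawn from a binomial read model
at the configured sequencing depth around the VAF expected from its true
clonal fraction and local copy state; segment log2 ratios and minor-allele
fractions are emitted at their expected values (segment-level noise is far
smaller than read-level noise after averaging over a segment).  Chromosome
arms use real GRCh37 coordinates so arm-level event calling is exercised
realistically without any sequence data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .case import LesionProfile, PatientCase
from .genome import arm_chrom, arm_intervals, normalize_chrom
from .segments import CNVSegment, write_segments
from .variants import (
    DEFAULT_DRIVER_PANEL,
    DriverPanel,
    SomaticVariant,
    write_variant_table,
)

SCENARIOS = ("monoclonal_branched", "independent")

#: GRCh37 loci of the driver-panel genes (start, end), used to place
#: injected driver mutations at realistic coordinates
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "NF2": ("22", 29999545, 30094589),
    "TRAF7": ("16", 2203639, 2226187),
    "AKT1": ("14", 105235686, 105262088),
    "KLF4": ("9", 110247133, 110252047),
    "PIK3CA": ("3", 178866311, 178952497),
    "PIK3R1": ("5", 67511584, 67597649),
    "SMO": ("7", 128828713, 128853662),
    "SUFU": ("10", 104263744, 104393292),
    "POLR2A": ("17", 7387685, 7417933),
    "SMARCB1": ("22", 24129150, 24176703),
    "PRKAR1A": ("17", 66507921, 66547460),
}

_BASES = ("A", "C", "G", "T")


class SimulationError(ValueError):
    """Raised for invalid simulation configurations or exhausted sampling."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``clonal_fraction_range`` bounds the true fraction of tumour cells
    carrying each event; ``sequencing_depth`` is the read depth of the
    binomial VAF noise model (``beta_binomial_rho`` switches to a
    beta-binomial with that overdispersion).  ``driver_panel_injection``
    guarantees each clone at least one driver-panel mutation.
    """

    n_patients: int = 1
    lesions_per_patient: int = 2
    scenario: str = "monoclonal_branched"
    n_truncal_snv: int = 5
    n_private_snv_per_lesion: int = 3
    truncal_cnv_events: tuple[tuple[str, str], ...] = (("chr22", "deletion"),)
    private_cnv_events_per_lesion: int = 1
    clonal_fraction_range: tuple[float, float] = (0.6, 1.0)
    sequencing_depth: int = 500
    driver_panel_injection: bool = True
    n_artifact_snv_per_lesion: int = 2
    chromosomes: tuple[str, ...] = ("1", "2", "7", "8", "15", "18", "22", "X")
    beta_binomial_rho: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{SCENARIOS}")
        if self.lesions_per_patient < 2:
            raise SimulationError("lesions_per_patient must be >= 2")
        lo, hi = self.clonal_fraction_range
        if not 0.0 < lo <= hi <= 1.0:
            raise SimulationError(
                "clonal_fraction_range must satisfy 0 < lo <= hi <= 1")
        if self.sequencing_depth < 1:
            raise SimulationError("sequencing_depth must be >= 1")
        for kind_pair in self.truncal_cnv_events:
            if kind_pair[1] not in ("deletion", "loh"):
                raise SimulationError(
                    f"truncal CNV kind must be deletion|loh, "
                    f"got {kind_pair[1]!r}")


@dataclass
class TruthRecord:
    """Ground truth of one simulated patient: which feature keys are truncal
    vs private, and the true clonal fraction of each event per lesion."""

    patient_id: str
    scenario: str
    truncal_features: list[str]
    private_features: dict[str, list[str]]
    clonal_fractions: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TruthRecord":
        return cls(**data)


def expected_vaf(clonal_fraction: float, copy_state: str = "het_diploid",
                 ) -> float:
    """Expected VAF of a point mutation carried by a fraction
    ``clonal_fraction`` of cells.

    het_diploid: one mutant of two copies in carriers -> c/2.
    cn_loh: mutation on the retained, duplicated allele -> c.
    hemizygous: carriers retain a single (mutant) copy, non-carriers are
    diploid -> c / (2 - c).
    """
    c = clonal_fraction
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"clonal_fraction outside [0, 1]: {c}")
    if copy_state == "het_diploid":
        return c / 2.0
    if copy_state == "cn_loh":
        return c
    if copy_state == "hemizygous":
        return c / (2.0 - c)
    raise ValueError(f"unknown copy_state {copy_state!r}")


@dataclass
class _SimEvent:
    chrom: str
    kind: str                 # deletion | loh
    intervals: list[tuple[int, int]]
    arms: list[str]
    key: str


def _canonical_cnv(spec: tuple[str, str]) -> tuple[str, str, list[str]]:
    """Normalise a (chrom-or-arm, kind) event spec -> (chrom, kind, arms)."""
    target, kind = spec
    name = str(target)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name and name[-1] in "pq":
        chrom = arm_chrom(name)
        arms = [f"{chrom}{name[-1]}"]
        if arms[0] not in arm_intervals(chrom):
            raise SimulationError(f"no such arm {name!r} on chr{chrom}")
    else:
        chrom = normalize_chrom(name)
        arms = list(arm_intervals(chrom))
    return chrom, kind, arms


def _event_key(chrom: str, kind: str, arms: list[str]) -> str:
    all_chrom_arms = list(arm_intervals(chrom))
    if set(arms) == set(all_chrom_arms):
        return f"chr{chrom}:{kind}"
    assert len(arms) == 1
    return f"{arms[0]}:{kind}"


def _snv_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _observe_vaf(rng: np.random.Generator, p: float, depth: int,
                 rho: float | None) -> float:
    if rho:
        # beta-binomial overdispersion with mean p
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        p = float(rng.beta(max(a, 1e-9), max(b, 1e-9)))
    return float(rng.binomial(depth, p)) / depth


class _PatientSampler:
    """Stateful sampler for one patient, avoiding feature-key collisions."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator,
                 panel: DriverPanel):
        self.config = config
        self.rng = rng
        self.panel = panel
        self.used_positions: set[tuple[str, int]] = set()
        self.gene_counter = 0

    def clonal_fraction(self) -> float:
        lo, hi = self.config.clonal_fraction_range
        return float(self.rng.uniform(lo, hi))

    def _sample_position(self, chrom: str, lo: int, hi: int,
                         retries: int = 100) -> int:
        for _ in range(retries):
            pos = int(self.rng.integers(lo + 1, hi + 1))  # 1-based
            if (chrom, pos) not in self.used_positions:
                self.used_positions.add((chrom, pos))
                return pos
        raise SimulationError(
            f"could not place a variant on chr{chrom} without collision")

    def driver_snv(self, gene: str) -> dict:
        chrom, start, end = GENE_LOCI[gene]
        pos = self._sample_position(chrom, start, end)
        ref, alt = _draw_alleles(self.rng)
        consequence = str(self.rng.choice(
            ["missense", "nonsense", "frameshift"]))
        return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    consequence=consequence)

    def passenger_snv(self) -> dict:
        chrom = str(self.rng.choice(self.config.chromosomes))
        arms = arm_intervals(chrom)
        arm = str(self.rng.choice(list(arms)))
        lo, hi = arms[arm]
        pos = self._sample_position(chrom, lo, hi)
        ref, alt = _draw_alleles(self.rng)
        self.gene_counter += 1
        return dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=f"GENE{self.gene_counter:04d}",
                    consequence="missense")


def simulate_patient(config: SimulationConfig, patient_index: int = 0,
                     panel: DriverPanel = DEFAULT_DRIVER_PANEL,
                     ) -> tuple[PatientCase, TruthRecord]:
    """Simulate one multi-lesion patient; deterministic given
    (config.seed, patient_index)."""
    rng = np.random.default_rng((config.seed + patient_index) % 2**31)
    sampler = _PatientSampler(config, rng, panel)
    patient_id = f"SIM{patient_index:03d}"
    lesion_ids = [f"{patient_id}-T{i + 1}"
                  for i in range(config.lesions_per_patient)]

    arm_pool = [a for c in config.chromosomes for a in arm_intervals(c)]

    truncal_cnvs: list[_SimEvent] = []
    truncal_snvs: list[dict] = []
    private_cnvs: dict[str, list[_SimEvent]] = {l: [] for l in lesion_ids}
    private_snvs: dict[str, list[dict]] = {l: [] for l in lesion_ids}

    def make_event(chrom: str, kind: str, arms: list[str],
                   full_arm: bool) -> _SimEvent:
        intervals = []
        for arm in arms:
            lo, hi = arm_intervals(chrom)[arm]
            if full_arm:
                intervals.append((lo, hi))
            else:
                frac = float(rng.uniform(0.7, 1.0))
                span = int(frac * (hi - lo))
                if rng.random() < 0.5:
                    intervals.append((lo, lo + span))
                else:
                    intervals.append((hi - span, hi))
        return _SimEvent(chrom=chrom, kind=kind, intervals=intervals,
                         arms=arms, key=_event_key(chrom, kind, arms))

    def draw_private_arm() -> str:
        if not arm_pool:
            raise SimulationError(
                "arm pool exhausted; reduce private_cnv_events_per_lesion "
                "or add chromosomes")
        arm = str(rng.choice(arm_pool))
        arm_pool.remove(arm)
        return arm

    if config.scenario == "monoclonal_branched":
        for spec in config.truncal_cnv_events:
            chrom, kind, arms = _canonical_cnv(spec)
            for arm in arms:
                if arm in arm_pool:
                    arm_pool.remove(arm)
            truncal_cnvs.append(make_event(chrom, kind, arms, full_arm=True))
        if config.driver_panel_injection and config.n_truncal_snv > 0:
            gene = str(rng.choice(panel.genes))
            truncal_snvs.append(sampler.driver_snv(gene))
        while len(truncal_snvs) < config.n_truncal_snv:
            truncal_snvs.append(sampler.passenger_snv())
        for lesion in lesion_ids:
            for _ in range(config.private_cnv_events_per_lesion):
                arm = draw_private_arm()
                kind = str(rng.choice(["deletion", "loh"]))
                private_cnvs[lesion].append(
                    make_event(arm_chrom(arm), kind, [arm], full_arm=False))
            for _ in range(config.n_private_snv_per_lesion):
                private_snvs[lesion].append(sampler.passenger_snv())
    else:  # independent: each lesion gets its own founder alterations
        driver_genes = list(rng.permutation(panel.genes))
        for i, lesion in enumerate(lesion_ids):
            if config.driver_panel_injection:
                gene = driver_genes[i % len(driver_genes)]
                private_snvs[lesion].append(sampler.driver_snv(gene))
            for _ in range(config.n_truncal_snv
                           + config.n_private_snv_per_lesion):
                private_snvs[lesion].append(sampler.passenger_snv())
            n_cnv = (len(config.truncal_cnv_events)
                     + config.private_cnv_events_per_lesion)
            for _ in range(n_cnv):
                arm = draw_private_arm()
                kind = str(rng.choice(["deletion", "loh"]))
                private_cnvs[lesion].append(
                    make_event(arm_chrom(arm), kind, [arm], full_arm=False))

    lesions: list[LesionProfile] = []
    clonal_fractions: dict[str, dict[str, float]] = {}
    for lesion in lesion_ids:
        events = truncal_cnvs + private_cnvs[lesion]
        fractions: dict[str, float] = {}
        for ev in events:
            fractions[ev.key] = sampler.clonal_fraction()
        segments = _build_segments(config, lesion, events, fractions)
        variants: list[SomaticVariant] = []
        for snv in truncal_snvs + private_snvs[lesion]:
            c = sampler.clonal_fraction()
            key = _snv_key(snv["chrom"], snv["pos"], snv["ref"], snv["alt"])
            fractions[key] = c
            state = _copy_state_at(snv["chrom"], snv["pos"], events)
            p = expected_vaf(c, state)
            vaf = _observe_vaf(rng, p, config.sequencing_depth,
                               config.beta_binomial_rho)
            variants.append(SomaticVariant(
                vaf=vaf, gnomad_af=None, lesion_id=lesion, **snv))
        variants.extend(_artifact_snvs(config, sampler, lesion))
        clonal_fractions[lesion] = fractions
        lesions.append(LesionProfile(lesion_id=lesion, variants=variants,
                                     segments=segments))

    truncal_keys = sorted(
        [ev.key for ev in truncal_cnvs]
        + [_snv_key(s["chrom"], s["pos"], s["ref"], s["alt"])
           for s in truncal_snvs])
    private_keys = {
        lesion: sorted(
            [ev.key for ev in private_cnvs[lesion]]
            + [_snv_key(s["chrom"], s["pos"], s["ref"], s["alt"])
               for s in private_snvs[lesion]])
        for lesion in lesion_ids}
    truth = TruthRecord(
        patient_id=patient_id, scenario=config.scenario,
        truncal_features=truncal_keys, private_features=private_keys,
        clonal_fractions=clonal_fractions)
    return PatientCase(patient_id=patient_id, lesions=lesions), truth


def _copy_state_at(chrom: str, pos: int, events: list[_SimEvent]) -> str:
    for ev in events:
        if ev.chrom != chrom:
            continue
        for lo, hi in ev.intervals:
            if lo < pos <= hi:
                return "hemizygous" if ev.kind == "deletion" else "cn_loh"
    return "het_diploid"


def _build_segments(config: SimulationConfig, lesion: str,
                    events: list[_SimEvent],
                    fractions: dict[str, float]) -> list[CNVSegment]:
    """Partition each simulated chromosome into event and neutral segments.

    Deletion carried by fraction c of cells: mean copy number 2 - c, so
    log2 ratio log2((2 - c)/2) and MAF (1 - c)/(2 - c).  Copy-neutral LOH:
    log2 0, MAF (1 - c)/2.  Neutral: log2 0, MAF 0.5.
    """
    segments: list[CNVSegment] = []
    for chrom in config.chromosomes:
        breaks: list[tuple[int, int, str, float]] = []
        for ev in events:
            if ev.chrom != chrom:
                continue
            c = fractions[ev.key]
            for lo, hi in ev.intervals:
                breaks.append((lo, hi, ev.kind, c))
        breaks.sort()
        chrom_arms = arm_intervals(chrom)
        chrom_lo = min(lo for lo, _ in chrom_arms.values())
        chrom_hi = max(hi for _, hi in chrom_arms.values())
        cursor = chrom_lo
        for lo, hi, kind, c in breaks:
            if lo > cursor:
                segments.append(CNVSegment(chrom, cursor, lo, 0.0, 0.5,
                                           lesion))
            if kind == "deletion":
                log2 = math.log2((2.0 - c) / 2.0)
                maf = (1.0 - c) / (2.0 - c)
            else:  # loh
                log2 = 0.0
                maf = (1.0 - c) / 2.0
            segments.append(CNVSegment(chrom, lo, hi, log2, maf, lesion))
            cursor = hi
        if cursor < chrom_hi:
            segments.append(CNVSegment(chrom, cursor, chrom_hi, 0.0, 0.5,
                                       lesion))
    return segments


def _artifact_snvs(config: SimulationConfig, sampler: _PatientSampler,
                   lesion: str) -> list[SomaticVariant]:
    """Calls the downstream filters must remove: common-population variants
    and synonymous changes, alternating."""
    rng = sampler.rng
    artifacts: list[SomaticVariant] = []
    for i in range(config.n_artifact_snv_per_lesion):
        snv = sampler.passenger_snv()
        if i % 2 == 0:
            snv["consequence"] = "missense"
            gnomad: float | None = float(rng.uniform(0.02, 0.5))
            vaf = float(rng.uniform(0.35, 0.65))
        else:
            snv["consequence"] = "synonymous"
            gnomad = None
            vaf = float(rng.uniform(0.2, 0.5))
        artifacts.append(SomaticVariant(
            vaf=vaf, gnomad_af=gnomad, lesion_id=lesion, **snv))
    return artifacts


def simulate_cohort(config: SimulationConfig,
                    ) -> list[tuple[PatientCase, TruthRecord]]:
    return [simulate_patient(config, i) for i in range(config.n_patients)]


def write_fixture(case: PatientCase, directory: str | Path,
                  truth: TruthRecord | None = None) -> Path:
    """Write a patient's variant/segment tables, manifest and (optionally)
    truth record; returns the manifest path.  Round-trips losslessly through
    the table readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def emit(profile: LesionProfile) -> dict:
        vpath = directory / f"{profile.lesion_id}.variants.tsv"
        spath = directory / f"{profile.lesion_id}.segments.seg"
        write_variant_table(profile.variants, vpath)
        write_segments(profile.segments, spath)
        return {"lesion_id": profile.lesion_id,
                "variants": vpath.name, "segments": spath.name}

    manifest = {
        "patient_id": case.patient_id,
        "lesions": [emit(p) for p in case.lesions],
        "normal": emit(case.normal) if case.normal is not None else None,
    }
    if truth is not None:
        truth_path = directory / f"{case.patient_id}.truth.json"
        truth_path.write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
        manifest["truth"] = truth_path.name
    manifest_path = directory / f"{case.patient_id}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
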