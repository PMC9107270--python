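"""Hand-encoded six-patient cohort fixture.

Fifteen tumours and one dural specimen from six patients (S1–S6), encoding
per lesion exactly the alterations reported for the cohort:

* S1 — five tumours, all sharing the same NF2 mutation and a chromosome 22
  deletion; S1-T5 additionally carries SMARCB1 p.R377H and CNV events on
  chromosomes 8 and 18; an uninvolved dura sample carries nothing.
* S2 — two tumours sharing an NF2 mutation and deletions of 1p, chromosome 2
  and chromosome 22; S2-T1 additionally TRAF7 p.G560D, S2-T2 additional CNV
  events on chromosomes 8 and 15.
* S3 — two tumours sharing the same multi-chromosome CNV events, including
  a chromosome 22 deletion; no panel SNVs.
* S4 — two tumours sharing a chromosome 22 deletion but carrying distinct
  NF2 mutations (p.Q410X vs p.F62fs); S4-T1 additionally a 1p deletion.
* S5 — two tumours sharing a lesion-wide chrX LOH segment (minor-allele
  fraction 0.30 in S5-T1, 0.11 in S5-T2) with distinct TRAF7 mutations
  (p.N520S at VAF 0.22, p.I634S at VAF 0.40).
* S6 — two tumours with completely distinct profiles: one POLR2A-mutant,
  one TRAF7-mutant, nothing shared.

SNV coordinates are representative positions inside the GRCh37 loci of the
named genes; where the cohort description names an alteration but not its
class (the chr8/15/18 CNV events), deletions are encoded — the subtype and
clonality calls do not depend on that choice.  The chrX event is encoded
with log2 −0.2 so it is called as an LOH event (its printed minor-allele
fractions, not its copy ratio, carry the clonality signal).
"""

from __future__ import annotations

from .case import LesionProfile, PatientCase
from .genome import CHROM_LENGTHS
from .segments import CNVSegment
from .variants import SomaticVariant


def _snv(lesion: str, chrom: str, pos: int, ref: str, alt: str, gene: str,
         consequence: str, vaf: float) -> SomaticVariant:
    return SomaticVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                          consequence=consequence, vaf=vaf, gnomad_af=None,
                          lesion_id=lesion)


def _whole_chrom(lesion: str, chrom: str, log2: float,
                 maf: float | None) -> CNVSegment:
    return CNVSegment(chrom=chrom, start=0, end=CHROM_LENGTHS[chrom],
                      log2_copy_ratio=log2, maf=maf, lesion_id=lesion)


def _del_1p(lesion: str) -> CNVSegment:
    # 1p deletion: p arm of chromosome 1 (GRCh37 centromere at 121.5 Mb)
    return CNVSegment(chrom="1", start=0, end=121535434,
                      log2_copy_ratio=-0.6, maf=0.2, lesion_id=lesion)


# shared NF2 mutations (one per patient where reported as identical)
_S1_NF2 = dict(chrom="22", pos=30051000, ref="C", alt="T", gene="NF2",
               consequence="nonsense")
_S2_NF2 = dict(chrom="22", pos=30035000, ref="CA", alt="C", gene="NF2",
               consequence="frameshift")


def _s1() -> PatientCase:
    lesions = []
    vafs = {"S1-T1": 0.42, "S1-T2": 0.38, "S1-T3": 0.45, "S1-T4": 0.40,
            "S1-T5": 0.41}
    for lesion, vaf in vafs.items():
        variants = [SomaticVariant(vaf=vaf, gnomad_af=None,
                                   lesion_id=lesion, **_S1_NF2)]
        segments = [_whole_chrom(lesion, "22", -0.8, 0.17)]
        if lesion == "S1-T5":
            variants.append(_snv(lesion, "22", 24145000, "G", "A",
                                 "SMARCB1", "missense", 0.38))
            segments.append(_whole_chrom(lesion, "8", -0.6, 0.2))
            segments.append(_whole_chrom(lesion, "18", -0.6, 0.2))
        lesions.append(LesionProfile(lesion, variants, segments))
    dura = LesionProfile("S1-dura", [], [])
    return PatientCase("S1", lesions, normal=dura)


def _s2() -> PatientCase:
    shared = lambda lesion: [
        _del_1p(lesion),
        _whole_chrom(lesion, "2", -0.6, 0.2),
        _whole_chrom(lesion, "22", -0.8, 0.17),
    ]
    t1 = LesionProfile("S2-T1", [
        SomaticVariant(vaf=0.41, gnomad_af=None, lesion_id="S2-T1",
                       **_S2_NF2),
        _snv("S2-T1", "16", 2225000, "G", "A", "TRAF7", "missense", 0.30),
    ], shared("S2-T1"))
    t2 = LesionProfile("S2-T2", [
        SomaticVariant(vaf=0.39, gnomad_af=None, lesion_id="S2-T2",
                       **_S2_NF2),
    ], shared("S2-T2") + [
        _whole_chrom("S2-T2", "8", -0.5, 0.22),
        _whole_chrom("S2-T2", "15", -0.5, 0.22),
    ])
    return PatientCase("S2", [t1, t2])


def _s3() -> PatientCase:
    def segs(lesion: str) -> list[CNVSegment]:
        return [
            _whole_chrom(lesion, "22", -0.7, 0.18),
            _del_1p(lesion),
            _whole_chrom(lesion, "18", -0.5, 0.22),
        ]
    return PatientCase("S3", [
        LesionProfile("S3-T1", [], segs("S3-T1")),
        LesionProfile("S3-T2", [], segs("S3-T2")),
    ])


def _s4() -> PatientCase:
    t1 = LesionProfile("S4-T1", [
        _snv("S4-T1", "22", 30070000, "C", "T", "NF2", "nonsense", 0.44),
    ], [_whole_chrom("S4-T1", "22", -0.8, 0.17), _del_1p("S4-T1")])
    t2 = LesionProfile("S4-T2", [
        _snv("S4-T2", "22", 30005000, "A", "AT", "NF2", "frameshift", 0.36),
    ], [_whole_chrom("S4-T2", "22", -0.8, 0.17)])
    return PatientCase("S4", [t1, t2])


def _s5() -> PatientCase:
    t1 = LesionProfile("S5-T1", [
        _snv("S5-T1", "16", 2224525, "A", "G", "TRAF7", "missense", 0.22),
    ], [_whole_chrom("S5-T1", "X", -0.2, 0.30)])
    t2 = LesionProfile("S5-T2", [
        _snv("S5-T2", "16", 2225600, "T", "G", "TRAF7", "missense", 0.40),
    ], [_whole_chrom("S5-T2", "X", -0.2, 0.11)])
    return PatientCase("S5", [t1, t2])


def _s6() -> PatientCase:
    t1 = LesionProfile("S6-T1", [
        _snv("S6-T1", "17", 7398000, "C", "T", "POLR2A", "missense", 0.35),
    ], [])
    t2 = LesionProfile("S6-T2", [
        _snv("S6-T2", "16", 2223000, "G", "A", "TRAF7", "missense", 0.30),
    ], [])
    return PatientCase("S6", [t1, t2])


def build_inpaper_fixture() -> list[PatientCase]:
    """The six-patient cohort (15 tumours + 1 dura) as PatientCase objects."""
    return [_s1(), _s2(), _s3(), _s4(), _s5(), _s6()]
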