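"""Per-lesion and per-patient containers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .segments import CNVSegment
from .variants import SomaticVariant


@dataclass
class LesionProfile:
    """All somatic calls of one lesion: variant calls as read from the
    variant table (pre-filter) and the allelic segmentation."""

    lesion_id: str
    variants: list[SomaticVariant] = field(default_factory=list)
    segments: list[CNVSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.lesion_id and v.lesion_id != self.lesion_id:
                raise ValueError(
                    f"variant lesion_id {v.lesion_id!r} does not match "
                    f"profile {self.lesion_id!r}")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant keys in {self.lesion_id!r}")


@dataclass
class PatientCase:
    """All tumour lesions of one patient, plus an optional matched
    normal/dura profile (never a source of tumour features; used only as the
    phylogeny outgroup check)."""

    patient_id: str
    lesions: list[LesionProfile]
    normal: LesionProfile | None = None

    def __post_init__(self) -> None:
        if not self.lesions:
            raise ValueError(f"patient {self.patient_id!r} has no lesions")
        ids = [p.lesion_id for p in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate lesion ids in {self.patient_id!r}")

    @property
    def lesion_ids(self) -> list[str]:
        return [p.lesion_id for p in self.lesions]
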