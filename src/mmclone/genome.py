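"""GRCh37 chromosome-arm coordinate table.

Arm-level CNV calling needs to know where chromosome arms begin and end.
The table below uses GRCh37/hg19 chromosome lengths and the UCSC gap-track
centromere intervals; the p arm runs from the start of the chromosome to the
centromere gap, the q arm from the end of the gap to the chromosome end.

The short arms of the acrocentric chromosomes (13, 14, 15, 21, 22) consist of
heterochromatic stalks and rDNA repeats that exome capture does not cover, so
they are excluded: for those chromosomes the q arm is the only arm, and a
q-arm-wide event is reported at chromosome level (e.g. "chr22").
"""

from __future__ import annotations

# chromosome -> total length (bp), GRCh37
CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560,
}

# chromosome -> (gap_start, gap_end), 0-based half-open, UCSC hg19 gap track
CENTROMERES: dict[str, tuple[int, int]] = {
    "1": (121535434, 124535434), "2": (92326171, 95326171),
    "3": (90504854, 93504854), "4": (49660117, 52660117),
    "5": (46405641, 49405641), "6": (58830166, 61830166),
    "7": (58054331, 61054331), "8": (43838887, 46838887),
    "9": (47367679, 50367679), "10": (39254935, 42254935),
    "11": (51644205, 54644205), "12": (34856694, 37856694),
    "13": (16000000, 19000000), "14": (16000000, 19000000),
    "15": (17000000, 20000000), "16": (35335801, 38335801),
    "17": (22263006, 25263006), "18": (15460898, 18460898),
    "19": (24681782, 27681782), "20": (26369569, 29369569),
    "21": (11288129, 14288129), "22": (13000000, 16000000),
    "X": (58632012, 61632012),
}

ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and canonicalise case ('chrx' -> 'X')."""
    name = str(chrom).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.lower() in ("x", "y"):
        name = name.upper()
    if name not in CHROM_LENGTHS:
        raise ValueError(f"unknown chromosome: {chrom!r}")
    return name


def arm_intervals(chrom: str) -> dict[str, tuple[int, int]]:
    """Arm label -> (start, end) in 0-based half-open coordinates.

    Acrocentric chromosomes expose only their q arm.
    """
    name = normalize_chrom(chrom)
    cen_start, cen_end = CENTROMERES[name]
    arms: dict[str, tuple[int, int]] = {}
    if name not in ACROCENTRIC:
        arms[f"{name}p"] = (0, cen_start)
    arms[f"{name}q"] = (cen_end, CHROM_LENGTHS[name])
    return arms


def all_arms(chromosomes=None) -> list[str]:
    """Ordered arm labels for the given chromosomes (default: all)."""
    chroms = list(CHROM_LENGTHS) if chromosomes is None else [
        normalize_chrom(c) for c in chromosomes
    ]
    labels: list[str] = []
    for c in chroms:
        labels.extend(arm_intervals(c))
    return labels


def arm_chrom(arm: str) -> str:
    """Chromosome of an arm label ('22q' -> '22')."""
    return normalize_chrom(arm.rstrip("pq"))
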