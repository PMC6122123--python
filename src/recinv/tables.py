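"""Reference tables for the ordered Hmel2 chromosomal assembly and the published crosses.

These are the printed physical/genetic map summaries used as fixed inputs for
arithmetic checks and for genome-scale simulations: the 21 chromosome lengths of
the ordered Hmel2 assembly (272,636,897 bp total), the per-chromosome genetic
lengths (cM) of the *H. melpomene*, *H. cydno* and hybrid paternal maps, and the
per-cross offspring counts and total map lengths.
"""

from __future__ import annotations

# chromosome -> physical length (bp), ordered Hmel2 assembly
HMEL2_CHROM_LENGTHS_BP: dict[str, int] = {
    "chr1": 17_206_585,
    "chr2": 9_045_316,
    "chr3": 10_541_528,
    "chr4": 9_662_098,
    "chr5": 9_908_586,
    "chr6": 14_054_175,
    "chr7": 14_308_859,
    "chr8": 9_320_449,
    "chr9": 8_708_747,
    "chr10": 17_965_481,
    "chr11": 11_759_272,
    "chr12": 16_327_298,
    "chr13": 18_127_314,
    "chr14": 9_174_305,
    "chr15": 10_235_750,
    "chr16": 10_083_215,
    "chr17": 14_773_299,
    "chr18": 16_803_890,
    "chr19": 16_399_344,
    "chr20": 14_871_695,
    "chr21": 13_359_691,
}

GENOME_LENGTH_BP: int = sum(HMEL2_CHROM_LENGTHS_BP.values())  # 272,636,897

# chromosome -> paternal genetic length (cM) per group
GENETIC_LENGTHS_CM: dict[str, dict[str, float]] = {
    "melpomene": {
        "chr1": 54.6, "chr2": 50.7, "chr3": 53.7, "chr4": 48.1, "chr5": 51.0,
        "chr6": 47.8, "chr7": 53.7, "chr8": 49.3, "chr9": 46.3, "chr10": 56.7,
        "chr11": 52.5, "chr12": 51.0, "chr13": 55.8, "chr14": 50.2, "chr15": 49.0,
        "chr16": 47.5, "chr17": 58.2, "chr18": 53.1, "chr19": 51.0, "chr20": 51.3,
        "chr21": 49.6,
    },
    "cydno": {
        "chr1": 54.5, "chr2": 47.5, "chr3": 50.2, "chr4": 50.5, "chr5": 50.2,
        "chr6": 54.5, "chr7": 52.2, "chr8": 49.8, "chr9": 50.8, "chr10": 55.9,
        "chr11": 49.8, "chr12": 52.9, "chr13": 54.2, "chr14": 44.4, "chr15": 50.8,
        "chr16": 50.8, "chr17": 49.2, "chr18": 48.8, "chr19": 53.9, "chr20": 54.9,
        "chr21": 48.1,
    },
    "hybrid": {
        "chr1": 56.2, "chr2": 44.4, "chr3": 49.9, "chr4": 46.9, "chr5": 48.7,
        "chr6": 49.9, "chr7": 50.2, "chr8": 49.6, "chr9": 52.3, "chr10": 53.8,
        "chr11": 51.4, "chr12": 52.9, "chr13": 56.8, "chr14": 55.3, "chr15": 49.3,
        "chr16": 52.0, "chr17": 48.3, "chr18": 52.9, "chr19": 54.1, "chr20": 51.7,
        "chr21": 51.1,
    },
}

# total genome genetic lengths (cM) per group, as printed
GENOME_CM: dict[str, float] = {
    "melpomene": 1081.2,
    "cydno": 1074.1,
    "hybrid": 1077.5,
}

# per-cross summaries: group -> list of (offspring, total map length in cM)
CROSS_SUMMARY: dict[str, list[tuple[int, float]]] = {
    "melpomene": [(111, 1048.0), (122, 1065.0), (102, 1135.0)],
    "cydno": [(95, 1076.0), (77, 1076.0), (125, 1070.0)],
    "hybrid": [(170, 1090.0), (88, 1069.0), (68, 1158.0), (5, 1040.0)],
}

# marker-gap summaries of the paternal maps (bp)
MARKER_GAP_SUMMARY_BP: dict[str, dict[str, float]] = {
    "melpomene": {"mean": 115_000, "median": 87_000, "max": 1_380_000},
    "cydno": {"mean": 135_000, "median": 101_000, "max": 1_140_000},
}


def hmel2_genome():
    """The 21 ordered Hmel2 chromosomes as a list of ChromosomeSpec."""
    from .synthetic import ChromosomeSpec

    return [ChromosomeSpec(name, bp) for name, bp in HMEL2_CHROM_LENGTHS_BP.items()]
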