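"""Default gene inventory and simulation parameters for the plastome simulator.

The tables below describe a canonical angiosperm-style plastome: 123 unique
genes (81 protein-coding, 38 tRNA, 4 rRNA) of which 23 lie in the inverted
repeat and are therefore present twice (146 placed gene copies).  Gene order
follows the conserved dicot arrangement so that the classic variable
intergenic spacers (trnS-trnG, accD-psaI, ndhF-rpl32, ...) exist by name.
Exon lengths approximate published plastome annotations; they are inputs to
the simulator, not measurements.
"""

from __future__ import annotations

# (name, class) ordered along each region; class: p = protein (CDS), t = tRNA, r = rRNA
LSC_GENE_ORDER: list[tuple[str, str]] = [
    ("psbA", "p"), ("trnK-UUU", "t"), ("matK", "p"), ("rps16", "p"),
    ("trnQ-UUG", "t"), ("psbK", "p"), ("psbI", "p"), ("trnS-GCU", "t"),
    ("trnG-GCC", "t"), ("trnR-UCU", "t"), ("atpA", "p"), ("atpF", "p"),
    ("atpH", "p"), ("atpI", "p"), ("rps2", "p"), ("rpoC2", "p"),
    ("rpoC1", "p"), ("rpoB", "p"), ("trnC-GCA", "t"), ("petN", "p"),
    ("psbM", "p"), ("trnD-GUC", "t"), ("trnY-GUA", "t"), ("trnE-UUC", "t"),
    ("psbD", "p"), ("psbC", "p"), ("psbZ", "p"), ("trnS-UGA", "t"),
    ("trnG-UCC", "t"), ("trnfM-CAU", "t"), ("rps14", "p"), ("psaB", "p"),
    ("psaA", "p"), ("ycf3", "p"), ("trnS-GGA", "t"), ("rps4", "p"),
    ("trnT-UGU", "t"), ("trnL-UAA", "t"), ("trnF-GAA", "t"), ("ndhJ", "p"),
    ("ndhK", "p"), ("ndhC", "p"), ("trnV-UAC", "t"), ("trnM-CAU", "t"),
    ("atpE", "p"), ("atpB", "p"), ("rbcL", "p"), ("accD", "p"),
    ("psaI", "p"), ("ycf4", "p"), ("cemA", "p"), ("petA", "p"),
    ("psbJ", "p"), ("psbL", "p"), ("psbF", "p"), ("psbE", "p"),
    ("petL", "p"), ("petG", "p"), ("trnW-CCA", "t"), ("trnP-UGG", "t"),
    ("psaJ", "p"), ("rpl33", "p"), ("rps18", "p"), ("rpl20", "p"),
    ("clpP", "p"), ("psbB", "p"), ("psbT", "p"), ("psbN", "p"),
    ("psbH", "p"), ("petB", "p"), ("petD", "p"), ("rpoA", "p"),
    ("rps11", "p"), ("rpl36", "p"), ("infA", "p"), ("rps8", "p"),
    ("rpl14", "p"), ("rpl16", "p"), ("rps3", "p"), ("rpl22", "p"),
    ("rps19", "p"), ("psaM", "p"), ("trnT-GGU", "t"), ("trnI-AAU", "t"),
    ("trnL-CAG", "t"), ("trnR-CCG", "t"), ("trnA-GGC", "t"),
]

SSC_GENE_ORDER: list[tuple[str, str]] = [
    ("ndhF", "p"), ("rpl32", "p"), ("trnL-UAG", "t"), ("ccsA", "p"),
    ("ndhD", "p"), ("psaC", "p"), ("ndhE", "p"), ("ndhG", "p"),
    ("ndhI", "p"), ("ndhA", "p"), ("ndhH", "p"), ("rps15", "p"),
    ("ycf1", "p"),
]

# 23 genes duplicated once in each inverted repeat copy
IR_GENE_ORDER: list[tuple[str, str]] = [
    ("rpl2", "p"), ("rpl23", "p"), ("trnI-CAU", "t"), ("ycf2", "p"),
    ("ycf15", "p"), ("trnL-CAA", "t"), ("ndhB", "p"), ("rps7", "p"),
    ("rps12", "p"), ("trnV-GAC", "t"), ("rrn16", "r"), ("trnI-GAU", "t"),
    ("trnA-UGC", "t"), ("rrn23", "r"), ("rrn4.5", "r"), ("rrn5", "r"),
    ("trnR-ACG", "t"), ("trnN-GUU", "t"), ("trnH-GUG", "t"), ("trnP-GGG", "t"),
    ("trnS-CGA", "t"), ("trnT-CGU", "t"), ("trnV-AAC", "t"),
]

# total exon length, bp (protein lengths are multiples of 3)
EXON_LENGTHS: dict[str, int] = {
    "psbA": 1062, "matK": 1530, "rps16": 261, "psbK": 186, "psbI": 111,
    "atpA": 1524, "atpF": 555, "atpH": 246, "atpI": 744, "rps2": 711,
    "rpoC2": 4140, "rpoC1": 2055, "rpoB": 3213, "petN": 90, "psbM": 105,
    "psbD": 1062, "psbC": 1422, "psbZ": 189, "rps14": 303, "psaB": 2205,
    "psaA": 2253, "ycf3": 507, "rps4": 606, "ndhJ": 477, "ndhK": 678,
    "ndhC": 363, "atpE": 402, "atpB": 1497, "rbcL": 1428, "accD": 1458,
    "psaI": 111, "ycf4": 555, "cemA": 690, "petA": 963, "psbJ": 123,
    "psbL": 117, "psbF": 120, "psbE": 252, "petL": 96, "petG": 114,
    "psaJ": 135, "rpl33": 201, "rps18": 306, "rpl20": 354, "clpP": 591,
    "psbB": 1527, "psbT": 108, "psbN": 132, "psbH": 222, "petB": 648,
    "petD": 483, "rpoA": 1014, "rps11": 417, "rpl36": 114, "infA": 234,
    "rps8": 405, "rpl14": 369, "rpl16": 408, "rps3": 657, "rpl22": 399,
    "rps19": 279, "psaM": 93,
    "ndhF": 2241, "rpl32": 174, "ccsA": 960, "ndhD": 1503, "psaC": 246,
    "ndhE": 306, "ndhG": 531, "ndhI": 504, "ndhA": 1092, "ndhH": 1182,
    "rps15": 273, "ycf1": 5496,
    "rpl2": 825, "rpl23": 282, "ycf2": 6834, "ycf15": 180, "ndhB": 1533,
    "rps7": 468, "rps12": 372,
    "rrn16": 1491, "rrn23": 2810, "rrn4.5": 103, "rrn5": 121,
}
TRNA_LENGTH = 60  # uniform tRNA exon length

# intron lengths, bp; two-intron genes list two values
INTRON_LENGTHS: dict[str, list[int]] = {
    "trnK-UUU": [2500], "rps16": [870], "trnG-GCC": [700], "atpF": [700],
    "rpoC1": [740], "ycf3": [730, 740], "trnL-UAA": [500], "trnV-UAC": [590],
    "clpP": [800, 630], "petB": [760], "petD": [720], "rpl16": [1020],
    "ndhA": [1080], "rpl2": [660], "ndhB": [680], "rps12": [540],
    "trnI-GAU": [940], "trnA-UGC": [810],
}

ONE_INTRON_GENES = [
    "atpF", "ndhA", "ndhB", "petB", "petD", "rpl16", "rpl2", "rpoC1",
    "rps12", "rps16", "trnA-UGC", "trnG-GCC", "trnI-GAU", "trnK-UUU",
    "trnL-UAA", "trnV-UAC",
]
TWO_INTRON_GENES = ["clpP", "ycf3"]

# minus-strand genes (a realistic mixture; orientation exercises the
# strand-handling paths, the statistics do not depend on it)
MINUS_STRAND_GENES = {
    "rps16", "trnQ-UUG", "rpoC2", "rpoC1", "rpoB", "trnC-GCA", "petN",
    "psbM", "trnD-GUC", "trnY-GUA", "psbD", "psbC", "psaB", "psaA",
    "ndhJ", "ndhK", "ndhC", "accD", "cemA", "petA", "psbJ", "psbL",
    "psbF", "psbE", "clpP", "rpoA", "rps11", "rpl36", "infA", "rps8",
    "rpl14", "rpl16", "rps3", "rpl22", "rps19",
    "ndhF", "rpl32", "ccsA", "ndhD", "psaC", "ndhE", "ndhG", "ndhI",
    "ndhA", "ndhH", "rps15",
    "rpl2", "rpl23", "ycf2", "ycf15", "ndhB", "rps7", "rps12",
}

# relative substitution-rate multipliers by feature class x structural region:
# single-copy noncoding evolves fastest, the IR slowest.  Separations are
# wide enough that the partition-level ordering SSC > introns/spacers > LSC >
# coding > IR is a property of the configuration rather than a sampling
# accident at single-genome scale.
DEFAULT_RATE_MULTIPLIERS: dict[str, dict[str, float]] = {
    "coding": {"LSC": 0.30, "SSC": 0.70, "IR": 0.10},
    "intron": {"LSC": 0.50, "SSC": 0.85, "IR": 0.18},
    "spacer": {"LSC": 0.62, "SSC": 1.05, "IR": 0.18},
}

# 7 ingroup individuals (6 species; sp4 sampled twice) + 4 outgroups.
# Branch lengths are expected substitutions/site at relative rate 1.0.
DEFAULT_TREE = (
    "(((sp1_a:0.0014,sp2_a:0.0013):0.0008,"
    "((sp3_a:0.0011,(sp4_a:0.00016,sp4_b:0.00016):0.0008):0.0006,"
    "(sp5_a:0.0013,sp6_a:0.0014):0.0006):0.0005):0.004,"
    "((og1:0.006,og2:0.007):0.002,(og3:0.008,og4:0.009):0.001):0.001);"
)

DEFAULT_SPECIES_LABELS = {
    "sp1_a": "species1", "sp2_a": "species2", "sp3_a": "species3",
    "sp4_a": "species4", "sp4_b": "species4", "sp5_a": "species5",
    "sp6_a": "species6",
    "og1": "outgroup1", "og2": "outgroup2", "og3": "outgroup3",
    "og4": "outgroup4",
}
DEFAULT_OUTGROUPS = ["og1", "og2", "og3", "og4"]

# planted repeat mix: 45 repeats, lengths 30-61 bp; tandem-heavy like real
# plastomes (19/45 = 42% tandem, 2/45 = 4% gene-similarity)
# entries: (category, motif length, mismatches between copies)
DEFAULT_REPEAT_SPEC: list[tuple[str, int, int]] = (
    [("tandem", 30 + (i * 2) % 32, 1 if i % 4 == 3 else 0) for i in range(19)]
    + [("gene_similarity", 33, 0), ("gene_similarity", 39, 1)]
    + [("palindromic", 31 + (i * 3) % 31, 1 if i % 3 == 2 else 0) for i in range(9)]
    + [("dispersed", 30 + (i * 5) % 32, 1 if i % 3 == 1 else 0) for i in range(15)]
)
GENE_SIMILARITY_TARGETS = [("rpoC2", "rpoB"), ("psaA", "psaB")]

DEFAULT_LSC_LEN = 86_204
DEFAULT_SSC_LEN = 18_318
DEFAULT_IR_LEN = 26_025
DEFAULT_AT_FRACTION = 0.627
DEFAULT_PROTEIN_FRACTION = 0.529  # target CDS share of genome length
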