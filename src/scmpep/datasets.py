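"""Published reference data for tumor-homing peptide scoring.

Bundles a published 20-residue propensity score card for tumor-homing
peptides (cutoff 301), the 40 benchmark peptides printed alongside it (the 20
top-scoring THPs and the 20 lowest-scoring non-THPs, with their reported
scores and physicochemical columns), the per-class amino-acid compositions
the card was estimated from, and two physicochemical property scales
(refractivity; free amino-acid molar extinction coefficients at 214 nm).
These serve as offline ground truth for tests and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring_card import ScoreCard

# Propensity scores of the 20 amino acids for the tumor-homing class
# (0-1000 scale), with the published decision cutoff.
REFERENCE_CARD_SCORES: dict[str, int] = {
    "C": 1000, "W": 981, "R": 598, "P": 587, "F": 424,
    "S": 407, "H": 382, "L": 374, "Y": 273, "M": 266,
    "Q": 198, "N": 195, "A": 160, "G": 157, "T": 150,
    "D": 103, "E": 67, "V": 48, "K": 45, "I": 0,
}
REFERENCE_CUTOFF: int = 301

# Per-class amino-acid composition (%) of the training set the card was
# estimated from, and their difference (positive minus negative).
REFERENCE_COMPOSITION: dict[str, tuple[float, float, float]] = {
    # residue: (THP %, non-THP %, difference)
    "C": (9.635, 1.082, 8.552),
    "W": (3.459, 1.088, 2.371),
    "R": (8.947, 5.062, 3.885),
    "P": (6.831, 4.940, 1.891),
    "F": (3.018, 3.846, -0.828),
    "S": (8.525, 6.860, 1.666),
    "H": (3.084, 2.699, 0.385),
    "L": (8.157, 9.394, -1.237),
    "Y": (3.023, 2.912, 0.111),
    "M": (2.629, 2.604, 0.025),
    "Q": (3.284, 4.052, -0.769),
    "N": (3.365, 4.169, -0.804),
    "A": (5.717, 8.099, -2.382),
    "G": (7.552, 7.203, 0.349),
    "T": (4.744, 5.364, -0.620),
    "D": (3.798, 5.664, -1.866),
    "E": (3.544, 6.153, -2.609),
    "V": (4.392, 6.906, -2.514),
    "K": (3.469, 6.008, -2.540),
    "I": (2.828, 5.894, -3.066),
}

# The 20 top-scoring THPs: (sequence, reported score, reported MW,
# reported extinction coefficient, reported net charge).
REFERENCE_THP_ROWS: list[tuple[str, int, float, int, int]] = [
    ("CFWPNRC", 684, 925.17, 5625, 1),
    ("QWCSRRWCT", 657, 1225.52, 11125, 2),
    ("WTCRASWCS", 632, 1099.35, 11125, 1),
    ("SGWCYRC", 631, 874.08, 7115, 1),
    ("RWCREKSCW", 631, 1253.57, 11125, 2),
    ("CSDWQHPWC", 627, 1161.39, 11125, -1),
    ("CPRGSRC", 621, 777.99, 125, 2),
    ("CWRKFYC", 617, 1005.30, 7115, 2),
    ("CSDSWHYWC", 615, 1186.39, 12615, -1),
    ("WRPCES", 607, 776.93, 5500, 0),
    ("CWLCNGRCGR", 606, 1167.52, 5625, 2),
    ("RHCFSQWCS", 600, 1153.41, 5625, 1),
    ("CDCRGDCFC", 598, 1021.26, 250, -1),
    ("CPHSKPCLC", 598, 987.33, 125, 1),
    ("CWGCNGRCRM", 595, 1185.55, 5625, 2),
    ("CSRPRRSEC", 585, 1093.34, 125, 2),
    ("CSRPRRSVC", 583, 1063.36, 125, 3),
    ("CVLCNGRCWS", 576, 1140.49, 5625, 1),
    ("CRGDGWC", 571, 795.97, 5625, 0),
    ("WREWFL", 571, 936.16, 11000, 0),
]

# The 20 lowest-scoring non-THPs, same columns.
REFERENCE_NONTHP_ROWS: list[tuple[str, int, float, int, int]] = [
    ("IKIQD", 69, 615.80, 0, 0),
    ("KKEKDIMKKTI", 74, 1361.87, 0, 3),
    ("INGKVT", 99, 630.83, 0, 1),
    ("VKNNVEVN", 105, 915.13, 0, 0),
    ("IGIGAG", 105, 486.66, 0, 0),
    ("AVKKAYDIAIQ", 108, 1219.60, 1490, 1),
    ("DVGTTE", 113, 620.69, 0, -2),
    ("IGDAT", 114, 475.56, 0, -1),
    ("VAIDM", 115, 547.73, 0, -1),
    ("DVKGVFVNI", 119, 990.30, 0, 0),
    ("DLAVVEVDQVMVVD", 119, 1530.96, 0, -4),
    ("TDIDDKIINRAI", 121, 1386.74, 0, -1),
    ("GDVVANT", 123, 674.80, 0, -1),
    ("IDKQLE", 131, 744.93, 0, -1),
    ("FGKKKKYKD", 131, 1141.50, 1490, 4),
    ("KENILNE", 135, 859.05, 0, -1),
    ("HEAVGI", 136, 624.78, 0, -1),
    ("HKNKGKKN", 139, 953.23, 0, 4),
    ("ENAKAAVAEMKDGDVVLLE", 139, 2002.54, 0, -3),
    ("ITDMAA", 140, 620.79, 0, -1),
]

# Refractivity scale (AAIndex accession MCMT640101).
REFRACTIVITY: dict[str, float] = {
    "A": 4.34, "R": 26.66, "N": 13.28, "D": 12.00, "C": 35.77,
    "Q": 17.56, "E": 17.26, "G": 0.00, "H": 21.81, "I": 19.06,
    "L": 18.78, "K": 21.29, "M": 21.64, "F": 29.40, "P": 10.93,
    "S": 6.35, "T": 11.01, "W": 42.53, "Y": 31.53, "V": 13.92,
}

# Molar extinction coefficients of free amino acids at 214 nm
# (M^-1 cm^-1, 20% acetonitrile / 0.1% formic acid).
EXTINCTION_214NM: dict[str, float] = {
    "C": 225, "W": 29050, "R": 102, "P": 30, "F": 5200,
    "S": 34, "H": 5125, "L": 45, "Y": 5375, "M": 980,
    "Q": 142, "N": 136, "A": 32, "G": 21, "T": 41,
    "D": 58, "E": 78, "V": 43, "K": 41, "I": 45,
}

# The refractivity scale rendered in AAIndex1 flat-file layout, for parser
# round-trips and offline property screening.
AAINDEX_FIXTURE_TEXT: str = """\
H MCMT640101
D Refractivity (McMeekin et al., 1964), Cited by Jones (1975)
R PMID:
A McMeekin, T.L., Groves, M.L. and Hipp, N.J.
T Refractive indices of amino acids, proteins and related substances
J In "Amino Acids and Serum Proteins" (Stekol, J.A., ed.), American Chemical
  Society, Washington, D.C., p.54 (1964)
C HANK990101    0.971
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     4.34   26.66   13.28   12.00   35.77   17.56   17.26    0.00   21.81   19.06
    18.78   21.29   21.64   29.40   10.93    6.35   11.01   42.53   31.53   13.92
//
"""


@dataclass(frozen=True)
class ReferenceBundle:
    """The published card plus the benchmark rows and property scales."""

    card: ScoreCard
    thp_rows: list[tuple[str, int, float, int, int]]
    nonthp_rows: list[tuple[str, int, float, int, int]]
    composition: dict[str, tuple[float, float, float]]
    refractivity: dict[str, float]
    extinction_214nm: dict[str, float]

    @property
    def sequences(self) -> list[str]:
        return [r[0] for r in self.thp_rows + self.nonthp_rows]


def load_reference_card() -> ScoreCard:
    """The published propensity card with its cutoff of 301."""
    return ScoreCard(dict(REFERENCE_CARD_SCORES), cutoff=REFERENCE_CUTOFF,
                     origin="literature")


def reference_bundle() -> ReferenceBundle:
    """All offline ground-truth fixtures in one object."""
    return ReferenceBundle(
        card=load_reference_card(),
        thp_rows=list(REFERENCE_THP_ROWS),
        nonthp_rows=list(REFERENCE_NONTHP_ROWS),
        composition=dict(REFERENCE_COMPOSITION),
        refractivity=dict(REFRACTIVITY),
        extinction_214nm=dict(EXTINCTION_214NM),
    )
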