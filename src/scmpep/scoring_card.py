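"""The propensity score card and the weighted-sum peptide scorer.

A score card maps each of the 20 standard residues to a propensity on a
0-1000 scale. A peptide's score is the composition-weighted sum

    S(P) = sum_i aa_i * APS_i = (1/L) * sum over positions of APS(residue)

where aa_i is the occurrence frequency (count/length) of residue i. A peptide
is called positive when its score strictly exceeds the card's cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequences_io import STANDARD_RESIDUES, Peptide, validate_sequence

RESIDUE_INDEX: dict[str, int] = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (112.5 -> 113)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScoreCard:
    """Per-residue propensity scores, with an optional decision cutoff.

    ``origin`` records how the card was obtained: ``"initial"`` (composition
    ratios), ``"optimized"`` (GA-refined) or ``"literature"`` (externally
    published scores).
    """

    scores: Mapping[str, float]
    cutoff: float | None = None
    origin: str = "literature"

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.scores)
        extra = set(self.scores) - set(STANDARD_RESIDUES)
        if missing or extra:
            raise ValueError(
                f"score card must cover exactly the 20 standard residues "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if self.origin in ("initial", "optimized"):
            vals = list(self.scores.values())
            if min(vals) < 0 or max(vals) > 1000:
                raise ValueError(f"{self.origin} card scores must lie in [0, 1000]")

    def as_vector(self) -> np.ndarray:
        """Scores in canonical residue order (alphabetical one-letter)."""
        return np.array([self.scores[r] for r in STANDARD_RESIDUES], dtype=float)

    def with_cutoff(self, cutoff: float) -> "ScoreCard":
        return ScoreCard(dict(self.scores), cutoff=cutoff, origin=self.origin)

    def __getitem__(self, residue: str) -> float:
        return self.scores[residue]


@dataclass(frozen=True)
class ScoredPeptide:
    """A peptide together with its weighted-sum score and optional call."""

    peptide: Peptide
    raw_score: float
    rounded_score: int
    prediction: int | None = None


def amino_acid_composition(seq: str) -> np.ndarray:
    """20-vector of residue frequencies (counts/length), canonical order.

    Entries sum to 1; residues absent from the sequence map to 0.
    """
    validate_sequence(seq)
    counts = np.zeros(20)
    for ch in seq:
        counts[RESIDUE_INDEX[ch]] += 1
    return counts / len(seq)


def composition_matrix(seqs: Iterable[str]) -> np.ndarray:
    """Stack compositions of many sequences into an (n, 20) matrix."""
    return np.array([amino_acid_composition(s) for s in seqs])


def raw_score(seq: str, card: ScoreCard) -> float:
    """Weighted-sum score: dot product of composition with the card vector."""
    return float(amino_acid_composition(seq) @ card.as_vector())


def score_peptide(peptide: Peptide | str, card: ScoreCard,
                  cutoff: float | None = None) -> ScoredPeptide:
    """Score one peptide; classify it if a cutoff is available.

    The cutoff argument overrides the card's own cutoff. The raw score always
    lies between the smallest and largest card scores (it is a convex
    combination of them).
    """
    if isinstance(peptide, str):
        peptide = Peptide("query", peptide)
    s = raw_score(peptide.seq, card)
    eff_cutoff = cutoff if cutoff is not None else card.cutoff
    pred = classify_score(s, eff_cutoff) if eff_cutoff is not None else None
    return ScoredPeptide(peptide, s, round_half_away(s), pred)


def classify_score(score: float, cutoff: float) -> int:
    """1 iff the raw score strictly exceeds the cutoff, else 0."""
    return 1 if score > cutoff else 0


def classify(scored: ScoredPeptide, cutoff: float) -> int:
    """Binary call for an already-scored peptide under the strict-'>' rule."""
    return classify_score(scored.raw_score, cutoff)


def score_dataset(seqs: Iterable[str], card: ScoreCard) -> np.ndarray:
    """Raw scores for many sequences at once."""
    return composition_matrix(seqs) @ card.as_vector()


# ---------------------------------------------------------------------------
# serialization: 2-column TSV (residue, score), optional "#cutoff=" header

def write_card(card: ScoreCard, path: str | Path | None = None) -> str:
    lines = []
    if card.cutoff is not None:
        lines.append(f"#cutoff={card.cutoff:g}")
    lines += [f"{r}\t{card.scores[r]:g}" for r in STANDARD_RESIDUES]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_card(source: str | Path, origin: str = "literature") -> ScoreCard:
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    cutoff: float | None = None
    scores: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key.strip() == "cutoff":
                cutoff = float(val)
            continue
        residue, _, value = line.partition("\t")
        scores[residue.strip()] = float(value)
    return ScoreCard(scores, cutoff=cutoff, origin=origin)


def write_predictions(scored: Iterable[ScoredPeptide],
                      path: str | Path | None = None) -> str:
    """Predictions TSV: id, sequence, raw_score, rounded_score, prediction."""
    lines = ["id\tsequence\traw_score\trounded_score\tprediction"]
    for sp in scored:
        pred = "" if sp.prediction is None else str(sp.prediction)
        lines.append(f"{sp.peptide.id}\t{sp.peptide.seq}\t{sp.raw_score:.4f}"
                     f"\t{sp.rounded_score}\t{pred}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
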