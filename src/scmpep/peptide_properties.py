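"""Reproducible physicochemical properties of peptides.

Covers molar extinction coefficient at 280 nm (Trp/Tyr/cystine rule with all
cysteines maximally paired), integer net charge at neutral pH counting only
Arg/Lys (+1) and Asp/Glu (-1), and average molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from .scoring_card import ScoreCard, score_peptide
from .sequences_io import Peptide, validate_sequence

# 280 nm molar absorptivities (M^-1 cm^-1): Trp, Tyr and disulfide-bonded
# cysteine pairs (cystine).
EXT_TRP = 5500
EXT_TYR = 1490
EXT_CYSTINE = 125


@dataclass(frozen=True)
class PropertyProfile:
    length: int
    molecular_weight: float
    extinction_coefficient: int
    net_charge: int


def extinction_coefficient(seq: str) -> int:
    """Molar extinction coefficient at 280 nm, M^-1 cm^-1.

    5500 per Trp + 1490 per Tyr + 125 per cystine, assuming every possible
    Cys pair is disulfide-bonded (an odd Cys contributes nothing).
    """
    validate_sequence(seq)
    return (EXT_TRP * seq.count("W")
            + EXT_TYR * seq.count("Y")
            + EXT_CYSTINE * (seq.count("C") // 2))


def net_charge(seq: str) -> int:
    """Integer net charge: +1 per Arg/Lys, -1 per Asp/Glu, His neutral."""
    validate_sequence(seq)
    return (seq.count("R") + seq.count("K")
            - seq.count("D") - seq.count("E"))


def molecular_weight(seq: str) -> float:
    """Average (not monoisotopic) molecular weight in daltons."""
    validate_sequence(seq)
    return float(_bio_mw(seq, seq_type="protein"))


def property_profile(seq: str) -> PropertyProfile:
    return PropertyProfile(
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        extinction_coefficient=extinction_coefficient(seq),
        net_charge=net_charge(seq),
    )


def profile_table(peptides: Iterable[Peptide | str],
                  card: ScoreCard,
                  summary_row: bool = True) -> pd.DataFrame:
    """Per-peptide scores and properties, sorted by descending THP score.

    Mirrors the published benchmark tables: one row per peptide plus, when
    ``summary_row`` is set and the table is non-empty, a trailing "mean" row
    of column means.
    """
    rows = []
    for p in peptides:
        pep = Peptide("query", p) if isinstance(p, str) else p
        sp = score_peptide(pep, card)
        prof = property_profile(pep.seq)
        rows.append({
            "sequence": pep.seq,
            "thp_score": sp.rounded_score,
            "length": prof.length,
            "molecular_weight": round(prof.molecular_weight, 2),
            "extinction_coefficient": prof.extinction_coefficient,
            "net_charge": prof.net_charge,
        })
    df = pd.DataFrame(rows, columns=["sequence", "thp_score", "length",
                                     "molecular_weight", "extinction_coefficient",
                                     "net_charge"])
    if df.empty:
        return df
    df = df.sort_values("thp_score", ascending=False, kind="stable").reset_index(drop=True)
    if summary_row:
        means = df.drop(columns="sequence").mean()
        mean_row = {"sequence": "mean", **{k: round(float(v), 2) for k, v in means.items()}}
        df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return df


def write_profile_table(df: pd.DataFrame, path: str | Path | None = None) -> str:
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text
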