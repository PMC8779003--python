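"""AAIndex1 physicochemical property parsing and correlation screening.

A fitted propensity card can be characterized by correlating its 20 scores
with published per-residue property scales (AAIndex1 records). Properties
whose Pearson correlation with the card exceeds 0.5 are flagged as candidate
properties underlying the modeled bioactivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from .scoring_card import STANDARD_RESIDUES, ScoreCard

# Residue order of the AAIndex1 I-section (row 1 then row 2).
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


class AAIndexParseError(ValueError):
    pass


@dataclass(frozen=True)
class PCPRecord:
    """One AAIndex1 property: accession, description, residue->value map."""

    accession: str
    description: str
    values: dict[str, float]
    has_na: bool = False

    def vector(self) -> np.ndarray:
        """Values in canonical (alphabetical one-letter) residue order."""
        return np.array([self.values[r] for r in STANDARD_RESIDUES], dtype=float)


@dataclass(frozen=True)
class PCPScreenResult:
    accession: str
    description: str
    r: float
    rank: int
    candidate: bool


def parse_aaindex(source: str | Path) -> list[PCPRecord]:
    """Parse AAIndex1 flat-file text into property records.

    The I section lists 20 values in the canonical A R N D C Q E G H I /
    L K M F P S T W Y V two-row order; they are re-keyed by one-letter
    symbol here, so downstream pairing is order-independent. Records with
    any 'NA' value are flagged ``has_na`` and excluded by :func:`screen`.
    """
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)

    records: list[PCPRecord] = []
    accession = ""
    description = ""
    value_tokens: list[str] = []
    in_values = False

    def flush() -> None:
        nonlocal accession, description, value_tokens, in_values
        if not accession:
            return
        if len(value_tokens) != 20:
            raise AAIndexParseError(
                f"record {accession}: I section has {len(value_tokens)} fields, expected 20"
            )
        has_na = False
        values: dict[str, float] = {}
        for residue, tok in zip(AAINDEX_ORDER, value_tokens):
            if tok.upper() == "NA":
                has_na = True
                values[residue] = math.nan
            else:
                try:
                    values[residue] = float(tok)
                except ValueError as exc:
                    raise AAIndexParseError(
                        f"record {accession}: unparseable value {tok!r}") from exc
        records.append(PCPRecord(accession, description.strip(), values, has_na))
        accession, description, value_tokens, in_values = "", "", [], False

    for line in text.splitlines():
        if line.startswith("//"):
            flush()
        elif line.startswith("H "):
            accession = line[2:].strip()
            in_values = False
        elif line.startswith("D "):
            description = line[2:].strip()
            in_values = False
        elif line.startswith("I "):
            in_values = True  # the residue-pair header row; values follow
        elif in_values and line.startswith((" ", "\t")):
            value_tokens.extend(line.split())
        elif line[:2].rstrip() and not line.startswith(" "):
            in_values = False
    flush()

    if not records:
        raise AAIndexParseError("no AAIndex records found in input")
    return records


def pearson_r(card: ScoreCard, pcp: PCPRecord) -> float:
    """Pearson correlation of the card with a property over the 20 residues.

    Pairing is by one-letter symbol. Zero variance on either side yields NaN
    (flagged non-value) rather than an exception.
    """
    if pcp.has_na:
        raise ValueError(f"property {pcp.accession} has NA values")
    x = card.as_vector()
    y = pcp.vector()
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(pearsonr(x, y).statistic)


def screen(card: ScoreCard, pcps: list[PCPRecord],
           min_r: float = 0.5) -> list[PCPScreenResult]:
    """Rank usable properties by descending correlation with the card.

    NA-flagged records are excluded; ``candidate`` is strict (r > min_r).
    Ranking is by signed r, so anti-correlated properties sort last.
    """
    usable = [p for p in pcps if not p.has_na]
    if not usable:
        raise ValueError("no usable (NA-free) property records")
    scored = [(p, pearson_r(card, p)) for p in usable]
    scored.sort(key=lambda t: (-(t[1] if not math.isnan(t[1]) else -math.inf),
                               t[0].accession))
    return [
        PCPScreenResult(p.accession, p.description, r, rank, bool(r > min_r))
        for rank, (p, r) in enumerate(scored, start=1)
    ]


def write_screen(results: list[PCPScreenResult],
                 path: str | Path | None = None) -> str:
    lines = ["accession\tdescription\tr\trank\tcandidate"]
    lines += [f"{s.accession}\t{s.description}\t{s.r:.4f}\t{s.rank}\t{int(s.candidate)}"
              for s in results]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
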