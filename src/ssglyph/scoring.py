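"""Per-column color scores: conservation, B-factors, custom files, Rate4Site, ConSurf.

The default conservation statistic is column-wise: take the consensus (modal)
residue of each column, then score the column as the fraction of its non-gap
residues whose BLOSUM62 substitution score against the consensus is >= 0.
Gaps never enter the normalization, so sparsely populated columns are scored
over the residues actually present.  1.0 means every residue is consensus-
compatible; 0.0 means none is.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from Bio.Align import substitution_matrices

from .registration import GAP, Alignment

__all__ = [
    "ScoreTrack",
    "consensus",
    "conservation_scores",
    "parse_custom_scores",
    "bfactor_scores",
    "normalize_scores",
    "rate4site_scores",
    "consurf_scores",
    "scores_to_columns",
    "blosum62_score",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

RATE4SITE_BINS = 9


@dataclass(frozen=True)
class ScoreTrack:
    """Positional scores in [0, 1]; ``None`` marks missing values."""

    values: tuple[float | None, ...]
    source_tag: str  # conservation | bfactor | custom | rate4site | consurf | solid

    def __post_init__(self):
        for v in self.values:
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"score {v} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 substitution score; any pair involving a nonstandard letter
    (including 'X') is forced negative so such residues dilute conservation."""
    if a not in _STANDARD_AA or b not in _STANDARD_AA:
        return -1.0
    return float(_BLOSUM62[a, b])


def consensus(alignment: Alignment) -> str:
    """Modal residue per column; gaps and nonstandard letters do not vote.
    Ties break alphabetically; a column with no votes yields '-'."""
    out = []
    for col in range(alignment.n_cols):
        counts: dict[str, int] = {}
        for _, seq in alignment.records:
            c = seq[col]
            if c in _STANDARD_AA:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append(GAP)
        else:
            best = max(counts.values())
            out.append(min(c for c, n in counts.items() if n == best))
    return "".join(out)


def conservation_scores(alignment: Alignment) -> ScoreTrack:
    """Fraction of non-gap residues per column with BLOSUM62(residue,
    consensus) >= 0; all-gap columns are missing."""
    cons = consensus(alignment)
    values: list[float | None] = []
    for col in range(alignment.n_cols):
        residues = [seq[col] for _, seq in alignment.records if seq[col] != GAP]
        if not residues:
            values.append(None)
            continue
        if cons[col] == GAP:
            values.append(0.0)  # only nonstandard letters present
            continue
        n_ok = sum(1 for r in residues if blosum62_score(r, cons[col]) >= 0)
        values.append(n_ok / len(residues))
    return ScoreTrack(values=tuple(values), source_tag="conservation")


def parse_custom_scores(path, expected_seq: str) -> list[float]:
    """Two space-delimited columns: one-letter code, score.  Row count and
    letters are verified position-by-position against ``expected_seq``."""
    rows: list[tuple[str, float]] = []
    with open(str(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two space-delimited columns, "
                    f"got {line!r}"
                )
            aa, score_s = parts
            try:
                score = float(score_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {score_s!r}")
            if not math.isfinite(score):
                raise ValueError(f"{path}:{lineno}: non-finite score {score_s!r}")
            rows.append((aa.upper(), score))
    if len(rows) != len(expected_seq):
        raise ValueError(
            f"{path}: {len(rows)} score rows but the sequence has "
            f"{len(expected_seq)} residues"
        )
    for i, ((aa, _), want) in enumerate(zip(rows, expected_seq), start=1):
        if aa != want.upper():
            raise ValueError(
                f"{path}: amino-acid mismatch at row {i}: file has {aa!r}, "
                f"sequence has {want!r}"
            )
    return [s for _, s in rows]


def bfactor_scores(model, mapping: list[int | None]) -> list[float | None]:
    """Raw CA B-factor per reference position; unresolved positions missing.

    The B column is a passthrough carrier, so AlphaFold-style pLDDT values
    arrive unchanged and are only rescaled by :func:`normalize_scores`.
    """
    return [
        model.residues[idx].b_factor if idx is not None else None
        for idx in mapping
    ]


def normalize_scores(raw, source_tag: str = "custom") -> ScoreTrack:
    """Min-max normalize present values to [0, 1]; constant input maps to 0.5."""
    present = [v for v in raw if v is not None]
    if not present:
        raise ValueError("cannot normalize: every score is missing")
    lo, hi = min(present), max(present)
    if hi == lo:
        values = [0.5 if v is not None else None for v in raw]
    else:
        values = [(v - lo) / (hi - lo) if v is not None else None for v in raw]
    return ScoreTrack(values=tuple(values), source_tag=source_tag)


_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def rate4site_scores(path) -> ScoreTrack:
    """Rate4Site output -> nine-bin normalized scores.

    Data lines are ``pos aa score ...``; the third field is the rate.  Rates
    are min-max normalized and quantized into nine equal-width bins with
    representative values 0/8, 1/8, ..., 8/8.
    """
    raw: list[float] = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3 or not _NUM_RE.fullmatch(parts[0]):
                continue
            try:
                raw.append(float(parts[2]))
            except ValueError:
                raise ValueError(f"malformed Rate4Site line: {line!r}")
    if not raw:
        raise ValueError(f"no Rate4Site score lines found in {path}")
    norm = normalize_scores(raw).values
    binned = tuple(
        min(int(v * RATE4SITE_BINS), RATE4SITE_BINS - 1) / (RATE4SITE_BINS - 1)
        for v in norm
    )
    return ScoreTrack(values=binned, source_tag="rate4site")


def consurf_scores(path) -> ScoreTrack:
    """ConSurf grades (integers 1-9) passed through; mapped to [0,1] as
    (grade-1)/8 purely for colormap lookup."""
    grades: list[int] = []
    with open(str(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue
            parts = line.replace("*", "").split()
            if not parts or not _NUM_RE.fullmatch(parts[0]):
                continue
            grade_s = parts[-1]
            try:
                grade = int(float(grade_s))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed ConSurf grade line")
            if not 1 <= grade <= 9:
                raise ValueError(
                    f"{path}:{lineno}: ConSurf grade {grade} outside 1-9"
                )
            grades.append(grade)
    if not grades:
        raise ValueError(f"no ConSurf grade lines found in {path}")
    return ScoreTrack(
        values=tuple((g - 1) / 8 for g in grades), source_tag="consurf"
    )


def scores_to_columns(
    per_ref_pos, alignment: Alignment, ref_id: str
) -> list[float | None]:
    """Spread per-reference-position values onto alignment columns
    (gap columns become missing)."""
    ref_row = alignment[ref_id]
    ref_len = sum(1 for c in ref_row if c != GAP)
    if len(per_ref_pos) != ref_len:
        raise ValueError(
            f"{len(per_ref_pos)} scores for a reference of {ref_len} residues"
        )
    out: list[float | None] = []
    pos = 0
    for c in ref_row:
        if c == GAP:
            out.append(None)
        else:
            out.append(per_ref_pos[pos])
            pos += 1
    return out
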