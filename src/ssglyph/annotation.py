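"""Secondary-structure annotation and reduction to the drawable 3-state form.

Two routes produce an annotation string:

* :func:`annotate_structure` assigns states from backbone geometry using the
  Kabsch–Sander hydrogen-bond energy (the criterion underlying DSSP): an
  N-H···O=C pair is bonded when the electrostatic pair energy

      E = 0.084 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN) * 332  kcal/mol

  falls below -0.5 kcal/mol.  Alpha-helices come from i -> i+4 bonded turns,
  strands/bridges from the ladder patterns of inter-strand bonds.  The amide
  hydrogen is reconstructed from the previous residue's C and O atoms, so
  only N/CA/C(/O) heavy atoms are required; a missing carbonyl O is rebuilt
  from the local sp2 frame.

* :func:`parse_horiz` / :func:`parse_dssp` ingest precomputed annotations,
  which is the only route for CA-only structures.

Reduction to the 3-state alphabet applies run-length thresholds: helices are
kept only for >=4 consecutive H, strands only for >=3 consecutive E/B mixed
in any way; everything else — including sub-threshold runs — becomes loop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnnotationString",
    "SSRun",
    "annotate_structure",
    "parse_horiz",
    "parse_dssp",
    "reduce_to_three_state",
    "kabsch_sander_hbonds",
]

EIGHT_STATE = set("HGIEBTSP ")
THREE_STATE = set("HEL")

HELIX_MIN_RUN = 4  # >=4 consecutive 'H'
STRAND_MIN_RUN = 3  # >=3 consecutive 'E'/'B', combined in any way

# Kabsch-Sander electrostatic model constants
_Q1Q2 = 0.084  # partial charges product, e^2
_F = 332.0  # dimensional factor, kcal*A/(mol*e^2)
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol

_NH_BOND = 1.01  # A, reconstructed amide H
_CO_BOND = 1.231  # A, reconstructed carbonyl O


@dataclass(frozen=True)
class AnnotationString:
    """Per-residue secondary-structure states."""

    states: str
    alphabet_tag: str  # "eight" | "three"

    def __post_init__(self):
        allowed = EIGHT_STATE if self.alphabet_tag == "eight" else THREE_STATE
        bad = set(self.states) - allowed
        if bad:
            raise ValueError(
                f"invalid {self.alphabet_tag}-state characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SSRun:
    """A maximal run of one 3-state label, [start, end) in residue indices."""

    state: str  # 'H' | 'E' | 'L'
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("SSRun requires start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector in backbone geometry")
    return v / n


def _backbone_arrays(model):
    """N/CA/C/O coordinate arrays with O reconstructed where missing."""
    n = len(model.residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, r in enumerate(model.residues):
        bb = r.backbone_xyz
        if "N" in bb:
            N[i] = bb["N"]
        CA[i] = r.ca_xyz
        if "C" in bb:
            C[i] = bb["C"]
        if "O" in bb:
            O[i] = bb["O"]
    # carbonyl O sits in the sp2 plane of CA-C-N(next), opposite their bisector
    for i in range(n):
        if not np.isnan(O[i]).any():
            continue
        if np.isnan(C[i]).any() or np.isnan(CA[i]).any():
            continue
        if i + 1 < n and not np.isnan(N[i + 1]).any():
            d = _unit(_unit(C[i] - CA[i]) + _unit(C[i] - N[i + 1]))
        else:
            d = _unit(C[i] - CA[i])
        O[i] = C[i] + _CO_BOND * d
    return N, CA, C, O


def kabsch_sander_hbonds(model) -> np.ndarray:
    """Boolean matrix ``hb[d, a]``: the NH of residue d donates to the C=O of a.

    Residue 0 and prolines have no amide hydrogen and never donate.  Donation
    to self or to the preceding residue (the shared peptide bond) is excluded.
    """
    n = len(model.residues)
    N, CA, C, O = _backbone_arrays(model)
    hb = np.zeros((n, n), dtype=bool)

    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if (
            np.isnan(N[i]).any()
            or np.isnan(C[i - 1]).any()
            or np.isnan(O[i - 1]).any()
        ):
            continue
        if model.residues[i].aa == "P":
            continue
        H[i] = N[i] + _NH_BOND * _unit(C[i - 1] - O[i - 1])

    for d in range(n):
        if np.isnan(H[d]).any():
            continue
        for a in range(n):
            if a in (d, d - 1) or np.isnan(C[a]).any() or np.isnan(O[a]).any():
                continue
            # 9 A CA-CA screen, as in classic DSSP, purely for speed
            if np.linalg.norm(CA[d] - CA[a]) > 9.0:
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a hydrogen bond
            e = _Q1Q2 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn) * _F
            if e < HBOND_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def annotate_structure(model) -> AnnotationString:
    """Assign 8-state secondary structure (emitting H, E, B and ' ') from geometry."""
    n = len(model.residues)
    if n < 3:
        raise ValueError("at least 3 residues are required for annotation")
    missing = [r for r in model.residues if not r.has_backbone]
    if missing:
        raise ValueError(
            "backbone N/CA/C atoms are required for geometric annotation; "
            "supply a precomputed annotation (.horiz) for CA-only structures"
        )
    hb = kabsch_sander_hbonds(model)

    # Hbond(a, d): C=O of residue a accepts from N-H of residue d
    def bond(acceptor, donor):
        return 0 <= donor < n and 0 <= acceptor < n and hb[donor, acceptor]

    states = [" "] * n

    # 4-turn at i when CO(i) <- NH(i+4); minimal alpha-helix i+1..i+4 needs
    # two consecutive 4-turns (at i-1 and i)
    turn4 = [bond(i, i + 4) for i in range(n)]
    for i in range(1, n):
        if turn4[i] and turn4[i - 1]:
            for k in range(i + 1, min(i + 5, n)):
                states[k] = "H"

    # bridges (Kabsch-Sander parallel/antiparallel patterns), i < j - 2
    bridges: list[tuple[int, int]] = []
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond(i - 1, j) and bond(j, i + 1)) or (
                bond(j - 1, i) and bond(i, j + 1)
            )
            anti = (bond(i, j) and bond(j, i)) or (
                bond(i - 1, j + 1) and bond(j - 1, i + 1)
            )
            if para or anti:
                bridges.append((i, j))

    bridge_set = set(bridges)
    in_ladder = set()
    for (i, j) in bridges:
        for (di, dj) in ((1, 1), (1, -1)):
            nxt = (i + di, j + dj)
            nxt_r = (min(nxt), max(nxt))
            if nxt_r in bridge_set:
                in_ladder.update({i, j, nxt_r[0], nxt_r[1]})
    for (i, j) in bridges:
        for k in (i, j):
            if states[k] != "H":  # helix takes precedence on overlap
                states[k] = "E" if k in in_ladder else "B"

    return AnnotationString(states="".join(states), alphabet_tag="eight")


_HORIZ_CHARS = set("HGIEBTSPC-")
_PRED_RE = re.compile(r"^\s*Pred:\s*(\S*)\s*$")


def parse_horiz(path, expected_length: int | None = None) -> AnnotationString:
    """Read a .horiz-style horizontal annotation file.

    Accepted lines are either ``Pred:`` lines (PSIPRED dialect) or bare lines
    consisting solely of annotation characters; header, sequence, confidence
    and numbering lines are ignored.  'C', '-' and ' ' all denote loop.
    """
    chunks: list[str] = []
    with open(str(path)) as fh:
        for raw in fh:
            m = _PRED_RE.match(raw)
            if m:
                chunks.append(m.group(1))
                continue
            line = raw.strip()
            if not line or line.startswith("#") or ":" in line:
                continue
            if set(line) <= _HORIZ_CHARS and not set(line) <= set("-"):
                chunks.append(line)
    states = "".join(chunks).replace("C", " ").replace("-", " ")
    if not states:
        raise ValueError(f"no annotation lines found in {path}")
    if expected_length is not None and len(states) != expected_length:
        raise ValueError(
            f"annotation length {len(states)} != expected {expected_length}"
        )
    return AnnotationString(states=states, alphabet_tag="eight")


def parse_dssp(path, expected_length: int | None = None) -> AnnotationString:
    """Read the classic per-residue DSSP output table (state = column 17)."""
    states = []
    with open(str(path)) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":  # chain break marker
                continue
            s = line[16]
            states.append(s if s in EIGHT_STATE else " ")
    if not states:
        raise ValueError(f"no DSSP residue table found in {path}")
    out = "".join(states)
    if expected_length is not None and len(out) != expected_length:
        raise ValueError(f"annotation length {len(out)} != expected {expected_length}")
    return AnnotationString(states=out, alphabet_tag="eight")


def _runs_of(labels: str) -> list[tuple[str, int, int]]:
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j
    return runs


def reduce_to_three_state(
    eight: AnnotationString,
) -> tuple[AnnotationString, list[SSRun]]:
    """Apply the run-length thresholds and collapse to {H, E, L}.

    Maximal runs of 'H' shorter than 4 and maximal runs over {E, B} (mixed in
    any way) shorter than 3 demote to loop, as do all remaining states.
    """
    s = eight.states
    # candidate classes: H -> helix, E/B -> strand, all else -> loop
    cand = "".join(
        "H" if c == "H" else ("E" if c in "EB" else "L") for c in s
    )
    out = list(cand)
    for state, i, j in _runs_of(cand):
        if state == "H" and j - i < HELIX_MIN_RUN:
            out[i:j] = "L" * (j - i)
        elif state == "E" and j - i < STRAND_MIN_RUN:
            out[i:j] = "L" * (j - i)
    three = "".join(out)
    runs = [SSRun(state=st, start=i, end=j) for st, i, j in _runs_of(three)]
    return AnnotationString(states=three, alphabet_tag="three"), runs
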