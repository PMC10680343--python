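"""Register a structure's 3-state annotation onto MSA columns.

A structure's resolved sequence rarely equals the reference row of the
alignment: crystallographic structures have unresolved stretches, tags, or
point mismatches.  The structure sequence is therefore matched to the
ungapped reference by global pairwise alignment (end gaps on the structure
side are free, so truncated constructs align cleanly), and the per-residue
annotation is then projected through the reference row's gapping onto
alignment columns.  Unresolved reference positions are treated as disordered
and drawn as loops; alignment gap columns carry no structure at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "Alignment",
    "RegisteredTrack",
    "read_fasta_alignment",
    "match_structure_to_reference",
    "register",
    "window",
    "track_runs",
]

logger = logging.getLogger(__name__)

GAP = "-"
MIN_IDENTITY = 0.30  # below this the reference is probably the wrong record

# Match-favoring scoring for reconciling structure and reference sequences.
# The mismatch penalty must exceed half the per-residue gap-extension cost of
# a long gap, otherwise an unresolved stretch aligns as mismatches instead of
# as a gap; -2 keeps point mismatches cheaper than two gaps while making gaps
# win for unresolved runs.
MATCH_SCORE = 2.0
MISMATCH_SCORE = -2.0
GAP_OPEN = -5.0
GAP_EXTEND = -0.5


@dataclass(frozen=True)
class Alignment:
    """An MSA (or a single sequence) as ordered (id, gapped sequence) rows."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def __getitem__(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)


@dataclass(frozen=True)
class RegisteredTrack:
    """Per-alignment-column 3-state structure, 'H'/'E'/'L' or '-' for gap."""

    states: str
    column_to_residue: tuple[int | None, ...]  # structure residue index or None
    ref_id: str

    def __post_init__(self):
        if len(self.states) != len(self.column_to_residue):
            raise ValueError("states and column_to_residue lengths differ")
        bad = set(self.states) - set("HEL-")
        if bad:
            raise ValueError(f"invalid track states {sorted(bad)!r}")
        present = [r for r in self.column_to_residue if r is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise ValueError("column_to_residue must be strictly increasing")

    @property
    def n_cols(self) -> int:
        return len(self.states)


def read_fasta_alignment(path) -> Alignment:
    """Read a FASTA MSA (or single ungapped sequence).

    Sequences are uppercased, '.' gaps normalized to '-', and one trailing
    '*' terminator per record stripped.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", GAP)
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(records=tuple(records))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps on the structure (query) side: a construct that covers
    # only part of the reference should not pay terminal gap penalties
    try:
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def match_structure_to_reference(
    struct_seq: str, ref_seq_ungapped: str
) -> list[int | None]:
    """Map each reference position to a structure residue index (or None).

    Returns a list of length ``len(ref_seq_ungapped)``; ``None`` marks
    positions with no resolved structure residue.  Structure residues that do
    not match any reference position (cloning tags etc.) are dropped with a
    warning.  Raises ``ValueError`` when identity over matched positions
    falls below 30%.
    """
    if not struct_seq or not ref_seq_ungapped:
        raise ValueError("empty sequence given to structure/reference matching")
    aln = _make_aligner().align(ref_seq_ungapped, struct_seq)[0]
    mapping: list[int | None] = [None] * len(ref_seq_ungapped)
    matched = 0
    identical = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[t0 + k] = int(q0 + k)
            matched += 1
            if ref_seq_ungapped[t0 + k] == struct_seq[q0 + k]:
                identical += 1
    if matched == 0 or identical / matched < MIN_IDENTITY:
        raise ValueError(
            "structure sequence does not match the chosen reference "
            f"(identity {identical}/{matched} over matched positions); "
            "was the right record id selected?"
        )
    mapped = {m for m in mapping if m is not None}
    dropped = sorted(set(range(len(struct_seq))) - mapped)
    if dropped:
        logger.warning(
            "%d structure residue(s) unmatched to the reference were dropped "
            "(indices %s...)",
            len(dropped),
            dropped[:10],
        )
    return mapping


def register(
    annotation,
    mapping: list[int | None],
    alignment: Alignment,
    ref_id: str,
) -> RegisteredTrack:
    """Project a 3-state annotation through the reference row onto columns.

    Gap columns of the reference become '-' (empty space when drawn);
    unresolved reference positions become 'L' (assumed disordered).
    """
    if annotation.alphabet_tag != "three":
        raise ValueError("register() requires a 3-state annotation")
    try:
        ref_row = alignment[ref_id]
    except KeyError:
        raise ValueError(
            f"reference id {ref_id!r} not in alignment (have {alignment.ids})"
        )
    ref_len = sum(1 for c in ref_row if c != GAP)
    if len(mapping) != ref_len:
        raise ValueError(
            f"mapping length {len(mapping)} != ungapped reference length {ref_len}"
        )
    states = []
    col_to_res: list[int | None] = []
    ref_pos = 0
    for c in ref_row:
        if c == GAP:
            states.append(GAP)
            col_to_res.append(None)
            continue
        struct_idx = mapping[ref_pos]
        ref_pos += 1
        if struct_idx is None:
            states.append("L")
            col_to_res.append(None)
        else:
            states.append(annotation.states[struct_idx])
            col_to_res.append(struct_idx)
    return RegisteredTrack(
        states="".join(states),
        column_to_residue=tuple(col_to_res),
        ref_id=ref_id,
    )


def window(track: RegisteredTrack, start_col: int, end_col: int) -> RegisteredTrack:
    """Slice a track to 1-based inclusive alignment columns [start_col, end_col]."""
    if not (1 <= start_col <= end_col <= track.n_cols):
        raise ValueError(
            f"window [{start_col}, {end_col}] out of range for "
            f"{track.n_cols} columns"
        )
    lo, hi = start_col - 1, end_col
    return RegisteredTrack(
        states=track.states[lo:hi],
        column_to_residue=track.column_to_residue[lo:hi],
        ref_id=track.ref_id,
    )


def track_runs(track: RegisteredTrack) -> list[tuple[str, int, int]]:
    """Maximal same-state column runs, split at gaps; gap columns excluded.

    Returns (state, start_col, end_col) with 0-based half-open columns.
    Runs shortened below the drawing thresholds by gaps or windowing are kept:
    the run-length thresholds apply at the annotation stage only.
    """
    runs = []
    s = track.states
    i = 0
    while i < len(s):
        if s[i] == GAP:
            i += 1
            continue
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        runs.append((s[i], i, j))
        i = j
    return runs
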