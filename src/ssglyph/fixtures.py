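"""Synthetic structures, annotations and alignments with known ground truth.

Structures are built from internal coordinates (natural extension reference
frame) with textbook ideal geometry: alpha-helix at (phi, psi) = (-57, -47),
beta-strand at (-139, 135), and an irregular polyproline-II-like coil for
loops.  Paired strand segments are assembled into antiparallel hairpin
geometry by a deterministic least-squares rigid fit of the second strand to
canonical N···O (2.9 A) and H···O (1.9 A) hydrogen-bond distances, so the
Kabsch–Sander energy criterion is satisfied robustly on interior residues.

Segments of a motif plan are placed as rigid bodies 20 A apart along x, so
no spurious inter-segment hydrogen bonds arise; chain continuity between
segments is not enforced (hydrogen-bond based annotation only uses local
backbone frames).  Strand segments pair consecutively (1st with 2nd, 3rd
with 4th, ...); an unpaired trailing strand has no bonding partner and will
annotate as loop.

Everything is reproducible from (spec, seed), and all outputs are plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_alignment",
    "write_pdb_text",
    "write_horiz_text",
    "write_score_file_text",
]

# ideal backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

DIHEDRALS = {"H": (-57.0, -47.0), "E": (-139.0, 135.0)}
_SEGMENT_GAP = 20.0  # A between independently placed segments

_AA_ALPHABET = "ADEFHIKLMNQRSTVWY"  # no P (no amide H), no G/C quirks needed

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure/alignment family."""

    motif_plan: tuple[tuple[str, int], ...] = (("L", 4), ("H", 12), ("L", 4))
    seed: int = 0
    unresolved_ranges: tuple[tuple[int, int], ...] = ()
    n_msa_sequences: int = 5
    mutation_rate: float = 0.1
    gap_rate: float = 0.05

    def __post_init__(self):
        for state, length in self.motif_plan:
            if state not in "HEL":
                raise ValueError(f"unknown motif state {state!r}")
            if length <= 0:
                raise ValueError("motif segment lengths must be positive")
        for rate in (self.mutation_rate, self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _unit(v):
    return v / np.linalg.norm(v)


def _place(a, b, c, bond, angle, torsion):
    """NeRF: position of atom D given A-B-C, |CD|, angle(BCD), dihedral(ABCD)."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang, tor = radians(angle), radians(torsion)
    d = np.array([-bond * cos(ang), bond * sin(ang) * cos(tor), bond * sin(ang) * sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_segment(n: int, state: str, rng) -> list[dict]:
    """Backbone N/CA/C/O coordinates for one segment in its own frame."""
    if state in DIHEDRALS:
        phipsi = [DIHEDRALS[state]] * n
    else:  # irregular extended coil, PPII-ish, no i->i+4 contacts
        phipsi = [
            (-75.0 + rng.uniform(-25, 25), 145.0 + rng.uniform(-25, 25))
            for _ in range(n)
        ]
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    # seed C0 at the ideal N-CA-C angle; the dummy reference atom only fixes
    # the (arbitrary) torsion of the first residue's frame
    C = [
        _place(np.array([0.0, 0.0, 1.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C, 60.0)
    ]
    for i in range(1, n):
        psi_prev = phipsi[i - 1][1]
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev))
        CA.append(_place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phipsi[i][0]))
    O = []
    for i in range(n):
        O.append(_place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, phipsi[i][1] - 180.0))
    return [
        {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]} for i in range(n)
    ]


def _apply(res_list, R=None, t=None):
    out = []
    for r in res_list:
        new = {}
        for k, v in r.items():
            w = v if R is None else R @ v
            new[k] = w if t is None else w + t
        out.append(new)
    return out


def _hairpin_partner(strand_a: list[dict], strand_b: list[dict]) -> list[dict]:
    """Rigidly place strand_b antiparallel to strand_a with canonical H-bonds."""
    nA, nB = len(strand_a), len(strand_b)
    npair = min(nA, nB)
    cb = np.mean([r["CA"] for r in strand_b], axis=0)
    ca = np.mean([r["CA"] for r in strand_a], axis=0)
    # initial guess: flip B end-for-end about z through its centroid, then
    # offset one sheet spacing in y
    R0 = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    base = _apply(strand_b, None, -cb)
    base = _apply(base, R0, ca + np.array([0.0, 4.8, 0.0]))

    def residuals(x, parity):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        t = x[3:]
        b = _apply(_apply(base, None, -ca), R, ca + t)
        res = []
        for k in range(npair):
            m = nB - 1 - k
            a_r, b_r = strand_a[k], b[m]
            res.append((np.linalg.norm(a_r["CA"] - b_r["CA"]) - 4.9) * 0.5)
            if k % 2 == parity:
                res.append(np.linalg.norm(a_r["N"] - b_r["O"]) - 2.9)
                res.append(np.linalg.norm(b_r["N"] - a_r["O"]) - 2.9)
                if k >= 1:
                    h = a_r["N"] + 1.01 * _unit(
                        strand_a[k - 1]["C"] - strand_a[k - 1]["O"]
                    )
                    res.append(np.linalg.norm(h - b_r["O"]) - 1.9)
                if m >= 1:
                    h = b_r["N"] + 1.01 * _unit(b[m - 1]["C"] - b[m - 1]["O"])
                    res.append(np.linalg.norm(h - a_r["O"]) - 1.9)
        return res

    best = None
    for parity in (0, 1):
        sol = least_squares(
            residuals, np.zeros(6), args=(parity,), xtol=1e-12, ftol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return _apply(_apply(base, None, -ca), R, ca + best.x[3:])


def _assemble(plan, rng) -> list[dict]:
    """Build and place all segments; returns one atom-dict per residue."""
    segments = [
        {"state": state, "coords": _build_segment(length, state, rng)}
        for state, length in plan
    ]
    strand_idx = [i for i, s in enumerate(segments) if s["state"] == "E"]
    pairs = {}
    for a, b in zip(strand_idx[0::2], strand_idx[1::2]):
        pairs[b] = a

    cursor = 0.0
    placed: dict[int, list[dict]] = {}
    for i, seg in enumerate(segments):
        if i in pairs:  # second strand of a hairpin: place relative to partner
            placed[i] = _hairpin_partner(placed[pairs[i]], seg["coords"])
            continue
        coords = seg["coords"]
        xs = [r[a][0] for r in coords for a in r]
        placed[i] = _apply(coords, None, np.array([cursor - min(xs), 0.0, 0.0]))
        xs = [r[a][0] for r in placed[i] for a in r]
        cursor = max(xs) + _SEGMENT_GAP
        if seg["state"] == "E" and i in [x for x in pairs.values()]:
            # leave room for the partner strand placed next to this one
            cursor += 10.0
    residues = []
    for i in range(len(segments)):
        residues.extend(placed[i])
    return residues


def make_structure(
    spec: FixtureSpec, b_factors=50.0, chain_id: str = "A"
) -> tuple[str, str]:
    """Generate PDB text plus the ground-truth 3-state annotation string.

    Residues are numbered from 1; ``spec.unresolved_ranges`` (1-based,
    inclusive) are omitted from the ATOM records but retain their numbering,
    emulating missing electron density.
    """
    total = sum(length for _, length in spec.motif_plan)
    if total < 3:
        raise ValueError("motif plan must cover at least 3 residues")
    rng = np.random.default_rng(spec.seed)
    coords = _assemble(spec.motif_plan, rng)
    truth = "".join(state * length for state, length in spec.motif_plan)
    seq = "".join(rng.choice(list(_AA_ALPHABET)) for _ in range(total))
    if np.isscalar(b_factors):
        b_list = [float(b_factors)] * total
    else:
        b_list = [float(b) for b in b_factors]
        if len(b_list) != total:
            raise ValueError("one B-factor per residue required")

    def resolved(res_num):
        return not any(lo <= res_num <= hi for lo, hi in spec.unresolved_ranges)

    records = [
        {
            "res_seq": i + 1,
            "aa": seq[i],
            "atoms": coords[i],
            "b": b_list[i],
        }
        for i in range(total)
        if resolved(i + 1)
    ]
    return write_pdb_text(records, chain_id=chain_id), truth


def write_pdb_text(records, chain_id: str = "A") -> str:
    """Serialize residue records ({res_seq, aa, atoms, b}) as PDB ATOM lines."""
    lines = []
    serial = 1
    for rec in records:
        resname = _THREE.get(rec["aa"].upper(), "UNK")
        for name in ("N", "CA", "C", "O"):
            if name not in rec["atoms"]:
                continue
            x, y, z = rec["atoms"][name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain_id}"
                f"{rec['res_seq']:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{rec['b']:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_alignment(ref_seq: str, spec: FixtureSpec, ref_id: str = "ref") -> str:
    """FASTA MSA: the ungapped reference plus mutated/gapped derived rows."""
    if not ref_seq:
        raise ValueError("empty reference sequence")
    rng = np.random.default_rng(spec.seed + 1)
    rows = [(ref_id, ref_seq)]
    for k in range(1, spec.n_msa_sequences):
        chars = []
        for c in ref_seq:
            if rng.random() < spec.gap_rate:
                chars.append("-")
            elif rng.random() < spec.mutation_rate:
                chars.append(rng.choice([a for a in _AA_ALPHABET if a != c]))
            else:
                chars.append(c)
        rows.append((f"seq{k}", "".join(chars)))
    out = []
    for rid, seq in rows:
        out.append(f">{rid}")
        out.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


def write_horiz_text(states: str, width: int = 60) -> str:
    """Annotation string as .horiz-style lines ('C' for loop)."""
    s = states.replace(" ", "C").replace("L", "C")
    return (
        "\n".join(s[i : i + width] for i in range(0, len(s), width)) + "\n"
    )


def write_score_file_text(seq: str, scores) -> str:
    """Two-column custom score file (one-letter code, score)."""
    if len(seq) != len(scores):
        raise ValueError("sequence and score lengths differ")
    return "".join(f"{aa} {float(s):g}\n" for aa, s in zip(seq, scores))
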