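"""Fixed-column PDB coordinate parsing into a single-chain residue model.

The drawing pipeline needs, per residue: identity, author numbering
(res_seq + insertion code), the CA position and its B-factor, and — when
present — the backbone N/CA/C/O atoms used for hydrogen-bond based
secondary-structure annotation.  PDB is a fixed-width format, so fields are
sliced by column, never tokenized by whitespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended

__all__ = ["Residue", "StructureModel", "parse_pdb", "extract_sequence"]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Solvent residue names excluded even when they sneak into ATOM records.
_WATER = {"HOH", "WAT", "DOD"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue of a parsed chain."""

    chain_id: str
    res_seq: int
    i_code: str  # insertion code, "" when absent
    aa: str  # one-letter code, 'X' for nonstandard
    ca_xyz: np.ndarray  # shape (3,), Angstrom
    backbone_xyz: dict[str, np.ndarray] = field(default_factory=dict)
    b_factor: float = 0.0

    @property
    def has_backbone(self) -> bool:
        """True when N, CA and C are all present (O may be reconstructed)."""
        return all(a in self.backbone_xyz for a in ("N", "CA", "C"))


@dataclass
class StructureModel:
    """Ordered residues of one chain of one model."""

    residues: list[Residue]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id if self.residues else ""


class PDBFormatError(ValueError):
    pass


def _one_letter(resname: str) -> str:
    aa = protein_letters_3to1_extended.get(resname.strip().upper(), "X")
    # BLOSUM62 has no row for U (selenocysteine) or O (pyrrolysine):
    # anything outside the 20 standard letters is normalized to 'X'.
    return aa if aa in _STANDARD_AA else "X"


def _parse_atom_line(line: str) -> dict:
    try:
        return {
            "name": line[12:16].strip(),
            "altloc": line[16],
            "resname": line[17:20].strip(),
            "chain": line[21],
            "res_seq": int(line[22:26]),
            "i_code": line[26].strip(),
            "xyz": np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            ),
            "occ": float(line[54:60]) if line[54:60].strip() else 1.0,
            "b": float(line[60:66]) if line[60:66].strip() else 0.0,
        }
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record: {line.rstrip()!r}") from exc


def _altloc_select(candidates: list[dict]) -> dict:
    """Highest occupancy wins; ties resolve toward altloc ' ' then 'A'."""
    return max(candidates, key=lambda a: (a["occ"], -ord(a["altloc"] or " ")))


def parse_pdb(
    path,
    chain_id: str | None = None,
    model_index: int | None = None,
) -> StructureModel:
    """Parse one chain of one model from a PDB file.

    Parameters
    ----------
    path
        PDB-format coordinate file.
    chain_id
        Chain to keep; default is the first chain encountered in file order.
    model_index
        0-based index among MODEL records; default is the first model (or the
        implicit model when the file has no MODEL records).

    Only ATOM records contribute; HETATM records and waters are excluded.
    Residues without a CA atom are dropped.  For alternate locations the
    highest-occupancy conformer is kept (tie broken toward blank/'A').
    """
    path = str(path)
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except FileNotFoundError:
        raise FileNotFoundError(f"PDB file not found: {path}")

    models_seen = -1  # becomes 0 at the first MODEL record
    in_wanted_model = model_index is None or model_index == 0
    # residue key -> atom name -> list of altloc candidates
    atoms: dict[tuple, dict[str, list[dict]]] = {}
    order: list[tuple] = []

    for line in lines:
        rec = line[0:6]
        if rec == "MODEL ":
            models_seen += 1
            wanted = 0 if model_index is None else model_index
            in_wanted_model = models_seen == wanted
            continue
        if rec == "ENDMDL":
            if in_wanted_model and models_seen >= 0:
                break
            continue
        if rec != "ATOM  " or not in_wanted_model:
            continue
        a = _parse_atom_line(line)
        if a["resname"] in _WATER:
            continue
        key = (a["chain"], a["res_seq"], a["i_code"])
        if key not in atoms:
            atoms[key] = {}
            order.append(key)
        atoms[key].setdefault(a["name"], []).append(a)

    if model_index is not None and model_index > 0 and models_seen < model_index:
        raise PDBFormatError(f"model index {model_index} not present in {path}")

    chains_in_order: list[str] = []
    for ch, _, _ in order:
        if ch not in chains_in_order:
            chains_in_order.append(ch)
    if not chains_in_order:
        raise PDBFormatError(f"no ATOM records found in {path}")
    if chain_id is None:
        chain_id = chains_in_order[0]
    elif chain_id not in chains_in_order:
        raise PDBFormatError(
            f"chain {chain_id!r} not found in {path} (have {chains_in_order})"
        )

    residues: list[Residue] = []
    seen: set[tuple] = set()
    for key in order:
        ch, res_seq, i_code = key
        if ch != chain_id:
            continue
        by_name = atoms[key]
        if "CA" not in by_name:
            continue
        if key in seen:
            raise PDBFormatError(f"duplicate residue {key} in {path}")
        seen.add(key)
        ca = _altloc_select(by_name["CA"])
        backbone = {
            name: _altloc_select(by_name[name])["xyz"]
            for name in BACKBONE_ATOMS
            if name in by_name
        }
        residues.append(
            Residue(
                chain_id=ch,
                res_seq=res_seq,
                i_code=i_code,
                aa=_one_letter(ca["resname"]),
                ca_xyz=ca["xyz"],
                backbone_xyz=backbone,
                b_factor=ca["b"],
            )
        )

    if not residues:
        raise PDBFormatError(f"no CA atoms in chain {chain_id!r} of {path}")
    return StructureModel(residues=residues, source_id=path)


def extract_sequence(model: StructureModel) -> tuple[str, list[tuple[int, str]]]:
    """Return the one-letter sequence and the parallel author numbering."""
    if not model.residues:
        raise ValueError("cannot extract a sequence from an empty model")
    seq = "".join(r.aa for r in model.residues)
    numbering = [(r.res_seq, r.i_code) for r in model.residues]
    return seq, numbering
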