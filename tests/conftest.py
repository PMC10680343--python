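"""Shared fixtures: every test input is generated programmatically."""

from __future__ import annotations

import pytest

from ssglyph.fixtures import FixtureSpec, make_alignment, make_structure
from ssglyph.pdb_io import parse_pdb

HELIX_PLAN = (("L", 3), ("H", 12), ("L", 3))
HAIRPIN_PLAN = (("L", 4), ("E", 5), ("L", 3), ("E", 5), ("L", 4))
MIXED_PLAN = (("L", 3), ("H", 10), ("L", 4), ("E", 6), ("L", 3), ("E", 6), ("L", 3))


@pytest.fixture(scope="session")
def helix_spec():
    return FixtureSpec(motif_plan=HELIX_PLAN, seed=7)


@pytest.fixture(scope="session")
def hairpin_spec():
    return FixtureSpec(motif_plan=HAIRPIN_PLAN, seed=7)


@pytest.fixture(scope="session")
def mixed_spec():
    return FixtureSpec(motif_plan=MIXED_PLAN, seed=7, n_msa_sequences=6)


@pytest.fixture(scope="session")
def helix_structure(helix_spec):
    return make_structure(helix_spec)  # (pdb_text, truth)


@pytest.fixture(scope="session")
def hairpin_structure(hairpin_spec):
    return make_structure(hairpin_spec)


@pytest.fixture(scope="session")
def mixed_structure(mixed_spec):
    return make_structure(mixed_spec)


@pytest.fixture(scope="session")
def mixed_model(tmp_path_factory, mixed_structure):
    pdb_text, _ = mixed_structure
    path = tmp_path_factory.mktemp("pdb") / "mixed.pdb"
    path.write_text(pdb_text)
    return parse_pdb(path)


@pytest.fixture(scope="session")
def mixed_msa_path(tmp_path_factory, mixed_model, mixed_spec):
    from ssglyph.pdb_io import extract_sequence

    seq, _ = extract_sequence(mixed_model)
    path = tmp_path_factory.mktemp("msa") / "mixed.fasta"
    path.write_text(make_alignment(seq, mixed_spec))
    return path
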