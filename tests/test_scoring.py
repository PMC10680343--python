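"""Color scores: conservation vs a brute-force BLOSUM62 oracle, file parsers,
normalization and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssglyph.fixtures import FixtureSpec, make_alignment
from ssglyph.registration import Alignment
from ssglyph.scoring import (
    ScoreTrack,
    bfactor_scores,
    blosum62_score,
    consensus,
    conservation_scores,
    consurf_scores,
    normalize_scores,
    parse_custom_scores,
    rate4site_scores,
    scores_to_columns,
)

_B62 = {  # spot values from the published half-bit matrix
    ("A", "A"): 4, ("D", "A"): -2, ("S", "A"): 1, ("W", "A"): -3,
}


def conservation_oracle(rows):
    """Explicit double loop over columns and rows with BLOSUM62 lookups."""
    n_cols = len(rows[0])
    out = []
    for c in range(n_cols):
        col = [r[c] for r in rows if r[c] != "-"]
        if not col:
            out.append(None)
            continue
        counts = {}
        for ch in col:
            if ch in "ACDEFGHIKLMNPQRSTVWY":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append(0.0)
            continue
        best = max(counts.values())
        cons = sorted(ch for ch, k in counts.items() if k == best)[0]
        n_ok = sum(1 for ch in col if blosum62_score(ch, cons) >= 0)
        out.append(n_ok / len(col))
    return out


def _aln(*rows):
    return Alignment(records=tuple((f"s{i}", r) for i, r in enumerate(rows)))


# --------------------------------------------------------------- consensus


def test_consensus_modal_tie_and_allgap():
    aln = _aln("AAA-", "ASA-", "SSD-")
    # col0: A2 S1 -> A; col1: tie A1 S1... actually A1,S2 -> S; col3 all gaps
    assert consensus(aln) == "ASA-"
    tie = _aln("AS", "SA")
    assert consensus(tie) == "AA"  # alphabetical tie-break


def test_blosum62_spot_values():
    for (a, b), v in _B62.items():
        assert blosum62_score(a, b) == v
    assert blosum62_score("X", "A") < 0
    assert blosum62_score("A", "X") < 0


# ------------------------------------------------------------ conservation


def test_fully_conserved_column_scores_one():
    aln = _aln("A", "A", "A", "A", "A")
    assert conservation_scores(aln).values == (1.0,)


def test_conservation_example_two_thirds():
    # consensus A; BLOSUM62(A,A)=4 >= 0 twice, BLOSUM62(D,A)=-2 < 0
    aln = _aln("A", "A", "D")
    assert conservation_scores(aln).values[0] == pytest.approx(2 / 3)


def test_gaps_excluded_from_normalization():
    aln = _aln("A", "-", "A")
    assert conservation_scores(aln).values == (1.0,)
    allgap = _aln("-", "-", "-")
    assert conservation_scores(allgap).values == (None,)


def test_conservation_matches_oracle_on_random_alignments():
    """>=500 random fixture alignments against the explicit double loop."""
    rng = np.random.default_rng(7)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWYX-"))
    for _ in range(500):
        n_rows = int(rng.integers(2, 7))
        n_cols = int(rng.integers(1, 15))
        rows = ["".join(rng.choice(aas, n_cols)) for _ in range(n_rows)]
        got = conservation_scores(_aln(*rows)).values
        want = conservation_oracle(rows)
        for g, w in zip(got, want):
            assert (g is None and w is None) or g == pytest.approx(w)


def test_conservation_row_permutation_invariant():
    rng = np.random.default_rng(3)
    aas = np.array(list("ACDEFG-"))
    rows = ["".join(rng.choice(aas, 12)) for _ in range(5)]
    base = conservation_scores(_aln(*rows)).values
    perm = conservation_scores(_aln(*[rows[i] for i in (4, 2, 0, 3, 1)])).values
    assert base == perm


def test_duplicating_consensus_row_never_decreases_scores():
    rng = np.random.default_rng(11)
    aas = np.array(list("ACDEFGHIKL"))
    rows = ["".join(rng.choice(aas, 10)) for _ in range(4)]
    aln = _aln(*rows)
    cons = consensus(aln)
    base = conservation_scores(aln).values
    dup = Alignment(records=aln.records + (("dup", rows[0]),))
    new = conservation_scores(dup).values
    for c in range(10):
        if rows[0][c] == cons[c]:
            assert new[c] >= base[c] - 1e-12


def test_generated_alignment_zero_mutation_is_fully_conserved(tmp_path):
    spec = FixtureSpec(seed=5, n_msa_sequences=6, mutation_rate=0.0, gap_rate=0.0)
    text = make_alignment("ACDEFGHIKLMNQRSTVWY", spec)
    p = tmp_path / "a.fasta"
    p.write_text(text)
    from ssglyph.registration import read_fasta_alignment

    aln = read_fasta_alignment(p)
    assert all(v == 1.0 for v in conservation_scores(aln).values)


# ------------------------------------------------------------ score files


def test_parse_custom_scores_ok(tmp_path):
    p = tmp_path / "s.txt"
    p.write_text("A 1.5\nC 0.2\n")
    assert parse_custom_scores(p, "AC") == [1.5, 0.2]


@pytest.mark.parametrize(
    "body,expected_seq,match",
    [
        ("A 1.5\n", "AC", "rows"),
        ("G 1.5\nC 0.2\n", "AC", "row 1"),
        ("A x\nC 0.2\n", "AC", "non-numeric"),
        ("A 1.5 9\nC 0.2\n", "AC", "two space-delimited"),
    ],
)
def test_parse_custom_scores_errors(tmp_path, body, expected_seq, match):
    p = tmp_path / "bad.txt"
    p.write_text(body)
    with pytest.raises(ValueError, match=match):
        parse_custom_scores(p, expected_seq)


def test_bfactor_scores_passthrough(mixed_model):
    n = len(mixed_model)
    mapping = list(range(n))
    raw = bfactor_scores(mixed_model, mapping)
    assert raw == [r.b_factor for r in mixed_model.residues]
    gappy = [0, None, 2]
    assert bfactor_scores(mixed_model, gappy)[1] is None
    assert normalize_scores(raw).values == tuple([0.5] * n)  # uniform B=50


# ----------------------------------------------------------- normalization


@pytest.mark.parametrize(
    "raw,expected",
    [
        ([2, 4, 6], (0.0, 0.5, 1.0)),
        ([7, 7, 7], (0.5, 0.5, 0.5)),
        ([0, 1], (0.0, 1.0)),
        ([1.0, None, 3.0], (0.0, None, 1.0)),
    ],
)
def test_normalize_scores(raw, expected):
    got = normalize_scores(raw).values
    assert all(
        (g is None and e is None) or g == pytest.approx(e)
        for g, e in zip(got, expected)
    )


def test_normalize_all_missing_errors():
    with pytest.raises(ValueError):
        normalize_scores([None, None])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
def test_normalize_bounds_property(raw):
    vals = normalize_scores(raw).values
    assert all(0.0 <= v <= 1.0 for v in vals)
    # order preserved
    for a, b, va, vb in zip(raw, raw[1:], vals, vals[1:]):
        if a < b:
            assert va <= vb


# ------------------------------------------------------- Rate4Site/ConSurf


def test_rate4site_nine_bins(tmp_path):
    p = tmp_path / "r4s.res"
    body = "".join(
        f"{i+1} A {score:.4f} [-1,1] 0.1 30/50\n"
        for i, score in enumerate(np.linspace(-2.0, 2.0, 90))
    )
    p.write_text("# Rate4Site output\n" + body)
    vals = rate4site_scores(p).values
    distinct = sorted(set(vals))
    assert len(distinct) == 9
    assert distinct == [pytest.approx(k / 8) for k in range(9)]


def test_rate4site_constant_and_monotone(tmp_path):
    const = tmp_path / "c.res"
    const.write_text("1 A 0.7\n2 C 0.7\n3 D 0.7\n")
    assert rate4site_scores(const).values == (0.5, 0.5, 0.5)
    mono = tmp_path / "m.res"
    mono.write_text("".join(f"{i+1} A {v}\n" for i, v in enumerate(range(10))))
    vals = rate4site_scores(mono).values
    assert list(vals) == sorted(vals)


def test_consurf_grades(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("# grades\n1 A -0.2 5\n2 C 0.9 1\n3 D -1.5 9*\n")
    assert consurf_scores(p).values == (0.5, 0.0, 1.0)
    bad = tmp_path / "bad.txt"
    bad.write_text("1 A 0.1 0\n")
    with pytest.raises(ValueError, match="1-9"):
        consurf_scores(bad)


# ------------------------------------------------------- column projection


def test_scores_to_columns_respects_gaps():
    aln = _aln("AC--DE")
    cols = scores_to_columns([1, 2, 3, 4], aln, "s0")
    assert cols == [1, 2, None, None, 3, 4]
    with pytest.raises(ValueError):
        scores_to_columns([1, 2, 3], aln, "s0")


def test_score_track_rejects_out_of_range():
    with pytest.raises(ValueError):
        ScoreTrack(values=(1.2,), source_tag="custom")
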