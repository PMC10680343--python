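"""Glyph geometry: the dimensional constants, extensions, layering and the
stackability of rows built from one alignment."""

import json

import numpy as np
import pytest

from ssglyph.annotation import AnnotationString
from ssglyph.geometry import (
    CANVAS_LENGTH_IN,
    COL,
    LOOP_EXTENSION,
    STRAND_CTERM_EXTENSION,
    STRAND_HEAD_LENGTH,
    STRAND_HEAD_WIDTH,
    assemble_scene,
    helix_glyphs,
    loop_glyphs,
    scene_to_json,
    strand_glyphs,
    track_to_glyphs,
)
from ssglyph.registration import Alignment, RegisteredTrack, register


def _track(states: str) -> RegisteredTrack:
    idx = 0
    col_to_res = []
    for c in states:
        if c == "-":
            col_to_res.append(None)
        else:
            col_to_res.append(idx)
            idx += 1
    return RegisteredTrack(
        states=states, column_to_residue=tuple(col_to_res), ref_id="t"
    )


def _width(g):
    return g.x_max - g.x_min


# ------------------------------------------------------------------- loops


def test_isolated_loop_width_is_run_over_six():
    (g,) = loop_glyphs([(0, 6, False, False)])
    assert _width(g) == pytest.approx(1.0)
    assert g.layer == 0 and g.clip_group == "loop"


def test_connecting_loop_extended_both_ends():
    (g,) = loop_glyphs([(4, 10, True, True)])
    assert _width(g) == pytest.approx(6 / 6 + 2 * LOOP_EXTENSION)


def test_terminal_loop_extended_one_end():
    (g,) = loop_glyphs([(0, 6, False, True)])
    assert _width(g) == pytest.approx(6 / 6 + 1 / 6)
    assert g.x_min == pytest.approx(0.0)  # extension is on the abutting end


# ----------------------------------------------------------------- strands


def test_terminal_strand_dimensions():
    (g,) = strand_glyphs([(0, 6, False)])
    assert _width(g) == pytest.approx(1.0)
    xs = sorted({x for x, _ in g.vertices})
    head_base = xs[1]
    assert 1.0 - head_base == pytest.approx(STRAND_HEAD_LENGTH)  # head 2/6
    ys = [y for _, y in g.vertices]
    assert max(ys) - min(ys) == pytest.approx(STRAND_HEAD_WIDTH)  # head width 2
    shaft_ys = sorted({y for x, y in g.vertices if x == 0.0})
    assert shaft_ys[1] - shaft_ys[0] == pytest.approx(1.0)  # shaft width 1


def test_strand_cterm_extension():
    (g,) = strand_glyphs([(0, 3, True)])
    assert _width(g) == pytest.approx(3 / 6 + STRAND_CTERM_EXTENSION)


def test_short_strand_run_rejected():
    with pytest.raises(ValueError, match="demoted"):
        strand_glyphs([(0, 2, False)])
    assert len(strand_glyphs([(0, 2, False)], allow_short=True)) == 1


# ----------------------------------------------------------------- helices


@pytest.mark.parametrize("n", [4, 7, 12])
def test_helix_run_width_and_patch_count(n):
    glyphs = helix_glyphs([(0, n)])
    assert min(g.x_min for g in glyphs) == pytest.approx(0.0)
    assert max(g.x_max for g in glyphs) == pytest.approx(n * COL)
    assert len(glyphs) == (n - 1) + 2  # interior patches + two terminals


def test_helix_right_leaning_layered_above_left():
    glyphs = helix_glyphs([(0, 6)])

    def leaning(g):
        if g.vertices[0][0] == g.vertices[3][0]:  # axis-aligned rectangle
            return "terminal"
        (x0, y0), (x1, y1) = g.vertices[0], g.vertices[2]
        return "right" if (x1 - x0) * (y1 - y0) > 0 else "left"

    layers = {"left": [], "right": []}
    for g in glyphs:
        kind = leaning(g)
        if kind != "terminal":
            layers[kind].append(g.layer)
    assert layers["left"] and layers["right"]
    assert max(layers["left"]) < min(layers["right"])


def test_short_helix_run_rejected():
    with pytest.raises(ValueError, match="demoted"):
        helix_glyphs([(0, 3)])


# ------------------------------------------------------------------ scenes


def test_track_layers_increase_left_to_right():
    track = _track("LLHHHHLLEEELLHHHHHL")
    glyphs = track_to_glyphs(track)
    loops = [g for g in glyphs if g.clip_group == "loop"]
    others = [g for g in glyphs if g.clip_group != "loop"]
    assert all(g.layer == 0 for g in loops)
    assert all(g.layer > 0 for g in others)
    # across runs: every glyph of a run left of another run has smaller layer
    by_run = {}
    for g in others:
        by_run.setdefault(g.column_span, []).append(g.layer)
    spans = sorted(by_run)
    for a, b in zip(spans, spans[1:]):
        assert max(by_run[a]) < min(by_run[b])
    layers = [g.layer for g in glyphs]
    assert len(set(layers)) == len(others) + 1  # loops share 0, rest unique


def test_gap_columns_produce_no_glyph_but_consume_space():
    track = _track("EEE----EEE")
    glyphs = track_to_glyphs(track)
    assert len(glyphs) == 2
    g1, g2 = sorted(glyphs, key=lambda g: g.x_min)
    assert g1.x_max == pytest.approx(3 * COL)
    assert g2.x_min == pytest.approx(7 * COL)  # gaps consumed 4 columns


def test_scene_canvas_and_stackability():
    t1, t2 = _track("LLHHHH--EE"), _track("EEELL--LLL")
    scene = assemble_scene([t1, t2], labels=["a", "b"])
    assert scene.canvas_length_in == CANVAS_LENGTH_IN == 25.0
    assert scene.units_per_column == pytest.approx(1 / 6)
    assert len(scene.rows) == 2
    # identical affine column->x mapping: column k spans [k, k+1]*COL in
    # both rows, so equal column_span implies equal x-extent
    for g in scene.rows[0][1] + scene.rows[1][1]:
        lo, hi = g.column_span
        assert g.x_min >= lo * COL - LOOP_EXTENSION - 1e-9
        assert g.x_max <= hi * COL + LOOP_EXTENSION + STRAND_HEAD_WIDTH / 6 + 1e-9


def test_scene_width_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        assemble_scene([_track("LLLL"), _track("LLLLL")])
    with pytest.raises(ValueError):
        assemble_scene([])


def test_row_width_sum_oracle():
    """Sum of glyph widths = (non-gap columns)/6 + applied extensions, on
    random tracks (construction oracle)."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        eight = "".join(rng.choice(list("HHHHEEEBT S-"), n))
        # build a legal track: reduce first, then sprinkle is already done
        from ssglyph.annotation import reduce_to_three_state

        three, _ = reduce_to_three_state(
            AnnotationString(eight.replace("-", " "), "eight")
        )
        track = _track(three.states)
        glyphs = track_to_glyphs(track)
        from ssglyph.registration import track_runs

        runs = track_runs(track)
        total = 0.0
        for g in glyphs:
            if g.clip_group == "helix":
                continue
            total += _width(g)
        helix_runs = [(s, e) for st, s, e in runs if st == "H"]
        total += sum((e - s) * COL for s, e in helix_runs)
        expected = sum((e - s) * COL for _, s, e in runs)
        # count applied extensions
        ext = 0
        for i, (st, s, e) in enumerate(runs):
            prev_ss = i > 0 and runs[i - 1][2] == s and runs[i - 1][0] in "HE"
            next_ss = i + 1 < len(runs) and runs[i + 1][1] == e and runs[i + 1][0] in "HE"
            if st == "L":
                ext += int(prev_ss) + int(next_ss)
            elif st == "E":
                ext += int(next_ss)
        assert total == pytest.approx(expected + ext * (1 / 6))


def test_geometry_deterministic_and_json_stable():
    track = _track("LLHHHHLLEEEL")
    s1 = assemble_scene([track], labels=["x"])
    s2 = assemble_scene([track], labels=["x"])
    j1, j2 = scene_to_json(s1), scene_to_json(s2)
    assert j1 == j2
    payload = json.loads(j1)
    assert payload["n_cols"] == 12
    kinds = {g["kind"] for g in payload["rows"][0]["glyphs"]}
    assert kinds == {"loop_rect", "strand_arrow", "helix_polygon"}
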