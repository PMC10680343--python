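"""Resolution-independent glyph geometry for linear secondary-structure rows.

Every alignment column occupies 1/6 drawing unit horizontally; a whole row is
scaled at render time to a 25-inch canvas, so shorter alignments draw larger
glyphs.  Dimensional rules:

* loops: thin rectangles, width = run_length/6, extended by 1/6 at each end
  that abuts a helix or strand (so the loop tucks underneath it); z-order 0.
* strands: arrows with shaft width 1.0 and head width 2.0 units, head length
  2/6 carved out of the run (total length run_length/6, +1/6 when regular
  secondary structure follows C-terminally).
* helices: n-1 interior parallelograms advancing 1/6 per half-turn (each
  spanning 2/6 horizontally, short horizontal sides of 1/6) between two short
  terminal patches of width 1/6, total width exactly run_length/6.
  Right-leaning patches layer above left-leaning ones.

Non-loop glyph layers increase strictly left-to-right across a row; every
loop sits below every helix/strand.  Gap columns produce no glyph but still
consume horizontal space, which is what keeps stacked rows registered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "Glyph",
    "Scene",
    "COL",
    "CANVAS_LENGTH_IN",
    "loop_glyphs",
    "strand_glyphs",
    "helix_glyphs",
    "runs_with_context",
    "track_to_glyphs",
    "assemble_scene",
    "scene_to_json",
]

COL = 1.0 / 6.0  # drawing units per alignment column
CANVAS_LENGTH_IN = 25.0  # horizontal figure length, inches

LOOP_HEIGHT = 0.25
LOOP_EXTENSION = 1.0 / 6.0
STRAND_SHAFT_WIDTH = 1.0
STRAND_HEAD_WIDTH = 2.0
STRAND_HEAD_LENGTH = 2.0 / 6.0
STRAND_CTERM_EXTENSION = 1.0 / 6.0
STRAND_LINEWIDTH = 0.5
HELIX_HEIGHT = 2.0
HELIX_TERMINAL_HEIGHT = 1.4
HELIX_TERMINAL_WIDTH = 1.0 / 6.0
HELIX_PATCH_EDGE = 1.0 / 6.0  # short (horizontal) side of interior patches
HELIX_PATCH_SPAN = 2.0 / 6.0  # full horizontal extent of interior patches

_MIN_RUN = {"E": 3, "H": 4}


@dataclass(frozen=True)
class Glyph:
    kind: str  # loop_rect | strand_arrow | helix_polygon
    vertices: tuple[tuple[float, float], ...]
    layer: int
    clip_group: str  # loop | strand | helix
    column_span: tuple[int, int]  # 0-based half-open columns

    @property
    def x_min(self) -> float:
        return min(x for x, _ in self.vertices)

    @property
    def x_max(self) -> float:
        return max(x for x, _ in self.vertices)


@dataclass(frozen=True)
class Scene:
    rows: tuple[tuple[str, tuple[Glyph, ...]], ...]  # (label, glyphs)
    n_cols: int
    canvas_length_in: float = CANVAS_LENGTH_IN
    units_per_column: float = COL
    row_ticks: tuple = field(default=())  # optional ((col, label), ...) per scene

    @property
    def width_units(self) -> float:
        return self.n_cols * COL


def _rect(x0, x1, y0, y1):
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def loop_glyphs(runs, layer: int = 0) -> list[Glyph]:
    """Rectangles for loop runs.

    ``runs`` are (start_col, end_col, abuts_ss_left, abuts_ss_right); the
    1/6-unit extension applies per end that touches a helix or strand.
    """
    glyphs = []
    for start, end, abut_l, abut_r in runs:
        x0 = start * COL - (LOOP_EXTENSION if abut_l else 0.0)
        x1 = end * COL + (LOOP_EXTENSION if abut_r else 0.0)
        glyphs.append(
            Glyph(
                kind="loop_rect",
                vertices=_rect(x0, x1, -LOOP_HEIGHT / 2, LOOP_HEIGHT / 2),
                layer=layer,
                clip_group="loop",
                column_span=(start, end),
            )
        )
    return glyphs


def strand_glyphs(runs, base_layer: int = 1, allow_short: bool = False) -> list[Glyph]:
    """Arrow polygons for strand runs.

    ``runs`` are (start_col, end_col, ss_follows); total length is
    run_length/6 plus 1/6 when regular secondary structure follows
    C-terminally.  The head is carved out of that length, never appended.
    """
    glyphs = []
    layer = base_layer
    for start, end, ss_follows in runs:
        n = end - start
        if n < _MIN_RUN["E"] and not allow_short:
            raise ValueError(
                f"strand run of {n} columns should have been demoted to loop"
            )
        x0 = start * COL
        x1 = end * COL + (STRAND_CTERM_EXTENSION if ss_follows else 0.0)
        xh = max(x0, x1 - STRAND_HEAD_LENGTH)  # head base
        hs = STRAND_SHAFT_WIDTH / 2
        hh = STRAND_HEAD_WIDTH / 2
        glyphs.append(
            Glyph(
                kind="strand_arrow",
                vertices=(
                    (x0, -hs),
                    (xh, -hs),
                    (xh, -hh),
                    (x1, 0.0),
                    (xh, hh),
                    (xh, hs),
                    (x0, hs),
                ),
                layer=layer,
                clip_group="strand",
                column_span=(start, end),
            )
        )
        layer += 1
    return glyphs


def _helix_run_glyphs(start: int, end: int, base_layer: int) -> list[Glyph]:
    n = end - start
    x0 = start * COL
    hh = HELIX_HEIGHT / 2
    th = HELIX_TERMINAL_HEIGHT / 2
    e = HELIX_PATCH_EDGE
    span = HELIX_PATCH_SPAN

    left_lean, right_lean = [], []
    for k in range(n - 1):
        xk = x0 + k * COL
        if k % 2 == 0:
            # right-leaning: rises left -> right, drawn on top
            verts = ((xk, -hh), (xk + e, -hh), (xk + span, hh), (xk + span - e, hh))
            right_lean.append((xk, verts))
        else:
            verts = ((xk, hh), (xk + e, hh), (xk + span, -hh), (xk + span - e, -hh))
            left_lean.append((xk, verts))

    glyphs = []
    layer = base_layer
    terminals = (
        _rect(x0, x0 + HELIX_TERMINAL_WIDTH, -th, th),
        _rect(x0 + (n - 1) * COL, x0 + n * COL, -th, th),
    )
    ordered = [("terminal", v) for v in terminals]
    ordered += [("left", v) for _, v in left_lean]
    ordered += [("right", v) for _, v in right_lean]
    for _, verts in ordered:
        glyphs.append(
            Glyph(
                kind="helix_polygon",
                vertices=verts,
                layer=layer,
                clip_group="helix",
                column_span=(start, end),
            )
        )
        layer += 1
    return glyphs


def helix_glyphs(runs, base_layer: int = 1, allow_short: bool = False) -> list[Glyph]:
    """Stacked-parallelogram patches for helix runs ((start_col, end_col))."""
    glyphs = []
    layer = base_layer
    for start, end in runs:
        if end - start < _MIN_RUN["H"] and not allow_short:
            raise ValueError(
                f"helix run of {end - start} columns should have been "
                "demoted to loop"
            )
        run = _helix_run_glyphs(start, end, layer)
        glyphs.extend(run)
        layer += len(run)
    return glyphs


def runs_with_context(track) -> list[tuple[str, int, int, dict]]:
    """Track runs plus adjacency flags needed by the glyph builders."""
    from .registration import track_runs

    runs = track_runs(track)
    out = []
    for idx, (state, start, end) in enumerate(runs):
        prev_ss = (
            idx > 0 and runs[idx - 1][2] == start and runs[idx - 1][0] in "HE"
        )
        next_ss = (
            idx + 1 < len(runs)
            and runs[idx + 1][1] == end
            and runs[idx + 1][0] in "HE"
        )
        out.append((state, start, end, {"prev_ss": prev_ss, "next_ss": next_ss}))
    return out


def track_to_glyphs(track) -> list[Glyph]:
    """All glyphs for one registered track, with row-wide layer assignment.

    Loops are built first at layer 0; helix/strand runs then receive strictly
    increasing positive layers left to right.  Sub-threshold helix/strand
    fragments created by alignment gaps or windowing are drawn as-is (the
    run-length thresholds belong to the annotation stage).
    """
    runs = runs_with_context(track)
    glyphs = loop_glyphs(
        [
            (start, end, ctx["prev_ss"], ctx["next_ss"])
            for state, start, end, ctx in runs
            if state == "L"
        ]
    )
    layer = 1
    for state, start, end, ctx in runs:
        if state == "E":
            new = strand_glyphs(
                [(start, end, ctx["next_ss"])], base_layer=layer, allow_short=True
            )
        elif state == "H":
            new = helix_glyphs([(start, end)], base_layer=layer, allow_short=True)
        else:
            continue
        glyphs.extend(new)
        layer += len(new)
    return glyphs


def assemble_scene(tracks, labels=None, ticks=()) -> Scene:
    """Stack registered tracks (which must share n_cols) into one Scene."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to assemble")
    n_cols = tracks[0].n_cols
    for t in tracks[1:]:
        if t.n_cols != n_cols:
            raise ValueError(
                f"tracks have mismatched widths ({t.n_cols} vs {n_cols}); "
                "structures must be registered to the same alignment to stack"
            )
    if labels is None:
        labels = [t.ref_id for t in tracks]
    if len(labels) != len(tracks):
        raise ValueError("one label per track required")
    rows = tuple(
        (label, tuple(track_to_glyphs(track)))
        for label, track in zip(labels, tracks)
    )
    return Scene(rows=rows, n_cols=n_cols, row_ticks=tuple(ticks))


def scene_to_json(scene: Scene) -> str:
    """Stable JSON form of a Scene for golden-file regression tests."""
    payload = {
        "n_cols": scene.n_cols,
        "canvas_length_in": scene.canvas_length_in,
        "units_per_column": scene.units_per_column,
        "rows": [
            {
                "label": label,
                "glyphs": [
                    {
                        "kind": g.kind,
                        "vertices": [[round(x, 9), round(y, 9)] for x, y in g.vertices],
                        "layer": g.layer,
                        "clip_group": g.clip_group,
                        "column_span": list(g.column_span),
                    }
                    for g in glyphs
                ],
            }
            for label, glyphs in scene.rows
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)
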