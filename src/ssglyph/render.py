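"""Rasterize/vectorize a Scene with clip-group coloring.

Glyphs are stroked with black edges; their interiors are filled by clipping
a row-spanning horizontal color gradient against the compound path of each
clip group.  Exactly three gradient images are built per row — one each for
loops, strands and helices — never one per glyph, which is what keeps
rendering fast for helix-rich rows.  The gradient samples one color per
alignment column from the ScoreTrack and interpolates linearly in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, to_rgba
from matplotlib.patches import PathPatch, Polygon
from matplotlib.path import Path as MplPath

from .geometry import COL, STRAND_LINEWIDTH, Scene

__all__ = [
    "ColorSpec",
    "RenderOptions",
    "column_colors",
    "render_scene",
    "stack_and_render",
    "gradient_constructions",
    "reset_gradient_counter",
]

FORMATS = ("png", "eps", "svg", "ps", "tiff")
DEFAULT_DPI = 600
CLIP_GROUPS = ("loop", "strand", "helix")
_FILL_Z = {"loop": 0.2, "strand": 0.5, "helix": 0.6}
_ROW_HEIGHT_IN = 2.0
_YLIM = (-1.45, 1.45)

# instrumentation: incremented every time a gradient image is constructed
_GRADIENT_CONSTRUCTIONS = 0


def gradient_constructions() -> int:
    return _GRADIENT_CONSTRUCTIONS


def reset_gradient_counter() -> None:
    global _GRADIENT_CONSTRUCTIONS
    _GRADIENT_CONSTRUCTIONS = 0


@dataclass(frozen=True)
class ColorSpec:
    """How scores map to colors."""

    mode: str = "named_colormap"  # named_colormap | solid | custom_list
    name_or_colors: object = "viridis"
    missing_color: str = "#d3d3d3"

    def colormap(self):
        if self.mode == "named_colormap":
            return matplotlib.colormaps[self.name_or_colors]
        if self.mode == "custom_list":
            colors = list(self.name_or_colors)
            if not colors:
                raise ValueError("custom color list is empty")
            if len(colors) == 1:
                colors = colors * 2
            return LinearSegmentedColormap.from_list("custom", colors)
        raise ValueError(f"no colormap for mode {self.mode!r}")


@dataclass(frozen=True)
class RenderOptions:
    format: str = "png"
    dpi: int = DEFAULT_DPI
    ticks_every: int | None = None
    output_path: str = "diagram.png"
    row_height_in: float = _ROW_HEIGHT_IN

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ValueError(f"format {self.format!r} not in {FORMATS}")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


def column_colors(scores, spec: ColorSpec, n_cols: int | None = None) -> np.ndarray:
    """Per-column RGBA array from a ScoreTrack (or list of scores).

    Scores in [0, 1] index the colormap at that fraction; missing scores take
    ``missing_color``; solid mode ignores scores entirely.
    """
    values = list(getattr(scores, "values", scores if scores is not None else []))
    if n_cols is None:
        n_cols = len(values)
    if spec.mode == "solid":
        return np.tile(to_rgba(spec.name_or_colors), (n_cols, 1))
    if len(values) != n_cols:
        raise ValueError(f"{len(values)} scores for {n_cols} columns")
    cmap = spec.colormap()
    missing = to_rgba(spec.missing_color)
    out = np.empty((n_cols, 4))
    for i, v in enumerate(values):
        out[i] = missing if v is None else cmap(float(v))
    return out


def _build_gradient(colors: np.ndarray) -> np.ndarray:
    """One-row RGBA image, one sample per alignment column (counted)."""
    global _GRADIENT_CONSTRUCTIONS
    _GRADIENT_CONSTRUCTIONS += 1
    return colors[np.newaxis, :, :]


def _draw_row(ax, glyphs, colors: np.ndarray, n_cols: int) -> None:
    by_group: dict[str, list] = {g: [] for g in CLIP_GROUPS}
    max_layer = 0
    for g in glyphs:
        by_group[g.clip_group].append(g)
        max_layer = max(max_layer, g.layer)

    # one gradient per clip group — three per row, regardless of glyph count
    for group in CLIP_GROUPS:
        img = _build_gradient(colors)
        members = by_group[group]
        if not members:
            continue
        verts, codes = [], []
        for g in members:
            verts.extend(list(g.vertices) + [g.vertices[0]])
            codes.extend(
                [MplPath.MOVETO]
                + [MplPath.LINETO] * (len(g.vertices) - 1)
                + [MplPath.CLOSEPOLY]
            )
        clip = PathPatch(
            MplPath(verts, codes), transform=ax.transData, visible=False
        )
        ax.add_patch(clip)
        im = ax.imshow(
            img,
            extent=(0.0, n_cols * COL, _YLIM[0], _YLIM[1]),
            aspect="auto",
            interpolation="bilinear",
            zorder=_FILL_Z[group],
            origin="lower",
        )
        im.set_clip_path(clip)

    for g in glyphs:
        ax.add_patch(
            Polygon(
                np.asarray(g.vertices),
                closed=True,
                fill=False,
                edgecolor="black",
                linewidth=STRAND_LINEWIDTH,
                zorder=g.layer + 1.0,
            )
        )


def render_scene(scene: Scene, colors, options: RenderOptions) -> str:
    """Draw every row of a Scene and write the image file.

    ``colors`` is one per-column RGBA array (or ScoreTrack-compatible object
    already converted via :func:`column_colors`) per row, or a single array
    shared by all rows.
    """
    n_rows = len(scene.rows)
    if n_rows == 0:
        raise ValueError("scene has no rows")
    if isinstance(colors, np.ndarray):
        row_colors = [colors] * n_rows
    else:
        row_colors = list(colors)
        if len(row_colors) == 1 and n_rows > 1:
            row_colors = row_colors * n_rows
    if len(row_colors) != n_rows:
        raise ValueError(f"{len(row_colors)} color rows for {n_rows} scene rows")

    with plt.rc_context({"svg.hashsalt": "ssglyph"}):
        fig, axes = plt.subplots(
            n_rows,
            1,
            figsize=(scene.canvas_length_in, options.row_height_in * n_rows),
            squeeze=False,
            sharex=True,
        )
        fig.subplots_adjust(left=0.04, right=0.995, top=0.98, bottom=0.12)
        for (label, glyphs), ax, colr in zip(scene.rows, axes[:, 0], row_colors):
            _draw_row(ax, glyphs, np.asarray(colr), scene.n_cols)
            ax.set_xlim(-0.02, scene.n_cols * COL + 0.02)
            ax.set_ylim(*_YLIM)
            for spine in ax.spines.values():
                spine.set_visible(False)
            ax.set_yticks([])
            ax.set_xticks([])
            if label:
                ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=14)
        if scene.row_ticks:
            bottom = axes[-1, 0]
            cols = [c for c, _ in scene.row_ticks]
            labels = [str(t) for _, t in scene.row_ticks]
            bottom.set_xticks([(c + 0.5) * COL for c in cols], labels)
            bottom.tick_params(axis="x", length=3)

        out = FsPath(options.output_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        save_kwargs: dict = {"dpi": options.dpi, "format": options.format}
        if options.format == "svg":
            save_kwargs["metadata"] = {"Date": None}
        elif options.format in ("eps", "ps"):
            save_kwargs["metadata"] = {"CreationDate": None}
        elif options.format == "tiff":
            save_kwargs["pil_kwargs"] = {"compression": None}
        fig.savefig(out, **save_kwargs)
        plt.close(fig)
    return str(out)


def stack_and_render(scenes, colors, options: RenderOptions) -> str:
    """Render one or more Scenes (sharing n_cols) stacked top to bottom."""
    scenes = list(scenes)
    if not scenes:
        raise ValueError("no scenes to stack")
    n_cols = scenes[0].n_cols
    rows = []
    ticks = ()
    for s in scenes:
        if s.n_cols != n_cols:
            raise ValueError("scenes have mismatched widths; cannot stack")
        rows.extend(s.rows)
        if s.row_ticks:
            ticks = s.row_ticks
    merged = Scene(rows=tuple(rows), n_cols=n_cols, row_ticks=ticks)
    return render_scene(merged, colors, options)
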