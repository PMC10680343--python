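"""End-to-end orchestration: parse -> annotate -> reduce -> register -> score
-> geometry -> render, with per-stage error reporting.

One run draws one figure: a single row for one structure, or several stacked
rows when multiple structures are registered to the same MSA.  Conservation
is always computed over the full alignment, so a windowed diagram agrees
with the full diagram on shared columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import annotation as ann
from . import geometry, registration, render, scoring
from .pdb_io import extract_sequence, parse_pdb

__all__ = ["RunConfig", "PipelineError", "run"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error in a named pipeline stage, with a readable message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class RunConfig:
    pdb_paths: list[str] = field(default_factory=list)
    fasta_path: str = ""
    ref_ids: list[str] = field(default_factory=list)
    chain_ids: list[str | None] | None = None
    annotation_paths: list[str | None] | None = None  # .horiz per structure
    scoring: str = "conservation"  # conservation | bfactor | custom | rate4site
    #                                | consurf | solid
    score_file: str | None = None
    colorspec: render.ColorSpec = field(default_factory=render.ColorSpec)
    window: tuple[int, int] | None = None  # 1-based inclusive alignment columns
    options: render.RenderOptions = field(default_factory=render.RenderOptions)

    def __post_init__(self):
        if self.ref_ids and len(self.ref_ids) != len(self.pdb_paths):
            raise ValueError("one reference id per PDB file is required")


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def _track_for_structure(cfg, idx, alignment):
    pdb_path = cfg.pdb_paths[idx]
    chain = cfg.chain_ids[idx] if cfg.chain_ids else None
    model = _stage("parse", parse_pdb, pdb_path, chain_id=chain)
    struct_seq, _ = extract_sequence(model)
    logger.info("parsed %s: %d residues", pdb_path, len(model))

    horiz = cfg.annotation_paths[idx] if cfg.annotation_paths else None
    if horiz:
        eight = _stage("annotate", ann.parse_horiz, horiz, len(model))
    else:
        eight = _stage("annotate", ann.annotate_structure, model)
    three, runs = _stage("reduce", ann.reduce_to_three_state, eight)
    logger.info(
        "annotated %s: %d helix/strand runs", pdb_path,
        sum(1 for r in runs if r.state != "L"),
    )

    ref_id = cfg.ref_ids[idx] if cfg.ref_ids else alignment.ids[0]
    ref_row = _stage("register", alignment.__getitem__, ref_id)
    mapping = _stage(
        "register",
        registration.match_structure_to_reference,
        struct_seq,
        ref_row.replace("-", ""),
    )
    track = _stage("register", registration.register, three, mapping, alignment, ref_id)
    return model, mapping, track, ref_id


def _column_scores(cfg, alignment, model, mapping, track, ref_id):
    tag = cfg.scoring
    if tag == "solid":
        return None
    if tag == "conservation":
        return _stage("score", scoring.conservation_scores, alignment)
    if tag == "bfactor":
        raw = scoring.bfactor_scores(model, mapping)
    elif tag == "custom":
        struct_seq, _ = extract_sequence(model)
        per_res = _stage(
            "score", scoring.parse_custom_scores, cfg.score_file, struct_seq
        )
        # structure residue scores -> reference positions through the mapping
        raw = [per_res[m] if m is not None else None for m in mapping]
    elif tag == "rate4site":
        st = _stage("score", scoring.rate4site_scores, cfg.score_file)
        raw = list(st.values)
    elif tag == "consurf":
        st = _stage("score", scoring.consurf_scores, cfg.score_file)
        raw = list(st.values)
    else:
        raise PipelineError("score", f"unknown scoring mode {tag!r}")
    cols = _stage("score", scoring.scores_to_columns, raw, alignment, ref_id)
    if tag in ("rate4site", "consurf"):
        return scoring.ScoreTrack(values=tuple(cols), source_tag=tag)
    return _stage("score", scoring.normalize_scores, cols, tag)


def _tick_marks(track, model, every: int):
    ticks = []
    for col, idx in enumerate(track.column_to_residue):
        if idx is None:
            continue
        res = model.residues[idx]
        if res.res_seq % every == 0 and not res.i_code:
            ticks.append((col, res.res_seq))
    return ticks


def run(config: RunConfig) -> str:
    """Execute the full pipeline; returns the written output path."""
    if not config.pdb_paths:
        raise PipelineError("config", "no PDB files given")
    alignment = _stage(
        "alignment", registration.read_fasta_alignment, config.fasta_path
    )
    logger.info(
        "alignment %s: %d records x %d columns",
        config.fasta_path, len(alignment.records), alignment.n_cols,
    )

    tracks, labels, colors = [], [], []
    ticks = ()
    for idx in range(len(config.pdb_paths)):
        model, mapping, track, ref_id = _track_for_structure(config, idx, alignment)
        score_track = _column_scores(
            config, alignment, model, mapping, track, ref_id
        )
        if config.window:
            lo, hi = config.window
            track = _stage("window", registration.window, track, lo, hi)
            if score_track is not None:
                score_track = scoring.ScoreTrack(
                    values=score_track.values[lo - 1 : hi],
                    source_tag=score_track.source_tag,
                )
        spec = config.colorspec
        if config.scoring == "solid" and spec.mode != "solid":
            spec = render.ColorSpec(mode="solid", name_or_colors="white")
        colors.append(
            _stage("color", render.column_colors, score_track, spec, track.n_cols)
        )
        if idx == 0 and config.options.ticks_every:
            ticks = tuple(_tick_marks(track, model, config.options.ticks_every))
        tracks.append(track)
        labels.append(ref_id)

    scene = _stage("geometry", geometry.assemble_scene, tracks, labels, ticks)
    out = _stage("render", render.render_scene, scene, colors, config.options)
    logger.info("wrote %s", out)
    return out
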