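# ssglyph

Linear, stackable protein secondary-structure diagrams from 3-D structures,
registered to a multiple sequence alignment and colored by conservation,
B-factor, or custom per-residue scores.

Structural biologists comparing homologs — especially fold-switching and
metamorphic proteins, where near-identical sequences adopt different folds —
need diagrams in which position X of protein A sits directly above position X
of protein B. `ssglyph` produces exactly that: each structure's per-residue
secondary structure is projected onto the columns of a shared MSA, so stacked
rows share one column-to-x mapping and structural divergence lines up
vertically.

## What it computes

**Annotation.** Secondary structure is assigned from backbone geometry with
the Kabsch–Sander hydrogen-bond criterion: an N–H···O=C pair is bonded when

```
E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol  <  −0.5
```

(amide H rebuilt from the preceding residue's C/O; missing carbonyl O rebuilt
from the local sp2 frame). i→i+4 bonded turns give helices (H), bridge/ladder
patterns give strands (E/B). Precomputed annotations (`.horiz`, DSSP tables)
can be supplied instead — the only route for CA-only structures.

**Reduction.** Helices are drawn only for ≥4 consecutive H; strands only for
≥3 consecutive E/B, mixed in any way; everything else — including
sub-threshold runs — is drawn as loop.

**Registration.** The structure's resolved sequence is matched to the chosen
reference record by global pairwise alignment (free end gaps on the structure
side); unresolved residues become loops (assumed disordered), and alignment
gap columns become empty space.

**Conservation.** Per column: the fraction of non-gap residues whose BLOSUM62
score against the column consensus is ≥ 0 (1.0 = fully conserved; gaps are
excluded from the normalization). Rate4Site rates are min-max normalized and
quantized to nine bins; ConSurf grades 1–9 pass through unchanged.

**Geometry.** Each alignment column spans 1/6 drawing unit on a 25-inch
canvas. Loops are thin rectangles (run/6, +1/6 per end that tucks under a
neighboring element, z-order 0); strands are arrows (shaft width 1.0, head
width 2.0, head length 2/6 carved from the run, +1/6 extension when regular
structure follows); helices are alternating slanted parallelograms with
right-leaning patches layered on top. Glyph interiors are filled by clipping
a per-column color gradient against the compound path of each glyph class —
three gradient constructions per row, never one per glyph.

## Worked example

`examples/single_diagram.py` builds a synthetic helix + hairpin structure,
annotates and draws it:

```
residues:        35
annotation:      LLLLLHHHHHHHHLLLLLEEEELLLLLEEEELLLL
drawn elements:  3 (helix/strand runs surviving the >=4 H / >=3 E,B thresholds)
wrote example_out/single.png  (one row, white fill, 25-inch canvas scaled to the 35 alignment columns)
```

The annotation string is the reduced 3-state track: one 8-residue helix and
two 4-residue strands survive the run-length thresholds; everything else is
loop. `examples/stacked_homologs.py` stacks two registered rows colored by
conservation (it prints the column conservation range, e.g. min 0.429 / max
1.000 — the fraction of residues per column compatible with the consensus),
and `examples/custom_scores.py` colors by pLDDT-style B-factors and shows the
nine-bin Rate4Site quantization.

The same pipeline is available from the shell:

```
ssglyph --pdb a.pdb --pdb b.pdb --fasta family.fasta --name A --name B \
        --score conservation --colormap viridis --output stacked.png
```

Output formats: png (600 ppi default), eps, svg, ps, tiff. `--start/--end`
window the alignment columns; `--ticks N` adds residue-number ticks.

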