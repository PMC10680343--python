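# Methods

## Secondary-structure assignment

The built-in annotator implements the Kabsch–Sander electrostatic
hydrogen-bond model on backbone heavy atoms. For donor residue *d* and
acceptor residue *a*,

E = q₁q₂ · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · f,  q₁q₂ = 0.084 e²,
f = 332 kcal·Å/(mol·e²),

and a bond is recorded when E < −0.5 kcal/mol. The amide hydrogen is placed
1.01 Å from N along the unit vector C(prev)→O(prev) reversed (H = N +
1.01·(C_prev − O_prev)/|·|); residue 0 and prolines never donate, and
donation to self or to the preceding residue is excluded. A 9 Å CA–CA screen
is applied purely for speed. When a carbonyl O is absent it is rebuilt
1.231 Å from C along the bisector of (C−CA) and (C−N_next) — this is also
what makes N/CA/C-only files annotatable. CA-only structures cannot be
annotated geometrically and require a precomputed annotation (`.horiz` or a
DSSP table); this is a deliberate scope boundary, since hydrogen-bond
assignment is not defined on CA traces.

States: a 4-turn at *i* exists when CO(i) accepts from NH(i+4); residues
i+1..i+4 are helix (H) when 4-turns exist at i−1 and i (the minimal-helix
rule). Parallel/antiparallel bridges follow the standard patterns; bridges
extended by a consecutive bridge become ladder strands (E), isolated bridges
stay B. Helix wins on overlap. The remaining DSSP states (G, I, T, S, P) are
not assigned and fall into loop, since they are not drawn anyway.

## Run-length reduction

Maximal runs of H shorter than 4 and maximal runs over {E, B} (mixed in any
way) shorter than 3 demote to loop; all other states are loop. Reduction is
length-preserving and idempotent. These thresholds apply **once**, at the
annotation stage: runs later fragmented by alignment gaps or by windowing
are drawn as-is, because re-thresholding after slicing would hide real
structure at window edges. Consequently the glyph builders accept
sub-threshold runs when called from scene assembly (`allow_short=True`) but
reject them when called directly, which is the contract violation signal.

## Registration

The structure's resolved sequence is matched to the ungapped reference row
by global pairwise alignment: match +2, mismatch −2, gap open −5, gap extend
−0.5, with free end gaps on the structure side. The mismatch penalty is −2
rather than something milder because an unresolved interior stretch must
place as a gap, not as a run of mismatches: with mismatch −1, two mismatches
(−2 against +4 of lost matches) outscore an internal 4-gap (−6.5), which
silently mis-registers unresolved regions. −2 keeps a point substitution
cheaper than two gaps while making gaps win for unresolved runs. Identity
below 30% over matched positions is a hard error (the likely cause is a
wrong reference id). Structure residues unmatched to the reference (cloning
tags, expression artifacts) are dropped with a warning.

Unresolved reference positions are drawn as loops (assumed disordered).
Alignment gap columns are empty space but still consume horizontal room —
that is the registration property that makes stacked rows comparable.

## Conservation and other scores

Consensus = modal standard residue per column (gaps and X do not vote; ties
break alphabetically for determinism). Score = |{residues r in column:
BLOSUM62(r, consensus) ≥ 0}| / |non-gap residues|; all-gap columns are
missing. Pairs involving nonstandard letters are forced to −1 so X dilutes
conservation but still counts in the denominator. Conservation is computed
over the full alignment even when a window is rendered, so windowed and full
diagrams agree on shared columns.

B-factor and custom-file scores are raw per-residue values, min-max
normalized to [0,1] (a constant vector maps to 0.5 everywhere; missing stays
missing). Rate4Site rates are min-max normalized, then quantized to nine
equal-width bins with representatives k/8, k = 0..8; the bin count follows
the ConSurf grade convention, and the representative values are this
package's documented choice since no canonical set exists. ConSurf grades
1–9 pass through unchanged and are mapped affinely to (g−1)/8 only for
colormap lookup.

## Glyph geometry

Units: one alignment column = 1/6 drawing unit; the canvas is always 25
inches long, so per-column size scales inversely with alignment length.
Vertical sizes (drawing units, shared midline): loop rectangles 0.25, strand
shaft 1.0, strand head 2.0, helix envelope 2.0, helix terminal patches 1.4.
The horizontal rules are exact: loop width = run/6 with a 1/6
extension per end abutting a helix/strand; strand length = run/6 (+1/6 when
regular structure follows C-terminally) with the 2/6 head carved out of, not
appended to, that length; helix width = exactly run/6.

Helix tiling convention (the slant is otherwise underdetermined): a run of
*n* columns gets two terminal rectangles of width 1/6 plus *n*−1 interior
parallelograms whose horizontal edges are 1/6 long, each spanning 2/6 and
advancing 1/6 per half-turn, alternating lean; right-leaning patches carry
higher layer indices (drawn on top) than left-leaning ones within the run.

Layering: all loops at z-order 0; helix/strand glyphs receive strictly
increasing positive layers left to right across the row (within a helix run,
ordering is terminals, then left-leaning, then right-leaning patches).

## Rendering

Glyph outlines are stroked black at line width 0.5. Interiors are filled by
building a one-pixel-tall RGBA gradient with one color sample per alignment
column (bilinear interpolation between columns — per-column sampling is this
package's documented convention) and clipping it against the compound path
of each glyph class. Exactly three gradient constructions happen per row —
loop, strand, helix — regardless of glyph count; an instrumented counter
(`render.gradient_constructions`) exposes this. Missing scores render light
gray; gap columns render nothing. Defaults: PNG at 600 ppi; eps/svg/ps/tiff
are also written, with SVG made byte-reproducible by fixing the hash salt
and stripping the date metadata. Tick labels use author residue numbering of
the first structure and are omitted on gap/unresolved columns.

## Synthetic data generator

`fixtures` builds structures by internal-coordinate chain construction with
ideal bond lengths/angles (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å;
ω = 180°): helices at (φ, ψ) = (−57°, −47°), strands at (−139°, 135°), loops
as irregular PPII-like coil (φ ∈ −75±25°, ψ ∈ 145±25°, seeded) that forms no
i→i+4 contacts. Segments are placed as rigid bodies 20 Å apart, so no
spurious inter-segment hydrogen bonds arise; chain continuity between
segments is **not** enforced — hydrogen-bond annotation only uses local
backbone frames, so the discontinuity is immaterial to what the fixtures
test, but the files are not physically realistic proteins. Consecutive
strand segments are paired into antiparallel sheets by a deterministic
least-squares rigid fit of the second strand to canonical N···O (2.9 Å) and
H···O (1.9 Å) distances with ~4.9 Å CA pairing; both bond-registry parities
are tried and the lower-residual fit kept. Side chains beyond CA are
omitted. Alignments are generated by i.i.d. per-site substitution
(default rate 0.1) and gap introduction (default 0.05) over a given
reference, reference row ungapped, default 5 rows — small, realistic values
for a close homolog family; columns keep their positions (no insertions), so
generated MSAs exercise gap handling but not insertion realism.

What passing tests show: the annotator recovers planted helices/strands on
idealized geometry (terminal ±2 tolerance, the usual edge ambiguity of
hydrogen-bond assignment), the reduction/registration/geometry rules are
exact, and the pipeline is deterministic. What they do not show: behavior on
experimental-quality coordinates (distorted geometry, chain breaks inside
segments, alternate conformers in dense crystals), or on large MSAs with
insertions relative to the reference.

## Numerical and degenerate-input choices

- Altloc selection: highest occupancy, ties toward blank then 'A'.
- Duplicate (res_seq, i_code) in one chain is an error; residues without CA
  are dropped.
- Consensus tie-break alphabetical; all-X columns score 0.0 (no consensus).
- min-max normalization of a constant vector → 0.5 (mid-colormap).
- Empty annotation reduces to an empty track with no runs.
- Window indices are 1-based inclusive at the interface, 0-based half-open
  internally.
- Scene JSON rounds vertices to 9 decimals for stable golden comparisons.

## Problem sizes

Tests and the acceptance script use structures of ~20–40 residues, MSAs of
5–7 rows, 500–1000 randomized oracle comparisons, and rasterization at
reduced dpi except where the 600 ppi default itself is under test; these
sizes fully exercise every rule while keeping the suite fast.

## Known limitations

- No mmCIF input; no multi-model ensembles beyond selecting one model.
- No π-helix/3₁₀/PPII glyphs (collapsed to loop by design).
- The built-in annotator implements the helix/strand core of the
  hydrogen-bond calculus, not the full DSSP state machine (no T/S/G/I
  states); precomputed annotations can supply them, where they are drawn
  as loops regardless.
- No MSA construction or structure superposition.
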