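"""Draw one ungapped secondary-structure diagram from a single structure.

Builds a small synthetic PDB (helix + hairpin, ideal geometry), annotates it
from backbone hydrogen bonds, and renders a solid-white diagram.
"""

from pathlib import Path

from ssglyph import (
    RunConfig, annotate_structure, extract_sequence, parse_pdb,
    reduce_to_three_state, run,
)
from ssglyph.fixtures import FixtureSpec, make_structure
from ssglyph.render import ColorSpec, RenderOptions

work = Path("example_out")
work.mkdir(exist_ok=True)

plan = (("L", 3), ("H", 10), ("L", 4), ("E", 6), ("L", 3), ("E", 6), ("L", 3))
pdb_text, truth = make_structure(FixtureSpec(motif_plan=plan, seed=7))
(work / "demo.pdb").write_text(pdb_text)

model = parse_pdb(work / "demo.pdb")
seq, _ = extract_sequence(model)
(work / "demo.fasta").write_text(f">demo\n{seq}\n")

three, runs = reduce_to_three_state(annotate_structure(model))
print(f"residues:        {len(model)}")
print(f"annotation:      {three.states}")
print(f"drawn elements:  {sum(1 for r in runs if r.state != 'L')} "
      "(helix/strand runs surviving the >=4 H / >=3 E,B thresholds)")

out = run(RunConfig(
    pdb_paths=[str(work / "demo.pdb")],
    fasta_path=str(work / "demo.fasta"),
    ref_ids=["demo"],
    scoring="solid",
    colorspec=ColorSpec(mode="solid", name_or_colors="white"),
    options=RenderOptions(output_path=str(work / "single.png"), dpi=150),
))
print(f"wrote {out}  (one row, white fill, 25-inch canvas scaled to the "
      f"{len(seq)} alignment columns)")
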