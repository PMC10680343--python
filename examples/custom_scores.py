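"""Color a diagram by per-residue scores carried in the B-factor column.

Emulates the AlphaFold-confidence workflow: pLDDT-like values (0-100) are
written into the CA B-factor column, min-max normalized, and used to look up
colors.  Also shows the Rate4Site nine-bin quantization on a score file.
"""

from pathlib import Path

import numpy as np

from ssglyph import RunConfig, extract_sequence, parse_pdb, run
from ssglyph.fixtures import FixtureSpec, make_structure
from ssglyph.render import ColorSpec, RenderOptions
from ssglyph.scoring import normalize_scores, rate4site_scores

work = Path("example_out")
work.mkdir(exist_ok=True)

plan = (("L", 4), ("H", 12), ("L", 4), ("E", 5), ("L", 3), ("E", 5), ("L", 4))
n = sum(l for _, l in plan)
rng = np.random.default_rng(0)
plddt = np.clip(90 - 40 * np.abs(np.sin(np.linspace(0, 3, n))) + rng.normal(0, 3, n), 0, 100)

pdb_text, _ = make_structure(FixtureSpec(motif_plan=plan, seed=21), b_factors=plddt)
(work / "conf.pdb").write_text(pdb_text)
seq, _ = extract_sequence(parse_pdb(work / "conf.pdb"))
(work / "conf.fasta").write_text(f">conf\n{seq}\n")

norm = normalize_scores(list(plddt))
print(f"B-factor (pLDDT-like) range: {plddt.min():.1f}..{plddt.max():.1f}; "
      f"normalized to [0, 1] before coloring (min->0, max->1)")

out = run(RunConfig(
    pdb_paths=[str(work / "conf.pdb")],
    fasta_path=str(work / "conf.fasta"), ref_ids=["conf"],
    scoring="bfactor",
    colorspec=ColorSpec(mode="custom_list", name_or_colors=("red", "yellow", "blue")),
    options=RenderOptions(output_path=str(work / "bfactor.png"), dpi=150),
))
print(f"wrote {out}  (low-confidence regions red, high-confidence blue)")

# Rate4Site-style rates quantize into nine bins
rates = np.linspace(-1.5, 1.5, n)
(work / "rates.res").write_text(
    "".join(f"{i+1} {seq[i]} {r:.4f}\n" for i, r in enumerate(rates))
)
binned = rate4site_scores(work / "rates.res")
print(f"Rate4Site binning: {len(set(binned.values))} distinct levels "
      "(nine equal-width bins at 0/8..8/8)")
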