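"""Generating a synthetic comparative study with known ground truth.

Writes a seeded Yule tree (Newick), a Carnivora-like trait table (CSV)
and the ground-truth effect graph (JSON).  Identical configurations give
byte-identical files, so fixtures never need to be stored.
"""

import json

import phylorange as pr
from phylorange.simulate import write_study

cfg = pr.strong_preset(n_species=40, seed=7)
paths = write_study(cfg, "scratch/example_study")
for role, path in paths.items():
    print(f"{role}: {path}")

truth = json.loads(paths["truth"].read_text())
print("\nplanted effects (source -> target, slope in latent units):")
for src, tgt, slope in truth["effects"]:
    print(f"  {src} -> {tgt}: {slope:+.1f}")

table = pr.load_trait_table(paths["table"])
print(f"\n{len(table)} species; per-column missingness "
      f"(rate {cfg.missing_rate}):")
print(table.isna().sum().to_string())
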