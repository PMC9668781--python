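#!/usr/bin/env python
"""Rank genotypes on the weighted-BLUP index and predict genetic gains.

Applies the breeding-programme economic weights (carotenoid content and
pulp colour +30, cyanogenic score -30, root yields +10, quality traits
+5) to the BLUP + intercept table, selects the top 30 parents for
recombination, and reports per-trait selected means, population means,
selection differentials and predicted gains G = h2m * S.

Writes selection.csv (per-genotype index and BLUPs for the selected set)
and gains.csv under results/selection/.
"""

import argparse
from pathlib import Path

import pandas as pd

from biofortqg.io import write_table
from biofortqg.selection import run_selection

ap = argparse.ArgumentParser()
ap.add_argument("--blups", type=Path, default=Path("results/fits/blups.csv"))
ap.add_argument("--components", type=Path,
                default=Path("results/fits/components.csv"))
ap.add_argument("--clusters", type=Path,
                default=Path("results/clusters/assignments.csv"))
ap.add_argument("-n", type=int, default=30)
ap.add_argument("--mode", choices=["blup", "rank"], default="blup")
ap.add_argument("--out-dir", type=Path, default=Path("results/selection"))
args = ap.parse_args()

blups = pd.read_csv(args.blups).set_index("genotype_id")
comp = pd.read_csv(args.components).set_index("trait")
h2m = comp["h2m"].to_dict()

res = run_selection(blups, h2m, n=args.n, mode=args.mode)

selected = blups.loc[res.selected].copy()
selected.insert(0, "SI", res.index_scores.loc[res.selected])
if args.clusters.exists():
    clusters = pd.read_csv(args.clusters).set_index("genotype_id")["cluster"]
    selected.insert(1, "cluster", clusters.reindex(selected.index))
write_table(selected.rename_axis("genotype_id").reset_index(),
            args.out_dir / "selection.csv")
write_table(res.report.reset_index(), args.out_dir / "gains.csv")

print(f"selected {len(res.selected)} of {len(res.index_scores)} genotypes "
      f"({args.mode} index)")
print(res.report.round(3).to_string())
print(f"outputs under {args.out_dir}")
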