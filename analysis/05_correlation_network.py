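#!/usr/bin/env python
"""Trait correlations and the partial-correlation network over BLUPs.

Computes pairwise-complete Pearson correlations with t-test p-values on
the genotype x trait BLUP table, orders the traits as a clustered
correlogram would, and fits the EBIC-selected graphical-lasso network of
partial correlations.  Writes r.csv, p.csv, ordering.txt and
network_edges.csv under results/corr/.
"""

import argparse
from pathlib import Path

import pandas as pd

from biofortqg.io import write_table
from biofortqg.network import order_correlogram, partial_correlation_network, pearson_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--blups", type=Path, default=Path("results/fits/blups.csv"))
ap.add_argument("--out-dir", type=Path, default=Path("results/corr"))
args = ap.parse_args()

blups = pd.read_csv(args.blups).set_index("genotype_id")
cm = pearson_matrix(blups)
order = order_correlogram(cm)
net = partial_correlation_network(blups)

args.out_dir.mkdir(parents=True, exist_ok=True)
write_table(cm.r.rename_axis("trait").reset_index(), args.out_dir / "r.csv")
write_table(cm.p.rename_axis("trait").reset_index(), args.out_dir / "p.csv")
(args.out_dir / "ordering.txt").write_text("\n".join(order) + "\n")
edges = net.edges()
write_table(edges, args.out_dir / "network_edges.csv")

sig = cm.significant()
print(f"{int(sig.to_numpy().sum() / 2)} of "
      f"{len(cm.traits) * (len(cm.traits) - 1) // 2} trait pairs significant "
      "at 5%")
print("correlogram order:", " ".join(order))
print(f"network: {len(edges)} edges at penalty {net.penalty:.3f}")
strongest = edges.reindex(edges.weight.abs().sort_values(ascending=False).index)
print(strongest.head(5).to_string(index=False))
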