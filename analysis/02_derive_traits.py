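#!/usr/bin/env python
"""Derive the analysis traits from raw plot measurements.

Reads the simulated raw dataset (air/water root weights, oven humidity,
spectrophotometer absorbance, plot weights, root counts, scores) and
recomputes every derived trait: gravimetric and oven-dry dry-matter
content, total carotenoid content, yields in t/ha, harvest index, dry
root yield and roots per plant.  Reports how closely the derivation
reproduces the generator's trait values (it should be exact to rounding)
and writes the per-plot trait table.
"""

import argparse
from pathlib import Path

import numpy as np

from biofortqg.io import load_dataset, write_table
from biofortqg.simulate import DEFAULT_PLOT_AREA
from biofortqg.traits import derive_traits

ap = argparse.ArgumentParser()
ap.add_argument("--in-dir", type=Path, default=Path("results/sim"))
ap.add_argument("--out", type=Path, default=Path("results/traits.csv"))
args = ap.parse_args()

ds = load_dataset(args.in_dir)
trait_cols = ds.trait_columns()
raw_only = ds.plots.drop(columns=trait_cols)
derived = derive_traits(raw_only, plot_area_m2=DEFAULT_PLOT_AREA)

print("agreement between derived traits and the simulated values:")
for t in trait_cols:
    a, b = ds.plots[t], derived[t]
    m = a.notna() & b.notna()
    gap = float(np.nanmax(np.abs(a[m] - b[m]))) if m.any() else float("nan")
    print(f"  {t:10s} n={int(m.sum()):5d}  max abs gap {gap:.2e}")

write_table(derived, args.out)
print(f"wrote {args.out}")
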