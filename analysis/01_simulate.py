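#!/usr/bin/env python
"""Generate the synthetic multi-trial germplasm dataset.

Draws an augmented-block-design trial series from the documented
generator preset — 265 test genotypes, 21 trials with 5-22 blocks and
4-34 shared checks, published per-trait means and variance components,
carotenoid content measured only in the last two trial-years — then
backfills raw field/laboratory measurements so the derivation step can
be exercised on realistic input.  With ``--demo`` (the default used by
the downstream drivers' documentation runs) the design is scaled to 120
genotypes and 8 trials so the whole pipeline finishes in a few minutes.

Writes trials.csv / germplasm.csv / plots.csv plus the generating truth
under results/sim/.
"""

import argparse
import json
from pathlib import Path

from biofortqg.io import save_dataset, write_table
from biofortqg.simulate import backfill_raw_measurements, generate_dataset, published_panel_config

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results/sim"))
ap.add_argument("--full", action="store_true",
                help="full 265-genotype x 21-trial scale instead of the demo scale")
args = ap.parse_args()

cfg = published_panel_config()
if not args.full:
    cfg.n_genotypes, cfg.n_trials = 120, 8
    cfg.blocks_per_trial, cfg.checks_per_trial = (4, 8), (4, 10)
    cfg.missingness = {"TCC": ["T07", "T08"]}

ds, truth = generate_dataset(cfg, seed=args.seed)
ds = backfill_raw_measurements(ds, on_invalid="skip")
save_dataset(ds, args.out_dir)
write_table(truth.genotype_effects.rename_axis("genotype_id").reset_index(),
            args.out_dir / "true_genotype_effects.csv")
(args.out_dir / "truth_components.json").write_text(json.dumps(
    {t: cfg.components(t) for t in cfg.traits}, indent=2))

n_checks = int(ds.germplasm.is_check.sum())
print(f"simulated {len(ds.plots)} plots: {cfg.n_genotypes} test genotypes, "
      f"{n_checks} checks, {cfg.n_trials} trials -> {args.out_dir}")
tcc_trials = sorted(ds.plots.loc[ds.plots['TCC'].notna(), 'trial_id'].unique())
print(f"carotenoid content measured in trials {tcc_trials} only")
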