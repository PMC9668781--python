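"""Published reference values for the 265-accession cassava panel.

Two small tables ship with the package:

* ``panel_variance_components.csv`` — per-trait means, REML variance
  components (genotype, genotype x trial, residual), both heritabilities
  and the likelihood-ratio chi-square statistics reported for the panel
  evaluated in 21 augmented-block trials (2011-2020);
* ``selected_parents_blups.csv`` — BLUP-plus-intercept values of the 30
  genotypes selected for recombination, with their diversity-cluster label.

They serve as worked-example fixtures: the heritability formulas, the
selection-report machinery and the synthetic-data presets are all checked
against them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TRAITS = ["TCC", "DMC.Grav", "DMC.OD", "FRY", "ShY", "HI", "DRY",
          "NRP", "StC", "PulpColor", "HCN"]

#: economic weights of the selection index (sum over traits of weight x BLUP)
DEFAULT_INDEX_WEIGHTS = {
    "DMC.Grav": 5.0, "DMC.OD": 5.0, "TCC": 30.0, "FRY": 10.0, "ShY": 5.0,
    "HI": 5.0, "DRY": 10.0, "NRP": 10.0, "StC": 5.0, "PulpColor": 30.0,
    "HCN": -30.0,
}

#: number of parents selected for recombination
DEFAULT_N_SELECTED = 30


def _read(name: str) -> pd.DataFrame:
    with resources.files("biofortqg.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def panel_variance_components() -> pd.DataFrame:
    """Per-trait variance components and heritabilities, indexed by trait."""
    return _read("panel_variance_components.csv").set_index("trait")


def selected_parents_blups() -> pd.DataFrame:
    """BLUP + intercept of the 30 selected parents, indexed by genotype."""
    return _read("selected_parents_blups.csv").set_index("genotype_id")
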