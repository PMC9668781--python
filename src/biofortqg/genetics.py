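"""Heritability and predicted genetic gain.

Broad-sense heritability on a plot basis,

    h2 = sigma2_g / (sigma2_g + sigma2_ge + sigma2_e),

clonal-mean heritability on the scale of genotype means over e trials
with effective replication r,

    h2m = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_e / (r e)),

and the predicted response to selecting a parent set,

    G = h2m * S,    S = mean(selected BLUP + intercept) - population mean,

reported also as a percentage of the population mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import ModelFit

__all__ = ["HeritabilityEstimate", "GainEstimate", "broad_sense_h2",
           "clonal_mean_h2", "heritability_from_fit", "genetic_gain"]


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    h2m: float
    e: int
    r: float


@dataclass
class GainEstimate:
    trait: str
    selected_mean: float
    population_mean: float
    S: float
    G: float
    G_pct: float


def broad_sense_h2(sigma2_g: float, sigma2_ge: float, sigma2_e: float) -> float:
    """Plot-basis broad-sense heritability from variance components."""
    for v in (sigma2_g, sigma2_ge, sigma2_e):
        if v < 0:
            raise ValueError("variance components must be >= 0")
    tot = sigma2_g + sigma2_ge + sigma2_e
    if tot == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / tot


def clonal_mean_h2(sigma2_g: float, sigma2_ge: float, sigma2_e: float,
                   e: float, r: float) -> float:
    """Heritability of genotype means across e trials with replication r."""
    for v in (sigma2_g, sigma2_ge, sigma2_e):
        if v < 0:
            raise ValueError("variance components must be >= 0")
    if e < 1 or r <= 0:
        raise ValueError("need e >= 1 trials and replication r > 0")
    denom = sigma2_g + sigma2_ge / e + sigma2_e / (r * e)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def heritability_from_fit(fit: ModelFit) -> HeritabilityEstimate:
    """Both heritabilities from a fitted model's components and design sizes."""
    vc = fit.variance_components
    g = vc.get("genotype", 0.0)
    ge = vc.get("ge", 0.0)
    e2 = vc["residual"]
    e, r = fit.n_trials_used, fit.effective_replication
    return HeritabilityEstimate(
        trait=fit.trait,
        h2=broad_sense_h2(g, ge, e2),
        h2m=clonal_mean_h2(g, ge, e2, e, r),
        e=e, r=r,
    )


def genetic_gain(blup_plus_intercept: pd.Series, selected, h2m: float,
                 population_mean: float | None = None,
                 trait: str = "") -> GainEstimate:
    """Predicted gain from recombining a selected parent set.

    ``blup_plus_intercept`` holds one value per candidate genotype; the
    population mean defaults to the mean over all candidates.
    """
    selected = list(selected)
    if len(selected) == 0:
        raise ValueError("selected set is empty")
    if not 0 <= h2m <= 1:
        raise ValueError("h2m must lie in [0, 1]")
    vals = blup_plus_intercept.dropna()
    if population_mean is None:
        population_mean = float(vals.mean())
    sel = vals.loc[[g for g in selected if g in vals.index]]
    if len(sel) == 0:
        raise ValueError("no selected genotype has a value for this trait")
    S = float(sel.mean()) - population_mean
    G = h2m * S
    G_pct = 100.0 * G / population_mean if population_mean != 0 else np.nan
    return GainEstimate(trait or str(blup_plus_intercept.name or ""),
                        float(sel.mean()), population_mean, S, G, G_pct)
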