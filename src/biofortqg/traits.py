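"""Derived root-quality and yield traits from raw plot measurements.

All the phenotypes that the downstream mixed models consume are simple
deterministic transforms of field and laboratory measurements:

* root dry-matter content either from the specific-gravity (air/water
  weighing) regression of Kawano or from oven drying (100 - humidity %),
* total carotenoid content from spectrophotometer absorbance at 450 nm,
* plot weights converted to t/ha, harvest index, dry root yield, roots
  per plant, and the sweet/bitter cyanogenic classification.

Scalar functions accept floats or numpy arrays and are vectorised; the
table-level entry point is :func:`derive_traits`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GravimetricReading",
    "SpectroReading",
    "dmc_gravimetric",
    "dmc_oven_dry",
    "harvest_index",
    "dry_root_yield",
    "tcc_spectro",
    "yields_per_hectare",
    "roots_per_plant",
    "classify_cyanogenic",
    "derive_traits",
    "BETA_CAROTENE_EXTINCTION",
    "SWEET_CASSAVA_HCN_LIMIT",
]

#: 1%, 1 cm extinction coefficient of beta-carotene in petroleum ether.
BETA_CAROTENE_EXTINCTION = 2592.0

#: mg cyanogenic compounds per kg fresh root separating sweet from bitter cassava.
SWEET_CASSAVA_HCN_LIMIT = 100.0


@dataclass(frozen=True)
class GravimetricReading:
    """Root weight in air and submerged in water, both in kg."""

    weight_air: float
    weight_water: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.weight_air) <= np.asarray(self.weight_water)):
            raise ValueError("weight_air must exceed weight_water")


@dataclass(frozen=True)
class SpectroReading:
    """Spectrophotometer reading for carotenoid quantification.

    absorbance (AU, 450 nm), extract volume V in mL, sample mass P in g and
    the extinction coefficient (default beta-carotene in petroleum ether).
    """

    absorbance: float
    extract_volume: float
    sample_mass: float
    extinction_coefficient: float = BETA_CAROTENE_EXTINCTION

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.absorbance) < 0):
            raise ValueError("absorbance must be >= 0")
        for name in ("extract_volume", "sample_mass", "extinction_coefficient"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be > 0")


def dmc_gravimetric(weight_air, weight_water, *, flag_out_of_range: bool = True):
    """Dry-matter content (%) from the specific-gravity regression.

    DMC = 158.3 * Wair / (Wair - Wwater) - 142.  Being an empirical
    regression the result can leave [0, 100]; such values are returned
    untouched but trigger a warning (silent clamping would hide assay
    errors).
    """
    wa = np.asarray(weight_air, dtype=float)
    ww = np.asarray(weight_water, dtype=float)
    if np.any(wa <= ww):
        raise ValueError("weight in air must exceed weight in water")
    dmc = 158.3 * wa / (wa - ww) - 142.0
    if flag_out_of_range and np.any((dmc < 0) | (dmc > 100)):
        warnings.warn("gravimetric DMC outside [0, 100]; check the weighing", stacklevel=2)
    return dmc if dmc.ndim else float(dmc)


def dmc_oven_dry(humidity):
    """Dry-matter content (%) from oven drying: 100 - humidity (%)."""
    h = np.asarray(humidity, dtype=float)
    if np.any((h < 0) | (h > 100)):
        raise ValueError("humidity must lie in [0, 100] %")
    out = 100.0 - h
    return out if out.ndim else float(out)


def harvest_index(fry, shy):
    """Harvest index (%): root yield as a share of root + shoot yield."""
    f = np.asarray(fry, dtype=float)
    s = np.asarray(shy, dtype=float)
    if np.any(f < 0) or np.any(s < 0):
        raise ValueError("yields must be >= 0")
    if np.any(f + s == 0):
        raise ValueError("root and shoot yield cannot both be zero")
    out = f / (f + s) * 100.0
    return out if out.ndim else float(out)


def dry_root_yield(fry, dmc_grav):
    """Dry root yield (t/ha) = fresh root yield x dry-matter fraction."""
    f = np.asarray(fry, dtype=float)
    d = np.asarray(dmc_grav, dtype=float)
    if np.any(f < 0):
        raise ValueError("fresh root yield must be >= 0")
    if np.any((d < 0) | (d > 100)):
        raise ValueError("dry-matter content must lie in [0, 100] %")
    out = f * d / 100.0
    return out if out.ndim else float(out)


def tcc_spectro(absorbance, extract_volume, sample_mass,
                extinction_coefficient: float = BETA_CAROTENE_EXTINCTION):
    """Total carotenoid content (ug/g): A * V * 1e4 / (A1%1cm * P)."""
    a = np.asarray(absorbance, dtype=float)
    v = np.asarray(extract_volume, dtype=float)
    p = np.asarray(sample_mass, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be >= 0")
    if np.any(v <= 0) or np.any(p <= 0) or extinction_coefficient <= 0:
        raise ValueError("volume, mass and extinction coefficient must be > 0")
    out = a * v * 1e4 / (extinction_coefficient * p)
    return out if out.ndim else float(out)


def yields_per_hectare(plot_weight_kg, plot_area_m2):
    """Convert a plot weight (kg) on a plot of given area (m2) to t/ha."""
    w = np.asarray(plot_weight_kg, dtype=float)
    a = np.asarray(plot_area_m2, dtype=float)
    if np.any(a <= 0):
        raise ValueError("plot area must be > 0")
    out = w / 1000.0 * 10000.0 / a
    return out if out.ndim else float(out)


def roots_per_plant(n_roots, n_plants_harvested):
    """Average roots per plant; zero harvested plants yields NaN, never zero."""
    r = np.asarray(n_roots, dtype=float)
    p = np.asarray(n_plants_harvested, dtype=float)
    if np.any(r < 0) or np.any(p < 0):
        raise ValueError("counts must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p > 0, r / np.where(p > 0, p, 1.0), np.nan)
    return out if out.ndim else float(out)


def classify_cyanogenic(hcn_mg_per_kg):
    """Classify roots as 'sweet' (<= 100 mg HCN equivalents / kg) or 'bitter'.

    Applies to quantitative mg/kg assays only; the 1-9 picrate score used
    in the trials stays on its ordinal scale for modelling.
    """
    x = np.asarray(hcn_mg_per_kg, dtype=float)
    if np.any(x < 0):
        raise ValueError("cyanogenic content must be >= 0")
    out = np.where(x <= SWEET_CASSAVA_HCN_LIMIT, "sweet", "bitter")
    return out if out.ndim else str(out)


# raw measurement columns -> trait computations used by derive_traits
_PASSTHROUGH = {"pulp_color": "PulpColor", "hcn_score": "HCN", "starch_pct": "StC"}


def derive_traits(plots: pd.DataFrame, *, plot_area_m2: float | None = None) -> pd.DataFrame:
    """Append derived trait columns to a plot-level table.

    Works with whatever raw columns are present; each trait is computed only
    where its inputs are non-missing.  ``plot_area_m2`` overrides the
    per-row ``plot_area`` column when given.
    """
    out = plots.copy()
    area = None
    if plot_area_m2 is not None:
        area = pd.Series(plot_area_m2, index=out.index, dtype=float)
    elif "plot_area" in out.columns:
        area = out["plot_area"].astype(float)

    def have(*cols):
        return all(c in out.columns for c in cols)

    if have("weight_air", "weight_water"):
        m = out["weight_air"].notna() & out["weight_water"].notna()
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = dmc_gravimetric(
                out.loc[m, "weight_air"], out.loc[m, "weight_water"]
            )
        out["DMC.Grav"] = vals
    if have("humidity"):
        m = out["humidity"].notna()
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = dmc_oven_dry(out.loc[m, "humidity"])
        out["DMC.OD"] = vals
    if have("absorbance", "extract_volume", "sample_mass"):
        m = out[["absorbance", "extract_volume", "sample_mass"]].notna().all(axis=1)
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = tcc_spectro(
                out.loc[m, "absorbance"], out.loc[m, "extract_volume"], out.loc[m, "sample_mass"]
            )
        out["TCC"] = vals
    if have("plot_root_weight") and area is not None:
        m = out["plot_root_weight"].notna() & area.notna()
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = yields_per_hectare(out.loc[m, "plot_root_weight"], area[m])
        out["FRY"] = vals
    if have("plot_shoot_weight") and area is not None:
        m = out["plot_shoot_weight"].notna() & area.notna()
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = yields_per_hectare(out.loc[m, "plot_shoot_weight"], area[m])
        out["ShY"] = vals
    if "FRY" in out and "ShY" in out:
        m = (out["FRY"].notna() & out["ShY"].notna()
             & (out["FRY"] >= 0) & (out["ShY"] >= 0)
             & ((out["FRY"] + out["ShY"]) > 0))
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = harvest_index(out.loc[m, "FRY"], out.loc[m, "ShY"])
        out["HI"] = vals
    if "FRY" in out and "DMC.Grav" in out:
        m = (out["FRY"].notna() & out["DMC.Grav"].notna() & (out["FRY"] >= 0)
             & (out["DMC.Grav"] >= 0) & (out["DMC.Grav"] <= 100))
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = dry_root_yield(out.loc[m, "FRY"], out.loc[m, "DMC.Grav"])
        out["DRY"] = vals
    if have("n_roots", "n_plants_harvested"):
        m = out["n_roots"].notna() & out["n_plants_harvested"].notna()
        vals = np.full(len(out), np.nan)
        if m.any():
            vals[m.to_numpy()] = roots_per_plant(
                out.loc[m, "n_roots"], out.loc[m, "n_plants_harvested"]
            )
        out["NRP"] = vals
    for raw, trait in _PASSTHROUGH.items():
        if raw in out.columns:
            out[trait] = out[raw].astype(float)
    return out
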