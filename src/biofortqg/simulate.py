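"""Synthetic multi-environment augmented-block trials with known truth.

The generator draws plot values from the same linear mixed model the
pipeline fits,

    Y_ijk = mu + E_i + B_(i)j + G_k + GE_ik + eps_ijk,

with every random term Gaussian: environment (trial) effects E_i, blocks
nested in trials B_(i)j, genotype effects G_k drawn jointly across traits
from a multivariate normal with covariance D R D (D = per-trait genetic
standard deviations, R = genetic correlation matrix), genotype-by-trial
interactions GE_ik, and iid plot errors.  Replicated check cultivars
appear in every block; unreplicated test genotypes appear once per trial,
spread across blocks — the augmented block design.

Ordinal scores (root pulp colour 1-3, cyanogenic picrate score 1-9) are
produced by thresholding the latent Gaussian trait at configurable cut
points; the latent values are kept in the returned truth object.

:func:`backfill_raw_measurements` inverts the trait formulas so a dataset
carries raw field/laboratory measurements from which
:func:`biofortqg.traits.derive_traits` reproduces the simulated values,
making the whole derive -> fit chain testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset
from .reference import TRAITS, panel_variance_components

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_dataset",
           "backfill_raw_measurements", "published_panel_config", "small_config",
           "default_genetic_correlation"]

#: default plot geometry: 20 plants at 0.90 m x 0.80 m spacing
PLANTS_PER_PLOT = 20
PLANT_SPACING_M2 = 0.90 * 0.80
DEFAULT_PLOT_AREA = PLANTS_PER_PLOT * PLANT_SPACING_M2  # 14.4 m2

#: ordinal trait -> (cut points on the latent scale, resulting labels)
DEFAULT_ORDINAL = {
    "PulpColor": ([1.5, 2.5], [1, 2, 3]),
    "HCN": ([1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5], list(range(1, 10))),
}


@dataclass
class GeneratorConfig:
    """Design sizes, per-trait variance components and trait correlations."""

    n_genotypes: int = 265
    n_checks: int = 34
    n_trials: int = 21
    blocks_per_trial: tuple[int, int] = (5, 22)
    checks_per_trial: tuple[int, int] = (4, 34)
    traits: tuple[str, ...] = tuple(TRAITS)
    trait_means: dict = field(default_factory=dict)
    # trait -> dict with keys env, block, genotype, ge, residual
    variance_components: dict = field(default_factory=dict)
    genetic_correlation: pd.DataFrame | None = None
    # trait -> list of trial ids where measured (None = everywhere)
    missingness: dict = field(default_factory=dict)
    ordinal: dict = field(default_factory=lambda: dict(DEFAULT_ORDINAL))
    discretize_ordinal: bool = True
    plot_area_m2: float = DEFAULT_PLOT_AREA

    def validate(self) -> None:
        if self.n_checks < 1:
            raise ValueError("need at least one check cultivar")
        if self.checks_per_trial[0] > self.n_checks:
            raise ValueError("checks_per_trial exceeds the check pool")
        for t in self.traits:
            vc = self.variance_components.get(t, {})
            if any(v < 0 for v in vc.values()):
                raise ValueError(f"negative variance component for {t}")
        R = self.correlation_matrix()
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-8:
            raise ValueError("genetic correlation matrix is not positive semidefinite")

    def correlation_matrix(self) -> np.ndarray:
        if self.genetic_correlation is None:
            return np.eye(len(self.traits))
        R = self.genetic_correlation.loc[list(self.traits), list(self.traits)]
        return R.to_numpy(dtype=float)

    def components(self, trait: str) -> dict:
        vc = dict(env=1.0, block=0.25, genotype=1.0, ge=0.5, residual=1.0)
        vc.update(self.variance_components.get(trait, {}))
        return vc


@dataclass
class SyntheticTruth:
    """Everything the generator knew: parameters and realised effects."""

    config: GeneratorConfig
    seed: int
    genotype_effects: pd.DataFrame      # genotype x trait (latent scale)
    env_effects: pd.DataFrame           # trial x trait
    block_effects: pd.DataFrame         # (trial, block) x trait
    ge_effects: pd.DataFrame            # (genotype, trial) x trait
    latent: pd.DataFrame                # plot-level latent values, ordinal traits
    realized_components: pd.DataFrame   # trait x component sample variances


def default_genetic_correlation(traits=tuple(TRAITS)) -> pd.DataFrame:
    """Signed genetic-correlation structure of the cassava panel.

    Encodes the qualitative pattern seen in the germplasm: carotenoid
    content moves with pulp colour but not with dry-matter content; the
    yield traits (fresh/dry root yield, shoot yield, harvest index, roots
    per plant) form a positively correlated block; starch tracks dry
    matter; the cyanogenic score is essentially independent of quality.
    Anchor values are projected to the nearest correlation matrix
    (eigenvalue clipping), so the result is always usable directly.
    """
    anchors = {
        ("TCC", "PulpColor"): 0.70,
        ("TCC", "DMC.Grav"): 0.00,
        ("TCC", "DMC.OD"): 0.05,
        ("DMC.Grav", "DMC.OD"): 0.65,
        ("DMC.Grav", "StC"): 0.70,
        ("DMC.OD", "StC"): 0.55,
        ("FRY", "DRY"): 0.90,
        ("FRY", "ShY"): 0.55,
        ("FRY", "HI"): 0.45,
        ("FRY", "NRP"): 0.50,
        ("DRY", "ShY"): 0.45,
        ("DRY", "HI"): 0.40,
        ("DRY", "DMC.Grav"): 0.35,
        ("DRY", "NRP"): 0.45,
        ("ShY", "HI"): -0.30,
        ("HI", "NRP"): 0.25,
        ("HCN", "TCC"): -0.10,
        ("HCN", "PulpColor"): -0.10,
    }
    t = list(traits)
    R = np.eye(len(t))
    for (a, b), r in anchors.items():
        if a in t and b in t:
            i, j = t.index(a), t.index(b)
            R[i, j] = R[j, i] = r
    # nearest PSD: clip eigenvalues, renormalise to unit diagonal
    w, V = np.linalg.eigh(R)
    R = (V * np.clip(w, 1e-6, None)) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return pd.DataFrame(R, index=t, columns=t)


def published_panel_config() -> GeneratorConfig:
    """Preset emulating the published 265-accession evaluation.

    21 trials with 5-22 augmented blocks and 4-34 common checks, the
    published per-trait means and genotype / genotype-by-trial / residual
    variance components, carotenoid content measured only in the last two
    trial-years, and the signed genetic correlation structure above.
    Environment and block variances are not published; they default to
    1.0 x and 0.25 x the residual variance respectively.
    """
    ref = panel_variance_components()
    vc = {
        t: dict(
            genotype=float(ref.at[t, "sigma2_g"]),
            ge=float(ref.at[t, "sigma2_ge"]),
            residual=float(ref.at[t, "sigma2_e"]),
            env=float(ref.at[t, "sigma2_e"]),
            block=0.25 * float(ref.at[t, "sigma2_e"]),
        )
        for t in TRAITS
    }
    means = {t: float(ref.at[t, "mean"]) for t in TRAITS}
    cfg = GeneratorConfig(
        trait_means=means,
        variance_components=vc,
        genetic_correlation=default_genetic_correlation(),
        # TCC assessed only in the last two trial-years
        missingness={"TCC": ["T20", "T21"]},
    )
    return cfg


def small_config(n_genotypes=60, n_checks=4, n_trials=3, n_blocks=4,
                 traits=("TCC",), **vc_overrides) -> GeneratorConfig:
    """Compact single-or-few-trait config for unit tests and simulations."""
    ref = panel_variance_components()
    vc = {}
    means = {}
    for t in traits:
        if t in ref.index:
            vc[t] = dict(
                genotype=float(ref.at[t, "sigma2_g"]),
                ge=float(ref.at[t, "sigma2_ge"]),
                residual=float(ref.at[t, "sigma2_e"]),
                env=float(ref.at[t, "sigma2_e"]),
                block=0.25 * float(ref.at[t, "sigma2_e"]),
            )
            means[t] = float(ref.at[t, "mean"])
        else:
            vc[t] = dict(genotype=1.0, ge=0.0, residual=1.0, env=1.0, block=0.25)
            means[t] = 0.0
        vc[t].update(vc_overrides)
    return GeneratorConfig(
        n_genotypes=n_genotypes, n_checks=n_checks, n_trials=n_trials,
        blocks_per_trial=(n_blocks, n_blocks), checks_per_trial=(n_checks, n_checks),
        traits=tuple(traits), trait_means=means, variance_components=vc,
        ordinal={k: v for k, v in DEFAULT_ORDINAL.items() if k in traits},
    )


def _trial_ids(n):
    return [f"T{i + 1:02d}" for i in range(n)]


def generate_dataset(cfg: GeneratorConfig, seed: int) -> tuple[Dataset, SyntheticTruth]:
    """Draw one dataset and its ground truth from the configured model."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    traits = list(cfg.traits)
    T = len(traits)

    test_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genotypes)]
    check_ids = [f"CHK{i + 1:02d}" for i in range(cfg.n_checks)]
    all_ids = check_ids + test_ids
    trials = _trial_ids(cfg.n_trials)

    # design: per trial draw block and check counts, place checks in every
    # block and scatter each test genotype once across the blocks
    lo_b, hi_b = cfg.blocks_per_trial
    lo_c, hi_c = cfg.checks_per_trial
    rows = []
    n_blocks_per_trial = {}
    for tr in trials:
        nb = int(rng.integers(lo_b, hi_b + 1))
        nc = int(rng.integers(lo_c, min(hi_c, cfg.n_checks) + 1))
        n_blocks_per_trial[tr] = nb
        trial_checks = list(rng.choice(check_ids, size=nc, replace=False))
        blocks = [f"B{j + 1:02d}" for j in range(nb)]
        for b in blocks:
            for g in trial_checks:
                rows.append((tr, b, g))
        order = rng.permutation(cfg.n_genotypes)
        for pos, gi in enumerate(order):
            rows.append((tr, blocks[pos % nb], test_ids[gi]))
    plots = pd.DataFrame(rows, columns=["trial_id", "block_id", "genotype_id"])

    # effect draws -------------------------------------------------------
    sd = {t: {k: np.sqrt(v) for k, v in cfg.components(t).items()} for t in traits}
    R = cfg.correlation_matrix()
    Dg = np.diag([sd[t]["genotype"] for t in traits])
    cov_g = Dg @ R @ Dg
    gen_eff = pd.DataFrame(
        rng.multivariate_normal(np.zeros(T), cov_g, size=len(all_ids), method="eigh"),
        index=all_ids, columns=traits,
    )
    env_eff = pd.DataFrame(
        rng.standard_normal((len(trials), T)) * [sd[t]["env"] for t in traits],
        index=trials, columns=traits,
    )
    blk_index = plots[["trial_id", "block_id"]].drop_duplicates()
    blk_mi = pd.MultiIndex.from_frame(blk_index)
    blk_eff = pd.DataFrame(
        rng.standard_normal((len(blk_mi), T)) * [sd[t]["block"] for t in traits],
        index=blk_mi, columns=traits,
    )
    ge_index = plots[["genotype_id", "trial_id"]].drop_duplicates()
    ge_mi = pd.MultiIndex.from_frame(ge_index)
    ge_eff = pd.DataFrame(
        rng.standard_normal((len(ge_mi), T)) * [sd[t]["ge"] for t in traits],
        index=ge_mi, columns=traits,
    )

    mu = np.array([cfg.trait_means.get(t, 0.0) for t in traits])
    eps = rng.standard_normal((len(plots), T)) * [sd[t]["residual"] for t in traits]
    latent = (
        mu
        + env_eff.loc[plots["trial_id"]].to_numpy()
        + blk_eff.loc[list(zip(plots["trial_id"], plots["block_id"]))].to_numpy()
        + gen_eff.loc[plots["genotype_id"]].to_numpy()
        + ge_eff.loc[list(zip(plots["genotype_id"], plots["trial_id"]))].to_numpy()
        + eps
    )
    latent = pd.DataFrame(latent, columns=traits)

    observed = latent.copy()
    if cfg.discretize_ordinal:
        for t, (cuts, labels) in cfg.ordinal.items():
            if t in observed.columns:
                observed[t] = np.asarray(labels, dtype=float)[
                    np.searchsorted(np.asarray(cuts, dtype=float), observed[t])
                ]
    for t, measured_in in cfg.missingness.items():
        if t in observed.columns and measured_in is not None:
            observed.loc[~plots["trial_id"].isin(measured_in).to_numpy(), t] = np.nan

    plots = pd.concat([plots, observed], axis=1)
    trials_df = pd.DataFrame({
        "trial_id": trials,
        "year": [2011 + i % 10 for i in range(len(trials))],
        "location": ["SIM"] * len(trials),
        "n_blocks": [n_blocks_per_trial[tr] for tr in trials],
    })
    germ = pd.DataFrame({
        "genotype_id": all_ids,
        "is_check": [g in set(check_ids) for g in all_ids],
    })

    realized = pd.DataFrame({
        "genotype": gen_eff.loc[test_ids].var(ddof=1),
        "env": env_eff.var(ddof=1),
        "block": blk_eff.var(ddof=1),
        "ge": ge_eff.var(ddof=1),
        "residual": pd.DataFrame(eps, columns=traits).var(ddof=1),
    })
    truth = SyntheticTruth(
        config=cfg, seed=seed, genotype_effects=gen_eff, env_effects=env_eff,
        block_effects=blk_eff, ge_effects=ge_eff,
        latent=latent[[t for t in cfg.ordinal if t in traits]],
        realized_components=realized,
    )
    return Dataset(trials_df, germ, plots), truth


# ---------------------------------------------------------------------------
# inverting the trait formulas

def backfill_raw_measurements(ds: Dataset, seed: int = 0, *,
                              on_invalid: str = "raise") -> Dataset:
    """Attach raw measurements that re-derive the simulated trait values.

    Gravimetric dry matter is inverted to an air/water weight pair,
    carotenoid content to an absorbance at fixed extract volume and
    sample mass, oven dry matter to a humidity, yields to plot weights,
    and roots per plant to (possibly fractional) root counts.  Harvest
    index and dry root yield are functions of the other traits, so they
    are recomputed from the backfilled yields and dry matter and the
    trait columns are overwritten to keep derive(backfill(ds)) an exact
    identity on the returned dataset.

    A trait value outside its invertible range (gravimetric DMC <= 16.3%
    with a non-negative water weight, negative carotenoid content, oven
    dry matter outside [0, 100]) raises by default; ``on_invalid='skip'``
    instead leaves the raw fields of those plots missing, which the
    Gaussian trait model makes occasionally necessary for low-mean
    traits whose simulated values can cross zero.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    from .traits import derive_traits

    out = ds.copy()
    p = out.plots
    area = DEFAULT_PLOT_AREA
    if "DMC.Grav" in p.columns:
        d = p["DMC.Grav"]
        if (d.dropna() <= 16.3).any():
            if on_invalid == "raise":
                raise ValueError("gravimetric DMC <= 16.3% has no non-negative water weight")
            d = d.where(d > 16.3)
        wair = pd.Series(5.0, index=p.index).where(d.notna())
        p["weight_air"] = wair
        p["weight_water"] = wair * (1.0 - 158.3 / (d + 142.0))
    if "DMC.OD" in p.columns:
        od = p["DMC.OD"]
        if ((od.dropna() < 0) | (od.dropna() > 100)).any():
            if on_invalid == "raise":
                raise ValueError("oven-dry DMC outside [0, 100] is not invertible")
            od = od.where((od >= 0) & (od <= 100))
        p["humidity"] = 100.0 - od
    if "TCC" in p.columns:
        tcc = p["TCC"]
        if (tcc.dropna() < 0).any():
            if on_invalid == "raise":
                raise ValueError("negative carotenoid content is not invertible")
            tcc = tcc.where(tcc >= 0)
        p["extract_volume"] = pd.Series(50.0, index=p.index).where(tcc.notna())
        p["sample_mass"] = pd.Series(10.0, index=p.index).where(tcc.notna())
        p["absorbance"] = tcc * 2592.0 * p["sample_mass"] / (p["extract_volume"] * 1e4)
    if "FRY" in p.columns:
        p["plot_root_weight"] = p["FRY"] * area / 10.0
    if "ShY" in p.columns:
        p["plot_shoot_weight"] = p["ShY"] * area / 10.0
    if "NRP" in p.columns:
        nrp = p["NRP"]
        if (nrp.dropna() < 0).any():
            if on_invalid == "raise":
                raise ValueError("negative roots-per-plant is not invertible")
            nrp = nrp.where(nrp >= 0)
        p["n_plants_harvested"] = pd.Series(
            float(PLANTS_PER_PLOT), index=p.index
        ).where(nrp.notna())
        p["n_roots"] = nrp * PLANTS_PER_PLOT
    if "StC" in p.columns:
        p["starch_pct"] = p["StC"]
    if "PulpColor" in p.columns:
        p["pulp_color"] = p["PulpColor"]
    if "HCN" in p.columns:
        p["hcn_score"] = p["HCN"]
    p["plot_area"] = area
    derived = derive_traits(p, plot_area_m2=area)
    for t in ("HI", "DRY"):
        if t in p.columns and t in derived.columns:
            p[t] = derived[t]
    out.plots = p
    return out
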