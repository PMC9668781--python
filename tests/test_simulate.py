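"""Generator correctness: model structure, determinism, inversion."""

import numpy as np
import pandas as pd
import pytest

from biofortqg.io import save_dataset
from biofortqg.simulate import (
    backfill_raw_measurements,
    default_genetic_correlation,
    generate_dataset,
    published_panel_config,
    small_config,
)
from biofortqg.traits import derive_traits


def test_all_variances_zero_reproduces_the_mean():
    cfg = small_config(n_genotypes=10, n_checks=2, n_trials=2, n_blocks=2,
                       traits=("Y",), genotype=0.0, ge=0.0, residual=0.0,
                       env=0.0, block=0.0)
    cfg.trait_means["Y"] = 3.5
    ds, _ = generate_dataset(cfg, seed=1)
    np.testing.assert_allclose(ds.plots["Y"], 3.5)


def test_same_seed_is_byte_identical(tmp_path):
    cfg = small_config(n_genotypes=15, n_checks=2, n_trials=2, n_blocks=2)
    for sub in ("a", "b"):
        ds, _ = generate_dataset(cfg, seed=99)
        save_dataset(ds, tmp_path / sub)
    assert (tmp_path / "a/plots.csv").read_bytes() == (tmp_path / "b/plots.csv").read_bytes()


def test_genotype_effect_variance_matches_config():
    # carotenoid-like components: sigma2_g 5.44, no GxE, residual 2.16
    cfg = small_config(n_genotypes=300, n_checks=5, n_trials=6, n_blocks=5,
                       traits=("TCC",), genotype=5.44, ge=0.0, residual=2.16)
    vs = []
    for seed in range(5):
        _, truth = generate_dataset(cfg, seed=21 + seed)
        vs.append(truth.genotype_effects.loc[
            [g for g in truth.genotype_effects.index if g.startswith("G")], "TCC"
        ].var(ddof=1))
    assert np.mean(vs) == pytest.approx(5.44, rel=0.15)


def test_design_is_augmented():
    cfg = small_config(n_genotypes=24, n_checks=3, n_trials=2, n_blocks=4)
    ds, _ = generate_dataset(cfg, seed=3)
    checks = ds.check_ids
    p = ds.plots
    for trial, sub in p.groupby("trial_id"):
        blocks = sub["block_id"].unique()
        trial_checks = set(sub.loc[sub.genotype_id.isin(checks), "genotype_id"])
        # every check used in the trial appears in every block
        for b in blocks:
            in_block = set(sub.loc[sub.block_id == b, "genotype_id"])
            assert trial_checks <= in_block
        # each test genotype appears exactly once per trial
        tests = sub.loc[~sub.genotype_id.isin(checks), "genotype_id"]
        assert tests.value_counts().max() == 1


def test_missingness_pattern_exact():
    cfg = published_panel_config()
    cfg.n_genotypes, cfg.n_checks, cfg.n_trials = 20, 4, 21
    cfg.blocks_per_trial, cfg.checks_per_trial = (3, 3), (4, 4)
    ds, _ = generate_dataset(cfg, seed=2)
    measured = ds.plots.loc[ds.plots["TCC"].notna(), "trial_id"].unique()
    assert sorted(measured) == ["T20", "T21"]
    for t in ("FRY", "HCN"):
        assert ds.plots[t].notna().all()


def test_ordinal_traits_are_thresholded():
    cfg = small_config(n_genotypes=50, n_checks=3, n_trials=2, n_blocks=3,
                       traits=("PulpColor", "HCN"))
    ds, truth = generate_dataset(cfg, seed=4)
    assert set(ds.plots["PulpColor"].unique()) <= {1.0, 2.0, 3.0}
    assert set(ds.plots["HCN"].unique()) <= set(float(x) for x in range(1, 10))
    # latent values are continuous and stored in the truth
    assert truth.latent["PulpColor"].nunique() > 3


def test_default_correlation_matrix_is_psd_with_unit_diagonal():
    R = default_genetic_correlation()
    np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
    assert np.linalg.eigvalsh(R.to_numpy()).min() > 0
    assert R.at["TCC", "PulpColor"] > 0.5
    assert abs(R.at["TCC", "DMC.Grav"]) < 0.15


def test_genotype_correlation_converges_to_configured():
    cfg = small_config(n_genotypes=800, n_checks=2, n_trials=1, n_blocks=2,
                       traits=("TCC", "PulpColor", "DMC.Grav"))
    cfg.genetic_correlation = default_genetic_correlation(
        ("TCC", "PulpColor", "DMC.Grav"))
    ds, truth = generate_dataset(cfg, seed=6)
    emp = truth.genotype_effects.corr()
    cfgR = cfg.genetic_correlation
    assert emp.at["TCC", "PulpColor"] == pytest.approx(
        cfgR.at["TCC", "PulpColor"], abs=0.1)
    assert emp.at["TCC", "DMC.Grav"] == pytest.approx(
        cfgR.at["TCC", "DMC.Grav"], abs=0.1)


class TestBackfill:
    def test_round_trip_identity(self, multitrait_dataset):
        ds, _ = multitrait_dataset
        filled = backfill_raw_measurements(ds.copy(), on_invalid="skip")
        derived = derive_traits(filled.plots.drop(columns=ds.trait_columns()),
                                plot_area_m2=14.4)
        for t in ds.trait_columns():
            m = filled.plots[t].notna() & derived[t].notna()
            assert m.any()
            np.testing.assert_allclose(derived.loc[m, t], filled.plots.loc[m, t],
                                       rtol=1e-9)

    def test_dmc_inversion_example(self):
        cfg = small_config(n_genotypes=6, n_checks=2, n_trials=1, n_blocks=2,
                           traits=("DMC.Grav",), genotype=0.0, ge=0.0,
                           residual=0.0, env=0.0, block=0.0)
        cfg.trait_means["DMC.Grav"] = 35.0
        ds, _ = generate_dataset(cfg, seed=1)
        filled = backfill_raw_measurements(ds)
        from biofortqg.traits import dmc_gravimetric
        got = dmc_gravimetric(filled.plots["weight_air"].iloc[0],
                              filled.plots["weight_water"].iloc[0])
        assert got == pytest.approx(35.0, abs=1e-9)

    def test_zero_tcc_gives_zero_absorbance(self):
        cfg = small_config(n_genotypes=6, n_checks=2, n_trials=1, n_blocks=2,
                           traits=("TCC",), genotype=0.0, ge=0.0,
                           residual=0.0, env=0.0, block=0.0)
        cfg.trait_means["TCC"] = 0.0
        ds, _ = generate_dataset(cfg, seed=1)
        filled = backfill_raw_measurements(ds)
        np.testing.assert_allclose(filled.plots["absorbance"], 0.0)

    def test_uninvertible_dmc_raises(self):
        cfg = small_config(n_genotypes=6, n_checks=2, n_trials=1, n_blocks=2,
                           traits=("DMC.Grav",), genotype=0.0, ge=0.0,
                           residual=0.0, env=0.0, block=0.0)
        cfg.trait_means["DMC.Grav"] = 10.0  # below the 16.3% regression floor
        ds, _ = generate_dataset(cfg, seed=1)
        with pytest.raises(ValueError, match="16.3"):
            backfill_raw_measurements(ds)


def test_non_psd_correlation_rejected():
    cfg = small_config(traits=("A", "B", "C"))
    R = pd.DataFrame([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
                     index=["A", "B", "C"], columns=["A", "B", "C"])
    cfg.genetic_correlation = R
    with pytest.raises(ValueError, match="semidefinite"):
        generate_dataset(cfg, seed=0)
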