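"""Mixed-model engine: closed-form oracles, lme4 cross-check, properties."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from biofortqg.io import Dataset
from biofortqg.lmm import (
    ModelSpec,
    blup_table,
    build_design,
    fit_reml,
    fit_trait,
    lrt_term,
)
from biofortqg.simulate import generate_dataset, small_config


def one_way_dataset(effects, sigma_e, reps, seed=0, mu=10.0):
    """Balanced one-way random design: g genotypes x r reps, one block."""
    rng = np.random.default_rng(seed)
    g = len(effects)
    rows = []
    for k in range(g):
        for _ in range(reps):
            rows.append(("T1", "B1", f"G{k:03d}",
                         mu + effects[k] + rng.normal(0, sigma_e)))
    plots = pd.DataFrame(rows, columns=["trial_id", "block_id", "genotype_id", "Y"])
    trials = pd.DataFrame({"trial_id": ["T1"], "year": [2019],
                           "location": ["X"], "n_blocks": [1]})
    germ = pd.DataFrame({"genotype_id": [f"G{k:03d}" for k in range(g)],
                         "is_check": False})
    return Dataset(trials, germ, plots)


class TestBalancedOneWayOracle:
    """On balanced designs REML equals the ANOVA moment estimators and
    BLUPs equal the closed-form shrunken means."""

    def setup_method(self):
        rng = np.random.default_rng(42)
        self.g, self.r = 40, 6
        self.effects = rng.normal(0, 2.0, self.g)
        self.ds = one_way_dataset(self.effects, sigma_e=1.5, reps=self.r, seed=1)
        # single trial: only the genotype term is identifiable
        self.fit = fit_trait(self.ds, "Y", random_terms=("genotype",))

    def anova_components(self):
        y = self.ds.plots.pivot_table(index="genotype_id", values="Y",
                                      aggfunc=["mean", "var", "count"])
        means = y["mean"]["Y"].to_numpy()
        msw = self.ds.plots.groupby("genotype_id")["Y"].var(ddof=1).mean()
        msb = self.r * np.var(means, ddof=1)
        return (msb - msw) / self.r, msw, means

    def test_components_match_anova(self):
        s2g, s2e, _ = self.anova_components()
        assert self.fit.variance_components["genotype"] == pytest.approx(s2g, abs=1e-6)
        assert self.fit.variance_components["residual"] == pytest.approx(s2e, abs=1e-6)

    def test_blups_match_shrunken_means(self):
        s2g, s2e, means = self.anova_components()
        mu = means.mean()
        shrink = s2g / (s2g + s2e / self.r)
        expected = shrink * (means - mu)
        got = self.fit.blups["genotype"].sort_index().to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)
        assert self.fit.intercept == pytest.approx(mu, abs=1e-6)

    def test_blup_shrinkage_property(self):
        _, _, means = self.anova_components()
        blups = self.fit.blups["genotype"]
        assert blups.var(ddof=1) < np.var(means, ddof=1)
        assert abs(blups.sum()) < 1e-6 * len(blups)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_reml_matches_lme4(tmp_path, tiny_dataset):
    """Independent oracle: lme4 on the identical model specification."""
    ds, _ = tiny_dataset
    fit = fit_trait(ds, "TCC")
    p = ds.plots.copy()
    p["is_check"] = p.genotype_id.isin(ds.check_ids).astype(int)
    p.to_csv(tmp_path / "d.csv", index=False)
    script = textwrap.dedent("""
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        d$check <- ifelse(d$is_check == 1, d$genotype_id, "TEST")
        d$test_geno <- ifelse(d$is_check == 1, "CHK", d$genotype_id)
        d$blk <- paste(d$trial_id, d$block_id, sep = "/")
        d$ge <- paste(d$genotype_id, d$trial_id, sep = "@")
        d$isg <- as.numeric(d$is_check == 0)
        m <- lmer(TCC ~ check + (1 | trial_id) + (1 | blk) +
                  (0 + isg | test_geno) + (1 | ge), data = d,
                  control = lmerControl(check.nobs.vs.nlev = "ignore",
                                        check.nobs.vs.nRE = "ignore"))
        v <- as.data.frame(VarCorr(m))
        cat(logLik(m), v$vcov[v$grp == "trial_id"], v$vcov[v$grp == "blk"],
            v$vcov[v$grp == "test_geno"], v$vcov[v$grp == "ge"],
            v$vcov[v$grp == "Residual"], sep = "\\n")
    """)
    (tmp_path / "m.R").write_text(script)
    out = subprocess.run(["Rscript", str(tmp_path / "m.R"), str(tmp_path / "d.csv")],
                         capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ll, env, blk, gen, ge, res = map(float, out.stdout.split())
    assert fit.reml_loglik == pytest.approx(ll, abs=1e-3)
    vc = fit.variance_components
    assert vc["env"] == pytest.approx(env, rel=1e-3, abs=1e-5)
    assert vc["block"] == pytest.approx(blk, rel=1e-3, abs=1e-5)
    assert vc["genotype"] == pytest.approx(gen, rel=1e-3, abs=1e-5)
    assert vc["ge"] == pytest.approx(ge, rel=1e-3, abs=1e-5)
    assert vc["residual"] == pytest.approx(res, rel=1e-3, abs=1e-5)


class TestBuildDesign:
    def test_trials_without_the_trait_are_excluded(self):
        cfg = small_config(n_genotypes=20, n_checks=3, n_trials=5, n_blocks=2)
        cfg.missingness = {"TCC": ["T04", "T05"]}
        ds, _ = generate_dataset(cfg, seed=0)
        design = build_design(ds, ModelSpec("TCC"))
        assert design.n_trials_used == 2

    def test_fixed_part_is_intercept_plus_check_contrasts(self, tiny_dataset):
        ds, _ = tiny_dataset
        design = build_design(ds, ModelSpec("TCC"))
        assert design.fixed_names[0] == "(Intercept)"
        assert len(design.fixed_names) == 1 + len(ds.check_ids)
        assert all(n.startswith("check[") for n in design.fixed_names[1:])
        assert len(design.levels["genotype"]) == 40  # test clones only

    def test_absent_trait_errors(self, tiny_dataset):
        ds, _ = tiny_dataset
        with pytest.raises(ValueError, match="absent"):
            build_design(ds, ModelSpec("NOPE"))

    def test_single_level_term_dropped_with_warning(self):
        cfg = small_config(n_genotypes=10, n_checks=2, n_trials=1, n_blocks=3)
        ds, _ = generate_dataset(cfg, seed=0)
        with pytest.warns(UserWarning, match="env"):
            design = build_design(ds, ModelSpec("TCC"))
        assert "env" not in design.Z
        assert "env" in design.dropped_terms


class TestFitProperties:
    def test_zero_genotype_variance_hits_boundary(self):
        cfg = small_config(n_genotypes=60, n_checks=3, n_trials=3, n_blocks=3,
                           genotype=0.0, ge=0.0, residual=1.0)
        ds, _ = generate_dataset(cfg, seed=13)
        fit = fit_trait(ds, "TCC")
        assert fit.variance_components["genotype"] < 0.05

    def test_relabeling_invariance(self, tiny_dataset):
        ds, _ = tiny_dataset
        fit1 = fit_trait(ds, "TCC")
        shuffled = ds.copy()
        mapping = {g: f"Z{i:03d}" for i, g in enumerate(
            sorted(ds.germplasm.genotype_id))}
        shuffled.plots["genotype_id"] = shuffled.plots.genotype_id.map(mapping)
        shuffled.germplasm["genotype_id"] = shuffled.germplasm.genotype_id.map(mapping)
        fit2 = fit_trait(shuffled, "TCC")
        for term in fit1.variance_components:
            assert fit1.variance_components[term] == pytest.approx(
                fit2.variance_components[term], rel=1e-5, abs=1e-8)

    def test_blup_recovery_correlation(self):
        # high-heritability setting: predictions should track true effects
        cfg = small_config(n_genotypes=300, n_checks=5, n_trials=6, n_blocks=5,
                           genotype=5.44, ge=0.0, residual=2.16)
        ds, truth = generate_dataset(cfg, seed=17)
        fit = fit_trait(ds, "TCC")
        blups = fit.blups["genotype"]
        true = truth.genotype_effects.loc[blups.index, "TCC"]
        assert np.corrcoef(blups, true)[0, 1] > 0.8


class TestLrt:
    def test_zero_variance_term_not_significant(self):
        cfg = small_config(n_genotypes=60, n_checks=3, n_trials=3, n_blocks=3,
                           genotype=0.0, ge=0.0, residual=1.0)
        ds, _ = generate_dataset(cfg, seed=19)
        res = lrt_term(ds, ModelSpec("TCC"), "genotype")
        assert res.chi_square < 2.0
        assert not res.significant_at_1pct

    def test_large_variance_term_detected(self):
        cfg = small_config(n_genotypes=100, n_checks=3, n_trials=3, n_blocks=3,
                           genotype=5.0, ge=0.0, residual=1.0)
        ds, _ = generate_dataset(cfg, seed=23)
        res = lrt_term(ds, ModelSpec("TCC"), "genotype")
        assert res.significant_at_1pct
        assert res.df == 1


class TestBlupTable:
    def test_shape_and_missing_cells(self, tiny_dataset):
        ds, _ = tiny_dataset
        fit = fit_trait(ds, "TCC")
        table = blup_table([fit])
        assert table.shape == (40, 1)
        assert table.columns.tolist() == ["TCC"]
        assert not table["TCC"].isna().any()

    def test_checks_optional(self, tiny_dataset):
        ds, _ = tiny_dataset
        fit = fit_trait(ds, "TCC")
        with_checks = blup_table([fit], include_checks=True)
        assert len(with_checks) == 40 + len(ds.check_ids)
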