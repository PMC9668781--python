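"""REML fitting of the augmented-design mixed model, BLUPs and LRTs.

One trait at a time the model is

    y_ijk = mu + T_k' + E_i + B_(i)j + T_(j)k + GE_ik + eps_ijk

with the common checks T_k' fixed (treatment contrasts against the
test-population intercept mu), and environments, blocks-within-
environment, unreplicated test genotypes and genotype-by-environment
cells random with independent variances.  Variance components are
estimated by restricted maximum likelihood; fixed effects and BLUPs then
solve Henderson's mixed-model equations at the converged components.

Implementation: with variance ratios gamma_t = sigma2_t / sigma2_e the
residual variance and fixed effects profile out of the REML criterion.
Writing W = [X  Z] and M(gamma) = W'W + diag(0, 1/gamma), a single sparse
(or dense, for small problems) factorisation of M yields the profiled
criterion

    -2 l_R = (n-p) log s2  +  log|M|  +  sum_t q_t log gamma_t
             + (n-p)(1 + log 2 pi),

where s2 = (y'y - sol'W'y)/(n-p) and sol = M^{-1} W'y, whose leading
blocks are the GLS fixed effects and the BLUPs.  The criterion is
minimised over log gamma with L-BFGS-B and polished with Nelder-Mead;
the objective only ever involves one factorisation per evaluation, which
keeps a full multi-trial fit well under a second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import optimize, stats

from .io import Dataset

__all__ = ["ModelSpec", "Design", "ModelFit", "LRTResult",
           "build_design", "fit_reml", "fit_trait", "lrt_term", "blup_table"]

RANDOM_TERMS = ("env", "block", "genotype", "ge")

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -14.0, 12.0
_DENSE_CUTOFF = 500  # MME dimension below which dense Cholesky wins


@dataclass
class ModelSpec:
    """Which random terms enter the model for one trait."""

    trait: str
    random_terms: tuple[str, ...] = RANDOM_TERMS

    def without(self, term: str) -> "ModelSpec":
        if term not in self.random_terms:
            raise ValueError(f"{term!r} is not a random term of this spec")
        return ModelSpec(self.trait, tuple(t for t in self.random_terms if t != term))


@dataclass
class Design:
    """Response, fixed design and random-term incidence matrices."""

    trait: str
    y: np.ndarray
    X: sp.csc_matrix
    fixed_names: list[str]
    Z: dict                      # term -> csc incidence matrix
    levels: dict                 # term -> list of level labels
    n_trials_used: int
    effective_replication: float
    dropped_terms: list[str] = field(default_factory=list)


@dataclass
class ModelFit:
    trait: str
    variance_components: dict            # term (incl. 'residual') -> sigma2
    fixed_estimates: pd.Series           # intercept + check effects
    blups: dict                          # term -> pd.Series of predicted effects
    reml_loglik: float
    converged: bool
    n_trials_used: int
    effective_replication: float
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.fixed_estimates["(Intercept)"])

    def blup_plus_intercept(self) -> pd.Series:
        """mu-hat + genotype BLUP for every test genotype."""
        return self.blups["genotype"] + self.intercept


@dataclass
class LRTResult:
    term: str
    chi_square: float
    df: int
    p_value: float
    significant_at_1pct: bool


def build_design(ds: Dataset, spec: ModelSpec) -> Design:
    """Assemble response and incidence structures for one trait.

    Trials without any observation of the trait are excluded; `e` is the
    count of the remaining trials.  A requested random term with fewer
    than two levels is dropped with a warning.  Effective replication r
    is the harmonic mean over genotypes of their plot counts in the
    included trials, divided by e (so r*e is a typical per-genotype plot
    total).
    """
    trait = spec.trait
    if trait not in ds.plots.columns:
        raise ValueError(f"trait {trait!r} is absent from the dataset")
    obs = ds.plots.loc[ds.plots[trait].notna()].reset_index(drop=True)
    if len(obs) == 0:
        raise ValueError(f"trait {trait!r} has no observations")
    y = obs[trait].to_numpy(dtype=float)
    n = len(obs)

    checks = ds.check_ids
    is_check = obs["genotype_id"].isin(checks).to_numpy()

    trials_used = sorted(obs["trial_id"].unique())
    e = len(trials_used)

    # fixed part: intercept + one treatment contrast per observed check
    check_levels = sorted(obs.loc[is_check, "genotype_id"].unique())
    cols = [np.ones(n)]
    fixed_names = ["(Intercept)"]
    for c in check_levels:
        cols.append((obs["genotype_id"] == c).to_numpy(dtype=float))
        fixed_names.append(f"check[{c}]")
    X = sp.csc_matrix(np.column_stack(cols))

    def indicator(labels):
        levels, codes = np.unique(labels, return_inverse=True)
        Zm = sp.csc_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
        )
        return list(levels), Zm

    Z, levels, dropped = {}, {}, []
    for term in spec.random_terms:
        if term == "env":
            labels = obs["trial_id"].to_numpy()
        elif term == "block":
            labels = (obs["trial_id"] + "/" + obs["block_id"]).to_numpy()
        elif term == "genotype":
            labels = np.where(is_check, "__check__", obs["genotype_id"])
        elif term == "ge":
            labels = (obs["genotype_id"] + "@" + obs["trial_id"]).to_numpy()
        else:
            raise ValueError(f"unknown random term {term!r}")
        lev, Zm = indicator(labels)
        if term == "genotype" and "__check__" in lev:
            keep = [i for i, l in enumerate(lev) if l != "__check__"]
            Zm = Zm[:, keep]
            lev = [lev[i] for i in keep]
        if len(lev) < 2:
            warnings.warn(f"random term {term!r} has <2 levels; dropped", stacklevel=2)
            dropped.append(term)
            continue
        Z[term] = Zm.tocsc()
        levels[term] = lev

    counts = obs.loc[~is_check].groupby("genotype_id").size().to_numpy(dtype=float)
    if len(counts) == 0:
        counts = obs.groupby("genotype_id").size().to_numpy(dtype=float)
    r = float(len(counts) / np.sum(1.0 / counts) / e)
    return Design(trait, y, X, fixed_names, Z, levels, e, r, dropped)


class _REMLObjective:
    """Profiled -2 log restricted likelihood over log variance ratios."""

    def __init__(self, design: Design):
        self.terms = list(design.Z)
        W = sp.hstack([design.X] + [design.Z[t] for t in self.terms]).tocsc()
        self.p = design.X.shape[1]
        self.q = [design.Z[t].shape[1] for t in self.terms]
        self.n = len(design.y)
        self.dim = W.shape[1]
        self.WtW = (W.T @ W).tocsc()
        self.Wty = np.asarray(W.T @ design.y).ravel()
        self.yty = float(design.y @ design.y)
        self.dense = self.dim <= _DENSE_CUTOFF
        if self.dense:
            self.WtW_dense = self.WtW.toarray()
        offsets = np.cumsum([self.p] + self.q)
        self.slices = [slice(offsets[i], offsets[i + 1]) for i in range(len(self.q))]

    def _solve(self, log_gamma):
        gamma = np.exp(log_gamma)
        d = np.zeros(self.dim)
        for s, g in zip(self.slices, gamma):
            d[s] = 1.0 / g
        if self.dense:
            M = self.WtW_dense + np.diag(d)
            c, low = sla.cho_factor(M, check_finite=False)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            sol = sla.cho_solve((c, low), self.Wty, check_finite=False)
        else:
            M = self.WtW + sp.diags(d)
            lu = spla.splu(
                M.tocsc(), permc_spec="MMD_AT_PLUS_A",
                options=dict(SymmetricMode=True),
            )
            logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            sol = lu.solve(self.Wty)
        return gamma, logdet, sol

    def neg2_loglik(self, log_gamma):
        gamma, logdet, sol = self._solve(log_gamma)
        rss = self.yty - self.Wty @ sol
        npf = self.n - self.p
        if rss <= 0:
            return np.inf
        s2 = rss / npf
        pen = sum(q * lg for q, lg in zip(self.q, log_gamma))
        return npf * np.log(s2) + logdet + pen + npf * (1.0 + np.log(2.0 * np.pi))

    def finalize(self, log_gamma):
        gamma, logdet, sol = self._solve(log_gamma)
        rss = self.yty - self.Wty @ sol
        s2 = rss / (self.n - self.p)
        beta = sol[: self.p]
        u = {t: sol[s] for t, s in zip(self.terms, self.slices)}
        sigma2 = {t: float(g * s2) for t, g in zip(self.terms, gamma)}
        sigma2["residual"] = float(s2)
        return beta, u, sigma2


def fit_reml(design: Design, *, max_iter: int = 500) -> ModelFit:
    """Estimate variance components by REML and solve for BLUPs.

    Components are kept non-negative by optimising log variance ratios on
    a bounded box; a ratio pinned at the lower bound is a boundary (zero)
    estimate.  The optimum from L-BFGS-B is polished with Nelder-Mead so
    balanced-design fits agree with closed-form ANOVA estimators to
    tight tolerance.
    """
    if np.var(design.y) == 0:
        raise ValueError("response has zero variance")
    obj = _REMLObjective(design)
    k = len(obj.terms)
    if k == 0:
        raise ValueError("no random terms left in the design")
    x0 = np.full(k, np.log(0.5))
    bounds = [(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * k
    res = optimize.minimize(
        obj.neg2_loglik, x0, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=max_iter, ftol=1e-12, gtol=1e-8),
    )
    polish = optimize.minimize(
        obj.neg2_loglik, res.x, method="Nelder-Mead",
        options=dict(maxiter=200 * k, xatol=1e-9, fatol=1e-10),
    )
    best = polish if polish.fun <= res.fun else res
    x = np.clip(best.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
    beta, u, sigma2 = obj.finalize(x)

    fixed = pd.Series(beta, index=design.fixed_names)
    blups = {
        t: pd.Series(u[t], index=design.levels[t], name=design.trait)
        for t in obj.terms
    }
    return ModelFit(
        trait=design.trait,
        variance_components=sigma2,
        fixed_estimates=fixed,
        blups=blups,
        reml_loglik=-0.5 * float(best.fun),
        converged=bool(res.success or polish.success),
        n_trials_used=design.n_trials_used,
        effective_replication=design.effective_replication,
        n_obs=obj.n,
        dropped_terms=design.dropped_terms,
    )


def fit_trait(ds: Dataset, trait: str,
              random_terms: tuple[str, ...] = RANDOM_TERMS) -> ModelFit:
    """Convenience wrapper: build the design for `trait` and fit it."""
    return fit_reml(build_design(ds, ModelSpec(trait, random_terms)))


def lrt_term(ds: Dataset, spec: ModelSpec, term: str,
             full_fit: ModelFit | None = None) -> LRTResult:
    """Deviance test of one random term: chi2 = 2(l_full - l_reduced), 1 df.

    The chi-square p-value is taken from the plain chi2(1) upper tail at
    the 1% level.  Because the null pins a variance at the boundary of
    its parameter space this is conservative; no 50:50 mixture correction
    is applied.
    """
    if full_fit is None:
        full_fit = fit_reml(build_design(ds, spec))
    reduced = fit_reml(build_design(ds, spec.without(term)))
    chi = max(0.0, 2.0 * (full_fit.reml_loglik - reduced.reml_loglik))
    p = float(stats.chi2.sf(chi, df=1))
    return LRTResult(term, chi, 1, p, p < 0.01)


def blup_table(fits: list[ModelFit], *, include_checks: bool = False) -> pd.DataFrame:
    """Genotype x trait table of BLUP + intercept.

    Default rows are the unreplicated test genotypes (checks are fixed
    effects); with ``include_checks`` the checks appear as intercept +
    estimated check effect.  A genotype absent from one trait's fit
    leaves that cell missing.
    """
    cols = {}
    for fit in fits:
        s = fit.blup_plus_intercept()
        if include_checks:
            chk = {
                name[len("check["):-1]: fit.intercept + val
                for name, val in fit.fixed_estimates.items()
                if name.startswith("check[")
            }
            s = pd.concat([s, pd.Series(chk)])
        cols[fit.trait] = s
    return pd.DataFrame(cols).sort_index()
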