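"""Trait correlations and the regularised partial-correlation network.

All three analyses run on the genotype x trait table of BLUP + intercept
values: pairwise-complete Pearson correlations with t-tests, an ordering
of traits by agglomerative clustering of 1 - r (the layout of a
clustered correlogram), and a Gaussian graphical model — partial
correlations from a graphical-lasso precision estimate whose penalty is
selected by the extended BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.covariance import graphical_lasso

__all__ = ["CorrelationMatrix", "TraitNetwork", "pearson_matrix",
           "order_correlogram", "partial_correlation_network"]


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean mask of cells with p < alpha (off-diagonal)."""
        sig = self.p < alpha
        np.fill_diagonal(sig.values, False)
        return sig


@dataclass
class TraitNetwork:
    nodes: list[str]
    weights: pd.DataFrame          # partial correlations, zero diagonal
    penalty: float
    ebic: float

    def edges(self) -> pd.DataFrame:
        rows = []
        w = self.weights
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                val = w.at[a, b]
                if val != 0.0:
                    rows.append((a, b, float(val), "+" if val > 0 else "-"))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight", "sign"])


def pearson_matrix(blups: pd.DataFrame, min_pairs: int = 3,
                   p_adjust: str | None = None) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with t-test p-values.

    p follows t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom,
    two-sided.  No multiple-testing correction is applied by default;
    ``p_adjust`` accepts any statsmodels method name (e.g. 'holm',
    'fdr_bh') to adjust the off-diagonal p-values as one family.  A
    trait constant over the complete pairs gets a missing correlation
    and a warning.
    """
    traits = list(blups.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    X = blups.to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = int(np.isfinite(X[:, i]).sum())
    for i in range(k):
        for j in range(i + 1, k):
            m = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            nij = int(m.sum())
            n[i, j] = n[j, i] = nij
            if nij < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} complete pairs for "
                    f"{traits[i]!r} x {traits[j]!r}"
                )
            xi, xj = X[m, i], X[m, j]
            if xi.std() == 0 or xj.std() == 0:
                warnings.warn(
                    f"constant trait in pair {traits[i]!r} x {traits[j]!r}; "
                    "correlation undefined", stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = min(1.0, max(-1.0, rij))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((nij - 2) / (1.0 - rij**2))
                pij = 2.0 * float(stats.t.sf(abs(t), df=nij - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(k, 1)
        raw = p[iu]
        ok = np.isfinite(raw)
        adj = raw.copy()
        if ok.any():
            adj[ok] = multipletests(raw[ok], method=p_adjust)[1]
        p[iu] = adj
        p.T[iu] = adj
    np.fill_diagonal(p, 1.0)  # convention: diagonal carries no test
    return CorrelationMatrix(
        traits,
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
        pd.DataFrame(n, index=traits, columns=traits),
    )


def order_correlogram(cm: CorrelationMatrix, method: str = "average") -> list[str]:
    """Trait ordering by hierarchical clustering on distance 1 - r."""
    if len(cm.traits) <= 2:
        return list(cm.traits)
    d = 1.0 - cm.r.to_numpy(copy=True)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    leaves = hierarchy.leaves_list(link)
    return [cm.traits[i] for i in leaves]


def _constrained_mle(S, support, max_iter=200, tol=1e-8):
    """Gaussian graphical-model MLE with a fixed edge set.

    Modified-regression / iterative-proportional-fitting scheme: cycle
    over nodes, regressing each on its graph neighbours only, until the
    working covariance stabilises.  Returns the precision matrix, which
    is exactly zero off the support.
    """
    k = S.shape[0]
    W = S.copy()
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(k):
            idx = [i for i in range(k) if i != j]
            nb = [i for i in idx if support[i, j]]
            w12 = np.zeros(k - 1)
            if nb:
                pos = [idx.index(i) for i in nb]
                W11 = W[np.ix_(idx, idx)]
                beta_nb = np.linalg.solve(W11[np.ix_(pos, pos)], S[nb, j])
                w12 = W11[:, pos] @ beta_nb
            W[idx, j] = w12
            W[j, idx] = w12
        if np.max(np.abs(W - W_old)) < tol * np.mean(np.abs(np.diag(S))):
            break
    prec = np.linalg.inv(W)
    mask = ~support
    np.fill_diagonal(mask, False)
    prec[mask] = 0.0
    prec = (prec + prec.T) / 2.0
    return prec


def _ebic(S, prec, n, gamma):
    k = S.shape[0]
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return np.inf
    ll = n / 2.0 * (logdet - np.trace(S @ prec))
    edges = int((np.abs(prec[np.triu_indices(k, 1)]) > 1e-10).sum())
    return -2.0 * ll + edges * np.log(n) + 4.0 * gamma * edges * np.log(k)


def partial_correlation_network(
    blups: pd.DataFrame,
    *,
    n_penalties: int = 50,
    penalty_range: tuple[float, float] = (1e-2, 1.0),
    ebic_gamma: float = 0.5,
    standardize: bool = True,
) -> TraitNetwork:
    """Sparse partial-correlation network via graphical lasso + EBIC.

    A log-spaced grid of l1 penalties is fitted on the (standardised)
    trait covariance; each distinct edge set along the path is refit as
    the graph-constrained maximum-likelihood precision (so shrinkage
    does not leak into model comparison) and scored with the extended
    BIC (gamma = 0.5 by default).  The winning precision Theta is
    converted to partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj).
    Rows with any missing trait are dropped first.
    """
    data = blups.dropna().to_numpy(dtype=float)
    n, k = data.shape
    if n <= k:
        warnings.warn("fewer complete genotypes than traits; the penalty "
                      "grid must stay away from zero", stacklevel=2)
    if standardize:
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant trait; remove it before network fitting")
        data = (data - data.mean(axis=0)) / sd
    S = np.cov(data, rowvar=False)
    alphas = np.logspace(np.log10(penalty_range[0]), np.log10(penalty_range[1]),
                         n_penalties)
    best = None
    seen_supports = set()
    for a in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec_pen = graphical_lasso(S, alpha=float(a), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        support = np.abs(prec_pen) > 1e-8
        np.fill_diagonal(support, True)
        key = support[np.triu_indices(k, 1)].tobytes()
        if key in seen_supports:
            continue
        seen_supports.add(key)
        prec = _constrained_mle(S, support)
        crit = _ebic(S, prec, n, ebic_gamma)
        if best is None or crit < best[0]:
            best = (crit, float(a), prec)
    if best is None:
        raise ValueError("graphical lasso failed on the whole penalty grid; "
                         "use a nonzero penalty range")
    crit, alpha, prec = best
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor[np.abs(pcor) < 1e-10] = 0.0
    traits = list(blups.columns)
    return TraitNetwork(
        traits, pd.DataFrame(pcor, index=traits, columns=traits), alpha, crit
    )
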