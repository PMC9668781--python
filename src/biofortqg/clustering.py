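"""Germplasm diversity: PCA, successive K-means with BIC, group contrasts.

Genotypes are clustered on principal-component scores of their (z-scored)
BLUP profiles by running K-means at every k in a range and keeping the
solution with the lowest BIC,

    BIC(k) = n ln(WSS_k / n) + k ln(n),

with ties resolved toward the smaller k.  Cluster trait summaries come
with all pairwise Welch comparisons, Holm-adjusted within each trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterSolution", "pca_scores", "kmeans_bic", "kmeans_bic_scan",
           "summarize_clusters", "holm_adjust"]


@dataclass
class ClusterSolution:
    k_selected: int
    assignments: pd.Series            # genotype -> 1-based cluster label
    bic_curve: pd.Series              # k -> BIC
    wss_curve: pd.Series              # k -> within-cluster sum of squares
    pca_scores: pd.DataFrame

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def pca_scores(blups: pd.DataFrame, *, standardize: bool = True,
               n_components: int | None = None,
               impute_missing: bool = True) -> pd.DataFrame:
    """Principal-component scores of the genotype x trait table.

    Traits are z-scored by default (units are incommensurable: t/ha
    against 1-9 scores).  Missing cells are mean-imputed per trait (the
    imputed fraction is logged via a warning when above zero) because
    K-means needs complete vectors.  Component signs follow the
    largest-absolute-loading-positive convention so results are
    reproducible across linear-algebra backends.
    """
    if blups.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    X = blups.to_numpy(dtype=float)
    miss = ~np.isfinite(X)
    if miss.any():
        if not impute_missing:
            raise ValueError("missing cells present and imputation disabled")
        warnings.warn(
            f"mean-imputing {miss.mean():.1%} of BLUP cells before PCA",
            stacklevel=2,
        )
        col_mean = np.nanmean(X, axis=0)
        X = np.where(miss, col_mean, X)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = n_components or min(X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=blups.index,
                        columns=[f"PC{j + 1}" for j in range(scores.shape[1])])


def kmeans_bic(wss: float, n: int, k: int, d: int = 1) -> float:
    """BIC of a K-means partition: n ln(WSS/n) + k d ln(n).

    ``d`` counts the free parameters per cluster.  The default scan uses
    d = number of score dimensions (each centroid contributes d
    coordinates), which penalises extra clusters enough for the lowest
    BIC to sit at the true k on well-separated data; d = 1 gives the
    lighter one-parameter-per-cluster form, whose minimum keeps drifting
    to larger k as K-means shaves marginal within-cluster variance.
    """
    if wss <= 0:
        raise ValueError("within-cluster sum of squares must be > 0")
    return n * np.log(wss / n) + k * d * np.log(n)


def kmeans_bic_scan(scores: pd.DataFrame, *, k_min: int = 2, k_max: int = 15,
                    n_restarts: int = 25, seed: int = 0,
                    bic_params_per_cluster: int | None = None) -> ClusterSolution:
    """Successive K-means over k = k_min..k_max, lowest BIC wins.

    Each k runs ``n_restarts`` k-means++ initialisations keeping the best
    within-cluster sum of squares; everything is reproducible under the
    root seed.  Exact BIC ties break toward the smaller k.  The BIC
    penalty counts ``bic_params_per_cluster`` parameters per cluster
    (default: the score dimensionality, see :func:`kmeans_bic`).
    """
    X = scores.to_numpy(dtype=float)
    n = len(X)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"k range [{k_min}, {k_max}] invalid for n = {n}")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical; clustering is degenerate")
    d = bic_params_per_cluster or X.shape[1]
    rng = np.random.default_rng(seed)
    bic, wss_all, labels_all = {}, {}, {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(X)
        wss = float(km.inertia_)
        wss_all[k] = wss
        bic[k] = kmeans_bic(wss, n, k, d)
        labels_all[k] = lab
    bic_s = pd.Series(bic).sort_index()
    k_sel = int(bic_s.idxmin())  # idxmin takes the first (smallest k) on ties
    return ClusterSolution(
        k_selected=k_sel,
        assignments=pd.Series(labels_all[k_sel] + 1, index=scores.index,
                              name="cluster"),
        bic_curve=bic_s,
        wss_curve=pd.Series(wss_all).sort_index(),
        pca_scores=scores,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="holm")[1]


def summarize_clusters(solution: ClusterSolution,
                       blups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptives per cluster x trait plus Holm-adjusted pairwise tests.

    Returns ``(summary, comparisons)``.  Comparisons are Welch two-sample
    t-tests between every cluster pair, adjusted by Holm within each
    trait family and starred at 0.05 / 0.01 / 0.001.  Clusters with fewer
    than two members are excluded from testing with a warning.
    """
    lab = solution.assignments.reindex(blups.index)
    rows = []
    for cl, idx in blups.groupby(lab).groups.items():
        sub = blups.loc[idx]
        for trait in blups.columns:
            v = sub[trait].dropna()
            rows.append({
                "cluster": int(cl), "trait": trait, "n": len(v),
                "mean": v.mean(), "median": v.median(),
                "q25": v.quantile(0.25), "q75": v.quantile(0.75),
            })
    summary = pd.DataFrame(rows)

    sizes = lab.value_counts()
    testable = sorted(int(c) for c in sizes.index[sizes >= 2])
    if len(testable) < len(sizes):
        warnings.warn("clusters of size < 2 excluded from pairwise tests",
                      stacklevel=2)
    comps = []
    for trait in blups.columns:
        fam = []
        for i, a in enumerate(testable):
            for b in testable[i + 1:]:
                va = blups.loc[lab == a, trait].dropna()
                vb = blups.loc[lab == b, trait].dropna()
                if len(va) < 2 or len(vb) < 2 or (va.std() == 0 and vb.std() == 0):
                    continue
                t, p = stats.ttest_ind(va, vb, equal_var=False)
                fam.append({"trait": trait, "cluster_a": a, "cluster_b": b,
                            "mean_a": va.mean(), "mean_b": vb.mean(),
                            "t": float(t), "p_raw": float(p)})
        if fam:
            adj = holm_adjust([f["p_raw"] for f in fam])
            for f, pa in zip(fam, adj):
                f["p_holm"] = float(pa)
                f["stars"] = ("***" if pa < 0.001 else "**" if pa < 0.01
                              else "*" if pa < 0.05 else "")
            comps.extend(fam)
    comparisons = pd.DataFrame(
        comps, columns=["trait", "cluster_a", "cluster_b", "mean_a", "mean_b",
                        "t", "p_raw", "p_holm", "stars"],
    )
    return summary, comparisons
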