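"""Simulation studies that validate the pipeline end to end.

Each study generates data with known ground truth via
:mod:`biofortqg.simulate`, runs the corresponding estimation stage, and
summarises how well the truth is recovered.  They are used by the test
suite and by ``scripts/acceptance.py``; sizes default to the study
conditions the package documents (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import kmeans_bic_scan, pca_scores
from .genetics import heritability_from_fit
from .lmm import ModelSpec, build_design, fit_reml, fit_trait, lrt_term
from .network import partial_correlation_network
from .simulate import generate_dataset, small_config

__all__ = ["reml_recovery_study", "lrt_null_calibration",
           "network_recovery_study", "clustering_recovery_study"]

# carotenoid-content generating values: genotype 5.44, no GxE, residual 2.16
TCC_COMPONENTS = dict(genotype=5.44, ge=0.0, residual=2.16)


def reml_recovery_study(*, n_seeds: int = 20, n_genotypes: int = 300,
                        n_trials: int = 6, n_blocks: int = 5,
                        seed: int = 0) -> dict:
    """Simulate the carotenoid-content trial series and refit by REML.

    Returns mean estimated components over seeds, their relative errors
    against the generating values, and the mean plot-basis heritability
    (true value 5.44 / (5.44 + 2.16) = 0.72).
    """
    cfg = small_config(n_genotypes=n_genotypes, n_checks=5, n_trials=n_trials,
                       n_blocks=n_blocks, traits=("TCC",), **TCC_COMPONENTS)
    rows = []
    for i in range(n_seeds):
        ds, _ = generate_dataset(cfg, seed=seed + i)
        fit = fit_trait(ds, "TCC")
        vc = fit.variance_components
        rows.append({**vc, "h2": heritability_from_fit(fit).h2})
    res = pd.DataFrame(rows).mean()
    true_g, true_e = TCC_COMPONENTS["genotype"], TCC_COMPONENTS["residual"]
    return {
        "mean_sigma2_g": float(res["genotype"]),
        "mean_sigma2_ge": float(res["ge"]),
        "mean_sigma2_e": float(res["residual"]),
        "rel_err_sigma2_g": float(abs(res["genotype"] - true_g) / true_g),
        "rel_err_sigma2_e": float(abs(res["residual"] - true_e) / true_e),
        "mean_h2": float(res["h2"]),
        "n_seeds": n_seeds,
        "n_genotypes": n_genotypes,
    }


def lrt_null_calibration(*, n_reps: int = 1000, seed: int = 0,
                         alpha: float = 0.01) -> dict:
    """Rejection rate of the genotype-variance deviance test under the null.

    Small trials (30 genotypes, 2 trials, 2 blocks) simulated with zero
    genotype variance; the chi2(1) test at ``alpha`` should reject at or
    below its nominal level because the null pins the variance at the
    boundary of the parameter space.
    """
    cfg = small_config(n_genotypes=30, n_checks=3, n_trials=2, n_blocks=2,
                       traits=("Y",), genotype=0.0, ge=0.3, residual=1.0,
                       env=1.0, block=0.25)
    rejections = 0
    spec = ModelSpec("Y")
    for i in range(n_reps):
        ds, _ = generate_dataset(cfg, seed=seed + i)
        full = fit_reml(build_design(ds, spec))
        res = lrt_term(ds, spec, "genotype", full_fit=full)
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps,
            "nominal_level": alpha}


def _random_sparse_precision(rng, p: int, n_edges: int):
    prec = np.eye(p)
    pairs = set()
    while len(pairs) < n_edges:
        i, j = sorted(rng.integers(0, p, 2))
        if i != j:
            pairs.add((i, j))
    for i, j in pairs:
        prec[i, j] = prec[j, i] = rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 0.4)
    w = np.linalg.eigvalsh(prec)
    if w.min() < 0.1:  # keep well conditioned
        prec += (0.1 - w.min()) * np.eye(p)
    return prec, pairs


def network_recovery_study(*, n_seeds: int = 10, n: int = 500, p: int = 12,
                           n_edges: int = 12, seed: int = 0) -> dict:
    """Edge recovery of the partial-correlation network on known graphs."""
    recalls, false_rates = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        prec, true_edges = _random_sparse_precision(rng, p, n_edges)
        X = rng.multivariate_normal(np.zeros(p), np.linalg.inv(prec), size=n)
        net = partial_correlation_network(
            pd.DataFrame(X, columns=[f"t{i}" for i in range(p)]))
        W = net.weights.to_numpy()
        est = {(i, j) for i in range(p) for j in range(i + 1, p) if W[i, j] != 0}
        recalls.append(len(est & true_edges) / len(true_edges))
        false_rates.append(len(est - true_edges) / len(est) if est else 0.0)
    return {"edge_recall": float(np.mean(recalls)),
            "false_edge_rate": float(np.mean(false_rates)),
            "n_seeds": n_seeds, "n": n, "p": p}


def clustering_recovery_study(*, n_seeds: int = 10, k_true: int = 6,
                              n_per_cluster: int = 40, p: int = 11,
                              separation: float = 4.0, seed: int = 0) -> dict:
    """How often the K-means/BIC scan finds the simulated group count."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        centers = rng.normal(0.0, separation, size=(k_true, p))
        X = np.vstack([rng.normal(c, 1.0, size=(n_per_cluster, p))
                       for c in centers])
        df = pd.DataFrame(X, index=[f"G{i:04d}" for i in range(len(X))])
        sol = kmeans_bic_scan(pca_scores(df), k_min=2, k_max=15, seed=seed + s)
        hits += sol.k_selected == k_true
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds,
            "k_true": k_true, "n": k_true * n_per_cluster}
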