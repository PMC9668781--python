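"""Economic-weight selection index, parent choice and the gain report.

The index of a genotype is the weighted sum of its BLUP + intercept
values, SI_g = sum_t w_t b_gt, with the breeding-programme weights
(carotenoid content and pulp colour +30, cyanogenic score -30, yields
+10, quality traits +5).  A rank-summation variant (Mulamba & Mock
style) is available: each trait is ranked in its favourable direction
and SI is the |w|-weighted rank sum.  The top-n genotypes (default 30)
form the parent set, and the report lists per-trait selected means,
population means, selection differentials and predicted gains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import genetic_gain
from .reference import DEFAULT_INDEX_WEIGHTS, DEFAULT_N_SELECTED

__all__ = ["SelectionResult", "compute_index", "select_parents", "gain_report",
           "run_selection"]


@dataclass
class SelectionResult:
    index_scores: pd.Series
    ranking: list[str]
    selected: list[str]
    report: pd.DataFrame


def compute_index(blups: pd.DataFrame, weights: dict | None = None, *,
                  standardize: bool = False, mode: str = "blup") -> pd.Series:
    """Selection-index score per genotype.

    mode='blup' (default): SI = sum_t w_t * value_gt on the raw BLUP +
    intercept scale, optionally z-scoring each trait first (raw weighted
    sums are unit-dependent).  mode='rank': each trait is ranked with
    rank 1 least favourable — ascending in the trait value for positive
    weights, descending for negative ones (a low cyanogenic score is
    favourable) — and SI = sum_t |w_t| * rank_gt.  Genotypes missing any
    weighted trait are excluded with a warning; an index over unequal
    trait sets is not comparable.
    """
    w = dict(DEFAULT_INDEX_WEIGHTS if weights is None else weights)
    if not any(v != 0 for v in w.values()):
        raise ValueError("at least one weight must be nonzero")
    unknown = [t for t in w if t not in blups.columns]
    if unknown:
        raise ValueError(f"weights refer to unknown traits {unknown}")
    cols = list(w)
    data = blups[cols].copy()
    incomplete = data.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"excluding {int(incomplete.sum())} genotype(s) with missing "
            "values on weighted traits", stacklevel=2,
        )
        data = data.loc[~incomplete]
    if mode == "rank":
        ranked = pd.DataFrame(index=data.index)
        for t in cols:
            ranked[t] = data[t].rank(ascending=w[t] >= 0, method="average")
        scores = sum(abs(w[t]) * ranked[t] for t in cols)
    elif mode == "blup":
        if standardize:
            data = (data - data.mean()) / data.std(ddof=1)
        scores = sum(w[t] * data[t] for t in cols)
    else:
        raise ValueError("mode must be 'blup' or 'rank'")
    return scores.rename("SI")


def select_parents(scores: pd.Series, n: int = DEFAULT_N_SELECTED) -> list[str]:
    """Top-n genotypes by index score; ties break lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(scores):
        warnings.warn("n exceeds the population; selecting everyone", stacklevel=2)
        n = len(scores)
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:n])


def gain_report(blups: pd.DataFrame, selected, heritabilities: dict,
                population_means: dict | None = None) -> pd.DataFrame:
    """Per-trait selected mean, population mean, S, G and G%.

    ``heritabilities`` maps trait -> clonal-mean heritability used in
    G = h2m * S.  A trait without one still gets its means and S; G is
    left missing.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set is empty")
    rows = []
    for trait in blups.columns:
        col = blups[trait].dropna()
        pop_mean = (population_means or {}).get(trait, float(col.mean()))
        sel_mean = float(col.loc[[g for g in selected if g in col.index]].mean())
        S = sel_mean - pop_mean
        h2m = heritabilities.get(trait)
        if h2m is None:
            G = G_pct = np.nan
        else:
            est = genetic_gain(col, selected, h2m, pop_mean, trait)
            G, G_pct = est.G, est.G_pct
        rows.append({"trait": trait, "selected_mean": sel_mean,
                     "population_mean": pop_mean, "S": S,
                     "h2m": np.nan if h2m is None else h2m,
                     "G": G, "G_pct": G_pct})
    return pd.DataFrame(rows).set_index("trait")


def run_selection(blups: pd.DataFrame, heritabilities: dict,
                  weights: dict | None = None, n: int = DEFAULT_N_SELECTED,
                  mode: str = "blup") -> SelectionResult:
    """Index, ranking, parent set and gain report in one call."""
    scores = compute_index(blups, weights, mode=mode)
    ranking = select_parents(scores, n=len(scores))
    selected = ranking[:min(n, len(ranking))]
    report = gain_report(blups, selected, heritabilities)
    return SelectionResult(scores, ranking, selected, report)
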