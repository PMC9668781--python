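# biofortqg

Quantitative-genetic evaluation of biofortified cassava germplasm from
multi-environment augmented-block trials.

Cassava breeding programmes screen large germplasm panels — typically a few
hundred unreplicated test clones grown alongside replicated check cultivars
in augmented blocks across many trial-years — for root quality (total
carotenoid content, dry-matter content, starch, pulp colour, cyanogenic
score) and agronomic performance (fresh/dry root yield, shoot yield, harvest
index, roots per plant). This package implements the full analysis such a
programme needs to pick parents for a biofortification breeding cycle:

1. **Trait derivation** (`biofortqg.traits`) — gravimetric dry-matter content
   from the air/water weighing regression `DMC = 158.3·Wair/(Wair−Wwater) − 142`,
   oven-dry DMC `= 100 − humidity%`, total carotenoid content
   `TCC = A·V·10⁴/(A¹%₁cₘ·P)` with the β-carotene extinction coefficient 2592,
   harvest index, dry root yield, t/ha conversions, sweet/bitter HCN
   classification.
2. **Mixed model per trait** (`biofortqg.lmm`) — REML fit of
   `y_ijk = µ + T_k′ + E_i + B_(i)j + T_(j)k + GE_ik + ε_ijk` with fixed
   checks `T_k′` and random environments, blocks, test genotypes and G×E;
   BLUPs from Henderson's equations; χ²₁ deviance tests of each random term
   at the 1 % level.
3. **Genetic parameters** (`biofortqg.genetics`) — broad-sense heritability
   `h² = σ²g/(σ²g+σ²ge+σ²e)`, clonal-mean heritability
   `h²ₘ = σ²g/(σ²g+σ²ge/e+σ²e/(re))`, and predicted gain `G = h²ₘ·S`.
4. **Trait networks** (`biofortqg.network`) — pairwise-complete Pearson
   correlations with `t = r√((n−2)/(1−r²))` tests, clustered-correlogram
   ordering, and an EBIC-selected graphical-lasso partial-correlation network.
5. **Diversity clustering** (`biofortqg.clustering`) — PCA of z-scored BLUP
   profiles, successive K-means over k = 2..15 with lowest-BIC selection, and
   Holm-adjusted pairwise cluster comparisons.
6. **Index selection** (`biofortqg.selection`) — the weighted-BLUP index
   `SI = Σ_t w_t·BLUP_t` (weights: TCC and PulpColor +30, HCN −30, FRY and
   DRY +10, others +5), top-30 parent choice, and the gain report.

Because panels like this are rarely deposited, `biofortqg.simulate` generates
augmented-design datasets from the very model the pipeline fits, with known
genotype effects, published variance-component magnitudes, a realistic
trait-correlation structure, carotenoid measurements restricted to two
trial-years, and raw measurements backfilled so even the derivation step is
exercised. Every stage is validated against this ground truth
(`biofortqg.evaluation`).

## Worked example

The analysis is organised as numbered drivers that run the pipeline end to
end on a simulated panel (120 genotypes × 8 trials at the default demo
scale; pass `--full` to `01_simulate.py` for the 265 × 21 design):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_derive_traits.py
python analysis/03_fit_mixed_models.py
python analysis/04_genetic_parameters.py
python analysis/05_correlation_network.py
python analysis/06_cluster_diversity.py
python analysis/07_select_parents.py
```

`03_fit_mixed_models.py` prints one line per trait, e.g.

```
TCC        e= 2  s2_g=  6.269  s2_ge=  0.039  s2_e=  2.156  h2=0.74  h2m=0.85
DMC.Grav   e= 8  s2_g=  5.842  s2_ge=  4.037  s2_e=  2.034  h2=0.49  h2m=0.89
HCN        e= 8  s2_g=  1.424  s2_ge=  0.409  s2_e=  0.568  h2=0.59  h2m=0.92
```

— carotenoid content was only measured in two trials (`e = 2`), and the
fitted components sit on top of the generating values (σ²g = 5.44,
σ²ge = 0, σ²e = 2.16 for TCC), giving h² ≈ 0.72-0.74. The final driver
reports the predicted response to recombining the 30 selected parents:

```
trait      selected_mean  population_mean      S    h2m      G   G_pct
TCC                5.792            3.684  2.108  0.851  1.794  48.683
HCN                5.756            6.506 -0.751  0.921 -0.691 -10.624
```

i.e. selection on the weighted-BLUP index is predicted to raise carotenoid
content sharply while lowering the cyanogenic score — the core goal of a
sweet-cassava biofortification programme.

## Layout

```
src/biofortqg/      library: io, traits, simulate, lmm, genetics,
                    network, clustering, selection, evaluation, reference
analysis/           numbered pipeline drivers (simulate → … → select)
tests/              pytest suite incl. oracle and recovery checks
scripts/acceptance.py
docs/methods.md     models, assumptions, numerical choices, limitations
```
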