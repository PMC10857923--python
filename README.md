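# phenobalance

Chemical-budget analysis of feeding experiments with herbivorous
caterpillars: per-compound ingestion–excretion mass balances, compound-fate
classification, constrained ordination of metabolized-polyphenol profiles,
rank-based host-transfer comparisons, and gut-pH inference from isomer
redistribution — plus a synthetic two-phase experiment generator with full
ground truth, so every analysis stage can be validated end to end.

## Who this is for

Chemical ecologists running leaf/frass feeding trials: you offer leaves of
known polyphenol composition to individual larvae, collect and analyze
their frass, and want to know the fate of every ingested compound, whether
host identity or prior dietary experience shapes metabolism, and what the
isomer chemistry of the frass says about gut conditions.

## The core computations

**Mass balance.** For one caterpillar and one chemical variable
(a compound or an activity measure),

```
X = W_Leaf · C_Leaf − W_Frass · C_Frass        [mg]
```

where `W` are dry masses (g) of leaf eaten and frass produced and `C` are
concentrations (mg/g). `X ≈ 0` means passive excretion, `X > 0` loss in
the gut (uptake, oxidation, hydrolysis, adsorption — the budget cannot
separate these), `X < 0` production in the gut from other substrates. The
dry leaf mass eaten is `fresh_offered / fresh_to_dry − dry_remaining`;
non-feeders (`W_Leaf ≤ 0`) are flagged excluded and never analyzed.

**Constrained ordination.** RDA of a response matrix `Y` on a k-level
factor: fitted values are group means, `R² = SS_fit / SS_total`, adjusted
by the Ezekiel correction `R²_adj = 1 − (1 − R²)(n − 1)/(n − k)`, with
`pseudo-F = (SS_fit/(k−1)) / (SS_res/(n−k))` tested by Monte-Carlo
permutation of response rows, `p = (1 + #{F* ≥ F}) / (n_perm + 1)`.

**Rank statistics.** Bray–Curtis dissimilarity `Σ|u−v| / Σ(u+v)`,
Mann–Whitney U (exact enumeration for small tie-free samples, normal
approximation with tie/continuity corrections otherwise) and tie-corrected
Kruskal–Wallis H.

**Gut pH.** Interconvertible isomers (the caffeoylquinic acids)
re-equilibrate in the alkaline gut; the equilibrium fractions depend on
pH. Observed frass fractions are matched against a pH-indexed model curve
(pH 9.0–11.0, step 0.01) by nearest Euclidean distance. The pH→fractions
mapping is pluggable (JSON anchors/midpoint/slope); the default is a
logistic interpolation between two anchor compositions.

## Worked example

```python
from phenobalance import (balance_table, generate_experiment, percent_loss,
                          retention_estimates, run_gut_ph)

experiment, truth = generate_experiment(seed=0)
table = balance_table(experiment.phase_records(1), experiment.catalog)
hh1 = table[(table.current_host == "carpinus") & (table.variable == "HH1")]
print(round(100 * percent_loss(hh1.ingested.sum(), hh1.excreted.sum()), 1))
# 96.4   -> geraniin is almost completely removed in the gut (true retention 0.98)

est = retention_estimates(table, experiment.catalog)
print(len(est), round(max(abs(est.loc[(h, c), "lambda_hat"] - truth.lambda_base[h][c])
                          for h, c in est.index), 3))
# 41 0.035  -> all 41 identifiable host x compound retentions recovered within 0.035

print(run_gut_ph(experiment).groupby("host").ph.mean().round(2).to_dict())
# {'acer': 9.91, 'carpinus': 9.9, 'quercus': 9.91}  -> true gut pH was 9.9
```

The `examples/` directory has one narrative script per capability
(simulation, budgets and fates, ordination, host-transfer analysis, gut
pH); each prints the numbers it computes with a line on what they mean.
The CLI mirrors the library:

```bash
phenobalance simulate --seed 0 --out exp/
phenobalance run exp/ --nperm 999 --seed 0 --out report/
phenobalance gutph exp/
```

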