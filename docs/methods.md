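# Methods

## The budget model

The unit of analysis is one caterpillar feeding on one host for 24 h. Its
chemical budget for a variable v (a quantified polyphenol, or one of two
assay-derived activity measures) is

    X_v = W_Leaf · C_Leaf,v − W_Frass · C_Frass,v     [mg]

with W the dry masses (g) of leaf tissue eaten and frass produced and C
the concentrations (mg/g dry weight) in the feeding tree's leaves and in
the caterpillar's frass. W_Leaf is derived from the fresh mass offered via
the species' fresh:dry ratio minus the dry mass left uneaten; a
non-positive W_Leaf identifies a non-feeding larva, which is flagged
excluded and barred from every downstream computation (the flag is
monotone: nothing un-excludes a record).

Fates are banded by a relative tolerance: |X| ≤ ε·max(ingested, floor) is
"passive", above it X > 0 is "lost" (removed in the gut — uptake,
oxidation, hydrolysis and adsorption are indistinguishable in a budget)
and X < 0 "produced" (formed in the gut from other substrates). Defaults
ε = 0.1 and floor = 0.01 mg; both are configurable and echoed in report
provenance. The floor keeps the passive band non-degenerate for trace
compounds whose ingested amount is ~0.

The two activity measures (oxidative activity, protein precipitation
capacity, both mg/g of standard equivalents) run through the same W·C
arithmetic as compounds. They are carried alongside compounds in every
analysis but never summed into subgroup totals.

The per-compound gut retention fraction λ (fraction of the ingested amount
removed in the gut) is estimated as the across-caterpillar mean of
X/ingested. Members of an isomer family are pooled before estimating:
isomerization shuffles mass within a family while conserving its total, so
only the family-level fraction is identifiable.

## Ordination

PCA and one-factor RDA are implemented directly on the centered data
matrix. For a factor with k levels the RDA fitted values are the group
means; constrained inertia is their sum of squares, and the decomposition
constrained + residual = total is exact to 1e-8. Variation explained is
reported as the Ezekiel-adjusted R² (constraint df = k − 1), multiplied by
100 when printed as a percentage; it can be negative under a null effect
and is never clipped. Significance uses free Monte-Carlo permutation of
response rows (999 by default): p = (1 + #{F* ≥ F}) / (n_perm + 1), so the
smallest attainable p is 1/(n_perm + 1). Ties F* = F count as exceedances
(conservative). Permutations compare F on the constrained-sum-of-squares
scale, which is equivalent for fixed group sizes and avoids recomputing
the full statistic.

Concentration matrices are log(1+x)-transformed before ordination. Balance
(X) matrices contain negative values; they are analyzed untransformed by
default, with a signed-log1p option (`PipelineConfig.x_transform`) for
heavy-tailed budgets — which convention the original analyses used is not
derivable from their description, so the package states its own.

## Rank statistics

Mann–Whitney U reports the rank-sum-based W convention (U of the first
sample). With pooled n ≤ 12 and no ties the two-sided p is exact, by
enumeration of all C(n, n_x) rank assignments; otherwise a normal
approximation with midranks, tie correction and continuity correction is
used. Kruskal–Wallis uses the tie-corrected H against chi-square with
k − 1 df. Bray–Curtis dissimilarity operates on raw (untransformed) mean
species profiles, on either the per-compound basis or the four subgroup
totals + two activities basis: the index is defined on abundances, and
raw mg/g is the abundance scale here.

The Phase-II retained-biomass comparisons report both a Kruskal–Wallis
test across the three origin groups within a current host and pairwise
Mann–Whitney tests; the two families of statistics answer slightly
different questions and both appear in the per-host report.

## Gut-pH model

The pH signal is carried by the *fractions* of an interconvertible isomer
family (default: the three caffeoylquinic acids), not by amounts, making
it robust to how much of the family was ingested or retained. The
pH→fractions mapping is pluggable; the default is

    f(pH) = normalize(anchor_low + (anchor_high − anchor_low) · σ((pH − m)/s))

with anchors at the ends of the 9.0–11.0 grid, midpoint m = 10.0, slope
s = 0.25 pH units, grid step 0.01. Published equilibrium calibrations can
be supplied as JSON (anchors/midpoint/slope) to reproduce a specific
laboratory mapping; the defaults are this package's design choice, and no
empirical pH value is asserted from them. Estimation is a grid argmin of
Euclidean distance, ties broken toward lower pH. The logistic is injective
on the grid, so noiseless round-trips invert exactly.

Identifiability caveat: the logistic saturates toward the grid ends, so
estimates are precise near the transition (around the midpoint ± ~0.5 pH)
and progressively less identifiable in the flat tails. The noise
robustness demonstrated by the tests (±0.1 pH at fraction noise sd 0.02)
is a statement about the transition region where the synthetic experiments
operate, not about the whole grid.

## The synthetic experiment generator

The generator's defaults are the study design: three host species (a
maple, a hornbeam, an oak) with species-specific compound support sets —
flavonoid glycosides, caffeoylquinic acids and procyanidins dominating the
maple; geraniin dominating the hornbeam; C-glycosidic ellagitannins the
oak — 10/9/11 trees sampled per species, one feeding tree per species,
59/59/65 caterpillars in Phase I and the 10,17,17 / 14,8,9 / 17,14,9
three-way Phase-II split. Activities are fixed linear combinations of
subgroup totals (oxidative activity weighted toward hydrolyzable tannins,
protein precipitation toward proanthocyanidins), applied consistently on
the leaf and frass side so that activity budgets close exactly in the
noiseless limit.

Mechanism per caterpillar: W_Leaf ~ lognormal (mean 0.2 g, CV 0.3);
ingested mg = W_Leaf × feeding-tree concentration × per-compound batch
noise; excreted mg = ingested × (1 − λ); isomer families are then
redistributed to the equilibrium fractions at the true gut pH (9.9) while
conserving family mass; frass dry mass = W_Leaf × (1 − assimilation), with
assimilation 0.36 ± 0.05 — the polyphenol mass fraction is treated as
negligible for bulk bookkeeping, since nothing in the design closes the
bulk-mass/compound-mass loop. Measured frass concentrations get
multiplicative measurement noise. All multiplicative noise is lognormal
with unit mean at the configured CV (tree 0.30, batch 0.15, measurement
0.10); per-caterpillar retention jitter is Gaussian (sd 0.05, clipped to
[0, 1]).

Habituation: transferred (two-host) larvae metabolize less of what they
ingest, λ_two-host = clip(λ_one-host − δ, 0, 1), default δ = 0.15 — the
magnitude is a free parameter chosen to make recovery tests well-powered,
as no quantitative effect size is available. Transferred larvae also
assimilate less bulk mass, by 0.08 × the Bray–Curtis dissimilarity between
the old and new hosts' baseline profiles; this gives the retained-biomass
comparisons a real effect to detect without touching the chemical budgets
(X is independent of assimilation by construction).

What the generator does *not* emulate: within-tree canopy heterogeneity
beyond a single batch CV, time-resolved (8-h) frass collection (one pooled
24-h profile per caterpillar-phase is stored, pooling being an explicit
assumption), compound co-variation beyond subgroup structure, instrument
drift, and any caterpillar growth or performance dynamics. Passing
recovery tests therefore demonstrates correctness of the estimators under
this noise model, not robustness to every failure mode of real
chromatography data.

## Problem sizes and numerical choices

The test suite and acceptance script run at the design scale (183 Phase-I
caterpillars) or below; calibration studies use 1000 simulations × 199
permutations, oracle sweeps 200 random matrices (n ≤ 12, ≤ 6 variables),
paired habituation detection 100 simulation pairs — sizes chosen so the
whole suite completes in minutes on one CPU while keeping Monte-Carlo
standard errors well inside the asserted bands. Degenerate inputs are
contracts, not crashes: constant matrices flag a degenerate PCA, all-zero
profile pairs yield a NaN dissimilarity, an all-zero isomer family yields
a missing pH, and a Phase-II host with fewer than two origin groups is
skipped with a flag. Exact decompositions are asserted at 1e-8–1e-10;
boundary rules follow strict inequalities (prevalence > 0.01 mg/g in
> 25% of samples) so edge cases are excluded, not included.

## Known limitations

- The budget attributes nothing mechanistically; "lost" conflates uptake,
  oxidation, hydrolysis and adsorption.
- Per-isomer retention inside a family is unidentifiable by design; only
  family totals are estimated.
- The default pH anchors are schematic; quantitative pH work requires a
  measured calibration table.
- The reproduction harness expects archived tables mapped onto the package
  CSV schema; it does not guess foreign column layouts.
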