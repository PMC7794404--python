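# Methods

`meltingpot` attributes spatial patterns of within-population genetic
diversity to two candidate drivers — admixture between divergent lineages at
secondary contact zones, and long-term bioclimatic stability near glacial
refugia — and ships a synthetic-data generator that builds complete study
systems with known drivers so the whole chain can be validated end to end.
This note records the models, the estimators, the defaults and the open
design choices.

## Diversity statistics

**Haplotype diversity** uses the unbiased estimator
h = n/(n−1)·(1 − Σ pᵢ²) over haplotype frequencies pᵢ. Sequences that
differ only at N/gap positions are merged into one haplotype, greedily in
input order (the compatibility relation is not transitive; greedy merging is
conservative and deterministic).

**Nucleotide diversity** π is the mean over sequence pairs of
(differences / comparable sites), with *pairwise deletion*: sites carrying N
or a gap in either member of a pair are excluded for that pair only. Pairs
with no comparable site are dropped with a warning. Complete deletion would
be the alternative; pairwise deletion preserves the most data and the two
cannot be distinguished from typical published tables.

**Expected heterozygosity** applies Nei's small-sample correction per locus,
He = 2n/(2n−1)·(1 − Σ pₐ²) with n scored genotypes, averaged over loci; the
uncorrected variant can be requested (`unbiased=False`). **Observed
heterozygosity** is the fraction of scored genotypes with unequal alleles,
averaged over loci.

**Rarefaction allelic richness** is the hypergeometric expectation of the
number of distinct alleles in a subsample of g gene copies,
Ar = Σₐ [1 − C(N−Nₐ, g)/C(N, g)], averaged over loci. The default g is the
global minimum of 2×(scored genotypes) over retained populations and loci —
one comparable subsample size for the whole table. Binomial ratios are
evaluated through log-gamma for numerical safety.

**Hardy–Weinberg testing** uses the conditional probability of the genotype
configuration given the allele counts (Guo & Thompson's statistic) with a
Monte-Carlo permutation null: random re-pairings of the observed allele
pool, p = (1 + hits)/(1 + permutations). Monomorphic loci return p = 1 with
a warning. Bonferroni adjustment is pᵢ′ = min(1, m·pᵢ).

**Filters.** Populations with fewer than `min_n` (default 4) scored
genotypes at *any* locus are excluded, a locus entirely missing counting as
zero. Loci flagged for null alleles in at least `max_flagged` populations
(default 14) are removed; flags are inputs — null-allele detection itself is
out of scope.

## Admixture summaries

Q-matrices (individuals × K cluster proportions, rows summing to 1) come
from external spatial Bayesian clustering. Population admixture is the
arithmetic mean of individual rows, renormalised. The admixture predictor
is **Simpson's diversity index** D = 1 − Σ qₖ² of the population-mean
proportions: 0 for a pure population, approaching 1 − 1/K under even
admixture. The complement form (not the inverse form 1/Σq²) is used because
it is bounded in [0, 1), which keeps the GLM predictor well-scaled. All K
clusters contribute to D; taxonomic restrictions are applied by subsetting
populations, not by dropping clusters.

K is selected from a DIC-versus-K table by a reproducible plateau rule:
mean DIC per K; the chosen K is the smallest whose improvement to K+1 falls
below ε × (max mean − min mean), ε = 0.05 by default. A curve that keeps
falling steeply returns the largest K with a warning. Replicate Q-matrices
are averaged over the `top_m` = 10 lowest-DIC runs; label alignment across
replicates is assumed done upstream, and a maximal-correlation column
matching only *warns* when replicates look switched.

## Ensemble SDM and refugia

Occurrence hygiene removes exact coordinate duplicates and records with
positional uncertainty ≥ 30 arcseconds. Spatial thinning is greedy: while
any pair is closer than d_min, drop the point with the most conflicts,
random tie-break per replicate; five replicate calibration datasets are
produced by default and each replicate's *excluded* points are kept for
validation. Distances are great-circle (haversine) on lon/lat grids and
planar on projected grids.

Collinear climate layers are pruned by iterative VIF: VIF_j = 1/(1−R²_j)
from regressing layer j on the others; the largest-VIF layer is dropped
while any VIF ≥ 5 (ties drop the later layer, keeping the earliest-listed
of a correlated pair). Background points follow the target-group approach:
records of a broader survey group falling in the region mask, one per cell.

Learners satisfy a minimal contract (fit, predict_probability, clone). Two
classes are built in: a binomial GLM with logit link fitted by IRLS on
standardised features, optionally with quadratic terms (falling back to a
ridge-penalised logistic fit if IRLS diverges, e.g. under separation), and
gradient-boosted classification trees. Every learner is fitted on every
thinned replicate (presences vs. background). Validation AUC is the rank
statistic on the replicate's excluded presences against a *fresh seeded
background sample disjoint from the training background* — the workflow
this emulates validates only with excluded presences, but AUC needs an
absence class; this choice is explicit and configurable
(`n_validation_background`). If thinning excluded nothing, validation falls
back to the training presences with a warning. Fits with AUC > 0.7 enter
the ensemble with weights ∝ AUC; ensemble suitability is their weighted
mean; the maxTSS threshold (smallest threshold maximising
sensitivity + specificity − 1, candidates = unique scores, predicted
present iff score ≥ t) binarises it.

Glacial refugia are cells classified suitable by at least `min_agree` = 2
of the per-GCM binary projections. Stability areas are the overlap of the
glacial consensus, the ancestral-area polygon (cell-centre inclusion) and —
by default — current binary suitability; `include_current=False` reduces the
definition to refugium ∩ ancestral. Nodata never counts as presence; row 0
is the northernmost row; values sit at cell centres.

## Attribution

Predictors per population: Simpson index, distance (km) to the nearest
refugium cell and to the nearest stability cell (0 inside; planar or
great-circle per grid metric; an empty mask is an error — geographic
exclusions are handled by subsetting populations, not by infinite
distances). Distances enter the models unscaled, in km.

For each response (Ar, He) six Gaussian GLMs (identity link = OLS) are
fitted: the full three-predictor model, the two Simpson-containing pairs
and the three singles. Interactions are implemented behind a flag and off
by default (the standard report lists none). Each fit carries coefficient
t-tests, sequential (Type I) ANOVA in formula order
(stability → refugia → simpson; each term's SS tested against the full
model's residual mean square), and

AIC = n·ln(2π·RSS/n) + n + 2·(k + 2),

counting intercept, k slopes and the Gaussian variance parameter — the
convention of mainstream GLM software, so rankings are comparable with
published values. Models are ranked per response; exact rank deficiency
(duplicated or constant predictors) is a hard error naming the aliased
columns.

## Synthetic worlds

The generator emulates a secondary-contact study system on a planar grid (default 50 × 70
cells of 5 km; row 0 north; lon/lat provided via an equirectangular
placement but all synthetic distances are planar km).

*Environment.* `n_layers` = 5 bioclim-like layers: bio1 carries a
north–south gradient (warm south) plus smoothed noise; the rest are
independent smoothed fields; `collinearity_spec` (default bio2 = 0.9·bio1 +
noise) induces the multicollinearity the VIF step must handle. True current
suitability is logistic in bio1. Each of `n_gcm` = 3 glacial scenarios
shifts bio1 by `lgm_shift` = 1 SD (colder glacial climate pushes suitability
south) and perturbs all layers with smooth noise of SD
`gcm_perturbation_sd` = 0.15. True refugia are the ≥2-GCM consensus of the
true glacial suitability at 0.5.

*Lineages and admixture.* Three lineages (emulating a north/centre/south
peninsular structure) meet along a 1-D logistic cline on a configurable
axis (default west–east, width 30 km, midpoints evenly spaced): stacked
logistic clines give each population's true proportions q. The cline axis
is orthogonal to the suitability gradient by default so admixture and
refugium distance are not confounded by construction. Ancestral areas are
circles of radius 0.24 × (grid height) around each lineage centre (placed
at 0.7 of the grid height so they intersect the refugia band): stability
areas are then substantial subsets of the refugia and the two distance
predictors are strongly correlated, as in real landscapes where stability
areas sit inside refugia. In rare
seeds the stability geometry collapses exactly onto the refugia geometry,
the predictors become identical and the model set is unidentifiable by
design; the recovery experiments redraw such degenerate worlds under a
shifted seed (the API itself still raises the rank-deficiency error).

*Genotypes.* Each locus has a shared allele pool and one private block per
lineage. The divergence fraction β_admixture moves mass from the shared
pool to the private blocks; all private blocks at a locus are permutations
of one evenness profile, so every lineage pool has the same Σp² and mixed
populations gain heterozygosity only through 1 − Σq² (the Simpson index of
their true admixture) — the melting-pot mechanism in its cleanest form.
Under the stability driver, pools collapse toward their single most common
allele with weight w(d) = min(1, d/erosion_scale)·β_stability at distance d
from the nearest true refugium cell (monotone, bounded, unit-free).
`driver_mode` ∈ {admixture, stability, both, none} wires these on and off;
`none` shares one pool and applies no erosion, so diversity varies only by
noise. Population allele frequencies receive Dirichlet jitter with
concentration 1/noise_sd² (noise_sd = 0.02 approximates the residual SD of
He), then 2×10 gene copies per population × locus are drawn, paired into
genotypes, and hit with 3% missingness.

*Default effect sizes.* No published effect sizes exist for the
admixture–diversity relation, so defaults were set by a signal-to-noise
argument: with β_admixture = 0.8, private-pool gene diversity ≈ 0.7 and a
Simpson range of ≈ 0.5 across the cline, the He range across populations is
≈ 0.2 against a per-population He standard error of ≈ 0.03 (10 individuals,
8 loci), giving slope t-statistics around 5–15 at 50 populations —
recoverable but not trivial; β_stability = 0.5 with erosion_scale = 100 km
produces a comparable gradient for the stability driver. Both are
configurable.

*Other artifacts.* mtDNA: 5 sequences of 600 bp per population, drawn from
lineage-specific haplotype pools (≈2% inter-lineage divergence, 6
within-lineage haplotypes). Q-matrices: individual rows are Dirichlet draws
around the true q (concentration 50 — clustering output is precise but not
exact). DIC tables: steep decline to the true lineage count, then a
near-flat plateau (slope −2 per K against a 150-per-K drop), 100 replicates
per K with SD 5, exercising the plateau rule. Occurrences: 400 points
drawn ∝ true suitability, jittered within cells, with ~8% high-uncertainty
records and a few literal duplicates so the hygiene step has work to do;
the target group is 1500 points from a smooth effort field. Identical
config + seed reproduces the whole world bit-identically (checksummed).

**What the generator does *not* emulate:** coalescent/mutational
realism (no genealogies, no stepwise mutation, no LD), geographic
projections, range shifts through time, spatially autocorrelated sampling
effort tied to diversity, or label switching in clustering output. Passing
recovery tests therefore show that the *attribution machinery* identifies
the programmed driver under realistic noise — not that real data meet these
assumptions.

## Recovery experiments and calibration

`experiments.run_admixture_recovery` generates admixture-driven worlds
(default 100 worlds × 50 populations), runs the attribution on
diversity responses with truth-mask distances, and counts worlds where the
AIC-best He model contains Simpson with p < 0.05 while *both* distance
terms are non-significant in the full model (coefficient t-tests — the full
model is where both terms always appear). The stability experiment is
symmetric: a distance term selected, significant, with a negative sign, and
Simpson (if selected) non-significant. Because stability areas are subsets
of refugia, the two distance predictors are strongly correlated and their
partial t-tests are anti-correlated; the expected recovery rate is bounded
near 1 − P(either distance term false-positive) ≈ 0.93, which the measured
rates match. `run_type1_calibration` checks that on driver-free worlds each
predictor's sequential F-test rejects at the nominal 5%.

Problem sizes used by the test suite and `scripts/acceptance.py` (100
worlds per driven mode, 1000 driver-free worlds, one full pipeline run) were
chosen so the whole validation runs in a few minutes on one CPU while
keeping Monte-Carlo error on the reported rates near one percentage point.

## Numerical and degenerate-input conventions

OLS is solved by statsmodels' QR path; rank checks use SVD. Sequential SS
come from nested least squares on the growing design. VIF treats R² ≥ 1 −
1e-12 as infinite. maxTSS breaks ties toward the smallest threshold. The
plateau rule on a perfectly flat DIC curve returns the smallest K. Thinning
with d_min large enough to leave fewer than two points warns rather than
errors. Empty distance masks and empty occurrence sets after cleaning are
errors. All randomness flows from explicit integer seeds; pipeline stages
derive per-stage substreams by hashing (seed, stage name).

## Known limitations

* The haplotype-merging rule for ambiguous bases is order-dependent.
* The IRLS learner's ridge fallback changes the estimator under perfect
  separation (documented, rare on realistic data).
* Validation absences are a synthetic background draw, not true absences;
  AUC values are relative, not absolute, measures of fit.
* No spatial autocorrelation correction in the GLMs (matching the emulated
  workflow); distances are Euclidean/great-circle, not least-cost paths.
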