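# meltingpot

**Why are hotspots of genetic diversity so hot?** Two classic explanations
compete: populations near long-term **glacial refugia** kept their diversity
through climatic cycles (*stability*), or divergent lineages met at secondary
contact zones and their **admixture** inflated diversity (*melting pots*).
`meltingpot` is a Python toolkit for attributing spatial patterns of
within-population genetic diversity to these drivers, aimed at
phylogeographers and landscape geneticists.

It implements the full analysis chain:

1. **Diversity statistics** — per population: haplotype diversity
   *h* = *n*/(*n*−1)·(1 − Σ*pᵢ*²), nucleotide diversity *π* (mean per-site
   pairwise difference, pairwise deletion), observed/expected heterozygosity
   (*Ho*, unbiased *He*), and rarefaction allelic richness
   *Ar* = Σₐ [1 − C(N−Nₐ, g)/C(N, g)]; filters for undersampled populations
   (*n* < 4 at any locus) and null-allele loci; a Monte-Carlo exact
   Hardy–Weinberg test with Bonferroni correction.
2. **Admixture summaries** — population-mean cluster proportions from
   Q-matrices, DIC-plateau selection of K, averaging of the lowest-DIC
   replicates, and **Simpson's index** D = 1 − Σ*qₖ*² as the admixture
   predictor.
3. **Ensemble SDM refugia mapping** — occurrence cleaning and spatial
   thinning, VIF < 5 variable pruning, target-group background, multiple
   learner classes validated by AUC on thinning-excluded presences,
   AUC-weighted ensemble (cutoff 0.7), maxTSS binarisation, ≥2-GCM glacial
   consensus refugia and stability areas (refugia ∩ ancestral polygon ∩
   current suitability).
4. **Attribution** — per-population predictors (Simpson, km to nearest
   refugium, km to nearest stability area) and the fixed set of Gaussian
   GLMs per response (*Ar*, *He*) with coefficient t-tests, sequential
   (Type I) ANOVA and AIC ranking:
   `resp ~ stability + refugia + simpson`, the two Simpson pairs and the
   three single-predictor models.
5. **Synthetic worlds** — a generator producing complete study systems
   (correlated bioclim-like rasters with GCM perturbations, lineages meeting
   along a logistic cline, lineage-specific allele pools, genotypes, mtDNA,
   Q-matrices, DIC tables, occurrences, ancestral polygons) with *known*
   drivers, so the whole chain is testable end to end without any download.

## Worked example

```python
import meltingpot as mp
from meltingpot.experiments import world_model_comparison, recovery_outcome

world = mp.generate_world(mp.WorldConfig(driver_mode="admixture", seed=11))
comparison = world_model_comparison(world)
best = comparison.best("He")
print(best.formula)                      # He ~ simpson
print(round(best.params["simpson"], 3)) # 0.21
out = recovery_outcome(comparison, "He")
print(round(out["stability_p_full"], 2),
      round(out["refugia_p_full"], 2))  # 0.5 0.62
```

The AIC-best model for expected heterozygosity contains only the Simpson
index with a positive, highly significant coefficient, while the two
distance predictors stay non-significant in the full model (p = 0.50 and
0.62): the attribution correctly identifies admixture, the driver this
world was generated with. `examples/` contains one short script per
capability (simulation, diversity table, Simpson index, ensemble SDM and
refugia maps, GLM attribution, full pipeline); each prints the numbers it
computes and what they mean.

The same chain runs from the shell on file artifacts:

```bash
meltingpot all --out run_demo --seed 11          # or stage by stage:
meltingpot simulate --out run_demo --seed 11
meltingpot divstats --out run_demo
meltingpot admix    --out run_demo
meltingpot sdm      --out run_demo --seed 11
meltingpot refugia  --out run_demo
meltingpot attribute --out run_demo
```

All artifacts are plain text: GenePop, FASTA, CSV, ESRI ASCII grids,
GeoJSON, YAML/JSON reports. Identical config + seed reproduces every
artifact bit-identically.

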