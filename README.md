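# dietclust

Dietary-pattern discovery and cardiovascular risk-factor association
analysis for repeat cross-sectional cohorts.

Nutritional epidemiology has a multicollinearity problem: fatty acids
travel together in foods, so per-nutrient regression adjustment breaks
down ("curse of dimensionality"), and people combine several fat spreads
at once.  `dietclust` takes the pattern-based route: subjects are
clustered on their whole intake profile, and the resulting pattern
memberships become the exposure variables of a conventional epidemiological
model.  It is aimed at analysts working with cohort data of the form
*subject x visit x (intakes, outcomes, covariates)* — and, because such
data are typically access-restricted, it ships a synthetic cohort
generator with planted structure so the entire pipeline is testable and
benchmarkable end to end.

## Method

1. **Exposure matrix** — per-subject mean intake across the two visits
   (31 fatty acids in g/day, or fat-spread intakes plus a no-spread
   indicator), column-standardized.
2. **K-NN network** — each subject is linked to its K = 20 nearest
   neighbours (Euclidean, exact search); links are symmetrized (union) and
   weighted by the cosine similarity of the two subjects' standardized
   intake profiles; non-positive weights are dropped.
3. **Louvain community detection** — written from first principles:
   greedy single-node moves maximizing the modularity gain, then community
   aggregation, repeated until no gain, with seeded restarts.  Modularity is
   the weighted Newman–Girvan form
   `Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)`.
4. **Derived outcomes** — clinic BP as the mean of readings 2–6 (the
   first seated reading is discarded), pulse pressure, HOMA-IR
   (insulin × glucose / 22.5), non-HDL cholesterol, hypertension staging.
5. **Association models** — Gaussian GLMs on the stacked two-visit data
   with both cluster factors entered together; log-transformed lipid
   outcomes reported as geometric-mean ratios (% change); cluster-robust
   (sandwich) errors by subject; a familywise gate (joint test per factor
   at α = 0.05, small-sample Hotelling-type reference) before individual
   contrasts; covariates multiply imputed by chained equations (m = 20,
   PMM for categorical covariates) and pooled by Rubin's rules.

## Worked example

```python
import dietclust as dc
from sklearn.metrics import adjusted_rand_score

cfg = dc.GeneratorConfig(n_subjects=800, seed=7)   # 8 FA / 10 spread patterns
cohort = dc.derive_outcomes(dc.generate_cohort(cfg))

matrix = dc.build_intake_matrix(cohort, "fatty_acids")
knn = dc.KnnParams()                                # K = 20, cosine weights
graph = dc.build_graph(dc.knn_search(matrix, knn), matrix, knn)
part = dc.relabel_by_size(dc.louvain(graph, dc.LouvainParams(seed=1)))

truth = dc.planted_truth(cohort).loc[matrix.subjects]
print(f"communities: {part.n_communities}")
print(f"modularity Q = {part.q:.3f}")
print(f"sizes: {part.sizes.tolist()}")
print(f"ARI vs planted truth = {adjusted_rand_score(truth, part.labels):.3f}")
```

prints

```
communities: 8
modularity Q = 0.796
sizes: [119, 110, 103, 101, 99, 96, 91, 81]
ARI vs planted truth = 0.975
```

i.e. the network analysis recovers the eight planted fatty-acid patterns
almost perfectly (adjusted Rand index 0.975) and the partition is strongly
modular (Q ≈ 0.8).  The same cohort run through the full pipeline
(`dc.run_pipeline(dc.RunConfig(seed=7))`) additionally clusters the spread
usage, cross-tabulates the two partitions, imputes the covariates and fits
the association models, writing a tidy `results.csv` with one row per
outcome × sex × model × cluster.

The same stages are available from the shell:

```
dietclust simulate --seed 7 --outdir out/
dietclust cluster  --cohort out/cohort.csv --outdir out/
dietclust run      --seed 7 --outdir out/ --plots
```

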