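# nichemix

Individual diet specialisation across three linked niche spaces — isotopic
(δ-space), prey-use (p-space) and nutritional (N-space) — for consumers
sampled through serially accreted tissues such as shark tooth files,
whiskers or baleen.

Ecologists quantify individual specialisation by variance partitioning:
total niche width splits into within- and between-individual components
(TNW = WIC + BIC), and specialisation rises as WIC:TNW falls. Isotope data
alone, however, say little about *which* prey individuals specialise on, or
whether prey-use differences matter nutritionally. `nichemix` chains the
three analyses:

1. **δ-space** — a trivariate random-intercept model
   `y_it = μ + b_i + e_it`, `b_i ~ N₃(0, G)`, `e_it ~ N₃(0, R)`, fitted by
   Gibbs sampling (conjugate normal / inverse-Wishart updates), partitions
   isotopic variance into BIC (G) and WIC (R). Per-individual breadth
   (s-index = tr WICᵢ / tr TNW) and displacement (o-index = Monte-Carlo
   overlap of 40%-coverage standard ellipsoids) summarise each consumer
   against the population.
2. **p-space** — a concentration-dependent Bayesian mixing model with
   individual random effects estimates diet proportions on the K-source
   simplex. Mixture moments are `w_k ∝ p_k c_ke`,
   `mean_e = Σ w_k (s_ke + Δ_e)`, `var_e = Σ w_k² (σ_ke² + σ_Δe²)` with
   TEF scenario Δ ± σ_Δ; individuals deviate from the population by normal
   random effects in isometric log-ratio coordinates.
3. **N-space** — diet posteriors are pushed through fixed prey
   macronutrient compositions, `%Y_diet = Σ_t %Y_t p_t`, giving posterior
   %protein/%lipid/%water intakes, P:L ratios, right-angled mixture-triangle
   coordinates, and a rescaled cosine-similarity index of nutritional
   specialisation.

Cross-cutting statistics (beta regression with AICc model selection,
pairwise PERMANOVA with Benjamini–Hochberg correction), collagen C:N
quality control, a ground-truth synthetic-data generator and an end-to-end
pipeline with seeded reproducibility round out the package. See
`docs/methods.md` for models, priors and calibration details.

## Worked example

Simulate a study-sized dataset (12 individuals × 5 teeth, six published
source groups, TEF_C) and run the three stages:

```python
import numpy as np
from nichemix import synthetic_data as syn
from nichemix.delta_niche import MCMCSettings, fit_mrlmm
from nichemix.mixing_model import MixingProblem, c_index, fit_mixing
from nichemix.nutrient_space import diet_to_nutrients

ds = syn.simulate_dataset(syn.SimulationConfig(seed=42))
teeth = {}
for rec in ds.consumers:
    teeth.setdefault(rec.individual_id, []).append(rec.iso.as_array())
teeth = {k: np.array(v) for k, v in teeth.items()}

y = np.vstack(list(teeth.values()))
ids = np.concatenate([[k] * len(v) for k, v in teeth.items()])
post = fit_mrlmm((y, ids), settings=MCMCSettings(8000, 2000, 5, 2), seed=1)
print(f"BIC:TNW = {100 * post.components.bic_tnw:.1f}%  "
      f"WIC:TNW = {100 * post.components.wic_tnw:.1f}%")

problem = MixingProblem(tuple(ds.sources), syn.tef_scenarios()["TEF_C"], teeth)
diets, diag = fit_mixing(problem, MCMCSettings(20000, 10000, 10, 2), seed=2)
pop = diets["population"]
for lab, m in zip(pop.source_labels, pop.mean):
    print(f"population {lab:26s} {100 * m:5.1f}%")

nutrients = diet_to_nutrients(pop, {s.label: s.nutrients for s in ds.sources})
pP, pL, pW = nutrients.mean
print(f"population intake: {pW:.1f}%W  {pP:.1f}%P  {pL:.1f}%L  "
      f"P:L = {np.mean(nutrients.pl_ratio):.2f}")
print(f"c-index_prey ws1 vs population: {c_index(diets['ws1'], pop):.3f}")
```

Output:

```
BIC:TNW = 89.8%  WIC:TNW = 10.2%
population whale                        6.3%
population dolphin                     13.8%
population shark_benthopelagic         29.2%
population benthic_rays_cephalopods     8.0%
population pelagic_teleost             34.4%
population estuary_teleost              8.3%
population intake: 68.8%W  18.8%P  12.4%L  P:L = 1.53
c-index_prey ws1 vs population: 0.921
```

Reading it: between-individual differences dominate isotopic variance
(BIC:TNW ≈ 90% for this realisation — strong individual specialisation);
the population assimilates a broad prey mix led by the mid-trophic
shark/benthopelagic group and pelagic teleosts; the implied diet is
water-rich, protein-dominated and moderately lipidic (P:L ≈ 1.5); and
individual ws1's prey use is close to, but distinguishable from, the
population (cosine similarity 0.92). Single 12-individual realisations
scatter substantially around the generator's configured population diet —
the reproduction script below averages replicates for that reason.

The same analysis runs from the shell:

```bash
nichemix simulate --seed 42 --out data/
nichemix run --consumers data/consumers.csv --sources data/sources.csv \
    --nutrients data/nutrients.csv --prey-samples data/prey_samples.csv \
    --out results/ --preset desk
```

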