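# connectopy

Benchmarking **connectopic mapping**: can a region's functional topography
be reconstructed from connectivity alone?

Topographic cortical areas such as primary visual cortex (V1) lay out
stimulus dimensions smoothly across the cortical sheet — eccentricity
along one axis, polar angle along the other.  Connectopic mapping embeds
each vertex's *connectivity fingerprint* (its vector of Fisher-z
correlations with reference timeseries) into a low-dimensional space; if
functionally similar vertices have similar fingerprints, the first two
embedding components should rediscover the region's retinotopic maps.

`connectopy` implements the full evaluation pipeline as a tested,
reusable library:

* a **seeded synthetic-data generator**: multi-run timeseries on a grid of
  vertices with known (eccentricity, polar-angle) coordinates, pairwise
  correlation decaying with grid distance, non-ROI source mixtures, noise
  controls, and an optional curvature parameter that bends the latent
  sheet so linear methods underperform;
* **fingerprint construction**: odd/even run splitting, lossless PCA of
  the sources (T−1 components, 100% variance), Fisher-transformed
  correlations, five connectivity-source variants (whole "brain", cortex,
  subcortex, moment-matched noise, within-ROI);
* an **embedding suite** of scikit-learn-style estimators, each returning
  two components: spectral embedding over five neighbourhood-graph
  variants, PCA, ICA, kernel PCA (poly²/RBF), MLLE, LTSA, Isomap,
  diffusion maps, and t-SNE (best of five restarts);
* **evaluation**: greedy 2×2 matching of components to ground-truth maps
  on absolute correlation, |r| accuracy records, split-half and cross-task
  reliability, and Gaussian-process Bayesian hyper-parameter selection
  cross-validated across the odd/even splits;
* the **statistical framework**: one-sample/paired t-tests with
  Holm–Bonferroni correction, repeated-measures ANOVA (1–4 within-subject
  factors) with Greenhouse–Geisser correction and partial/generalized η²,
  Tukey contrasts, and exact non-central power calculations.

## Worked example

```python
import numpy as np
import connectopy as cp

# a 12 x 10 V1-like grid, 4 runs x 300 timepoints, seeded
grid = cp.make_retinotopic_grid((12, 10))
cfg = cp.SimulationConfig(seed=1)
roi, latents = cp.simulate_roi_timeseries(grid, cfg, return_latents=True)
sources = {
    "cortex": cp.simulate_nonroi_timeseries(latents, cfg, "cortex"),
    "subcortex": cp.simulate_nonroi_timeseries(latents, cfg, "subcortex"),
}

# odd runs -> fingerprints (lossless PCA + Fisher-z correlations)
odd_roi, _ = cp.split_odd_even(roi)
odd_sources = {k: cp.split_odd_even(v)[0] for k, v in sources.items()}
fp = cp.build_connectivity(odd_roi, odd_sources, mode="all")
print(fp.values.shape)            # (120, 599): N vertices x T-1 components

# embed and score against the ground-truth maps
emb = cp.IsomapGradients(k=10).fit_transform(fp.values)
truth = np.column_stack([grid.ecc, grid.polar])
print(cp.prediction_accuracy(emb, truth))
# {'eccentricity': 0.998, 'polar': 0.997}
```

The two numbers are the absolute Pearson correlations between each
ground-truth map and its greedily matched embedding component: here
Isomap reconstructs both retinotopic gradients from the fingerprints of
the odd scan runs almost perfectly.

The end-to-end experiment runner (odd/even cross-validation, Bayesian
parameter selection, group statistics) is available as a library call
(`cp.run_experiment`) or from the shell:

```bash
connectopy run --subjects 4 --algorithms spectral_knn_unweighted,isomap \
    --seed 7 --out results/
```

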