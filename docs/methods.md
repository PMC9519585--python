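# Methods

## The problem

Topographically organized cortical regions — primary visual cortex (V1)
being the canonical case — map a stimulus dimension smoothly across the
cortical sheet: eccentricity (distance from fixation) along one axis and
polar angle around fixation along the other.  Connectopic mapping tries to
recover such maps without a functional localizer, from functional
connectivity alone: if neighbouring neurons have similar response
properties, they should also have similar connectivity *fingerprints*, so
embedding each vertex's fingerprint into a low-dimensional space should
rediscover the region's spatial gradients.

`connectopy` implements and benchmarks that claim end-to-end: a seeded
generative model of a topographic ROI, the fingerprint construction, a
suite of linear and non-linear embeddings, cross-validated hyper-parameter
selection, accuracy scoring against ground-truth maps, and the
repeated-measures statistical framework used to compare algorithms.

## Pipeline

1. **Split.** Scan runs are partitioned into odd and even halves so that
   hyper-parameters can be selected on one half and applied to the other.
   Runs are concatenated within each half after run-wise conversion to
   percent signal change.
2. **Compress.** The non-ROI sources (M rows, T timepoints, M > T) are
   rotated by a lossless PCA treating timepoints as observations.  After
   mean-centering, exactly T−1 orthogonal component timeseries carry 100%
   of the variance; the operation is a rotation of the T samples in feature
   space and preserves all pairwise distances between timepoints, so
   downstream correlations are unaffected by it (only computation cost is).
3. **Correlate.** Each ROI vertex timeseries is Pearson-correlated with
   every component timeseries; correlations are Fisher z-transformed after
   clipping |r| ≤ 1 − 1e−7 so accidental duplicates stay finite.  Five
   connectivity sources are supported: cortex+subcortex (`all`), each block
   alone, moment-matched Gaussian noise in place of the sources (`noise`),
   and within-ROI correlation (`within_roi`, diagonal set to zero; its PCA
   variant correlates the ROI rows with their own min(N, T) − 1 principal
   components).
4. **Embed.** Fingerprint rows are reduced to m = 2 components by one of:
   spectral embedding over five graph variants (unweighted/weighted kNN,
   unweighted/weighted ε-radius, fully-connected weighted), PCA, ICA,
   kernel PCA (second-order polynomial (xᵀy+1)² or RBF), MLLE, LTSA,
   Isomap, diffusion maps, or t-SNE.
5. **Score.** The two components are matched to the two ground-truth maps
   greedily on absolute Pearson correlation (largest |r| pair first; the
   absolute value absorbs the inherent sign ambiguity) and each matched
   pair contributes one |r| observation.

## Synthetic ground truth

The generator emulates the statistical structure the analysis depends on,
not fMRI physics.  An (n_ecc × n_pol) grid of vertices carries evenly
spaced eccentricity (degrees, default 1–8) and polar-angle (radians,
default [0, π] — one hemifield, so neither map wraps) coordinates.  One
latent standard-normal source sits at every grid node; vertex v mixes the
sources with Gaussian weights exp(−d(v,s)²/2ℓ²) where d is distance in
grid units, plus i.i.d. noise, independently per run, on a constant
baseline of 100 scanner units, then converts to percent signal change per
run.  Pairwise correlation therefore decays monotonically with grid
distance; placing a source at every node guarantees both map axes are
recoverable.  Non-ROI `cortex` rows are random mixtures of all latent
sources, `subcortex` rows mix a random quarter of them (a narrower
functional repertoire), `unrelated` rows are pure noise.

`manifold_curvature` κ bends the sheet before the mixing distances are
computed: the first grid axis is rolled onto a circular arc of radius 1/κ
(arc length preserved), so for κ large enough chord distances fold while
intrinsic distances do not — the configuration in which geodesic methods
should beat linear ones.

Defaults are the reference study conditions: 12 × 10 grid, 4 runs × 300
timepoints, ℓ = 1.5, noise sd 0.5, κ = 0.  The non-ROI count defaults to
650 rows per block so that a single block still exceeds the 600-timepoint
split half, as the real data's non-ROI count always exceeds T.  The
generator has no rest-vs-movie structure; different "tasks" are simply
independent seeded sessions, and nothing here should be read as modelling
task differences.

## Embedding details and numerical choices

* **Graphs.** Neighbourhoods are defined on *squared* Euclidean distance
  (the ε-radius threshold is in squared-distance units).  kNN graphs are
  symmetrized by OR.  Weights are Pearson correlations between fingerprint
  rows rescaled to [0, 1] via (r+1)/2.
* **Spectral.** The symmetric normalized Laplacian is decomposed (dense up
  to n = 512, ARPACK shift-invert above); the returned maps are the
  generalized eigenvectors D^{-1/2}u of L f = λ D f for the two smallest
  non-zero eigenvalues — the standard Laplacian-eigenmaps solution, which
  e.g. orders a path graph monotonically.  A graph with more than one
  connected component (tolerance 1e−8 on the spectral bound) raises
  `DisconnectedGraphError`, which the optimizer treats as an invalid trial
  (score −∞): connectivity is a precondition, not something to silently
  repair.
* **Diffusion maps.** Gaussian kernel exp(−‖x−y‖²/ε) evaluated on kNN
  edges (plus the diagonal), α-normalization K_α = D^{−α} K D^{−α}, row
  normalization to the transition matrix, eigenvectors 2..3 scaled by
  λ^t with t = 1.  The kernel is evaluated on the kNN edges rather than
  sparsifying a dense kernel; with a decaying kernel the two differ only
  in the far tail.
* **t-SNE.** Initialized from the (rescaled) PCA embedding; five seeded
  fits, the one with the smallest KL divergence is returned, all five
  divergences kept in the diagnostics.
* **Sign convention.** Each returned column's largest-magnitude entry is
  made positive.  This is purely for reproducibility — accuracy is
  sign-invariant by construction.
* **Seeding.** Every stochastic stage (ICA, t-SNE restarts, noise
  substitution, optimizer) takes an explicit seed; identical configuration
  implies bit-identical output.

## Hyper-parameter selection

A Gaussian-process Bayesian optimizer (Matern-5/2 surrogate, expected
improvement maximized over random candidates plus local perturbations of
the incumbent) maximizes the mean matched |r| on the training split.  The
reference budget is 100 iterations per free parameter including 10 random
starts per parameter ("including" — the starts count toward the budget);
invalid trials are kept in the trace at −∞ and imputed just below the
worst valid score when fitting the surrogate.  Search spaces:
k ∈ [3, n/2] (integer, log-spaced), ε-radius between the 1st and 99th
percentile of squared distances (log), RBF γ and diffusion ε log-uniform
over [1e−4, 1e4] × the median (inverse) squared-distance scale,
α ∈ [0, 1], perplexity ∈ [5, n/4], learning rate ∈ [10, 1000] (log).
Parameters are never fit on the evaluation split; both cross-fitting
directions are available and kept as separate records.

## Statistics

* One-sample and paired t-tests (d_z = mean/sd), Holm–Bonferroni within
  algorithm.
* Repeated-measures ANOVA for fully within-subject balanced designs with
  1–4 factors.  Sums of squares come from the balanced-design
  inclusion–exclusion identity (each effect's estimate is the alternating
  sum of collapsed cell means); every effect is tested against its own
  subject-by-effect stratum.  Greenhouse–Geisser ε is computed from the
  covariance of orthonormal within-subject contrast scores, clamped to
  [1/df, 1], and applied to every effect (a no-op at df = 1).  η²_p =
  SS_eff/(SS_eff+SS_err); generalized η² uses SS_eff/(SS_eff + all
  subject-involving SS), treating every factor as manipulated.  For
  interactions our ε comes directly from the interaction-contrast
  covariance; pingouin's two-way ε uses an approximation it itself flags,
  so cross-checks against pingouin compare interactions on F and η²_G
  only.
* Tukey contrasts via the studentized range on the effect's own error
  stratum; with two cells this reduces to the unadjusted paired t.
* Power: exact non-central t (λ = d√n) and non-central F with the
  SPSS-style effect-size convention λ = f²·n, df = (m−1, (n−1)(m−1)).
  With the reference inputs (d = 1.76 or f = 1.33 at n = 174) any standard
  convention saturates at 100% to machine precision, so the choice of
  convention is documented rather than consequential.

## Problem sizes used in the shipped analyses

The recovery benchmark runs ten simulated subjects at the reference
conditions with a single cross-fitting direction and an optimizer budget
of 15 iterations per free parameter; the curved-manifold ordering
comparison uses κ = 0.3.  These sizes are the package's default desk-scale
configuration; the library accepts the full reference budget (100 per
parameter, both directions) unchanged.

## What passing tests do and do not show

The generator satisfies the analysis' assumptions by construction: smooth
topography, monotone correlation decay, sources spanning both axes, and
(optionally) a cleanly parameterized curvature.  Real fMRI violates all of
these to some degree — hemodynamic autocorrelation, spatially structured
noise, vascular artefacts, inter-subject variability and task structure
are all absent here.  Passing recovery tests therefore validates the
*implementation* of the pipeline and the internal consistency of the
benchmark, not the empirical claim that connectopic mapping works on any
particular dataset.

## Known limitations

* Polar angle is treated as a linear variable in Pearson correlations,
  mirroring the benchmark procedure; within a single hemifield ([0, π])
  this is defensible, across hemifields it would not be.
* The within-ROI + PCA variant retains min(N, T) − 1 components by
  convention ("one fewer than the smaller dimension"); for N < T the
  centered rank can be N, so the last component's variance is discarded.
* The rm-ANOVA requires balanced complete designs; missing cells are an
  error, not imputed.
* GIFTI reading is a thin optional adapter (`nibabel`); no test depends
  on it and CIFTI support is limited to what `nibabel` exposes.
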