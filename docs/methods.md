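# Methods

## Problem and data model

The package estimates a continuous kidney-function endpoint — rat blood
urea nitrogen (BUN) in mg/dl after compound administration — from two
per-compound feature blocks: a ternary transcriptome signature (G genes,
values −1/0/+1; 964 landmark genes in the real resource) measured in
human cell lines, and a binary substructure fingerprint (B bits; 166 for
MACCS keys). One representative perturbation is kept per compound — the
highest dose, then the longest treatment, then first-in-file on full
ties — because ternarized profiles are nearly dose-invariant; the
`dose_redundancy_stats` statistic (share of (compound, gene) pairs whose
ternary value has exactly zero standard deviation across doses, plus the
mean of those standard deviations) quantifies that redundancy on any
signature table. Compounds are matched across the three sources by
exact string identity after trimming and case-folding; several BUN
records for one compound are averaged.

## Train/test splitting

The held-out fraction (default 20%) can be drawn uniformly or as
*divergent* compounds: farthest-point sampling in Tanimoto distance on
the fingerprint block, seeded at the compound with the largest mean
distance to all others and greedily adding the compound with the largest
minimum distance to the chosen set. This is the stricter evaluation —
the test compounds are the ones least like anything in training. When
any fingerprint row is all zeros the Tanimoto distance is undefined and
the selection falls back to Euclidean distance with a warning.

## Dimensionality reduction

Truncated SVD operates on the uncentered matrix (the usual truncated-SVD
convention; PCA, which centers, is kept as a distinct baseline). The
hierarchical reducer (t-SVDh) fits an independent truncated SVD per
feature block and selects, per block, the smallest k whose leading
squared singular values reach the retention threshold (default 0.95 of
the squared-singular-value mass, computed from the block's full spectrum
— exact rather than estimated, affordable at these sizes). Reduced
blocks are concatenated, chemical components first. Reducers are fitted
on training rows only by default, to avoid leaking test-set structure;
fitting on all rows is possible by transforming before splitting.

Numerical conventions: singular vectors are sign-fixed (largest-|entry|
of each right-singular vector positive, lowest index on ties) so fits
are bit-stable; k requested above the numerical rank is clamped with a
warning; the numerical rank uses the standard `max(N,d)·eps·σ_max`
cutoff. `inverse_transform(transform(X)) = X` holds exactly (to 1e−6)
when every block retains its full rank.

## Gaussian-process regressor

Covariance: RBF times σ_f², plus white noise σ_n² on the diagonal of
same-set kernel matrices. Length scales are per-dimension (ARD) on
reduced spaces, or one shared scale on very wide raw spaces, where a
single scale is cheaper and far better conditioned. Targets are
centered by the training mean before fitting and the mean is restored at
prediction; a zero-mean prior would otherwise be badly specified for BUN
levels around 10–40 mg/dl. Predictive standard deviations include the
white-noise variance (they describe the predictive distribution of a new
measurement, not the latent function).

Hyperparameters maximize the log marginal likelihood by L-BFGS-B in
log-parameter space with analytic gradients, bounds [1e−3, 1e3] on every
hyperparameter, and a default of 5 extra log-uniform random restarts.
Two data-driven starts are always included: median-pairwise-distance
length scales (per-dimension spread in ARD mode) and, in ARD mode, an
*isotropic* start with every dimension at the shared median-distance
scale. The isotropic start matters: the all-equal-scales solution is
often the dominant likelihood basin, and per-dimension random starts
essentially never land in it. Cholesky factorizations escalate diagonal
jitter from 1e−10×mean(diag K) by factors of 10 up to 1e−4×mean(diag K)
(interpreted relative to the kernel's scale) before failing.

## Metrics

MAE, RMSE, r² (= 1 − SS_res/SS_tot; reported as missing, never as 0,
when the target is constant), Pearson r, the average predictive SD
(ASD), and an uncertainty-weighted RMSE `sqrt(Σ w_i e_i² / Σ w_i)`. The
weighting is inverse-variance, `w_i = 1/sd_i²` — the standard
precision weighting, adopted here as an interpretation since only the
idea of uncertainty weighting, not a formula, is fixed by convention;
`w_i = 1/sd_i` is available as an alternative. Cross-validation offers
seeded ShuffleSplit (default: 10 splits, 10% validation) and K-fold;
grid search is exhaustive with ties broken by grid order and failing
configurations logged and skipped.

## Benchmark

Eight regressor families (linear, random forest, SVR, XGBoost, gradient
boosting, GP, KNN, LightGBM; a mean-predictor baseline is also
registered) are evaluated on one shared split. Reduction is assigned
per family — by default t-SVDh for linear, SVR, KNN, XGBoost and GP, raw
features for the tree ensembles, which is where each family performs
best; the policy, suite and small default hyperparameter grids live in
`default_benchmark.yaml`. If xgboost or lightgbm is not installed that
family degrades to sklearn's gradient boosting with a warning.

## Attribution

Two routes. (1) An extremely randomized trees ensemble on the raw fused
features yields impurity-decrease importances, normalized to sum to 1;
per-modality shares are block sums, and `n_significant` counts features
above a threshold (default 4e−9). (2) The fitted ARD length scales rank
reduced dimensions (shortest = most influential, ties by index); the
chosen dimension's reduced-space unit vector is inverse-transformed, so
its per-feature contributions are exactly the corresponding column of
the owning block's V matrix — confined to that block by construction.
"Switching on" a dimension is interpreted as the unit vector: magnitude
scaling cannot change the contribution ranking. Signs are retained;
selection uses |contribution| > threshold (default 0.5).

## Synthetic-data generator

Each compound draws a latent vector z ~ N(0, I_r) (default rank r = 10).
Observation channels:

* **Expression**: a linear map of z plus Gaussian noise (SD 0.5),
  ternarized by symmetric per-gene quantile thresholds so a configured
  fraction of entries (default 0.7) is exactly 0. Only a fraction of
  genes (default 0.3) has nonzero loadings; the rest are pure ternary
  noise, as most landmark genes do not respond to a given compound.
* **Fingerprint**: Bernoulli bits with logits 1.5·(z·W) + intercept;
  default 0.6 of bits informative.
* **Target**: an affine map of z·w into the configured range (default
  7.75–39.60 mg/dl, the span of the real BUN measurements) plus Gaussian
  noise with SD = std(signal)/signal_to_noise (default 5), clipped to
  the range.

Each block observes only a fraction of the latent dimensions (default
0.7: expression the leading ones, chemistry the trailing ones, with
overlap). This realizes the structure the pipeline assumes: the blocks
share latent structure, yet neither alone carries the full target
signal, so combining modalities genuinely helps — without it, 964
redundant informative genes make the expression block sufficient by
itself and a combination experiment is vacuous.

Dose series replicate each base profile at `n_doses` doses; the highest
dose is the base profile exactly (so representative selection recovers
it) and every other (gene, dose) value flips to one of the two other
ternary values with probability p. A pair is dose-invariant iff no flip
occurred, so a target zero-SD fraction f calibrates analytically as
p = 1 − f^(1/(n_doses−1)). Out-of-distribution compounds displace fresh
latent draws by a chosen number of latent standard deviations along a
random unit direction and push them through the same frozen observation
model.

What the generator does **not** emulate: real gene–gene correlation
structure, MACCS bit semantics, dose–response pharmacology, assay batch
effects, or compound-identity ambiguity across databases. Passing tests
on this data show that the pipeline's machinery behaves as designed
under its stated assumptions — not that those assumptions hold for any
particular real dataset.

## Problem sizes and randomness

The behavioural checks sweep 20 seeds at n = 300 compounds (combination
and uncertainty effects) and n = 100 compounds at the full 1,130-feature
width (reduction benefit), with 2 optimizer restarts per GP fit —
desk-scale settings chosen so a full verification run completes in
minutes on one core. All stochastic steps (generation, splitting,
optimizer restarts, forests) are explicitly seeded; fits and artifacts
are byte-reproducible given a config and seed.

## Known limitations

* Exact-string compound matching will under-match real SEP-L1000 and
  DrugMatrix exports, whose identifier vocabularies differ; name
  reconciliation is deliberately out of scope and surfaced as dropped
  ids in the match report.
* The dense GP scales as O(N³) in training points; no sparse or
  inducing-point approximations are provided (nor needed at hundreds of
  compounds).
* "Divergent" splitting is one defensible operationalization
  (farthest-point Tanimoto); metrics on real data depend on this choice.
* The marginal-likelihood surface is multimodal; with few restarts ARD
  fits on weakly informative data can land in poor basins. The
  isotropic start mitigates but does not eliminate this.
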