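# Methods

This note records the models implemented in `metalesion`, their assumptions,
the defaults that matter, the numerical choices, and what the synthetic-data
tests do and do not establish about real data.

## Why metabolic lesions

Classical lesion–deficit mapping infers function from the spatial pattern of
damage accompanying impairment. With vascular lesions the inference is
distorted twice over: damage follows arterial territories, so voxels far
apart are strongly co-lesioned in anisotropic patterns (a voxel can be
"blamed" for a deficit merely because it is co-damaged with the responsible
one), and structural maps miss disconnection effects. Focal hypometabolism
on interictal FDG-PET behaves as a *graded functional lesion*: it reflects
both local dysfunction and disconnection, and its spatial covariance is
close to isotropic. The package provides the diagnostics to demonstrate that
contrast and the inferential machinery that exploits it.

## Synthetic cohorts

The generator (`metalesion.synth`) emulates the data structure the analysis
assumes; it is the substrate of every stochastic test.

- **Geometry.** Grid 20 × 24 × 20 at 10 mm isotropic. Brain = ellipsoid at
  0.88 of the half-extent; white matter core at 0.655; ventricles at 0.18.
  The grey shell holds ~2,040 voxels, matching the coarse working
  resolution (~1,900 voxels) of a whole-brain analysis after 10 mm
  smoothing and downsampling.
- **Baseline and background.** A fixed smooth positive field (~100 a.u.
  with low-order cosine ripple) is scaled per subject by three lognormal
  multipliers (log-SD 0.10, emulating tracer dose/uptake-time variation):
  global, white-matter, and ventricular (ventricles at 0.35 of parenchymal
  intensity).
- **Lesions.** Per subject, 1–2 foci uniform over grey matter; each focus
  multiplies the volume by `1 − a·exp(−½ Σ (x_i/σ_i)²)` with amplitude
  `a = 0.4` (40% peak hypometabolism, a realistic focal deficit) and
  per-axis `σ_i = 15 mm × anisotropy_i`. Anisotropy (1,1,1) gives the
  isotropic metabolic class; the binary "vascular" comparator thresholds
  elongated ellipsoids (it reproduces territory-like anisotropic
  co-lesioning without modelling an arterial tree, which is all the
  covariance diagnostics need).
- **Scores.** The effect map assigns signed slopes d(score)/d(lesion load)
  on the grey voxels; the default implants a deficit sphere (slope −1,
  radius 2.6 voxels) and an enhancement sphere (+1) at mirrored loci. The
  effect-weighted load, standardized, is latent factor 1; two further
  independent N(0,1) traits complete a 3-factor model mixed through a
  deterministic 16 × 3 loading matrix (all-positive loadings 0.55–0.85 on
  the deficit factor), plus N(0, 0.5²) noise. This makes the battery
  strongly inter-correlated — the regime in which latent-factor imputation
  is worthwhile. Two instruments are flagged higher-is-worse and stored
  sign-flipped, exercising the direction convention end to end.
- **Missingness.** 24% per instrument by default (emulating a clinic where
  ~76% of patients receive each test), either MCAR or score-dependent. The
  score-dependent mechanism uses the logistic weight `w = 1/(1+e^z)` of the
  oriented z-score, rescaled to the marginal rate — a monotone
  low-scorers-missing-more link; the clinic's true mechanism is unknown, so
  both are provided.
- **Determinism.** One integer seed; identical config + seed reproduces the
  cohort bit for bit. Ground truth (centres, loads, factors, pre-noise
  scores, scales) is stored for recovery tests and never read by inference.

What the generator does *not* emulate: PET physics (scatter, attenuation,
reconstruction), registration error, atrophy, non-linear lesion–behaviour
links, and clinic-specific missingness. Passing tests therefore establish
correctness of the *statistical machinery* under the stated model, not
clinical performance.

## Preprocessing

- **Optimal-threshold mask**: exhaustive sweep over the distinct values of
  the mean volume (optionally quantile-subsampled), keeping the threshold
  maximizing the Pearson correlation between the 0/1 inclusion indicator
  and the mean image; exact ties break toward the higher threshold
  (smaller mask). This sweep convention is the package's fixed reading of
  the mask-optimization idea.
- **Smoothing**: separable Gaussian, per-axis SD = FWHM/(voxel ×
  2√(2 ln 2)), reflect padding (conserves intensity near edges better than
  zero padding and keeps results bit-reproducible). FWHM below 0.1
  voxel-SD is not representable: warn and return the input.
- **Downsampling**: block mean over non-overlapping cubes; the target must
  be an integer multiple of the source voxel size; incomplete trailing
  blocks are dropped; the affine is rescaled and its origin shifted to
  block centres.
- **Residualization**: QR-based least squares per voxel on [intercept, age,
  handedness indicators, global/WM/ventricular sums]. Handedness is
  categorical with an explicit `unknown` level (missing handedness is
  common in clinical records; this avoids dropping subjects or silently
  imputing). Rank deficiency raises an error naming the collinear columns
  (a greedy rank-growth scan identifies them).

## Spatial covariance diagnostics

- **Binarization**: lesioned iff intensity < per-voxel median − 2 × sample
  SD (ddof = 1) across subjects, computed on the residualized stack;
  zero-variance voxels are never lesioned; fewer than 3 subjects is an
  error.
- **Local dependency**: vector = mean of the six `p_u · d_u` contributions.
  Out-of-mask neighbours contribute p = 0 with the divisor kept at 6, so
  magnitudes remain comparable across voxels and bounded in [0, 1]; this
  attenuates edge voxels towards 0 (documented bias, identical for both
  lesion classes being compared). Conditional probabilities are plug-in
  (co-count/count), unsmoothed. Never-lesioned voxels are flagged
  undefined and excluded from summaries and from the KS comparison (counts
  are recorded).
- **KS test**: D is the exact sup-difference of the two ECDFs; p uses the
  asymptotic Kolmogorov law at effective size `n_a n_b/(n_a+n_b)`.
- **Correlogram**: pairwise phi (Pearson on 0/1 columns — the natural
  binary specialization) for all in-mask pairs within a max per-axis offset
  (default 6 voxels), binned by displacement under a canonical sign (first
  non-zero component positive, since (Δ, −Δ) index the same pair); per-bin
  summary is the median; pairs with a constant column are skipped and
  counted. Hemispheres split at the central x-coordinate, midline voxels
  excluded from hemispheric runs. The axis decay length (offset at which
  the median rho falls to a level, default 0.2, linearly interpolated
  through rho = 1 at lag 0) summarizes isocontour extent per axis; the
  elongation ratio compares axes.

## PPCA imputation

Model: `x = mu + W t + eps`, `t ~ N(0, I_k)`, `eps ~ N(0, sigma² I)`, fitted
on per-instrument z-scores (IQ points and affect points are incommensurate;
the inverse transform restores units). The EM treats both the latent
factors and the missing entries as latent; the M-step is ECM (mu, then the
rows of W, then sigma², each maximized against the same E-step posterior),
which preserves the monotone observed-data log-likelihood guarantee — the
implementation asserts monotonicity at every accepted iteration. The E-step
is fully vectorized over subjects (batched k × k inversions), and the
observed-data likelihood uses the determinant/inversion lemmas so only
k × k factorizations appear.

Numerical choices: initialization from classical PCA of the zero-filled
z-scored matrix with sigma² from the discarded spectrum and seeded 1e-8
jitter to break ties; sigma² floored at 1e-12, with a clean stop when the
floor is reached (the noiseless-limit likelihood is unbounded there and
float monotonicity degrades); a non-finite `tol` runs exactly one iteration
and reports `converged=False`.

Imputation is *single* (posterior mean back-projection), not multiple;
observed entries pass through bitwise untouched and a per-entry provenance
table (observed/imputed) is emitted. `select_k` masks an extra 10% of
observed entries per fold and picks the smallest k whose mean held-out RMSE
is within one standard error of the minimum — the usual parsimony rule;
plain argmin overselects here because z-scored noise is mildly
heteroscedastic and extra factors absorb it.

## Mass-univariate mapping

Per voxel, OLS of intensity on [intercept, standardized confounds, score],
with the score oriented so higher = better (higher-is-worse instruments
sign-flipped), making a positive t uniformly mean "hypometabolism
accompanies impairment". The implementation computes the score column's
beta/SE/t by Frisch–Waugh partialling, which is algebraically identical to
the full normal equations (verified against them to 1e-8) and lets all
permutations run as one batched matrix product.

Inference: cluster-forming threshold = one-tailed Student-t quantile at
1 − 1e-4 with the design df; clusters are 6-connected (faces only,
consistent with the 6-neighbour dependency convention); family-wise error
is controlled at 0.025 per tail (the conventional two-tailed 0.05 halved)
by Freedman–Lane permutation: the score is residualized on the confounds,
those residuals are permuted, re-residualized, and refitted; each tail's
null is the maximum suprathreshold cluster size, and
`p_FWE = (1 + #{max ≥ s})/(B + 1)`. Permutation replaces random-field
theory deliberately: it is assumption-light, exact under exchangeability,
and avoids smoothness estimation entirely. Perfect-fit voxels carry a
capped t sentinel (1e4) and are excluded from permutation maxima;
zero-variance voxels are flagged undefined. Peak ties break toward the
lowest in-mask linear index; peaks are reported in mm through the mask
affine (0-based voxel indices).

## Bayesian lasso

Park–Casella hierarchy with per-coefficient local scales (the "adaptive
Laplace" shrinkage family): `beta_j ~ N(0, sigma² tau_j²)`,
`tau_j² ~ Exp(lambda²/2)`, `lambda² ~ Gamma(shape 1, rate 1.78)` (the
configurable default), `sigma² ~` scale-invariant. Gibbs conditionals:
multivariate normal for beta (direct Cholesky for p ≤ n; the exact
auxiliary-variable construction at O(n²p) for p > n — validated against the
direct draw's moments), inverse-Gaussian for 1/tau_j² (Michael–Schucany–Haas
in a cancellation-free form, means clipped to [1e-10, 1e8]), Gamma for
lambda², inverse-Gamma for sigma² (floored at 1e-12). Defaults follow the
5000-retained / 1000-burn-in / thin-5 protocol. Freezing tau_j² reduces the
model to Bayesian ridge, whose closed-form posterior validates the weight
conditional.

Prediction uses the posterior-mean weights plus the training mean of y;
predictors are standardized on the *training split only* in the repeated
hold-out protocol (15% test, 50 repeats by default) to prevent leakage.
Confound covariates do not enter the multivariate model by default; callers
may append them as predictor columns. The weight map reports per-voxel
pseudo-t = posterior mean / posterior SD. Diagnostics: split-R̂ (two
half-chains) and a Geyer initial-positive-sequence ESS on sigma² and ten
random weights; sigma² mixes slowly in high-SNR p ≫ n problems (ESS of
order tens at default settings), so its R̂ is noisy there — weight
summaries, which average thousands of draws, are much better behaved.

## Pipeline and reproducibility

All randomness descends from one config seed via
`numpy.random.SeedSequence.spawn`, one child per stage in fixed order, so
toggling a stage never shifts another's stream. Every output file is
declared in a sha256 manifest; identical config + seed reproduces identical
checksums (volumes are written as uncompressed `.nii` in the pipeline for
byte-stable output). CSVs are UTF-8, comma-separated, empty cell = missing.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data at
the study's natural scale where cheap (n = 159, ~2,000 voxels for recovery,
covariance and imputation checks) and at reduced scale where the full
protocol would be wasteful: the null calibration of the cluster test uses
100–200 cohorts of n = 60 with 500 permutations; Bayesian-lasso recovery
uses n = 100, p = 500 with 1,000 retained draws and 10 hold-out repeats.
These sizes are the package's choice of a thorough-but-frugal default;
every check recomputes its quantities from scratch at run time.

## Known limitations

- The edge-attenuation bias of the dependency field (out-of-mask p = 0)
  slightly depresses magnitudes at mask borders.
- The correlogram's canonical-sign binning pools (Δ, −Δ); directional
  asymmetries (as opposed to axis anisotropies) are invisible to it.
- Single imputation understates downstream uncertainty relative to multiple
  imputation; ordinal/non-Gaussian instruments are treated as Gaussian.
- Permutation FWE assumes exchangeability of score residuals under the
  confound model; heteroscedastic subjects would violate it.
- sigma²'s slow mixing in p ≫ n lasso fits means its interval estimates
  need long chains even when weight summaries are stable.
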