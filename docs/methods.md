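# Methods

This note records the models implemented in `dtipair`, the assumptions they
make, the parameters that matter, and the design choices taken where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and tensor fit

Water diffusion per voxel is modelled by a single symmetric positive tensor
D (mm²/s) in the standard mono-exponential signal equation
S(b, g) = S₀ · exp(−b · gᵀDg). The fit is ordinary (unweighted) log-linear
least squares over the six unique components: S₀ is the mean of the b = 0
volumes, and each masked voxel solves ln(S/S₀) = −b gᵀDg. One pseudoinverse
of the shared design matrix serves every voxel. The scheme must contain at
least one b = 0 volume and span rank 6 in the quadratic-form design;
otherwise the fit refuses with "degenerate gradient scheme".

Numerical choices:

- **Signal floor.** Signals are clipped at 10⁻⁶·S₀ before the logarithm so
  noise-dominated voxels produce large-but-finite diffusivities instead of
  −∞.
- **Negative eigenvalues** (possible under noise, since the log-linear fit
  does not constrain positivity) are *kept*, not clamped, and counted for
  QC. Clamping would silently bias TSkew, which is cubic in the deviations;
  FA may exceed 1 on such voxels and the affected-voxel count is reported.
- **Units.** Everything is standardized on mm²/s with b in s/mm²; the
  scaling identity S(c·b, D/c) = S(b, D) is covered by a test.
- **Weighting.** Weighted least squares (per-signal weights) was left out:
  on the noise regimes exercised here the OLS estimator is unbiased enough
  (median FA bias under Rician σ = S₀/30 is bounded by 0.05 in the suite)
  and OLS is exactly reproducible with one matrix factorization.

## Scalar metrics

From sorted eigenvalues λ₁ ≥ λ₂ ≥ λ₃:

| metric | definition | units |
|---|---|---|
| MD | (λ₁+λ₂+λ₃)/3 | mm²/s |
| FA | √(3/2) · ‖λ−MD‖ / ‖λ‖, 0 if λ = 0 | — |
| AD | λ₁ | mm²/s |
| RD1, RD2 | λ₂, λ₃ | mm²/s |
| TSkew | ⅓ Σᵢ (λᵢ−MD)³ | (mm²/s)³ |

FA uses the standard normalized-deviation form (the common convention when
no explicit formula is mandated). All five scalar functions are symmetric
in their arguments; this permutation invariance is property-tested.

## Regional aggregation

Scalar maps are reduced over the 48 regions of the JHU ICBM-DTI-81
white-matter atlas (the packaged `data/jhu_regions.tsv` fixes ids 1–48 and
names). Atlas-to-subject registration is out of scope: label volumes are
expected (and synthesized) in subject space.

Per region and metric, three summary statistics: mean, sample standard
deviation (ddof = 1), and moment skewness g₁ = m₃/m₂^{3/2}. g₁ (the biased
moment form) was chosen over the adjusted G₁ as the simplest convention;
regions here have enough voxels for the difference to be immaterial. A
statistic whose minimum sample size is not met (≥1 for μ, ≥2 for σ, ≥3 and
nonzero variance for sk) is stored as 0 with a missing flag, never NaN.
Column order is frozen: metric-major (FA, MD, AD, RD1, RD2, TSkew),
statistic-minor (μ, σ, sk) — `FA_mu … TSkew_sk`.

Subject-level QC follows the blank-volume rule: a subject fails if any
metric volume is zero at more than a threshold fraction (default 0.5,
configurable and logged) of in-mask voxels — the signature of an upstream
fit or masking failure. Region-level degeneracies only flag cells; they
never reject a subject.

One reading ambiguity is recorded rather than guessed at: "ranking" feature
values across areas is implemented as assembling the ordered 48-row matrix,
not as a rank transform — the worked feature matrix contains raw summary
statistics.

## Pair-correlation representation

For subject i, ρ_{l,m} = Pearson correlation of the 18-element rows
F[l,:] and F[m,:]. The rows are correlated **raw** — no per-column
standardization — because the representation is defined that way.
Caveat: the 18 columns mix scales (FA ∈ [0,1], MD ≈ 10⁻³ mm²/s,
TSkew ≈ 10⁻⁹), so large-scale columns dominate the correlation. An
optional within-subject z-scoring across regions (`zscore_columns=True`)
exists, OFF by default.

Zero-variance rows and missing regions yield ρ := 0 with a flag (not NaN),
keeping downstream matrices finite. The strict upper triangle is serialized
in lexicographic (l, m) order; for 48 regions,
pos(l, m) = (l−1)(96−l)/2 + (m−l) − 1 with 1-based l < m and 0-based pos,
giving 1128 features. The formula and its inverse are frozen and
exhaustively round-trip-tested so that selected-feature indices are
portable across runs.

## RFE-CV feature selection

The selector is scored by balanced accuracy — the mean of per-class
recalls, robust to class imbalance. If a class is absent from the truth
labels, the score is computed over the classes present, with a warning
(sklearn's scorer agrees whenever both classes appear; that agreement is a
test).

Procedure, per stratified fold (default k = 10, shuffled with a fixed
seed): fit the ranking kernel on the training split, score the held-out
split at the current subset size, drop the `step` weakest features by the
training-split ranking, repeat down to one feature. Per-size means over
folds select the winning size (ties → smaller size); the elimination is
then repeated on the full data to name the selected set, and the kernel is
refit on it for final signed importances.

The fold-wise design is deliberate. Ranking on the *full* data at each
round — the naïve two-loop reading — leaks the held-out labels into every
per-size score: on label-free data at n = 120, p = 1128 it certifies a
selected subset at a CV score of ~1.0 (the classic selection-bias artifact
in gene-expression RFE). The fold-wise protocol keeps the per-size scores
honest (null cohorts score 0.50–0.60 in the suite) and is what the
standard toolkit implementation does; that implementation also serves as
an independent oracle in the tests, which require exact agreement of every
per-size mean score and of the selected set. Note the selected set itself
is still named on the full cohort — evaluating classifiers on it with CV
over the same cohort inherits the source design's optimism; the harness's
`selector=` argument to `cross_validate` offers a fully nested protocol as
a clearly separate, honest-estimate mode.

Ranking kernels: linear SVM (C = 1), random forest (100 trees), logistic
regression with l1 (liblinear) or l2 (lbfgs) penalty. Linear kernels rank
by |coefficient|, the forest by impurity importance; exact ties break
toward the smaller feature index so the order is total and elimination
deterministic.

`step` (features dropped per round) defaults to 1; desk-scale runs on the
1128 pair features use step = 25, which visits sizes …, 53, 28, 3, 1 and
keeps proper resolution near small optima at ~2% of the step-1 cost. A
very coarse tail (e.g. step = 100, jumping 28 → 1) can strand the argmax
on a single feature when one planted pair alone classifies well.

## Classifier harness

Eight families behind one adapter (fit / predict / decision-score):
LinearSVC, LogisticRegression, PassiveAggressive, SVC, GaussianNB,
RandomForest, XGBoost, MLP. The classifiers are off-the-shelf; the
folding, scoring, grid search and report layout are bespoke. Grid search
is exhaustive over the packaged `data/grids.yaml` with stratified 5-fold
mean balanced accuracy as the criterion; parameter combinations the
library rejects (e.g. l1 + hinge for a linear SVM, some solver/penalty
pairs for logistic regression) are skipped and counted, not fatal.
`data/fixed_params.yaml` ships a frozen per-family configuration for
re-split evaluation runs at k ∈ {2, 4, 5, 10}. AUC is pooled over the
concatenated test folds from continuous decision scores where available
(`decision_function`, else `predict_proba`), falling back to predicted
labels with the source flagged. MLP training is capped at 400 epochs for
bounded desk runtime. Stored mean/sd are validated against the stored
per-fold scores at construction, so reports cannot drift from their folds.

## Synthetic cohorts

The generators define controlled study conditions with known ground truth;
they are stand-ins, not data facsimiles, and every distributional choice is
recorded in the ground-truth sidecar.

**DWI phantoms.** A deterministic slab partition of the voxel grid gives
each of the 48 regions ≥1 voxel. Each region receives a ground-truth tensor
with baseline eigenvalues (1.7, 0.4, 0.3)×10⁻³ mm²/s — the physiological
white-matter regime, keeping FA ≈ 0.76 and MD ≈ 0.8×10⁻³ where the metrics
are meaningful — rotated to a seed-reproducible random orientation shared
across classes. Case subjects scale the eigenvalues of regions in
`affected_pairs` by (1 + effect_size). Signals follow the forward model
with S₀ = 1000 and Rician noise sqrt((S+ε₁)² + ε₂²), ε ~ N(0, σ²), default
σ = S₀/30 (a mid-range magnitude-SNR of 30); with S = 0 the magnitude is
Rayleigh with mean σ√(π/2), which is Monte-Carlo-tested. Defaults:
grid 12×12×12, 32 Fibonacci-spiral directions at b = 1000 s/mm² plus one
b = 0 (the minimal 6-direction case falls back to the classic icosahedral
scheme, since the 6-point spiral is rank-deficient for the tensor design).

**Feature-level fast path.** Per subject, region rows are
x_r = p + e_r ∈ ℝ¹⁸ with a cohort-level shared profile p (scale 0.7,
inducing a common baseline inter-region correlation ≈ 0.33, mimicking the
shared-profile correlation floor of real regional statistics) and unit
Gaussian noise e_r. In case subjects only, each affected pair mixes a
shared latent w into both rows with weight a = effect_size/(1+effect_size)
— a latent *orientation-coupling* analog — so the planted class difference
lives exactly in ρ_{l,m}. Control subjects burn the same RNG draws so the
two classes' streams stay aligned. The generated matrices then pass
through the real correlation stage. Defaults: n_per_class = 60 (cohort
n = 120, comparable to a mid-sized multi-site study), effect_size = 1.5,
planted pairs (18,45), (4,48), (1,11) — anatomically meaningful internal
capsule/uncinate, corpus callosum/tapetum and cerebellar-peduncle pairs.

What passing tests on these cohorts show: the pipeline detects planted
inter-region coupling of the stated strength at the stated sample size,
and certifies nothing when there is none. What they do not show: robustness
to site effects, registration error, crossing fibers, motion, or any other
real-data pathology the generators do not model.

## Problem sizes used in the shipped runs

The acceptance script and end-to-end tests use: 100 random noiseless
tensors for fit recovery; 20 seeded cohorts of n = 120 at effect size 1.5
(RFE step 25) for planted-pair recovery; one null cohort of n = 120 for
the chance-level checks; classifier evaluation with the frozen parameter
set. These sizes give stable Monte-Carlo estimates (recovery-rate SE ≈ 7%
at rate 0.9, fold-score SE ≈ 0.02) while keeping a full run in minutes on
one CPU.

## Known limitations

- Single-tensor model only: no multi-shell, DKI/NODDI, or crossing-fiber
  voxels; no eddy/motion/EPI simulation; no skull stripping or atlas
  registration (out of scope by construction).
- Raw-row correlations are scale-dominated by MD-like columns (documented
  caveat; optional z-scoring available).
- The headline protocol selects features on the full cohort before CV, as
  the source design does; honest generalization estimates require the
  nested mode.
- Balanced-accuracy tie-breaks and importance tie-breaks are deterministic
  but convention-bound (smaller size / smaller index); other conventions
  would select different but equally-scoring sets.
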