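# Methods

## Model

An FC matrix is the Pearson correlation of BOLD time series between R brain
regions: symmetric, unit diagonal, entries in [−1, 1].  The angle-basis model
treats the bandpass-filtered signal at region c as a constant-amplitude
sinusoid at a shared frequency with phase θ_c, in which case the correlation
of two regions is exactly cos(θ_c − θ_d).  A per-region jitter j_c ∈ [0, 1]
models partial decorrelation of a region from all others (j_c = 0 removes
every correlation involving c; in the time domain it corresponds to mixing
the sinusoid with independent noise of matched variance, x_c = j·sin +
√(1−j²)·ε, which has expected correlation j_c j_d cos(θ_c − θ_d) — the form
`signals.generate_sine_signals` realizes and the test suite verifies by
Monte Carlo).  Averaging N such bases gives the reconstruction

    ρ̃_cd = (1/N) Σ_n j_c⁽ⁿ⁾ j_d⁽ⁿ⁾ cos(θ_c⁽ⁿ⁾ − θ_d⁽ⁿ⁾),

a PSD matrix of rank ≤ 2N (each basis contributes uu᙮ + vv᙮ with
u = j∘cosθ, v = j∘sinθ).  The residual r = ρ − ρ̃ carries what the low-rank
phase structure cannot: in practice, stable subject-unique structure.

Conventions, applied everywhere:

- **Diagonal exclusion.**  The model diagonal is mean_n j_c², not 1, and the
  FC diagonal is uninformative; all losses, residual features and
  vectorizations use strictly off-diagonal entries only.
- **Loss.**  The optimizer minimizes the mean square residual over the
  R(R−1) off-diagonal entries and reports its square root (RMSE); the two
  have the same minimizer.
- **Vectorization.**  Strict upper triangle, row-major:
  (0,1),(0,2),…,(1,2),… — fixed so feature vectors are comparable across
  runs.  Length R(R−1)/2 (34,716 at R = 264); a basis holds 2R parameters.
- **Validation.**  Symmetry/range checks use absolute tolerance 1e-8; inputs
  within tolerance are symmetrized as (M+Mᵀ)/2 and clipped, beyond it
  rejected with the offending cell named.

## Fitting

Plain projected gradient descent with closed-form gradients; after every
step jitters are clipped to [0, 1] and phases wrapped modulo 2π.  The
best-seen iterate is returned.  Two schedule elements matter in practice:

- **Phase-first warmup** (`phase_warmup_fraction`, default 0.25): for the
  first quarter of the iterations only phases move.  Joint descent from a
  random initialization lets jitters collapse toward the absorbing j = 0
  set before the phases can organize (an all-zero-jitter basis has exactly
  zero gradient); with the warmup, single-basis recovery on model-realizable
  FC reaches machine precision.
- **R-independent step size**: the update multiplies the mean-loss gradient
  by learning_rate·(R−1)/4, making the default learning_rate = 1.0 work
  unchanged from R = 30 to R = 264.  Larger rates (≥ 5× default) diverge.

Defaults: N = 1, learning_rate 1.0, max_iterations 2000, convergence
tolerance 1e-8 on the per-step RMSE change (never triggered during warmup),
init: phases uniform on [0, 2π), jitters 1 (`random_phase_full_jitter`) or
uniform (`random_both`).  The problem is non-convex (bases are exchangeable
and each is invariant to a global phase shift or reflection, so only
cos-differences and jitter products are identified); `n_restarts` reseeds
the initialization and keeps the best loss.  With unit-jitter single-basis
targets random restarts essentially always succeed; with strongly varied
jitters roughly one restart in ten lands in a local minimum — use restarts.

`fit_many` runs the same update rule across a batch of matrices in lockstep
(converged elements frozen), yielding per-matrix results identical to
sequential fits while decomposing whole cohorts orders of magnitude faster.

**Basis-count sweeps.**  `fit_sweep` fits a strictly increasing list of N.
Because ρ̃ is a *mean* over bases, growing a solution from N_old to N_new
by proportionally duplicating bases (jitters rescaled by
√(N_new/(k·N_old)) per copy) preserves the reconstruction exactly whenever
N_old divides N_new, so the warm-started candidate cannot end worse than
its predecessor; each step also runs a fresh random fit and keeps the
better of the two, since warm starts alone stay trapped in the previous
solution's basin when more bases admit a much better joint fit.

## Signals and PLV

`pearson_fc` is the standard correlation matrix (zero-variance rows
rejected by region index).  The analytic signal uses the frequency-domain
Hilbert construction (scipy); PLV_cd = |mean_t e^{i(φ_c−φ_d)}| over analytic
phases, discarding 5% of samples at each end (configurable) against FFT edge
artifacts.  PLV is included as a comparison metric only.

## Fingerprinting

Every scan of a subject with ≥ 2 scans queries all scans with a *different*
scan label; a hit is a top-1 cosine-similarity match to the same subject.
Ties break to the lowest row index (measure-zero in practice).  Same-task
pairs are never compared; the same/different-subject similarity pools
partition all admissible pairs exactly once (histogram-ready).

## Prediction harness

Linear models only: Ridge (α = 1) for continuous targets (RMSE, targets
centered by the *training* mean — the centering constant never sees test
rows), L2 logistic regression (C = 1, ≤ 1000 iterations) for binary targets
(ROC AUC from decision scores).  Evaluation repeats random 80/20 splits
(default 20; splits resampled until both classes appear on both sides).
"Repeated splits" rather than resampling-with-replacement is the chosen
reading of bootstrap evaluation.  Ensembles average the two views' outputs
on identical splits, so ensembling a view with itself reproduces the single
view exactly — the correct null.  Cross-cohort transfer is one fit on the
full training cohort, one evaluation on the other cohort.  Result samples
are compared by two-sided Welch t-test (p = 1 for identical samples); the
choice of Welch over alternatives is a convention.  Ancestry analyses keep
two declared labels (AA/EA by default) and drop other rows before any
split.  Feature selection fits Ridge/Lasso on a caller-designated selection
half and returns the k largest-|coefficient| indices.

## Synthetic cohorts (the stated world)

`generate_cohort` draws, per subject: phenotype labels (age uniform on
8–22 y, sex F/M, ancestry AA/EA, diagnosis SZ with probability 0.3 — a
developmental-cohort age range with a case-enriched diagnosis mix), an
angle basis equal to a blocky population template (4 phase-clustered blocks;
the first block, highest jitter 0.9, plays the default-mode-network role)
plus phenotype effects and N(0, subject sd) trait variation, and a fixed
symmetric signature matrix.  Each scan perturbs the subject's basis with
fresh N(0, scan sd) state variation — different in-scanner tasks put the
brain in different large-scale phase configurations — and adds fresh
symmetric noise; matrices are symmetrized, clipped and given a unit
diagonal.  Defaults: subject phase/jitter sd 0.04/0.02, scan phase/jitter
sd 0.15/0.05, signature sd 0.04, scan noise sd 0.05; default effects are
moderate (sex: +0.15 jitter on the DMN-like block for F; diagnosis: −0.15
for SZ; ancestry: +0.25 rad phase and +0.10 jitter on another block; age:
0.30 rad per age-sd on a third).  Chosen once so that the generated world
reproduces the qualitative regime reported for real cohorts — cross-task
FC fingerprinting mediocre (~0.8 here), residual fingerprinting near
perfect, sex AUC ≈ 0.9 — with scan-state variation exceeding trait
variation as the operative mechanism.

What the generator does *not* emulate: temporal autocorrelation or
hemodynamics (FC is built directly, not from time series), site/scanner
effects, heavy-tailed motion artifacts, realistic empirical marginals of
FC entries, or correlated phenotypes (age and diagnosis are independent
here).  A green cohort-level test therefore establishes that the analysis
chain behaves correctly in a world obeying the model's own assumptions plus
structured nuisance — not that real data obey them.

## Phenotype-conditioned synthesis

`train_phenotype_models` fits 20 frozen linear critics per phenotype on
bootstrap resamples of vectorized FC and records, per classification
phenotype, the class-conditional mean decision score, plus the cohort's
mean feature vector.  `synthesize_fc` starts from a seeded random basis and
runs projected gradient descent (same warmup; sup-norm-normalized steps
with cosine decay from 0.05) on

    mean_p ((bag prediction − target_p)/scale_p)² + anchor · mean(((v−v̄)/s)²)

Targeting the class-conditional mean score rather than a fixed ±1 and
anchoring to the population mean FC (anchor weight 1.0) are both necessary:
±1 is far inside the decision boundary, and without the anchor the
optimizer controls only a few linear directions, leaving the matrix in a
random-basis regime that independent critics classify incorrectly (0/20
held-out acceptance in piloting, vs 18/20 with both changes).  Different
seeds give visibly different matrices with matching achieved predictions.

## Numerical notes and limitations

- Fitting is deterministic given (FC, config, seed) under a fixed
  floating-point environment; bundles store seed and final loss.
- N-basis feasible sets are not nested for N → N+1 in general (per-basis
  jitter mass is capped), only for N → kN; sweep monotonicity for
  non-divisible steps is empirical, not guaranteed.
- Only cos(θ_c − θ_d) and jitter *products* are identifiable (gauge,
  reflection, and basis-permutation invariance); reported parameters are
  one representative of the equivalence class.
- Decomposition bundles are plain-text directories (TSV at 17 significant
  digits + meta.json, schema version 1); round trips are lossless at double
  precision.
- The time-domain simulator uses white Gaussian jitter noise and a single
  frequency; multi-frequency synthesis and bandpass filtering are out of
  scope, and PLV here is a generic implementation for comparison only.
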