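# Methods

This note documents the model behind `latentgeom`, the choices made where
the design was genuinely open, and what the synthetic validations do and do
not establish.

## The Gaussian code model and the error formula

The package models paired neural responses **x** ∈ ℝⁿ and latent variables
**z** ∈ ℝᵈ as jointly zero-mean Gaussian with covariances Ψ = E[xxᵀ],
Φ = E[xzᵀ], Ω = E[zzᵀ]. A task is a hyperplane through the origin of the
latent space with standard-Gaussian normal **T**; its labels are
y = sign(T·z). The readout is supervised-Hebbian: w = (1/p) Σ_μ y_μ x_μ,
prediction sign(w·x). For balanced labels this is exactly the
difference-of-means classifier (an identity the test suite checks
bit-exactly).

Averaged over tasks, the generalization error after p training samples is

E_g = (1/π) arctan √( π/(2 p c² PR(Ψ)) + 1/f + 1/s − 1 ),

with the four geometry statistics defined in the README. Conventions and
numerical choices:

- **Squared-trace reading.** The numerator of f and s is the *squared
  trace* [Tr(ΦΦᵀ)]², not Tr[(ΦΦᵀ)²]. Only this reading gives f ≤ 1 with
  equality exactly when ΦᵀΦ ∝ Ω (a Cauchy–Schwarz argument on
  Ω^{1/2} vs Ω^{−1/2}ΦᵀΦ), which matches the role of f as a whiteness
  measure; it is also the reading under which the optimal-spectrum formula
  below is the exact stationarity condition of the error (we re-derived the
  stationarity to confirm).
- **Degenerate Ω.** Ω is inverted through its eigendecomposition with a
  relative cutoff of 1e−10 times the largest eigenvalue; directions below
  the cutoff are dropped. Centering/z-scoring pipelines can make latents
  exactly rank-deficient and this keeps all metrics finite.
- **Infinite SNF.** Noiseless codes (Ψ = ΦΩ⁻¹Φᵀ) have no noise along the
  coding directions; s is stored as +inf and 1/s contributes exactly 0.
  The noise-overlap trace is declared zero below 1e−12 of the metric's
  natural scale; a negative overlap beyond tolerance raises an error (the
  triple is not realizable).
- **Radicand clamping.** Near perfect codes, floating point can push the
  radicand slightly negative; it is clamped to 0 (E_g = 0) and a warning is
  emitted if the violation exceeds 1e−6.
- **PSD tolerance.** Sample covariances are accepted as PSD when the
  smallest eigenvalue is ≥ −1e−8 times the largest, and clipped to zero.
- **c = 0.** A code with Φ = 0 carries no task information; the predicted
  error is returned as exactly 0.5 with a `chance` flag.

The formula is asymptotic (n, d, p large and comparable). At small n and d
(tens), predictions are accurate to roughly 0.01–0.02 in E_g in our
simulations; the tests quantify this under the protocols below.

## Monte-Carlo validation protocol

The Gaussian validation grid draws latents with power-law covariance
spectra ω_i = 5 i^{−α}, α ∈ {0, 0.5, 1}, d = 40, and forms codes either by
a random Gaussian mixing matrix A (n = 80; x = Az) or by whitening
(x = Ω^{−1/2}z). Each cell trains the Hebbian rule on p ∈ {20, 50, 100,
300} samples for 300 random tasks, evaluates on 1000 fresh samples, and
repeats the whole procedure 30 times with fresh tasks and data. The
analytical prediction uses the *population* covariances of the drawn code
(one mixing matrix per cell), so theory and simulation are compared on the
same object. Acceptance requires |theory − simulation| ≤ max(0.02, 3 SEM)
in every cell, with the SEM taken across repeats (the across-task SEM is
reported as a diagnostic). The test-set size is not pinned down by the
protocol; 1000 is the package default and is configurable.

Labels are never rebalanced: the Hebbian rule is applied verbatim, and the
class balance of each training set is reported as a diagnostic. Ties
(sign(0)) resolve to +1 deterministically — a probability-zero event under
continuous latents, fixed for reproducibility.

## Optimal codes

For fixed Ω (eigenvalues ω₁ ≥ … ≥ ω_d) and budget p, the error-minimizing
code is noiseless and rank d, with Ψ's principal axes mapped one-to-one
onto Ω's and eigenvalues

ψ_i = C · ω_i / (2p ω_i + π Σ_k ω_k),   C > 0 arbitrary.

Intuition: with tasks drawn uniformly, low-variance latent directions are
on average less informative; at small p the optimal code compresses them
(steep spectrum, higher c, lower PR), and as p grows it expands them (the
spectrum flattens toward ∝ ω_i / ω_i = const).

The numerical validator parameterizes realizable codes by the factor
L = [[Ω^{1/2}, 0], [X₁, X₂]] with LLᵀ the joint covariance, so PSD holds by
construction, Φ = X₁Ω^{1/2} and Ψ = X₁X₁ᵀ + X₂X₂ᵀ. Choices:

- The optimizer minimizes the *inner argument* π/(2pc²PR) + 1/f + 1/s − 1
  rather than E_g itself: arctan√ is a strictly increasing transform, so
  the minimizers coincide, and the inner argument has no vanishing
  gradients near perfect codes. Analytic gradients are supplied.
- The objective is invariant to a joint rescaling of (X₁, X₂); the returned
  code is trace-normalized (Tr Ψ = 1) after the fact. L-BFGS runs from 5
  random starts (guarding permutation-related saddles) with ftol 1e−12;
  convergence diagnostics are recorded in the code's metadata and a run
  with no converged restart is flagged and warned about, never silently
  returned.
- The constructed closed-form code is chosen rank-d exactly (any extra
  units carry zero variance). The error depends on Ψ only through Tr(Ψ²)
  once the signal part is fixed, and any variance added outside the signal
  axes increases Tr(Ψ²) or the noise overlap, so rank d is optimal; ties in
  ω are broken by stable index order.

## Hidden-manifold MLP experiments

Non-Gaussian responses are produced by passing Gaussian latents
(ω_k = k^{−0.2}) through a random MLP whose layer widths double at each of
three linear+ReLU stages (1/√fan-in Gaussian weights), and a *trained*
three-hidden-layer MLP of linear–batchnorm–ReLU blocks with one linear
readout per task from the shared penultimate layer, trained with Adam
(lr 1e−3, batch 128) for one epoch on the multitask logistic loss. The MLP
engine is a small in-package numpy implementation (forward, batchnorm,
backprop, Adam); batch-norm statistics are frozen at their running
estimates whenever representations are extracted, so representations are
deterministic functions of inputs.

Default experiment sizes are desk scale: d = 20 latents, 2·10⁴ training
latents, 100 training tasks; evaluation on 1000 fresh latents and 300 fresh
tasks, theory at p = 300, empirical error from 300/700 train/test splits
(averaged over 5 splits). The full-scale protocol (d = 40, 5·10⁵ latents,
500 tasks) is reachable through the same config fields. The trained
network's hidden widths default to the input width (constant); only the
depth of the trained network is pinned down by the protocol, and a
constant width keeps the desk-scale run cheap while preserving the layer
trends of interest. At these sizes the three qualitative signatures hold
robustly across seeds: penultimate-layer error below input error,
theory-vs-empirical R² ≥ 0.99 across layers, and a PR increase at every
ReLU stage of the trained network.

Per-layer geometry is computed from *sample* covariances of the evaluation
set (1/(p−1), both matrices centered — the unbiased convention; the model
is zero-mean so centering only removes the sample mean).

## Poisson-GLM signal-subspace dimension

The estimator asks how many dimensions of a population's activity carry
information about behavioral latents, separating signal from trial-to-trial
noise by modeling the conditional mean v(z) = E[x|z]:

1. **Basis.** Isotropic 2-D Gaussian bumps tile the occupied position bins
   (centers only where occupancy exceeds 20 time bins, adapting to the
   trajectory); 1-D Gaussians tile each further variable (velocities)
   separately; the whole block is duplicated per trajectory type when one
   is supplied. Widths default to the bin sizes; a grid search over widths
   is available but off by default. Features equal 1 at their own center.
2. **Per-unit GLM.** ℓ2-regularized Poisson regression with exponential
   link (scikit-learn's `PoissonRegressor`), regularization chosen per unit
   by 10-fold cross-validated deviance over 10 log-spaced values in
   1e−4..1e2.
3. **Null screening.** D² = 1 − dev(model)/dev(null) with the
   constant-rate null, both cross-validated. A unit counts as *tuned* only
   if its CV D² exceeds max(0.01, 2 fold-wise SEs of the D² estimate);
   otherwise it is replaced by the null model. The floor is needed because
   the winning regularizer is a minimum over the grid: a pure-noise unit's
   CV D² lands slightly *above* zero (we measured −7e−6..1e−3 across noise
   units at 5000 bins), and the selection bias is shared across folds, so
   an SE rule alone has heavy tails. The 0.01 floor ("at least 1% of
   deviance explained") sits orders of magnitude above that bias scale and
   far below genuinely tuned units; the cost is that very weakly tuned
   units may be screened out, which biases the dimension estimate
   conservatively.
4. **Dimension.** v(z) is evaluated on the empirical latent distribution
   (a regular-grid evaluation is available but off by default), each unit's
   column is z-scored — null units z-score to exactly zero and cannot
   contribute — and the dimension is PR(cov v). If every unit is null the
   dimension is undefined and an error is raised rather than a number
   returned.

The synthetic validation population uses a mean-reverting (OU) position
trajectory in the unit box (timescale 20 bins, step 0.08, clipped at the
walls), 500 ms bins, and log-linear Gaussian-bump tuning (amplitude 2,
width 0.15, base rate 2 Hz) — rates and coverage in the range of
hippocampal place-cell recordings, and within the GLM's model family so
that estimation error, not model mismatch, is what the recovery test
measures. With 30 units (5 pure noise) and 5000 bins, the pipeline recovers
the ground-truth signal-subspace PR within 5% in our runs (10% is the
acceptance bound) and null-flags all noise units.

## What the synthetic validations do not show

- The Gaussian and hidden-manifold generators have stationary statistics
  and exactly (or asymptotically) Gaussian latents; real recordings have
  drift, heavy tails and latent variables that are neither Gaussian nor
  fully observed. The formula's accuracy there is an empirical question the
  package can help ask, not one these tests answer.
- The GLM recovery is a self-consistency check: real tuning curves are not
  log-linear in any fixed basis, and unmeasured latents inflate apparent
  noise. The null screen's 1%-deviance floor may discard genuinely but
  weakly tuned units.
- Multi-unit confounds (recording quality differing across regions,
  local tuning similarity) can bias PR and SNF in ways no synthetic test
  reproduces.

## Reproducibility

Every stochastic routine takes a numpy `Generator`; experiment configs
carry a single seed expanded into independent child streams via
`SeedSequence` spawning, so identical configs reproduce outputs
bit-for-bit. Experiment runners return tidy DataFrames plus a provenance
dict (config, config hash, library version) and write CSV/JSON twins; no
result exists only as a plot. `scripts/acceptance.py --seed S --out F`
re-runs all validations at the sizes above (~90 s on one CPU).
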