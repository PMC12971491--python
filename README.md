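# latentgeom

Geometry of neural population codes for multitask linear readout.

## The problem

Animals (and networks) learn many binary decisions that all depend on the
same low-dimensional latent structure — an object's position, a maze
coordinate, a pose parameter. Which features of a neural population's
activity make those latents easy to read out downstream? `latentgeom`
implements an analytical answer for a supervised Hebbian readout and the
machinery to validate and apply it: if responses **x** ∈ ℝⁿ and latents
**z** ∈ ℝᵈ are jointly zero-mean with covariances

```
Ψ = E[xxᵀ]   (neuron–neuron),   Φ = E[xzᵀ]   (neuron–latent),   Ω = E[zzᵀ]   (latent),
```

then four statistics of this triple determine the error of the readout
ŷ = sign(w·x), w = (1/p) Σ_μ y_μ x_μ, averaged over random linear
shatterings of the latent space (labels y = sign(T·z), T Gaussian):

| statistic | definition | meaning |
|---|---|---|
| `c`  | Tr(ΦΦᵀ) / (Tr Ψ · Tr Ω) | total neural–latent correlation |
| `PR` | [Tr Ψ]² / Tr(Ψ²) | participation-ratio dimension of the responses |
| `f`  | [Tr ΦΦᵀ]² / (Tr Ω · Tr(ΦᵀΦ Ω⁻¹ ΦᵀΦ)) | signal–signal factorization, = 1 iff ΦᵀΦ ∝ Ω (whitened signal) |
| `s`  | [Tr ΦΦᵀ]² / (Tr Ω · Tr(Φᵀ(Ψ − ΦΩ⁻¹Φᵀ)Φ)) | signal–noise factorization, = ∞ for noiseless codes |

The task-averaged generalization error after training on p samples is

```
E_g = (1/π) · arctan √( π / (2 p c² PR)  +  1/f + 1/s − 1 ).
```

The first term decays as 1/p (few-shot regime: maximize total signal and
dimension); `1/f + 1/s` is an irreducible error set by how well the code
factorizes signal from signal and signal from noise (many-shot regime).

The package also provides:

- **Hebbian readout simulator** — random task batteries, exact Hebbian
  weights, Monte-Carlo error estimates that validate the formula;
- **optimal codes** — the closed-form error-minimizing spectrum
  ψᵢ = C·ωᵢ/(2pωᵢ + π Σₖωₖ) at a fixed latent covariance and sample budget,
  plus a direct numerical optimizer over realizable (jointly PSD) codes that
  confirms it;
- **synthetic generators** — power-law Gaussian latents, linear/whitened
  codes, random and multitask-trained MLP codes (the hidden-manifold
  construction), and covariance estimation from finite samples;
- **signal-subspace dimension** — a Poisson-GLM pipeline (Gaussian basis
  functions, cross-validated ℓ2 regularization, deviance-explained null
  screening) that estimates the dimension of the task-relevant subspace,
  PR(cov E[x|z]), from spike counts and behavioral traces.

## Worked example

Fit the Gaussian code model to paired responses/latents and compare the
analytical error prediction with a simulated Hebbian readout:

```python
import numpy as np
from latentgeom import (GaussianCodeModel, PowerLawSpectrumSpec,
                        power_law_omega, sample_gaussian_latents)

rng = np.random.default_rng(0)
omega = power_law_omega(PowerLawSpectrumSpec(d=20, alpha=0.5))
Z = sample_gaussian_latents(omega, 10_000, rng)
A = rng.standard_normal((60, 20))
X = Z @ A.T + 0.5 * rng.standard_normal((10_000, 60))   # noisy linear code

res = GaussianCodeModel(X, Z).fit(bootstrap=50, rng=rng)
print(res.summary(p=100))
mc = res.monte_carlo_error(p=100, n_tasks=100, n_test=500, n_repeats=10,
                           rng=np.random.default_rng(1))
print(f"simulated E_g at p=100: {mc.mean:.4f} +/- {mc.sem:.4f}")
```

```
      Gaussian Code Geometry Results
==============================================
Units (n):            60
Latent dim (d):       20
No. observations:     10000
----------------------------------------------
statistic                 estimate     boot SE
----------------------------------------------
correlation c            0.0624019    0.000311
dimension PR               12.7356      0.0706
SSF f                     0.667813     0.00401
SNF s                      602.711        5.34
----------------------------------------------
E_g (p=100)               0.233829
  few-shot term            0.31674
  irreducible term         1.49908
==============================================
simulated E_g at p=100: 0.2245 +/- 0.0019
```

The 60-unit code concentrates on ~13 effective dimensions (`PR`), carries a
total signal correlation `c` ≈ 0.06, and mixes latents into correlated
neural directions (`f` ≈ 0.67, so even with unlimited data the readout
would keep an irreducible error); the added isotropic noise barely overlaps
the coding directions (`s` ≈ 600). Plugging these into the formula predicts
E_g ≈ 0.234 at p = 100 training samples, within about 0.01 of the simulated
readout error.

A command-line interface mirrors the library:

```bash
latentgeom metrics --responses X.tsv --latents Z.tsv -p 100
latentgeom simulate-readout --d 40 --n 80 --alpha 1.0 --code whitened -p 300
latentgeom optimal-code --omega 3,1 --p-grid 1,10,100 --n 4
latentgeom task-dimension --counts counts.tsv --latents latents.tsv
latentgeom experiment gaussian --seed 0 --out-dir results
```

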