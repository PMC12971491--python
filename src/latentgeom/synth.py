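"""Synthetic ensembles for exercising the geometry theory.

Generators for every data regime the theory is validated on:

* Gaussian latents with power-law covariance spectra (omega_i = scale * i^-alpha);
* linear codes x = A z (random Gaussian mixing, optional isotropic noise) and
  whitened codes x = Omega^{-1/2} z;
* random multilayer-perceptron codes (hidden-manifold construction) and
  multitask-*trained* MLP codes, with per-layer representations;
* sample covariance estimation from paired (X, Z) matrices, random
  projections and column z-scoring used when comparing representations of
  different sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._mlp import MultitaskMLP
from .code import GaussianCode
from .readout import TaskBattery, make_labels

__all__ = [
    "PowerLawSpectrumSpec",
    "LinearCodeSpec",
    "MlpSpec",
    "power_law_omega",
    "sample_gaussian_latents",
    "apply_code",
    "make_random_mlp",
    "train_multitask_mlp",
    "random_code",
    "estimate_covariances",
    "random_projection",
    "zscore_columns",
    "save_dataset",
]


@dataclass(frozen=True)
class PowerLawSpectrumSpec:
    """Latent covariance with eigenvalues scale * i^-alpha, i = 1..d."""

    d: int
    alpha: float
    scale: float = 5.0
    rotate: bool = False  # apply a random orthogonal rotation to the eigenbasis

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class LinearCodeSpec:
    """Linear code x = A z (+ optional isotropic Gaussian noise).

    Either an explicit mixing matrix ``a_matrix`` or ``whiten=True``
    (x = Omega^{-1/2} z, which needs the latent covariance at apply time).
    """

    a_matrix: np.ndarray | None = None
    whiten: bool = False
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.whiten and self.a_matrix is not None:
            raise ValueError("whiten flag and explicit a_matrix are exclusive")
        if not self.whiten and self.a_matrix is None:
            raise ValueError("give a_matrix or set whiten=True")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_widths(d_in: int, depth: int = 3) -> list[int]:
    """Expanding width rule: each layer twice the size of the previous one."""
    widths, w = [], d_in
    for _ in range(depth):
        w *= 2
        widths.append(w)
    return widths


@dataclass(frozen=True)
class MlpSpec:
    """Random or trained MLP code over the latents.

    Untrained (``trained=False``): a random feature map of linear +
    nonlinearity stacks with 1/sqrt(fan-in) Gaussian weights; widths default
    to doubling each layer so the representation never loses dimension.
    Trained (``trained=True``): a three-hidden-layer network of
    linear–batchnorm–nonlinearity blocks with one linear readout per task
    from the shared penultimate layer, trained by Adam for ``epochs`` epochs.
    """

    widths: tuple[int, ...] | None = None  # None -> doubling rule from d_in
    nonlinearity: str = "relu"
    trained: bool = False
    n_tasks: int = 100
    epochs: int = 1
    batch_size: int = 128
    lr: float = 1e-3
    batchnorm: bool = True  # trained networks only

    def resolve_widths(self, d_in: int) -> list[int]:
        if self.widths is not None:
            return list(self.widths)
        return default_widths(d_in)


def power_law_omega(
    spec: PowerLawSpectrumSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Latent covariance with the power-law spectrum (diagonal unless rotated)."""
    eigs = spec.scale * np.arange(1, spec.d + 1, dtype=float) ** (-spec.alpha)
    omega = np.diag(eigs)
    if spec.rotate:
        if rng is None:
            raise ValueError("rotate=True needs an rng")
        q = _random_orthogonal(spec.d, rng)
        omega = q @ omega @ q.T
        omega = 0.5 * (omega + omega.T)
    return omega


def _random_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    return q * np.sign(np.diag(r))


def sample_gaussian_latents(
    omega: np.ndarray, p: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw p zero-mean Gaussian latent vectors with covariance omega."""
    omega = np.asarray(omega, dtype=float)
    w, v = np.linalg.eigh(0.5 * (omega + omega.T))
    root = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((p, omega.shape[0])) @ root.T


def _omega_inv_root(omega: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (omega + omega.T))
    if w[0] <= 0:
        raise ValueError("whitening needs a positive-definite latent covariance")
    return (v / np.sqrt(w)) @ v.T


def apply_code(
    Z: np.ndarray,
    spec: LinearCodeSpec | MlpSpec | MultitaskMLP,
    rng: np.random.Generator | None = None,
    omega: np.ndarray | None = None,
):
    """Map latents through a code.

    Linear specs return the response matrix X. MLP specs (or an already-built
    :class:`MultitaskMLP`) return the full list of per-stage representations
    ``[(name, array), ...]`` — the input, every linear stage and every
    nonlinearity stage — so layer-wise geometry can be computed.
    """
    Z = np.asarray(Z, dtype=float)
    if isinstance(spec, LinearCodeSpec):
        if spec.whiten:
            if omega is None:
                omega = np.cov(Z, rowvar=False)
            X = Z @ _omega_inv_root(np.asarray(omega, dtype=float)).T
        else:
            A = np.asarray(spec.a_matrix, dtype=float)
            if A.shape[1] != Z.shape[1]:
                raise ValueError(
                    f"mixing matrix expects d={A.shape[1]}, got {Z.shape[1]}"
                )
            X = Z @ A.T
        if spec.noise_sigma > 0:
            if rng is None:
                raise ValueError("noisy code needs an rng")
            X = X + spec.noise_sigma * rng.standard_normal(X.shape)
        return X
    if isinstance(spec, MlpSpec):
        if spec.trained:
            raise ValueError(
                "trained MlpSpec: build the network with train_multitask_mlp "
                "first, then pass the network to apply_code"
            )
        net = make_random_mlp(Z.shape[1], spec, rng)
        return net.representations(Z)
    if isinstance(spec, MultitaskMLP):
        return spec.representations(Z)
    raise TypeError(f"unsupported code spec {type(spec).__name__}")


def make_random_mlp(
    d_in: int, spec: MlpSpec, rng: np.random.Generator
) -> MultitaskMLP:
    """Random (untrained) feature-map MLP; no batchnorm, no readout heads."""
    if rng is None:
        raise ValueError("random MLP needs an rng")
    return MultitaskMLP(
        d_in=d_in,
        hidden=spec.resolve_widths(d_in),
        n_tasks=0,
        rng=rng,
        nonlinearity=spec.nonlinearity,
        batchnorm=False,
    )


def train_multitask_mlp(
    Z_train: np.ndarray,
    battery: TaskBattery,
    spec: MlpSpec,
    rng: np.random.Generator,
    inputs: np.ndarray | None = None,
) -> tuple[MultitaskMLP, np.ndarray]:
    """Train the multitask network on labels from ``battery``.

    Labels are the battery's shatterings of the *latents* ``Z_train``; the
    network itself consumes ``inputs`` (default: the latents themselves; in
    the hidden-manifold construction, the responses of a random MLP to those
    latents). The network has three hidden linear–batchnorm–nonlinearity
    blocks (widths from the spec; default constant at the input width) and
    one linear readout per task from the shared penultimate layer. Returns
    the trained network and the per-minibatch loss trace.
    """
    if not spec.trained:
        raise ValueError("spec.trained must be True")
    Z_train = np.asarray(Z_train, dtype=float)
    X_in = Z_train if inputs is None else np.asarray(inputs, dtype=float)
    if X_in.shape[0] != Z_train.shape[0]:
        raise ValueError("inputs and latents must have matching row counts")
    d_in = X_in.shape[1]
    widths = list(spec.widths) if spec.widths is not None else [d_in] * 3
    net = MultitaskMLP(
        d_in=d_in,
        hidden=widths,
        n_tasks=battery.n_tasks,
        rng=rng,
        nonlinearity=spec.nonlinearity,
        batchnorm=spec.batchnorm,
    )
    Y = make_labels(Z_train, battery)
    losses = net.train_epochs(
        X_in, Y, rng=rng, epochs=spec.epochs,
        batch_size=spec.batch_size, lr=spec.lr,
    )
    return net, losses


def random_code(
    n: int, d: int, rng: np.random.Generator, noiseless: bool = False
) -> GaussianCode:
    """Random realizable Gaussian code (joint covariance PSD by construction).

    Built through the Cholesky-style factor [[Omega^{1/2}, 0], [X1, X2]] with
    Gaussian X1, X2; ``noiseless=True`` drops the X2 block so all response
    variance is latent-driven (infinite SNF).
    """
    omega_factor = rng.standard_normal((d, d + 2))
    omega = omega_factor @ omega_factor.T / (d + 2)
    w, v = np.linalg.eigh(omega)
    omega_root = (v * np.sqrt(np.clip(w, 1e-12, None))) @ v.T
    x1 = rng.standard_normal((n, d))
    phi = x1 @ omega_root
    psi = x1 @ x1.T
    if not noiseless:
        x2 = rng.standard_normal((n, n)) / np.sqrt(n)
        psi = psi + x2 @ x2.T
    return GaussianCode(psi=psi, phi=phi, omega=omega)


def estimate_covariances(X: np.ndarray, Z: np.ndarray) -> GaussianCode:
    """Sample covariance triple from paired data, centering both matrices.

    Uses the unbiased 1/(p-1) normalization throughout; the joint sample
    covariance is PSD by construction (up to roundoff).
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z must have matching row counts")
    p = X.shape[0]
    if p < 2:
        raise ValueError("need at least 2 samples to estimate covariances")
    Xc = X - X.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    psi = Xc.T @ Xc / (p - 1)
    phi = Xc.T @ Zc / (p - 1)
    omega = Zc.T @ Zc / (p - 1)
    return GaussianCode(
        psi=0.5 * (psi + psi.T), phi=phi, omega=0.5 * (omega + omega.T),
        meta={"estimated_from_samples": p},
    )


def random_projection(
    X: np.ndarray,
    target_dim: int,
    n_projections: int,
    rng: np.random.Generator,
    orthogonalize: bool = False,
) -> list[np.ndarray]:
    """Gaussian random projections of X down to ``target_dim`` columns.

    Used to compare representations of different widths on equal footing;
    downstream metrics are averaged over the ``n_projections`` draws. With
    ``orthogonalize=True`` the projection matrix has orthonormal columns
    (exactly metric-preserving when target_dim equals the source width).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if target_dim > n:
        raise ValueError(f"target_dim {target_dim} exceeds width {n}")
    out = []
    for _ in range(n_projections):
        P = rng.standard_normal((n, target_dim)) / np.sqrt(target_dim)
        if orthogonalize:
            P, _ = np.linalg.qr(P)
        out.append(X @ P)
    return out


def zscore_columns(M: np.ndarray, sd_floor: float = 0.0) -> np.ndarray:
    """Center each column and divide by (sd + sd_floor).

    A positive floor keeps near-constant columns from being blown up
    (constant columns map to exact zeros instead of dividing by zero).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to z-score")
    sd = M.std(axis=0, ddof=1)
    centered = M - M.mean(axis=0)
    denom = sd + sd_floor
    out = np.zeros_like(centered)
    np.divide(centered, denom, out=out, where=denom > 0)
    return out


def save_dataset(
    directory: str | Path,
    X: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray | None = None,
    manifest: dict | None = None,
    name: str = "dataset",
) -> None:
    """Write (X, Z[, Y]) as delimited text plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{name}_X.tsv", X, delimiter="\t")
    np.savetxt(directory / f"{name}_Z.tsv", Z, delimiter="\t")
    info = {"p": int(np.asarray(X).shape[0]),
            "n": int(np.asarray(X).shape[1]),
            "d": int(np.asarray(Z).shape[1])}
    if Y is not None:
        np.savetxt(directory / f"{name}_Y.tsv", Y, delimiter="\t", fmt="%d")
        info["n_tasks"] = int(np.asarray(Y).shape[1])
    if manifest:
        info["manifest"] = manifest
    (directory / f"{name}.json").write_text(json.dumps(info, indent=2, default=str))
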