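"""Geometry statistics of a Gaussian code and the analytical readout error.

Four sample-size-independent statistics of the covariance triple
(psi, phi, omega) determine the task-averaged generalization error of a
supervised Hebbian readout trained on p samples:

* ``c``  — total neural–latent correlation,
  Tr(Phi Phi^T) / (Tr(Psi) Tr(Omega))
* ``PR`` — participation ratio of Psi, [Tr(Psi)]^2 / Tr(Psi^2)
* ``f``  — signal–signal factorization (SSF), in (0, 1]; equals 1 iff
  Phi^T Phi is proportional to Omega (whitened signal)
* ``s``  — signal–noise factorization (SNF), in [0, +inf]; infinite for
  noiseless codes

and the error is

    E_g = (1/pi) * arctan( sqrt( pi / (2 p c^2 PR) + 1/f + 1/s - 1 ) ).

The first term under the root decays as 1/p (few-shot term); 1/f + 1/s is
an irreducible error independent of the amount of training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .code import GaussianCode, InvalidCodeError, stable_inverse

__all__ = [
    "GeometrySummary",
    "ErrorPrediction",
    "UndefinedMetricError",
    "participation_ratio",
    "neural_latent_correlation",
    "noise_covariance",
    "ssf",
    "snf",
    "geometry_summary",
    "theoretical_error",
]

#: denominator traces below this (relative to numerator scale) count as zero
_ZERO_RTOL = 1e-12


class UndefinedMetricError(ValueError):
    """Raised when a factorization metric is undefined (e.g. Phi = 0)."""


@dataclass(frozen=True)
class GeometrySummary:
    """The four geometry statistics of a code (sample-size independent)."""

    c: float
    pr: float
    f: float
    s: float  # may be +inf for noiseless codes

    def as_dict(self) -> dict:
        return {"c": self.c, "pr": self.pr, "f": self.f, "s": self.s}


@dataclass(frozen=True)
class ErrorPrediction:
    """Analytical task-averaged readout error at training-set size p."""

    p: int
    e_g: float
    fewshot_term: float      # pi / (2 p c^2 PR), decays as 1/p
    irreducible_term: float  # 1/f + 1/s, independent of p
    chance: bool = False     # True when c = 0 forces chance-level error


def participation_ratio(psi: np.ndarray) -> float:
    """Effective dimension of the population activity, [Tr(Psi)]^2 / Tr(Psi^2).

    Lies in [1, n]: 1 for a rank-one covariance, n for an isotropic one.
    """
    psi = np.asarray(psi, dtype=float)
    tr = np.trace(psi)
    if tr <= 0:
        raise InvalidCodeError("participation ratio needs Tr(psi) > 0")
    tr2 = np.sum(psi * psi.T)  # Tr(psi @ psi) without forming the product
    return float(tr * tr / tr2)


def neural_latent_correlation(code: GaussianCode) -> float:
    """Total neural–latent correlation c = Tr(Phi Phi^T) / (Tr Psi * Tr Omega)."""
    tr_psi = np.trace(code.psi)
    tr_omega = np.trace(code.omega)
    if tr_psi <= 0 or tr_omega <= 0:
        raise InvalidCodeError("correlation needs Tr(psi) > 0 and Tr(omega) > 0")
    return float(np.sum(code.phi**2) / (tr_psi * tr_omega))


def noise_covariance(code: GaussianCode) -> np.ndarray:
    """Trial-to-trial covariance unexplained by latents: Psi - Phi Omega^-1 Phi^T.

    Symmetric and PSD for a realizable code; eigenvalues below the PSD
    tolerance raise :class:`InvalidCodeError`.
    """
    noise = code.psi - code.phi @ stable_inverse(code.omega) @ code.phi.T
    noise = 0.5 * (noise + noise.T)
    w = np.linalg.eigvalsh(noise)
    scale = max(np.abs(np.linalg.eigvalsh(code.psi)).max(), 1e-300)
    if w[0] < -1e-8 * scale:
        raise InvalidCodeError(
            f"noise covariance has eigenvalue {w[0]:.3e}; covariance triple "
            "is not realizable"
        )
    return noise


def _signal_traces(code: GaussianCode):
    tr_phiphit = float(np.sum(code.phi**2))
    if tr_phiphit <= 0:
        raise UndefinedMetricError("factorization metrics undefined for Phi = 0")
    return tr_phiphit


def ssf(code: GaussianCode) -> float:
    """Signal–signal factorization f in (0, 1].

    f = [Tr(Phi Phi^T)]^2 / ( Tr(Omega) * Tr(Phi^T Phi Omega^-1 Phi^T Phi) ).
    Equals 1 exactly when Phi^T Phi is proportional to Omega, i.e. when
    independent latents occupy uncorrelated, equal-variance neural directions.
    """
    tr_phiphit = _signal_traces(code)
    g = code.phi.T @ code.phi  # d x d
    denom = np.trace(code.omega) * np.trace(g @ stable_inverse(code.omega) @ g)
    return float(tr_phiphit**2 / denom)


def snf(code: GaussianCode) -> float:
    """Signal–noise factorization s in [0, +inf].

    s = [Tr(Phi Phi^T)]^2 / ( Tr(Omega) * Tr(Phi^T N Phi) ) with
    N = Psi - Phi Omega^-1 Phi^T the noise covariance. Returns +inf when the
    noise has no component along the coding directions (noiseless codes).
    """
    tr_phiphit = _signal_traces(code)
    noise = noise_covariance(code)
    overlap = float(np.trace(code.phi.T @ noise @ code.phi))
    scale = tr_phiphit**2 / max(np.trace(code.omega), 1e-300)
    if overlap <= _ZERO_RTOL * max(scale, 1e-300):
        if overlap < -1e-6 * max(scale, 1e-300):
            raise InvalidCodeError("negative noise overlap beyond tolerance")
        return float("inf")
    return float(tr_phiphit**2 / (np.trace(code.omega) * overlap))


def geometry_summary(code: GaussianCode) -> GeometrySummary:
    """Bundle c, PR, f, s; identical to calling each metric individually."""
    return GeometrySummary(
        c=neural_latent_correlation(code),
        pr=participation_ratio(code.psi),
        f=ssf(code),
        s=snf(code),
    )


def theoretical_error(summary: GeometrySummary, p: int) -> ErrorPrediction:
    """Analytical task-averaged generalization error of the Hebbian readout.

    E_g = (1/pi) arctan( sqrt( pi/(2 p c^2 PR) + 1/f + 1/s - 1 ) ), with the
    radicand clamped at zero (perfect codes can dip a hair below zero in
    floating point). ``s = +inf`` contributes exactly 0 through 1/s. A code
    with c = 0 carries no task information: the error is chance (0.5),
    returned flagged.
    """
    if p < 1:
        raise ValueError("training-set size p must be >= 1")
    if summary.c == 0:
        return ErrorPrediction(
            p=int(p), e_g=0.5, fewshot_term=float("inf"),
            irreducible_term=1.0 / summary.f + _inv(summary.s), chance=True,
        )
    fewshot = float(np.pi / (2.0 * p * summary.c**2 * summary.pr))
    irreducible = float(1.0 / summary.f + _inv(summary.s))
    radicand = fewshot + irreducible - 1.0
    if radicand < 0.0:
        if radicand < -1e-6:
            warnings.warn(
                f"error radicand {radicand:.3e} clamped to 0; geometry at or "
                "beyond the perfect-code boundary", stacklevel=2,
            )
        radicand = 0.0
    e_g = float(np.arctan(np.sqrt(radicand)) / np.pi)
    return ErrorPrediction(
        p=int(p), e_g=e_g, fewshot_term=fewshot, irreducible_term=irreducible,
    )


def _inv(s: float) -> float:
    return 0.0 if np.isinf(s) else 1.0 / s
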