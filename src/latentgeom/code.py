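"""Container for a Gaussian neural code.

A *code* is the second-moment description of a jointly zero-mean Gaussian
model of neural responses ``x`` (n units) and latent variables ``z``
(d dimensions):

* ``psi``   — n x n neuron–neuron covariance  E[x x^T]
* ``phi``   — n x d neuron–latent cross-covariance  E[x z^T]
* ``omega`` — d x d latent covariance  E[z z^T]

All downstream geometry statistics and the analytical readout error are
functions of this triple alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GaussianCode", "InvalidCodeError", "psd_project", "stable_inverse"]

#: relative PSD tolerance: eigenvalues >= -PSD_RTOL * max eigenvalue are
#: accepted and clipped to zero (sample covariances are only approximately PSD)
PSD_RTOL = 1e-8

#: relative cutoff for inverting (possibly rank-deficient) covariances
INV_RCOND = 1e-10


class InvalidCodeError(ValueError):
    """Raised when a covariance triple cannot describe a realizable code."""


def _check_symmetric(m: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidCodeError(f"{name} must be square, got shape {m.shape}")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > tol * scale:
        raise InvalidCodeError(f"{name} is not symmetric within tolerance")
    return 0.5 * (m + m.T)


def psd_project(m: np.ndarray, rtol: float = PSD_RTOL) -> np.ndarray:
    """Clip slightly negative eigenvalues of a symmetric matrix to zero.

    Eigenvalues below ``-rtol * max_eig`` raise :class:`InvalidCodeError`;
    anything in ``[-rtol * max_eig, 0)`` is treated as numerical noise.
    """
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    top = max(w[-1], 0.0)
    if w[0] < -rtol * max(top, 1e-300):
        raise InvalidCodeError(
            f"matrix has eigenvalue {w[0]:.3e} below PSD tolerance "
            f"(-{rtol:.0e} * {top:.3e})"
        )
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def stable_inverse(m: np.ndarray, rcond: float = INV_RCOND) -> np.ndarray:
    """Invert a symmetric PSD matrix via eigendecomposition.

    Directions with eigenvalue below ``rcond * max_eig`` are dropped
    (pseudo-inverse), which keeps the metrics well defined for degenerate
    latent covariances produced by centering or z-scoring pipelines.
    """
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    cut = rcond * max(w[-1], 0.0)
    inv_w = np.where(w > cut, 1.0 / np.where(w > cut, w, 1.0), 0.0)
    return (v * inv_w) @ v.T


@dataclass(frozen=True)
class GaussianCode:
    """Covariance triple (psi, phi, omega) of a Gaussian neural code."""

    psi: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        psi = _check_symmetric(self.psi, "psi")
        omega = _check_symmetric(self.omega, "omega")
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2:
            raise InvalidCodeError(f"phi must be 2-D, got shape {phi.shape}")
        n, d = phi.shape
        if psi.shape != (n, n) or omega.shape != (d, d):
            raise InvalidCodeError(
                f"inconsistent shapes: psi {psi.shape}, phi {phi.shape}, "
                f"omega {omega.shape}"
            )
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "omega", omega)

    @property
    def n(self) -> int:
        """Number of units."""
        return self.phi.shape[0]

    @property
    def d(self) -> int:
        """Latent dimension."""
        return self.phi.shape[1]

    def joint_covariance(self) -> np.ndarray:
        """Assemble the (n+d) x (n+d) block covariance [[omega, phi^T], [phi, psi]]."""
        top = np.hstack([self.omega, self.phi.T])
        bot = np.hstack([self.phi, self.psi])
        return np.vstack([top, bot])

    def validate(self, rtol: float = PSD_RTOL) -> "GaussianCode":
        """Check realizability: joint covariance and noise covariance PSD.

        Returns self so validation can be chained; raises
        :class:`InvalidCodeError` otherwise.
        """
        joint = self.joint_covariance()
        w = np.linalg.eigvalsh(joint)
        top = max(w[-1], 0.0)
        if w[0] < -rtol * max(top, 1e-300):
            raise InvalidCodeError(
                f"joint (x, z) covariance not PSD: min eig {w[0]:.3e}"
            )
        # noise covariance check (psi minus signal part)
        noise = self.psi - self.phi @ stable_inverse(self.omega) @ self.phi.T
        psd_project(noise, rtol=max(rtol, PSD_RTOL))
        return self

    def is_omega_full_rank(self, rcond: float = INV_RCOND) -> bool:
        w = np.linalg.eigvalsh(self.omega)
        return bool(w[0] > rcond * max(w[-1], 0.0))

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path, name: str = "code") -> None:
        """Write the triple as three delimited-text matrices + JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / f"{name}_psi.tsv", self.psi, delimiter="\t")
        np.savetxt(directory / f"{name}_phi.tsv", self.phi, delimiter="\t")
        np.savetxt(directory / f"{name}_omega.tsv", self.omega, delimiter="\t")
        sidecar = {"n": self.n, "d": self.d, "meta": _jsonable(self.meta)}
        (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path, name: str = "code") -> "GaussianCode":
        directory = Path(directory)
        psi = np.loadtxt(directory / f"{name}_psi.tsv", delimiter="\t", ndmin=2)
        phi = np.loadtxt(directory / f"{name}_phi.tsv", delimiter="\t", ndmin=2)
        omega = np.loadtxt(directory / f"{name}_omega.tsv", delimiter="\t", ndmin=2)
        sidecar_path = directory / f"{name}.json"
        meta = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            meta = sidecar.get("meta", {})
            if sidecar.get("n") != phi.shape[0] or sidecar.get("d") != phi.shape[1]:
                raise InvalidCodeError(
                    "sidecar (n, d) does not match the stored matrices"
                )
        return cls(psi=psi, phi=phi, omega=omega, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
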