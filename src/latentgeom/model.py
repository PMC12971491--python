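"""Model/Results interface over the population-geometry theory.

``GaussianCodeModel`` holds paired response/latent data (or a known
covariance triple) for the jointly Gaussian code model; ``fit`` estimates
the covariances by method of moments and returns a ``GeometryResults``
carrying the four geometry statistics, optional bootstrap standard errors,
analytical error predictions and simulation/Monte-Carlo utilities.

Example
-------
>>> import numpy as np
>>> from latentgeom import GaussianCodeModel
>>> rng = np.random.default_rng(0)
>>> Z = rng.standard_normal((5000, 4))
>>> X = Z @ rng.standard_normal((12, 4)).T + 0.5 * rng.standard_normal((5000, 12))
>>> res = GaussianCodeModel(X, Z).fit()
>>> pred = res.predict_error(p=100)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .code import GaussianCode
from .metrics import (
    ErrorPrediction,
    GeometrySummary,
    geometry_summary,
    theoretical_error,
)
from .readout import MonteCarloResult, monte_carlo_error, sample_joint
from .synth import estimate_covariances

__all__ = ["GaussianCodeModel", "GeometryResults"]


class GaussianCodeModel:
    """Jointly Gaussian model of neural responses and latent variables.

    Parameters
    ----------
    X : (p, n) response matrix, or None when building from a known code
    Z : (p, d) latent matrix
    code : a known :class:`GaussianCode` (exclusive with data)
    """

    def __init__(
        self,
        X: np.ndarray | None = None,
        Z: np.ndarray | None = None,
        code: GaussianCode | None = None,
    ):
        if code is not None:
            if X is not None or Z is not None:
                raise ValueError("give either (X, Z) data or a code, not both")
            self.X = self.Z = None
            self.code = code
        else:
            if X is None or Z is None:
                raise ValueError("need both X and Z (or a code)")
            self.X = np.asarray(X, dtype=float)
            self.Z = np.asarray(Z, dtype=float)
            if self.X.shape[0] != self.Z.shape[0]:
                raise ValueError("X and Z must have matching row counts")
            self.code = None

    @classmethod
    def from_code(cls, code: GaussianCode) -> "GaussianCodeModel":
        """Build directly from a known covariance triple (no estimation)."""
        return cls(code=code)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response_cols: Sequence[str],
        latent_cols: Sequence[str],
    ) -> "GaussianCodeModel":
        """Build from a tidy table with named response and latent columns."""
        return cls(
            X=data[list(response_cols)].to_numpy(dtype=float),
            Z=data[list(latent_cols)].to_numpy(dtype=float),
        )

    @property
    def nobs(self) -> int | None:
        return None if self.X is None else self.X.shape[0]

    def fit(
        self,
        bootstrap: int = 0,
        rng: np.random.Generator | None = None,
    ) -> "GeometryResults":
        """Estimate the covariance triple and its geometry statistics.

        With data, covariances are the centered sample moments (1/(p-1));
        ``bootstrap`` > 0 additionally resamples rows with replacement to
        attach standard errors to each statistic (infinite SNF draws are
        excluded from its SE and counted instead).
        """
        if self.code is not None:
            code = self.code.validate()
        else:
            code = estimate_covariances(self.X, self.Z)
        summary = geometry_summary(code)
        boot_se = None
        if bootstrap > 0:
            if self.X is None:
                raise ValueError("bootstrap needs sample data, not a fixed code")
            if rng is None:
                rng = np.random.default_rng()
            boot_se = _bootstrap_se(self.X, self.Z, bootstrap, rng)
        return GeometryResults(
            model=self, code=code, geometry=summary, boot_se=boot_se,
            nobs=self.nobs,
        )


def _bootstrap_se(X, Z, n_boot: int, rng: np.random.Generator) -> dict:
    p = X.shape[0]
    draws = {"c": [], "pr": [], "f": [], "s": []}
    inf_s = 0
    for _ in range(n_boot):
        idx = rng.integers(0, p, size=p)
        summ = geometry_summary(estimate_covariances(X[idx], Z[idx]))
        draws["c"].append(summ.c)
        draws["pr"].append(summ.pr)
        draws["f"].append(summ.f)
        if np.isinf(summ.s):
            inf_s += 1
        else:
            draws["s"].append(summ.s)
    se = {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
          for k, v in draws.items()}
    se["n_boot"] = n_boot
    se["n_infinite_s"] = inf_s
    return se


class GeometryResults:
    """Fitted geometry of a Gaussian code.

    Attributes
    ----------
    code : the (estimated or supplied) covariance triple
    geometry : :class:`GeometrySummary` with c, PR, f, s
    boot_se : dict of bootstrap standard errors, or None
    """

    def __init__(self, model, code, geometry: GeometrySummary,
                 boot_se: dict | None, nobs: int | None):
        self.model = model
        self.code = code
        self.geometry = geometry
        self.boot_se = boot_se
        self.nobs = nobs

    # --------------------------------------------------------------- theory
    def predict_error(self, p: int) -> ErrorPrediction:
        """Analytical task-averaged Hebbian readout error at training size p."""
        return theoretical_error(self.geometry, p)

    def error_curve(self, p_grid) -> pd.DataFrame:
        """Error prediction along a grid of training sizes (tidy table)."""
        rows = []
        for p in p_grid:
            pred = self.predict_error(int(p))
            rows.append({
                "p": pred.p, "e_g": pred.e_g,
                "fewshot_term": pred.fewshot_term,
                "irreducible_term": pred.irreducible_term,
            })
        return pd.DataFrame(rows)

    # ----------------------------------------------------------- simulation
    def simulate(self, p: int, rng: np.random.Generator):
        """Draw p paired (X, Z) samples from the fitted Gaussian model."""
        return sample_joint(self.code, p, rng)

    def monte_carlo_error(
        self, p: int, n_tasks: int = 300, n_test: int = 1000,
        n_repeats: int = 30, rng: np.random.Generator | None = None,
    ) -> MonteCarloResult:
        """Empirical Hebbian readout error under the fitted model."""
        return monte_carlo_error(
            self.code, p, n_tasks=n_tasks, n_test=n_test,
            n_repeats=n_repeats, rng=rng,
        )

    # -------------------------------------------------------------- summary
    def summary(self, p: int | None = None) -> str:
        """Human-readable fit summary in the style of statsmodels."""
        g = self.geometry
        se = self.boot_se or {}

        def fmt(v):
            return "inf" if np.isinf(v) else f"{v:.6g}"

        def fmt_se(k):
            return f"{se[k]:.3g}" if k in se and np.isfinite(se.get(k, np.nan)) \
                else "--"

        lines = [
            "      Gaussian Code Geometry Results",
            "=" * 46,
            f"Units (n):            {self.code.n}",
            f"Latent dim (d):       {self.code.d}",
            f"No. observations:     {self.nobs if self.nobs else '-- (fixed code)'}",
            "-" * 46,
            f"{'statistic':<22}{'estimate':>12}{'boot SE':>12}",
            "-" * 46,
            f"{'correlation c':<22}{fmt(g.c):>12}{fmt_se('c'):>12}",
            f"{'dimension PR':<22}{fmt(g.pr):>12}{fmt_se('pr'):>12}",
            f"{'SSF f':<22}{fmt(g.f):>12}{fmt_se('f'):>12}",
            f"{'SNF s':<22}{fmt(g.s):>12}{fmt_se('s'):>12}",
        ]
        if p is not None:
            pred = self.predict_error(p)
            lines += [
                "-" * 46,
                f"{'E_g (p=%d)' % p:<22}{pred.e_g:>12.6g}",
                f"{'  few-shot term':<22}{fmt(pred.fewshot_term):>12}",
                f"{'  irreducible term':<22}{pred.irreducible_term:>12.6g}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self):
        g = self.geometry
        return (f"<GeometryResults c={g.c:.4g} pr={g.pr:.4g} "
                f"f={g.f:.4g} s={'inf' if np.isinf(g.s) else f'{g.s:.4g}'}>")
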