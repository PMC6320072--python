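"""Power-law scaling inference in log-log space.

Every scaling relation in this package is a power law ``y = a * x**b``
fitted as a straight line ``ln y = ln a + b * ln x``.  The default
estimator is iteratively reweighted least squares with a Tukey bisquare
weight function (95% Gaussian efficiency), which down-weights the
occasional grossly mis-measured animal without discarding it.  Ordinary
least squares is available for comparison and as an oracle in tests.

Fitted laws form a small algebra: laws can be composed (``z ~ y`` with
``y ~ x`` gives ``z ~ x``), inverted, and converted to per-unit form
(``y/x ~ x``).  Standard errors follow through each operation by
first-order (delta-method) propagation, treating distinct fits as
independent — the convention used when a quantity is derived from
several separately measured relations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PowerLawModel",
    "PowerLawResults",
    "fit_power_law",
    "compose",
    "invert",
    "per_unit",
]

BISQUARE_TUNING = 4.685
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8

ROBUST = "robust_bisquare"
OLS = "ols"
DERIVED = "derived"


class PowerLawDomainError(ValueError):
    """Raised when inputs leave the domain of a power-law operation."""


@dataclass(frozen=True)
class PowerLawResults:
    """A fitted (or derived) power law ``y = a * x**b``.

    Parameters are reported on the natural-log scale: ``log_prefactor``
    is ``ln a``, the value of ``ln y`` at ``x = 1`` in input units.

    Attributes
    ----------
    exponent : float
        The scaling exponent ``b`` (slope in log-log space).
    log_prefactor : float
        ``ln a``.
    se_exponent, se_log_prefactor : float
        Standard errors of ``b`` and ``ln a``.
    cov_exp_lna : float
        Covariance between ``b`` and ``ln a``.
    n : int
        Number of data points behind the fit (for derived laws, the
        smaller of the parents' sample sizes).
    method : str
        ``"robust_bisquare"``, ``"ols"`` or ``"derived"``.
    """

    exponent: float
    log_prefactor: float
    se_exponent: float
    se_log_prefactor: float
    cov_exp_lna: float
    n: int
    method: str
    derivation: str = field(default="direct", compare=False)

    def __post_init__(self) -> None:
        vals = (self.exponent, self.log_prefactor, self.se_exponent,
                self.se_log_prefactor, self.cov_exp_lna)
        if not all(np.isfinite(v) for v in vals):
            raise PowerLawDomainError(f"non-finite power-law fields: {vals}")
        if self.se_exponent < 0 or self.se_log_prefactor < 0:
            raise PowerLawDomainError("standard errors must be >= 0")

    # -- basic quantities -------------------------------------------------
    @property
    def prefactor(self) -> float:
        """``a = exp(ln a)``, the value of ``y`` at ``x = 1``."""
        return math.exp(self.log_prefactor)

    def predict(self, x, with_se: bool = False):
        """Evaluate ``y = a * x**b`` (optionally with delta-method SE).

        The SE of the prediction accounts for the joint uncertainty in
        ``(b, ln a)``: ``var(ln y) = se_lna^2 + (ln x)^2 se_b^2 +
        2 ln x cov`` and ``se_y = y * se_lny`` to first order.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise PowerLawDomainError("predict requires x > 0")
        lnx = np.log(x)
        lny = self.log_prefactor + self.exponent * lnx
        y = np.exp(lny)
        if not with_se:
            return y if y.ndim else float(y)
        var_lny = (self.se_log_prefactor ** 2
                   + lnx ** 2 * self.se_exponent ** 2
                   + 2.0 * lnx * self.cov_exp_lna)
        se = np.exp(lny) * np.sqrt(np.maximum(var_lny, 0.0))
        if y.ndim:
            return y, se
        return float(y), float(se)

    def __call__(self, x):
        return self.predict(x)

    # -- algebra ----------------------------------------------------------
    def compose(self, inner: "PowerLawResults") -> "PowerLawResults":
        return compose(self, inner)

    def invert(self) -> "PowerLawResults":
        return invert(self)

    def per_unit(self) -> "PowerLawResults":
        return per_unit(self)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLawResults":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "PowerLawResults":
        return cls.from_dict(json.loads(s))

    @classmethod
    def identity(cls, n: int = 3) -> "PowerLawResults":
        """The exact law ``y = x`` (b = 1, a = 1, zero uncertainty)."""
        return cls(1.0, 0.0, 0.0, 0.0, 0.0, n, DERIVED, derivation="identity")

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Power-law fit  y = a * x**b",
            "=" * 34,
            f"method          {self.method}",
            f"n               {self.n}",
            f"exponent b      {self.exponent: .4f} +/- {self.se_exponent:.4f}",
            f"ln a            {self.log_prefactor: .4f} +/- {self.se_log_prefactor:.4f}",
            f"a (y at x=1)    {self.prefactor: .6g}",
            f"cov(b, ln a)    {self.cov_exp_lna: .3e}",
            f"derivation      {self.derivation}",
        ]
        return "\n".join(lines)

    def plot(self, x=None, y=None, ax=None, **scatter_kw):
        """Diagnostic log-log plot of the law (and data, if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if x is not None:
            ax.scatter(x, y, s=12, alpha=0.6, **scatter_kw)
            grid = np.geomspace(np.min(x), np.max(x), 50)
        else:
            grid = np.geomspace(0.1, 10.0, 50)
        ax.plot(grid, self.predict(grid), color="C3",
                label=f"b = {self.exponent:.3f} ± {self.se_exponent:.3f}")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.legend()
        return ax


class PowerLawModel:
    """Model for a power law ``y = a * x**b`` given paired samples.

    Parameters
    ----------
    x, y : array-like of positive floats
        Paired observations; at least three points.
    x_min : float, optional
        If given, only points with ``x > x_min`` enter the fit (used e.g.
        to restrict the wet-mass range of a fit).

    Examples
    --------
    >>> res = PowerLawModel([1, 10, 100], [2, 2 * 10**0.75, 2 * 100**0.75]).fit()
    >>> round(res.exponent, 10)
    0.75
    """

    def __init__(self, x: Sequence[float], y: Sequence[float],
                 x_min: float | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise PowerLawDomainError("x and y must be equal-length 1-d arrays")
        if np.any(x <= 0) or np.any(y <= 0) or not (
                np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise PowerLawDomainError("all x and y must be positive and finite")
        if x_min is not None:
            keep = x > x_min
            x, y = x[keep], y[keep]
        if x.size < 3:
            raise PowerLawDomainError("need at least 3 points to fit a power law")
        self.x = x
        self.y = y
        self.lnx = np.log(x)
        self.lny = np.log(y)

    def fit(self, method: str = ROBUST) -> PowerLawResults:
        """Fit the line ``ln y = ln a + b ln x``.

        ``robust_bisquare`` runs IRLS with Tukey bisquare weights
        (tuning constant 4.685, MAD scale); ``ols`` is ordinary least
        squares. Standard errors come from the method's weighted
        parameter covariance.
        """
        X = sm.add_constant(self.lnx)
        ols_res = sm.OLS(self.lny, X).fit()
        exact = bool(np.max(np.abs(ols_res.resid))
                     < 1e-12 * max(1.0, float(np.max(np.abs(self.lny)))))
        if method == OLS or exact:
            # on (numerically) exact power-law data IRLS has zero scale;
            # the OLS solution is the robust solution there
            res, cov = ols_res, np.asarray(ols_res.cov_params())
            if exact:
                cov = np.zeros((2, 2))
        elif method == ROBUST:
            rlm = sm.RLM(self.lny, X,
                         M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
            with np.errstate(invalid="ignore", divide="ignore"):
                res = rlm.fit(maxiter=IRLS_MAX_ITER, tol=IRLS_TOL,
                              scale_est="mad")
            if not np.all(np.isfinite(res.params)):
                raise RuntimeError(
                    f"IRLS did not converge within {IRLS_MAX_ITER} iterations")
            cov = np.asarray(res.bcov_scaled)
        else:
            raise ValueError(f"unknown fit method {method!r}")
        lna, b = res.params
        return PowerLawResults(
            exponent=float(b),
            log_prefactor=float(lna),
            se_exponent=float(np.sqrt(cov[1, 1])),
            se_log_prefactor=float(np.sqrt(cov[0, 0])),
            cov_exp_lna=float(cov[0, 1]),
            n=int(self.x.size),
            method=method,
        )


def fit_power_law(x, y, method: str = ROBUST,
                  x_min: float | None = None) -> PowerLawResults:
    """Convenience wrapper: ``PowerLawModel(x, y, x_min).fit(method)``."""
    return PowerLawModel(x, y, x_min=x_min).fit(method=method)


def _cov2(fit: PowerLawResults) -> np.ndarray:
    """2x2 covariance of (b, ln a)."""
    return np.array([[fit.se_exponent ** 2, fit.cov_exp_lna],
                     [fit.cov_exp_lna, fit.se_log_prefactor ** 2]])


def _from_jacobian(theta: np.ndarray, J: np.ndarray, Sigma: np.ndarray,
                   n: int, derivation: str) -> PowerLawResults:
    cov = J @ Sigma @ J.T
    return PowerLawResults(
        exponent=float(theta[0]),
        log_prefactor=float(theta[1]),
        se_exponent=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_log_prefactor=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_exp_lna=float(cov[0, 1]),
        n=n,
        method=DERIVED,
        derivation=derivation,
    )


def compose(outer: PowerLawResults, inner: PowerLawResults) -> PowerLawResults:
    """Chain two laws: ``z ~ y`` composed with ``y ~ x`` gives ``z ~ x``.

    ``z = a_o * (a_i * x**b_i)**b_o``, so ``b = b_o * b_i`` and
    ``ln a = ln a_o + b_o * ln a_i``.  The two fits are treated as
    independent; uncertainty propagates to first order, giving
    ``se_b = sqrt((b_o se_i)^2 + (b_i se_o)^2)``.
    """
    bo, lao = outer.exponent, outer.log_prefactor
    bi, lai = inner.exponent, inner.log_prefactor
    theta = np.array([bo * bi, lao + bo * lai])
    # parameter order: (b_o, lna_o, b_i, lna_i)
    J = np.array([[bi, 0.0, bo, 0.0],
                  [lai, 1.0, 0.0, bo]])
    Sigma = np.zeros((4, 4))
    Sigma[:2, :2] = _cov2(outer)
    Sigma[2:, 2:] = _cov2(inner)
    return _from_jacobian(theta, J, Sigma, min(outer.n, inner.n),
                          f"compose({outer.derivation}, {inner.derivation})")


def invert(fit: PowerLawResults) -> PowerLawResults:
    """Swap axes: from ``y = a x**b`` obtain ``x = a**(-1/b) y**(1/b)``.

    First-order propagation gives ``se(1/b) = se_b / b**2``.
    """
    b, la = fit.exponent, fit.log_prefactor
    if b == 0:
        raise PowerLawDomainError("cannot invert a law with exponent 0")
    theta = np.array([1.0 / b, -la / b])
    J = np.array([[-1.0 / b ** 2, 0.0],
                  [la / b ** 2, -1.0 / b]])
    return _from_jacobian(theta, J, _cov2(fit), fit.n,
                          f"invert({fit.derivation})")


def per_unit(fit: PowerLawResults) -> PowerLawResults:
    """From ``y ~ x`` derive ``(y/x) ~ x``: exponent drops by one.

    ``y/x = a x**(b-1)``; uncertainties are unchanged because the
    transformation is a deterministic shift of the exponent.
    """
    return PowerLawResults(
        exponent=fit.exponent - 1.0,
        log_prefactor=fit.log_prefactor,
        se_exponent=fit.se_exponent,
        se_log_prefactor=fit.se_log_prefactor,
        cov_exp_lna=fit.cov_exp_lna,
        n=fit.n,
        method=DERIVED,
        derivation=f"per_unit({fit.derivation})",
    )
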