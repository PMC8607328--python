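"""Prior elicitation: turn legacy summaries or expert intervals into hyperparameters.

Supported routes:

* precision prior from a legacy variance and a chosen coefficient of
  variation of the precision (``gamma_from_mean_cv``);
* areal-fraction prior from a legacy proportion, placed at the beta mode,
  and a prior sample size (``beta_from_mode_n0``);
* either prior from an expert interval interpreted as a pair of quantiles
  (``beta_from_quantiles``, ``gamma_from_variance_interval``), solved by
  two-dimensional root finding on the log hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import betaincinv, gammaincinv

from .priors import BetaPrior

__all__ = [
    "gamma_from_mean_cv",
    "beta_from_mode_n0",
    "beta_from_quantiles",
    "gamma_from_variance_interval",
    "QuantileFit",
]

_QTOL = 1e-6  # required agreement, in quantile space, of the fitted distribution


class ElicitationError(RuntimeError):
    """Quantile matching failed to converge to the requested tolerance."""


@dataclass(frozen=True)
class QuantileFit:
    """Hyperparameters fitted to a pair of quantiles.

    ``params`` is the continuous solution, ``rounded`` its element-wise
    nearest-integer version (reported alongside, never silently
    substituted), ``max_quantile_error`` the largest absolute quantile
    discrepancy of the continuous solution.
    """

    family: str  # "beta" or "gamma"
    params: tuple
    rounded: tuple
    max_quantile_error: float


def gamma_from_mean_cv(legacy_variance: float, cv: float) -> tuple:
    """Gamma (shape, rate) for the precision from a legacy variance and a CV.

    The gamma mean is set to the reciprocal of the legacy variance and its
    coefficient of variation to `cv`, giving ``a = 1/cv^2`` and
    ``b = a * legacy_variance``.
    """
    if not legacy_variance > 0:
        raise ValueError(f"legacy_variance must be positive, got {legacy_variance}")
    if not cv > 0:
        raise ValueError(f"cv must be positive, got {cv}")
    a = 1.0 / cv**2
    return a, a * legacy_variance


def beta_from_mode_n0(pi0: float, n0: float) -> BetaPrior:
    """Beta prior with mode `pi0` and prior sample size `n0`.

    ``c = n0*pi0 + 1`` and ``d = n0*(1 - pi0) + 1``; ``n0 = 0`` gives the
    uniform Beta(1, 1).
    """
    if not 0 <= pi0 <= 1:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    if n0 < 0:
        raise ValueError(f"prior sample size n0 must be >= 0, got {n0}")
    return BetaPrior(n0 * pi0 + 1.0, n0 * (1.0 - pi0) + 1.0)


def _fit_two_quantiles(residuals, x0) -> np.ndarray:
    sol = optimize.root(residuals, np.log(x0), method="hybr", tol=1e-13)
    params = np.exp(sol.x)
    err = float(np.max(np.abs(residuals(sol.x))))
    if err > _QTOL:
        raise ElicitationError(
            f"quantile matching did not converge (max quantile error {err:.3g}, "
            f"solver message: {sol.message})")
    return params, err


def beta_from_quantiles(q_lo: float, q_hi: float,
                        p_lo: float = 0.025, p_hi: float = 0.975) -> QuantileFit:
    """Beta hyperparameters whose (p_lo, p_hi) quantiles equal (q_lo, q_hi).

    Typical use: an expert states that a proportion most likely lies in
    (q_lo, q_hi), read as a central 95% prior interval.
    """
    if not (0 < q_lo < q_hi < 1):
        raise ValueError(f"need 0 < q_lo < q_hi < 1, got ({q_lo}, {q_hi})")
    if not (0 < p_lo < p_hi < 1):
        raise ValueError(f"need 0 < p_lo < p_hi < 1, got ({p_lo}, {p_hi})")

    # moment-matched normal approximation as starting point
    z_lo, z_hi = stats.norm.ppf([p_lo, p_hi])
    m = 0.5 * (q_lo + q_hi)
    s = (q_hi - q_lo) / (z_hi - z_lo)
    conc = max(m * (1.0 - m) / s**2 - 1.0, 1e-2)
    x0 = (max(m * conc, 1e-3), max((1.0 - m) * conc, 1e-3))

    def residuals(x):
        c, d = np.exp(x)
        return [betaincinv(c, d, p_lo) - q_lo, betaincinv(c, d, p_hi) - q_hi]

    params, err = _fit_two_quantiles(residuals, x0)
    return QuantileFit("beta", tuple(params), tuple(int(round(p)) for p in params), err)


def gamma_from_variance_interval(v_lo: float, v_hi: float,
                                 p_lo: float = 0.025, p_hi: float = 0.975) -> QuantileFit:
    """Gamma (shape, rate) for the precision from an expert variance interval.

    The variance interval (v_lo, v_hi) is inverted into a precision
    interval (1/v_hi, 1/v_lo) whose ends are matched to the (p_lo, p_hi)
    gamma quantiles.
    """
    if not (0 < v_lo < v_hi):
        raise ValueError(f"need 0 < v_lo < v_hi, got ({v_lo}, {v_hi})")
    if not (0 < p_lo < p_hi < 1):
        raise ValueError(f"need 0 < p_lo < p_hi < 1, got ({p_lo}, {p_hi})")
    x_lo, x_hi = 1.0 / v_hi, 1.0 / v_lo

    z_lo, z_hi = stats.norm.ppf([p_lo, p_hi])
    m = 0.5 * (x_lo + x_hi)
    s = (x_hi - x_lo) / (z_hi - z_lo)
    x0 = ((m / s) ** 2, m / s**2)

    def residuals(x):
        a, b = np.exp(x)
        return [gammaincinv(a, p_lo) / b - x_lo, gammaincinv(a, p_hi) / b - x_hi]

    params, err = _fit_two_quantiles(residuals, x0)
    return QuantileFit("gamma", tuple(params), tuple(int(round(p)) for p in params), err)
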