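"""Conjugate prior specifications.

Two prior families cover the two estimation problems handled by this
package:

* :class:`NormalGammaPrior` — joint conjugate prior for the mean ``mu``
  and precision ``lambda = 1/sigma^2`` of a normal population:
  ``lambda ~ Gamma(a, rate=b)`` and ``mu | lambda ~ N(mu0, precision
  n0*lambda)``.  ``n0`` is the prior sample size for the mean; ``n0 = 0``
  encodes a flat (improper) prior on ``mu``.
* :class:`BetaPrior` — conjugate ``Beta(c, d)`` prior for a binomial
  probability (areal fraction) ``pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["NormalGammaPrior", "BetaPrior"]


@dataclass(frozen=True)
class NormalGammaPrior:
    """Normal-gamma prior for (mean, precision) of a normal population.

    Parameters
    ----------
    mu0 : float
        Prior mean of the population mean.
    n0 : float
        Prior sample size for the mean (>= 0, need not be an integer).
        With ``n0 = 0`` the prior on the mean is flat and `mu0` is inert.
    a, b : float
        Shape and rate of the gamma prior on the precision
        ``lambda = 1/sigma^2``; prior mean of lambda is ``a/b`` and its
        coefficient of variation is ``1/sqrt(a)``.
    """

    mu0: float
    n0: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"gamma hyperparameters must be positive, got a={self.a}, b={self.b}")
        if self.n0 < 0:
            raise ValueError(f"prior sample size n0 must be >= 0, got {self.n0}")

    @property
    def precision_mean(self) -> float:
        """Prior mean of the precision, a/b."""
        return self.a / self.b

    @property
    def precision_cv(self) -> float:
        """Prior coefficient of variation of the precision, 1/sqrt(a)."""
        return 1.0 / math.sqrt(self.a)

    @property
    def sigma0(self) -> float:
        """Point guess of the population standard deviation, sqrt(b/a)."""
        return math.sqrt(self.b / self.a)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(c, d) prior for a binomial probability parameter."""

    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.c > 0 and self.d > 0):
            raise ValueError(f"beta hyperparameters must be positive, got c={self.c}, d={self.d}")

    @property
    def mean(self) -> float:
        return self.c / (self.c + self.d)

    @property
    def mode(self) -> float:
        """Mode (c-1)/(c+d-2); defined for interior-mode shapes (c>1, d>1)."""
        if self.c > 1 and self.d > 1:
            return (self.c - 1) / (self.c + self.d - 2)
        raise ValueError("mode is only defined for c > 1 and d > 1")

    @property
    def prior_sample_size(self) -> float:
        """Equivalent number of prior observations, c + d - 2."""
        return self.c + self.d - 2
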