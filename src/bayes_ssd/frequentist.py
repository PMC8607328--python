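"""Closed-form frequentist sample sizes for a mean and a Wald proportion."""

from __future__ import annotations

import math

from scipy import stats

from .design import PrecisionSpec

__all__ = ["n_mean_frequentist", "n_prop_wald"]


def n_mean_frequentist(sigma0: float, spec: PrecisionSpec) -> int:
    """Sample size for a maximum confidence-interval length for a mean.

    Normal-approximation interval of length ``2 u_{1-alpha/2} sigma0 /
    sqrt(n)``; the result is the ceiling of the rearranged formula and is
    never below 1.
    """
    if not sigma0 > 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    u = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    n = math.ceil((u * sigma0 / (spec.lmax / 2.0)) ** 2)
    return max(n, 1)


def n_prop_wald(pi0: float, spec: PrecisionSpec) -> int:
    """Wald sample size for a maximum confidence-interval length for a proportion."""
    if not 0 <= pi0 <= 1:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    if spec.lmax >= 1:
        raise ValueError(f"lmax must be < 1 for a proportion, got {spec.lmax}")
    u = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    n = math.ceil(u**2 * pi0 * (1.0 - pi0) / (spec.lmax / 2.0) ** 2 + 1.0)
    return max(n, 1)
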