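"""Bayesian and mixed Bayesian-likelihood sample sizes for a binomial proportion.

The outcome space of n binomial trials is finite ({0, ..., n}), so every
criterion is an exact finite sum over the beta-binomial preposterior: for
each possible number of successes z the posterior of the probability
parameter is Beta(z+c, n-z+d) (fully Bayesian) or Beta(z+1, n-z+1) (mixed
approach: uniform analysis prior), its 1-alpha HPD length or
fixed-length maximal coverage is computed by `bayes_ssd.hpd`, and the
results are weighted by the beta-binomial probability of z.

Criteria, at candidate n:

* ALC  — sum_z l(z, n) f(z|n) <= lmax;
* ACC  — sum_z Pr{pi in best length-lmax interval | z} f(z|n) >= 1-alpha;
* WOC  — the requirement l(z, n) <= lmax must hold on a set of outcomes
  carrying at least `worst_level` preposterior mass; equivalently the
  worst_level quantile of the length distribution over z is at most lmax.

The smallest satisfying n is found by an upward linear scan (with a
downward certification walk), because the binomial criteria are not
guaranteed monotone in n.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betaln, gammaln

from .design import PrecisionSpec, SSDResult
from .frequentist import n_prop_wald
from .hpd import hpd_beta_batch, max_coverage_beta_batch
from .priors import BetaPrior

__all__ = [
    "BinomialOutcomeSpace",
    "betabinom_pmf",
    "posterior_pi",
    "evaluate_criterion",
    "n_prop_criterion",
]

_N_CAP = 10**6


class BinomialOutcomeSpace:
    """The data space {0, ..., n} with its beta-binomial preposterior pmf."""

    def __init__(self, n: int, prior: BetaPrior):
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        self.n = n
        self.z = np.arange(n + 1)
        self.pmf = betabinom_pmf(self.z, n, prior)

    def __len__(self) -> int:
        return self.n + 1


def betabinom_pmf(z, n: int, prior: BetaPrior):
    """Beta-binomial preposterior probability of z successes in n trials.

    ``C(n, z) B(z+c, n-z+d) / B(c, d)``, evaluated in log space.  Scalar in,
    scalar out; arrays broadcast.
    """
    z_arr = np.asarray(z)
    if np.any((z_arr < 0) | (z_arr > n)):
        raise ValueError(f"z must lie in 0..{n}")
    logpmf = (gammaln(n + 1) - gammaln(z_arr + 1) - gammaln(n - z_arr + 1)
              + betaln(z_arr + prior.c, n - z_arr + prior.d) - betaln(prior.c, prior.d))
    out = np.exp(logpmf)
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def posterior_pi(z: int, n: int, prior: BetaPrior, approach: str = "fully_bayesian") -> BetaPrior:
    """Posterior of the binomial probability after z successes in n trials.

    Fully Bayesian: Beta(z+c, n-z+d).  Mixed: Beta(z+1, n-z+1) — a uniform
    analysis prior, whatever design prior generated the preposterior.
    """
    if not 0 <= z <= n:
        raise ValueError(f"z must lie in 0..{n}, got {z}")
    if approach in ("fully_bayesian", "bayes", "fb"):
        return BetaPrior(z + prior.c, n - z + prior.d)
    if approach in ("mixed", "mbl"):
        return BetaPrior(z + 1.0, n - z + 1.0)
    raise ValueError(f"unknown approach {approach!r}")


def _analysis_params(n: int, prior: BetaPrior, approach: str):
    z = np.arange(n + 1)
    if approach == "fully_bayesian":
        return z + prior.c, n - z + prior.d, prior.c == prior.d
    return z + 1.0, n - z + 1.0, True


def _hpd_lengths(n: int, prior: BetaPrior, approach: str, coverage: float) -> np.ndarray:
    """HPD lengths for every z in 0..n, exploiting the z <-> n-z symmetry
    of the analysis posterior when its prior is symmetric."""
    ca, da, symmetric = _analysis_params(n, prior, approach)
    if symmetric:
        half = n // 2 + 1
        lo, up = hpd_beta_batch(ca[:half], da[:half], coverage)
        ell = np.empty(n + 1)
        ell[:half] = up - lo
        ell[half:] = ell[: n + 1 - half][::-1]
        return ell
    lo, up = hpd_beta_batch(ca, da, coverage)
    return up - lo


def _max_coverages(n: int, prior: BetaPrior, approach: str, lmax: float) -> np.ndarray:
    ca, da, symmetric = _analysis_params(n, prior, approach)
    if symmetric:
        half = n // 2 + 1
        cov_half = max_coverage_beta_batch(ca[:half], da[:half], lmax)
        cov = np.empty(n + 1)
        cov[:half] = cov_half
        cov[half:] = cov[: n + 1 - half][::-1]
        return cov
    return max_coverage_beta_batch(ca, da, lmax)


def evaluate_criterion(n: int, prior: BetaPrior, spec: PrecisionSpec):
    """Criterion value and satisfaction at a candidate n.

    Returns ``(satisfied, achieved)`` where `achieved` is the average HPD
    length (ALC), average maximal coverage (ACC) or the worst_level
    quantile of the HPD length distribution (WOC).
    """
    if spec.lmax >= 1:
        raise ValueError(f"lmax must be < 1 for a proportion, got {spec.lmax}")
    # n = 0 degenerates gracefully: one outcome (z = 0) with probability 1,
    # whose "posterior" is the analysis prior itself.
    pmf = betabinom_pmf(np.arange(n + 1), n, prior)
    approach = spec.approach
    if spec.criterion == "alc":
        ell = _hpd_lengths(n, prior, approach, 1.0 - spec.alpha)
        achieved = float(np.sum(pmf * ell))
        return achieved <= spec.lmax, achieved
    if spec.criterion == "acc":
        cov = _max_coverages(n, prior, approach, spec.lmax)
        achieved = float(np.sum(pmf * cov))
        return achieved >= 1.0 - spec.alpha, achieved
    if spec.criterion == "woc":
        ell = _hpd_lengths(n, prior, approach, 1.0 - spec.alpha)
        order = np.argsort(ell)
        cum = np.cumsum(pmf[order])
        k = int(np.searchsorted(cum, spec.worst_level - 1e-12))
        achieved = float(ell[order[min(k, n)]])
        return achieved <= spec.lmax, achieved
    raise ValueError(f"criterion must be alc/acc/woc, got {spec.criterion}")


def _scan_start(prior: BetaPrior, spec: PrecisionSpec) -> int:
    """Wald sample size at the prior mode (prior mean for flat-ish shapes),
    minus a 50% safety margin."""
    if prior.c > 1 and prior.d > 1:
        pi_guess = prior.mode
    else:
        pi_guess = prior.mean
    wald = n_prop_wald(pi_guess, spec)
    return max(1, math.ceil(0.5 * wald))


def n_prop_criterion(prior: BetaPrior, spec: PrecisionSpec) -> SSDResult:
    """Smallest sample size for a proportion under ALC, ACC or WOC.

    Exact finite sums at every candidate n; upward linear scan from half
    the Wald sample size at the prior mode, with a downward walk when the
    start already satisfies the criterion, so that the returned n is
    certified smallest on the scanned range.
    """
    if spec.criterion not in ("alc", "acc", "woc"):
        raise ValueError(f"criterion must be alc/acc/woc, got {spec.criterion}")
    if spec.approach not in ("fully_bayesian", "mixed"):
        raise ValueError(f"approach must be fully_bayesian or mixed, got {spec.approach}")
    n = _scan_start(prior, spec)
    ok, achieved = evaluate_criterion(n, prior, spec)
    if ok:
        while n > 1:
            ok_prev, ach_prev = evaluate_criterion(n - 1, prior, spec)
            if not ok_prev:
                break
            n, achieved = n - 1, ach_prev
    else:
        while not ok:
            n += 1
            if n > _N_CAP:
                raise RuntimeError(f"no sample size up to {_N_CAP} meets the criterion")
            ok, achieved = evaluate_criterion(n, prior, spec)
    return SSDResult(n=n, achieved=achieved, criterion=spec.criterion,
                     approach=spec.approach)
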