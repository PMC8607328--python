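"""Brute-force oracles kept independent of the package's numerics.

Every interval search here is a plain two-stage grid minimisation /
maximisation over candidate lower bounds, refined to an effective step far
below the tolerances asserted by the tests.  The package itself locates
interval bounds by bisection on density equality, so agreement between the
two routes is a genuine cross-check.
"""

import numpy as np
from scipy import stats


def grid_hpd(cdf, ppf, coverage, n_grid=2000, refinements=2):
    """Shortest interval of the given mass: grid search over the lower bound.

    The lower bound v ranges over [ppf(0), ppf(1-coverage)]; the upper
    bound is ppf(cdf(v) + coverage).  Returns (lower, upper).
    """
    lo_edge, hi_edge = 0.0, 1.0 - coverage

    def lengths(w):
        v = ppf(w)
        u = ppf(np.minimum(w + coverage, 1.0))
        return v, u

    w_lo, w_hi = lo_edge, hi_edge
    best_v = best_u = None
    for _ in range(refinements + 1):
        w = np.linspace(w_lo, w_hi, n_grid)
        v, u = lengths(w)
        i = int(np.argmin(u - v))
        best_v, best_u = float(v[i]), float(u[i])
        step = (w_hi - w_lo) / (n_grid - 1)
        w_lo = max(lo_edge, w[i] - 2 * step)
        w_hi = min(hi_edge, w[i] + 2 * step)
    return best_v, best_u


def grid_hpd_beta(c, d, coverage, **kw):
    dist = stats.beta(c, d)
    return grid_hpd(dist.cdf, dist.ppf, coverage, **kw)


def grid_hpd_t(df, loc, scale, coverage, **kw):
    dist = stats.t(df, loc=loc, scale=scale)
    return grid_hpd(dist.cdf, dist.ppf, coverage, **kw)


def grid_max_coverage_beta(c, d, lmax, n_grid=2000, refinements=2):
    """Maximal mass of a length-lmax window: grid search over its left end."""
    dist = stats.beta(c, d)
    v_lo, v_hi = 0.0, 1.0 - lmax
    best = 0.0
    for _ in range(refinements + 1):
        v = np.linspace(v_lo, v_hi, n_grid)
        cov = dist.cdf(v + lmax) - dist.cdf(v)
        i = int(np.argmax(cov))
        best = float(cov[i])
        step = (v_hi - v_lo) / (n_grid - 1)
        v_lo = max(0.0, v[i] - 2 * step)
        v_hi = min(1.0 - lmax, v[i] + 2 * step)
    return best
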