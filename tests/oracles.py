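"""Independent reference implementations used to validate the package.

These deliberately use a different code path than the implementation:
scipy.stats.betabinom for the beta-binomial pmf and an explicit trapezoid
sum over the variant-fraction grid.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import betabinom, binom


def quadrature_log_bayes_factor(
    alt_fwd: int,
    alt_rev: int,
    depth_fwd: int,
    depth_rev: int,
    mu_fwd: float,
    mu_rev: float,
    rho: float,
    n_grid: int = 2001,
) -> float:
    """Brute-force AND-model log Bayes factor via scipy betabinom + trapezoid."""
    nu = np.logspace(-8, 0, n_grid)
    w = np.empty(n_grid)
    w[1:-1] = (nu[2:] - nu[:-2]) / 2.0
    w[0] = (nu[1] - nu[0]) / 2.0
    w[-1] = (nu[-1] - nu[-2]) / 2.0
    t = (1.0 - rho) / rho

    def lp(x, d, p):
        p = np.clip(p, 1e-12, 1.0 - 1e-9)
        return betabinom.logpmf(x, d, p * t, (1.0 - p) * t)

    f = lp(alt_fwd, depth_fwd, mu_fwd + nu) + lp(alt_rev, depth_rev, mu_rev + nu)
    null = lp(alt_fwd, depth_fwd, mu_fwd) + lp(alt_rev, depth_rev, mu_rev)
    return float(logsumexp(f, b=w) - null)


def binomial_lod(depth: int, specificity: float = 0.99, power: float = 0.95) -> float:
    """Closed-form LOD in the noiseless binomial limit (mu = 0, rho -> 0).

    With zero noise a single alt read is decisive (c* = 1) and the LOD is
    the smallest f with 1 - (1 - f)^depth >= power.
    """
    assert 0 < power < 1
    return 1.0 - (1.0 - power) ** (1.0 / depth)


def binomial_tail_lod(depth: int, mu: float, specificity: float, power: float) -> float:
    """Reference LOD with binomial tails (for small-rho cross-checks)."""
    alpha_tail = 1.0 - specificity
    c = 1
    while binom.sf(c - 1, depth, mu) > alpha_tail:
        c += 1
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if binom.sf(c - 1, depth, min(mu + mid, 1.0)) >= power:
            hi = mid
        else:
            lo = mid
    return hi
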