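"""Bayesian disproportionality: BCPNN information component and the
multi-item gamma-Poisson shrinker (MGPS).

BCPNN
-----
The information component IC = log2 p(drug, event) / (p(drug) p(event)) is
scored with the closed-form posterior approximation of the original BCPNN
formulation: independent Beta priors on the joint and marginal reporting
probabilities give

    IC = log2 [ (a + g11)(N + alpha)(N + beta)
                / ((N + g)(a+b + alpha1)(a+c + beta1)) ]

with alpha1 = beta1 = 1, alpha = beta = 2, g11 = 1 and
g = g11 (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)).  IC025 is the
two-standard-deviation lower bound IC - 2 sd.

MGPS
----
Counts a are modelled as Poisson with rate lambda * E, where E is the
expected count under independence and lambda carries a two-component gamma
mixture prior.  Marginally a follows a mixture of negative binomials, whose
likelihood is maximised over the five hyperparameters (w, a1, b1, a2, b2).
The posterior on lambda is again a gamma mixture; EBGM is the geometric
mean 2^(E[log2 lambda]) and EBGM05 the 5th posterior percentile.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .disproportionality import ContingencyTable

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class BcpnnResult:
    ic: float
    ic_sd: float
    ic025: float
    flag: bool


def bcpnn_ic(t: ContingencyTable, ic025_min: float = 0.0) -> BcpnnResult:
    """Closed-form BCPNN information component with IC025.

    Defined for a = 0; the priors keep every quantity finite.
    """
    a, n = t.a, t.N
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    g11 = 1.0
    m1 = t.a + t.b   # drug margin
    m2 = t.a + t.c   # event margin
    g = g11 * (n + alpha) * (n + beta) / ((m1 + alpha1) * (m2 + beta1))
    ic = math.log2((a + g11) * (n + alpha) * (n + beta)
                   / ((n + g) * (m1 + alpha1) * (m2 + beta1)))
    var = ((n - a + g - g11) / ((a + g11) * (1 + n + g))
           + (n - m1 + alpha - alpha1) / ((m1 + alpha1) * (1 + n + alpha))
           + (n - m2 + beta - beta1) / ((m2 + beta1) * (1 + n + beta)))
    sd = math.sqrt(var) / LN2
    ic025 = ic - 2.0 * sd
    return BcpnnResult(ic=ic, ic_sd=sd, ic025=ic025, flag=ic025 > ic025_min)


@dataclass(frozen=True)
class GammaMixturePrior:
    """Hyperparameters of the MGPS two-component gamma mixture prior.

    Shapes alpha_j and rates beta_j; *w* is the weight of component 1.
    The conventional starting point is w=1/3, a1=0.2, b1=0.1, a2=2, b2=4.
    """

    w: float = 1.0 / 3.0
    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.w < 1.0):
            raise ValueError("mixture weight w must be in (0, 1)")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")

    def mixture_cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Prior CDF of lambda (used for recovery diagnostics)."""
        return (self.w * stats.gamma.cdf(x, self.alpha1, scale=1 / self.beta1)
                + (1 - self.w) * stats.gamma.cdf(x, self.alpha2,
                                                 scale=1 / self.beta2))


@dataclass(frozen=True)
class MgpsResult:
    expected: float
    rr: float
    ebgm: float
    ebgm05: float
    flag: bool


def _log_marginal(a: np.ndarray, e: np.ndarray, w: float, a1: float,
                  b1: float, a2: float, b2: float) -> np.ndarray:
    """Log marginal pmf of counts under the negative-binomial mixture."""
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return np.logaddexp(math.log(w) + lp1, math.log1p(-w) + lp2)


def fit_mgps_prior(counts: np.ndarray, expecteds: np.ndarray,
                   init: GammaMixturePrior = GammaMixturePrior(),
                   max_iter: int = 500, tol: float = 1e-8,
                   ) -> GammaMixturePrior:
    """Maximum-likelihood fit of the gamma mixture prior over all pairs.

    Optimisation runs in unconstrained space (log for the positive
    parameters, logit for w) with L-BFGS-B; the fit is deterministic given
    the data and the starting point.  Non-convergence returns the
    best-so-far parameters with a warning.
    """
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expecteds, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("counts and expecteds must be 1-D arrays of equal length")
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    if not np.any(a > 0):
        raise ValueError("degenerate data: all observed counts are zero")
    if len(a) < 100:
        warnings.warn("fewer than 100 pairs: the mixture prior fit may be "
                      "poorly identified", stacklevel=2)

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
        w = special.expit(theta[0])
        # clip so exploratory optimizer steps cannot overflow exp
        a1, b1, a2, b2 = np.exp(np.clip(theta[1:], -300.0, 300.0))
        return w, a1, b1, a2, b2

    def nll(theta: np.ndarray) -> float:
        w, a1, b1, a2, b2 = unpack(theta)
        w = min(max(w, 1e-12), 1 - 1e-12)
        with np.errstate(all="ignore"):
            ll = _log_marginal(a, e, w, a1, b1, a2, b2)
        if np.any(np.isnan(ll)) or np.sum(ll) == -np.inf:
            return 1e30
        return -float(np.sum(ll))

    x0 = np.array([special.logit(init.w),
                   math.log(init.alpha1), math.log(init.beta1),
                   math.log(init.alpha2), math.log(init.beta2)])
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-10})
    if not res.success:
        warnings.warn(f"MGPS prior fit did not converge: {res.message}; "
                      "returning best parameters found", stacklevel=2)
    # ascent guarantee: never return a point worse than the start
    theta = res.x if res.fun <= nll(x0) else x0
    w, a1, b1, a2, b2 = unpack(theta)
    w = min(max(w, 1e-9), 1 - 1e-9)
    logger.info("MGPS prior fit: w=%.4f a1=%.4f b1=%.4f a2=%.4f b2=%.4f "
                "(nll %.4f)", w, a1, b1, a2, b2, res.fun)
    return GammaMixturePrior(w=w, alpha1=a1, beta1=b1, alpha2=a2, beta2=b2)


def prior_log_likelihood(prior: GammaMixturePrior, counts: np.ndarray,
                         expecteds: np.ndarray) -> float:
    """Sum of log marginal likelihood of the data under *prior*."""
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expecteds, dtype=float)
    return float(np.sum(_log_marginal(a, e, prior.w, prior.alpha1,
                                      prior.beta1, prior.alpha2, prior.beta2)))


def _posterior(a: float, e: float, prior: GammaMixturePrior,
               ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior mixture weight of component 1 and the two gamma components
    (shape, rate) given one observed count."""
    lp1 = (math.log(prior.w)
           + stats.nbinom.logpmf(a, prior.alpha1,
                                 prior.beta1 / (prior.beta1 + e)))
    lp2 = (math.log1p(-prior.w)
           + stats.nbinom.logpmf(a, prior.alpha2,
                                 prior.beta2 / (prior.beta2 + e)))
    q1 = float(np.exp(lp1 - np.logaddexp(lp1, lp2)))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a,
                                                     prior.beta2 + e)


def posterior_mixture_cdf(x: float, a: float, e: float,
                          prior: GammaMixturePrior) -> float:
    """Posterior CDF of the rate ratio lambda at *x*."""
    q1, (s1, r1), (s2, r2) = _posterior(a, e, prior)
    return (q1 * stats.gamma.cdf(x, s1, scale=1 / r1)
            + (1 - q1) * stats.gamma.cdf(x, s2, scale=1 / r2))


def mgps_score(t: ContingencyTable, prior: GammaMixturePrior,
               ebgm05_min: float = 2.0, quantile: float = 0.05) -> MgpsResult:
    """EBGM and EBGM05 for one table under a fitted prior.

    EBGM = 2^(E[log2 lambda]) via the digamma closed form per posterior
    component; EBGM05 solves the posterior mixture CDF = 0.05 by bracketed
    root-finding to 1e-10 relative tolerance.
    """
    return mgps_score_from_counts(t.a, t.expected, prior,
                                  ebgm05_min=ebgm05_min, quantile=quantile)


def mgps_score_from_counts(a: float, e: float, prior: GammaMixturePrior,
                           ebgm05_min: float = 2.0, quantile: float = 0.05,
                           ) -> MgpsResult:
    """:func:`mgps_score` on a raw (observed, expected) count pair."""
    if e <= 0:
        raise ValueError("expected count must be positive")
    a = float(a)
    q1, (s1, r1), (s2, r2) = _posterior(a, e, prior)
    mean_log = (q1 * (special.digamma(s1) - math.log(r1))
                + (1 - q1) * (special.digamma(s2) - math.log(r2)))
    ebgm = math.exp(mean_log)
    rr = a / e

    def f(x: float) -> float:
        return (q1 * stats.gamma.cdf(x, s1, scale=1 / r1)
                + (1 - q1) * stats.gamma.cdf(x, s2, scale=1 / r2) - quantile)

    lo, hi = 1e-12, max(rr, 1.0) * 1e3
    while f(hi) < 0:   # prior mass far to the right; expand the bracket
        hi *= 10
    if f(lo) >= 0:
        # a tiny posterior shape piles >5% mass below the bracket floor
        ebgm05 = 0.0
    else:
        ebgm05 = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=1e-12)
    return MgpsResult(expected=e, rr=rr, ebgm=ebgm, ebgm05=ebgm05,
                      flag=ebgm05 > ebgm05_min)
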