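"""Reference distributions fitted to the exact permutation moments.

Linear statistic: a Gaussian N(0, var T~), or a scaled beta on the exact
permutation range [A, B] matching mean 0 and var T~ (four quantities
matched: min, max, mean, variance).  Quadratic statistic: a scaled
chi-squared sigma^2 chi2_(nu) (equivalently a gamma) matching E(C~) and
var(C~).  All three references are continuous, so they avoid permutation
granularity; the beta is bounded and can return exactly 0 or 1 at the
support ends, for which an epsilon-adjustment using the data granularity is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError
from .moments import LinearMoments, QuadMoments

__all__ = [
    "BetaApprox",
    "ChiSqApprox",
    "PValueSet",
    "normal_p",
    "beta_fit",
    "beta_p",
    "epsilon_adjust",
    "chisq_fit_p",
]


@dataclass(frozen=True)
class PValueSet:
    """Left/right/central p-values (linear) or the quadratic tail p."""

    p_left: float = None
    p_right: float = None
    p_central: float = None
    p_q: float = None
    epsilon_used: float = None
    degenerate: bool = False


@dataclass(frozen=True)
class BetaApprox:
    """Scaled beta reference A + (B - A) beta(alpha, beta)."""

    A: float
    B: float
    alpha: float
    beta: float

    def mean(self) -> float:
        return self.A + (self.B - self.A) * self.alpha / (self.alpha + self.beta)

    def var(self) -> float:
        a, b = self.alpha, self.beta
        return (self.B - self.A) ** 2 * a * b / ((a + b) ** 2 * (a + b + 1))


@dataclass(frozen=True)
class ChiSqApprox:
    """Scaled chi-squared reference sigma2 * chi2_(nu); nu need not be integer."""

    nu: float
    sigma2: float

    def mean(self) -> float:
        return self.nu * self.sigma2

    def var(self) -> float:
        return 2.0 * self.nu * self.sigma2 ** 2


def _central(p_left: float, p_right: float) -> float:
    return min(1.0, 2.0 * min(p_left, p_right))


def normal_p(T_hat: float, var_T: float) -> PValueSet:
    """Gaussian p-values: p_left = Phi(T_hat / sqrt(var T~)).

    A zero variance marks a degenerate set; p = 1 is reported with a flag
    rather than raising, so one bad set does not abort a batch.
    """
    if var_T <= 0:
        return PValueSet(p_left=1.0, p_right=1.0, p_central=1.0,
                         degenerate=True)
    pl = float(stats.norm.cdf(T_hat / np.sqrt(var_T)))
    pr = float(stats.norm.sf(T_hat / np.sqrt(var_T)))
    return PValueSet(p_left=pl, p_right=pr, p_central=_central(pl, pr))


def beta_fit(lin: LinearMoments) -> BetaApprox:
    """Fit the scaled beta to the exact range and variance of T~.

    alpha = A/(B-A) (AB/var + 1),  beta = -B/(B-A) (AB/var + 1).
    Both are positive because A < 0 < B and, by the Bhatia-Davis
    inequality, var(T~) <= -AB with equality only in degenerate cases
    where T~ takes one or two distinct values.
    """
    A, B, v = lin.range_A, lin.range_B, lin.var_T
    if lin.degenerate or not (A < 0 < B):
        raise DegenerateStatisticError(
            "pseudo-gene statistic has no usable permutation range")
    if v >= -A * B:
        raise DegenerateStatisticError(
            "var(T~) >= -A*B: the statistic only takes one or two distinct "
            "values under permutation")
    factor = A * B / v + 1.0   # negative
    return BetaApprox(A, B, A / (B - A) * factor, -B / (B - A) * factor)


def beta_p(fit: BetaApprox, T_hat: float) -> PValueSet:
    """p_left = Pr(beta(alpha, beta) <= (T_hat - A)/(B - A)).

    T_hat lies in [A, B] by construction; values outside by more than a
    round-off tolerance indicate an internal inconsistency.
    """
    span = fit.B - fit.A
    z = (T_hat - fit.A) / span
    if z < -1e-12 / span or z > 1 + 1e-12 / span:
        raise ValueError("observed statistic outside the fitted support")
    z = min(1.0, max(0.0, z))
    pl = float(stats.beta.cdf(z, fit.alpha, fit.beta))
    pr = float(stats.beta.sf(z, fit.alpha, fit.beta))
    return PValueSet(p_left=pl, p_right=pr, p_central=_central(pl, pr))


def epsilon_adjust(pvals: PValueSet, epsilon: float) -> PValueSet:
    """Granularity adjustment p~_L = eps + (1 - 2 eps) p_L.

    Maps [0, 1] onto [eps, 1 - eps] so a bounded reference can never return
    an exact 0 — no permutation test could either, since its smallest
    attainable p-value is the data granularity eps.  p~_R = 1 - p~_L and
    p~_C = 2 min(p~_L, p~_R).
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 1/2)")
    pl = epsilon + (1.0 - 2.0 * epsilon) * pvals.p_left
    pr = 1.0 - pl
    return replace(pvals, p_left=pl, p_right=pr, p_central=_central(pl, pr),
                   epsilon_used=epsilon)


def chisq_fit_p(qm: QuadMoments):
    """Fit sigma^2 chi2_(nu) to (E C~, var C~) and report the tail p-value.

    nu = 2 E(C~)^2 / var(C~), sigma^2 = E(C~)/nu;
    p_Q = Pr(sigma^2 chi2_(nu) >= C_hat), computed through the upper gamma
    tail (shape nu/2, scale 2 sigma^2) so fractional nu is exact.
    """
    if qm.degenerate or qm.mean_C <= 0 or qm.var_C <= 0:
        return None, PValueSet(p_q=1.0, degenerate=True)
    nu = 2.0 * qm.mean_C ** 2 / qm.var_C
    sigma2 = qm.mean_C / nu
    p_q = float(stats.gamma.sf(qm.C_hat, a=nu / 2.0, scale=2.0 * sigma2))
    return ChiSqApprox(nu, sigma2), PValueSet(p_q=p_q)
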