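"""Exact permutation moments of the linear and quadratic gene set statistics.

For centered data, permuting the phenotype Y induces an exact null
distribution for

    T~ = sum_g w_g beta~_g      (linear)
    C~ = sum_g w_g beta~_g^2    (quadratic)

whose low-order moments have closed forms in a handful of data moments:
mu2 = (1/n) sum Y^2, mu4 = (1/n) sum Y^4, the gene cross-moments
Xbar_gh = (1/n) sum_i X_gi X_hi, and fourth cross-moments such as
Xbar_gghh = (1/n) sum_i X_gi^2 X_hi^2.  The fourth-moment machinery is a
fixed 2x2 matrix A^T B, where A (n-dependent) maps (mu2^2, mu4) to the five
distinct-index permutation moments of Y (four of a kind, three of a kind,
two pair, one pair, none) and B (constant) collects the combinatorial
coefficients of the X cross-moments.

Everything here is exact — not asymptotic — and is validated elsewhere in
the package against exhaustive enumeration of all n! permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSamplesError, WeightSignError
from .preprocess import Phenotype

__all__ = [
    "YMoments",
    "CrossMoments",
    "MomentMachinery",
    "LinearMoments",
    "QuadMoments",
    "y_moments",
    "moment_machinery",
    "linear_moments",
    "pair_covariance",
    "pair_sq_covariance",
    "quad_moments",
    "kurtosis_diagnostic",
]

# Constant coefficient matrix pairing the five Y-moments with
# (Xbar*_ghrs / n^2, Xbar_ghrs / n^3) in the fourth-moment expansion.
B_MATRIX = np.array([[0.0, 1.0],
                     [0.0, -4.0],
                     [1.0, -3.0],
                     [-2.0, 12.0],
                     [1.0, -6.0]])


def _as_values(y) -> np.ndarray:
    if isinstance(y, Phenotype):
        if not y.centered:
            raise ValueError("phenotype must be centered")
        return y.values
    return np.asarray(y, dtype=float)


@dataclass(frozen=True)
class MomentMachinery:
    """The n-dependent matrices of the fourth-moment closed form."""

    n: int
    A: np.ndarray        # 5 x 2, maps (mu2^2, mu4) to the five Y moments
    B: np.ndarray        # 5 x 2 constant matrix
    ATB: np.ndarray      # 2 x 2 product A^T B


def moment_machinery(n: int) -> MomentMachinery:
    """Build A, B and A^T B for an experiment with n samples (n >= 4)."""
    if n < 4:
        raise InsufficientSamplesError("fourth moments require n >= 4")
    d2 = n - 1.0
    d3 = (n - 1.0) * (n - 2.0)
    d4 = (n - 1.0) * (n - 2.0) * (n - 3.0)
    A = np.array([[0.0, 1.0],           # mu_4k  (four of a kind)
                  [0.0, -1.0 / d2],     # mu_3k  (three of a kind)
                  [n / d2, -1.0 / d2],  # mu_2p  (two pair)
                  [-n / d3, 2.0 / d3],  # mu_1p  (one pair)
                  [3.0 * n / d4, -6.0 / d4]])   # mu_empty
    return MomentMachinery(n, A, B_MATRIX, A.T @ B_MATRIX)


@dataclass(frozen=True)
class YMoments:
    """Even data moments of Y and the derived distinct-index moments.

    mu_4k..mu_empty are the permutation expectations E(Y~_i^4),
    E(Y~_i^3 Y~_j), E(Y~_i^2 Y~_j^2), E(Y~_i^2 Y~_j Y~_k) and
    E(Y~_i Y~_j Y~_k Y~_l) over distinct sample indices.
    """

    n: int
    mu2: float
    mu4: float
    mu_4k: float = None
    mu_3k: float = None
    mu_2p: float = None
    mu_1p: float = None
    mu_empty: float = None

    @property
    def vector(self) -> np.ndarray:
        if self.mu_4k is None:
            raise InsufficientSamplesError("derived moments require n >= 4")
        return np.array([self.mu_4k, self.mu_3k, self.mu_2p,
                         self.mu_1p, self.mu_empty])


def y_moments(y) -> YMoments:
    """Data moments of the centered phenotype.

    The five distinct-index moments equal A @ (mu2^2, mu4); they are only
    defined for n >= 4 (fewer samples leave no four distinct indices).
    """
    yv = _as_values(y)
    n = yv.size
    mu2 = float((yv ** 2).mean())
    mu4 = float((yv ** 4).mean())
    if n < 4:
        return YMoments(n, mu2, mu4)
    derived = moment_machinery(n).A @ np.array([mu2 ** 2, mu4])
    return YMoments(n, mu2, mu4, *derived.tolist())


@dataclass(frozen=True)
class CrossMoments:
    """Second and fourth cross-moments of a block of gene rows."""

    xbar: np.ndarray        # p x p matrix of Xbar_gh
    xbar_sq: np.ndarray     # p x p matrix of Xbar_gghh

    @classmethod
    def from_rows(cls, rows: np.ndarray) -> "CrossMoments":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        n = rows.shape[1]
        sq = rows ** 2
        return cls(rows @ rows.T / n, sq @ sq.T / n)


@dataclass(frozen=True)
class LinearMoments:
    """Observed linear statistic plus its exact permutation moments."""

    T_hat: float
    var_T: float
    range_A: float          # min of T~ over permutations
    range_B: float          # max of T~ over permutations
    fourth_moment: float = None   # E(T~^4), available for n >= 4
    n: int = 0
    degenerate: bool = False      # pseudo-gene identically zero


@dataclass(frozen=True)
class QuadMoments:
    """Observed quadratic statistic plus its exact permutation moments."""

    C_hat: float
    mean_C: float
    var_C: float
    S1: float
    S2: float
    S3: float
    n: int = 0
    degenerate: bool = False


def pair_covariance(g: int, h: int, cross: CrossMoments, ym: YMoments,
                    mach: MomentMachinery = None) -> float:
    """cov(beta~_g, beta~_h) = mu2 Xbar_gh / (n - 1)."""
    return ym.mu2 * cross.xbar[g, h] / (ym.n - 1)


def pair_sq_covariance(g: int, h: int, cross: CrossMoments, ym: YMoments,
                       mach: MomentMachinery) -> float:
    """cov(beta~_g^2, beta~_h^2) from the fourth-moment closed form.

    E(beta~_g^2 beta~_h^2) = (mu2^2, mu4) A^T B (Xbar*_gghh/n^2, Xbar_gghh/n^3)
    with Xbar*_gghh = Xbar_gg Xbar_hh + 2 Xbar_gh^2, minus the product of the
    second moments mu2^2 Xbar_gg Xbar_hh / (n-1)^2.
    """
    if ym.n < 4:
        raise InsufficientSamplesError("pair_sq_covariance requires n >= 4")
    n = ym.n
    xbar = cross.xbar
    star = xbar[g, g] * xbar[h, h] + 2.0 * xbar[g, h] ** 2
    m = np.array([ym.mu2 ** 2, ym.mu4])
    raw = m @ mach.ATB @ np.array([star / n ** 2, cross.xbar_sq[g, h] / n ** 3])
    return float(raw - ym.mu2 ** 2 * xbar[g, g] * xbar[h, h] / (n - 1) ** 2)


def linear_moments(x_G: np.ndarray, y) -> LinearMoments:
    """Moments of the linear statistic for a (weight-absorbed) pseudo-gene.

    var(T~) = mu2 Xbar_GG / (n-1).  The exact permutation range [A, B]
    follows from the rearrangement inequality: B co-sorts X_G with Y,
    A anti-sorts them.  E(T~^4) uses the fourth-moment machinery applied to
    the single pseudo-gene (n >= 4).
    """
    x = np.asarray(x_G, dtype=float).ravel()
    yv = _as_values(y)
    n = yv.size
    if x.size != n:
        raise ValueError("pseudo-gene and phenotype lengths differ")
    T_hat = float(x @ yv / n)
    mu2 = float((yv ** 2).mean())
    xbar_GG = float((x ** 2).mean())
    var_T = mu2 * xbar_GG / (n - 1)
    xs, ys = np.sort(x), np.sort(yv)
    range_B = float(xs @ ys / n)
    range_A = float(xs @ ys[::-1] / n)
    fourth = None
    if n >= 4:
        mach = moment_machinery(n)
        xbar_GGGG = float((x ** 4).mean())
        mu4 = float((yv ** 4).mean())
        fourth = float(np.array([mu2 ** 2, mu4]) @ mach.ATB
                       @ np.array([3.0 * xbar_GG ** 2 / n ** 2,
                                   xbar_GGGG / n ** 3]))
    return LinearMoments(T_hat, var_T, range_A, range_B, fourth,
                         n=n, degenerate=(xbar_GG == 0.0))


def quad_moments(rows: np.ndarray, y, var_c_clip: float = 1e-10) -> QuadMoments:
    """Moments of the quadratic statistic for sqrt(w)-scaled set rows.

    With weights absorbed as sqrt(w_g) X_gi (valid for w >= 0),

        E(C~)   = mu2 sum_g Xbar_gg / (n-1)
        var(C~) = (mu2^2, mu4) A^T B ((S1 + 2 S3)/n^2, S2/n^3)
                  - mu2^2 S1 / (n-1)^2

    where S1 = (sum_g Xbar_gg)^2, S2 = (1/n) sum_i (sum_g X_gi^2)^2 and
    S3 = sum_gh Xbar_gh^2.  S1 and S2 are O(np); S3 is computed through the
    p x p Gram matrix when p <= n (O(n p^2)) and through the n x n sample
    Gram matrix otherwise (O(n^2 p)) — the two routes are algebraically
    identical.

    Tiny negative var(C~) from round-off (> -var_c_clip * mean_C^2) is
    clipped to zero; anything more negative raises.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    yv = _as_values(y)
    p, n = rows.shape
    if yv.size != n:
        raise ValueError("set rows and phenotype lengths differ")
    if n < 4:
        raise InsufficientSamplesError("quad_moments requires n >= 4")
    mu2 = float((yv ** 2).mean())
    mu4 = float((yv ** 4).mean())
    beta = rows @ yv / n
    C_hat = float(beta @ beta)

    xbar_gg = (rows ** 2).mean(axis=1)
    sum_xgg = float(xbar_gg.sum())
    mean_C = mu2 * sum_xgg / (n - 1)
    S1 = sum_xgg ** 2
    col_sq = (rows ** 2).sum(axis=0)
    S2 = float((col_sq ** 2).mean())
    if p <= n:
        G = rows @ rows.T / n
        S3 = float((G ** 2).sum())
    else:
        K = rows.T @ rows / n
        S3 = float((K ** 2).sum())

    mach = moment_machinery(n)
    m = np.array([mu2 ** 2, mu4])
    var_C = float(m @ mach.ATB @ np.array([(S1 + 2.0 * S3) / n ** 2,
                                           S2 / n ** 3])
                  - mu2 ** 2 * S1 / (n - 1) ** 2)
    if var_C < 0:
        if var_C > -var_c_clip * max(mean_C ** 2, 1.0):
            var_C = 0.0
        else:
            raise ValueError(f"var(C~) = {var_C} is significantly negative; "
                             "inconsistent inputs")
    return QuadMoments(C_hat, mean_C, var_C, S1, S2, S3,
                       n=n, degenerate=(sum_xgg == 0.0))


def kurtosis_diagnostic(lin: LinearMoments) -> float:
    """Excess fourth moment E(T~^4) - 3 var(T~)^2.

    Negative values (the typical case for standardized data) mean the
    permutation distribution has lighter tails than the normal — the reason
    a bounded beta reference is offered instead of a t reference.
    """
    if lin.fourth_moment is None:
        raise InsufficientSamplesError("fourth moment unavailable (n < 4)")
    return lin.fourth_moment - 3.0 * lin.var_T ** 2
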