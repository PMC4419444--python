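"""Ground-truth resampling: permutation and rotation oracles.

These routines exist to validate the closed-form moments and fitted
reference distributions, not to produce production p-values:

* Monte-Carlo permutation draws (independent uniform permutations) with the
  +1 p-value convention that counts the identity permutation.
* Exhaustive enumeration of all n! permutations for n <= 8, the arbiter
  oracle for the moment formulas.
* Mean-preserving random rotations Y~ = ((1/n) 1 1^T + W Q* W^T) Y with a
  Helmert contrast matrix W and Haar-uniform Q*; their first and second
  moments (and E C~) coincide with the permutation values, while var(C~)
  depends on the choice of W.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import helmert

from .approx import PValueSet
from .moments import _as_values

__all__ = [
    "ResampleDraws",
    "RotationDraws",
    "permutation_draws",
    "exhaustive_draws",
    "exhaustive_moments",
    "perm_pvalues",
    "contrast_matrix",
    "haar_rotations",
    "random_rotation_draws",
]

MAX_EXHAUSTIVE_N = 8


@dataclass(frozen=True)
class ResampleDraws:
    """Resampled statistic values T~_m or C~_m."""

    kind: str               # "permutation" | "exhaustive"
    statistic: str          # "linear" | "quadratic"
    draws: np.ndarray
    M: int
    seed: int = None


@dataclass(frozen=True)
class RotationDraws:
    """Rotation-resampled per-gene coefficients and set statistics."""

    betas: np.ndarray       # M x p
    T: np.ndarray           # M
    C: np.ndarray           # M
    M: int
    seed: int


def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _stat_draws(rows: np.ndarray, Yp: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic values for each permuted phenotype row of ``Yp``."""
    rows = np.atleast_2d(rows)
    n = rows.shape[1]
    beta = Yp @ rows.T / n          # (M, p)
    if statistic == "linear":
        return beta.sum(axis=1)     # rows are the pseudo-gene (p = 1) or
                                    # weight-absorbed profiles summed here
    if statistic == "quadratic":
        return (beta ** 2).sum(axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_draws(rows: np.ndarray, y, M: int, seed: int,
                      statistic: str = "linear") -> ResampleDraws:
    """M independent uniform permutations (sampling with replacement).

    ``rows`` is the pseudo-gene vector for the linear statistic or the
    sqrt(w)-scaled set rows for the quadratic one.
    """
    yv = _as_values(y)
    rng = np.random.default_rng(seed)
    Yp = rng.permuted(np.broadcast_to(yv, (M, yv.size)), axis=1)
    return ResampleDraws("permutation", statistic,
                         _stat_draws(rows, Yp, statistic), M, seed)


def exhaustive_draws(rows: np.ndarray, y,
                     statistic: str = "linear") -> ResampleDraws:
    """Statistic values over all n! permutations (refused for n > 8)."""
    yv = _as_values(y)
    n = yv.size
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive enumeration limited to n <= "
                         f"{MAX_EXHAUSTIVE_N}, got n = {n}")
    Yp = yv[_perm_matrix(n)]
    return ResampleDraws("exhaustive", statistic,
                         _stat_draws(rows, Yp, statistic), math.factorial(n))


def exhaustive_moments(rows: np.ndarray, y) -> dict:
    """Exact E/var/E^4 of T~ and E/var of C~ by full enumeration (n <= 8).

    ``rows``: the full block of (weight-absorbed / sqrt(w)-scaled) set rows;
    the linear statistic uses their sum as pseudo-gene.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    yv = _as_values(y)
    n = yv.size
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive enumeration limited to n <= "
                         f"{MAX_EXHAUSTIVE_N}, got n = {n}")
    Yp = yv[_perm_matrix(n)]
    beta = Yp @ rows.T / n
    T = beta.sum(axis=1)
    C = (beta ** 2).sum(axis=1)
    return {
        "E_T": float(T.mean()),
        "var_T": float(T.var()),
        "E_T4": float((T ** 4).mean()),
        "E_C": float(C.mean()),
        "var_C": float(C.var()),
    }


def perm_pvalues(draws: ResampleDraws, observed: float) -> PValueSet:
    """Permutation p-values with the +1 identity-permutation convention.

    p_L = (#{T~_m <= T^} + 1)/(M + 1), and analogously p_R, p_C (central,
    on |T~|) and p_Q (upper tail of C~).  Over exhaustive enumeration of
    continuous data the p-value is uniform on {1/(M+1), ..., 1}.
    """
    d = draws.draws
    if d.size == 0:
        raise ValueError("empty draws")
    M = d.size
    if draws.statistic == "quadratic":
        p_q = (np.count_nonzero(d >= observed) + 1) / (M + 1)
        return PValueSet(p_q=float(p_q))
    pl = (np.count_nonzero(d <= observed) + 1) / (M + 1)
    pr = (np.count_nonzero(d >= observed) + 1) / (M + 1)
    pc = (np.count_nonzero(np.abs(d) >= abs(observed)) + 1) / (M + 1)
    return PValueSet(p_left=float(pl), p_right=float(pr),
                     p_central=float(min(1.0, pc)))


def contrast_matrix(n: int) -> np.ndarray:
    """An n x (n-1) orthonormal contrast matrix (Helmert construction).

    Columns are orthonormal and orthogonal to the all-ones vector:
    W^T W = I_(n-1), W^T 1_n = 0.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    return helmert(n, full=False).T


def haar_rotations(dim: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform orthogonal matrices via QR of a Gaussian matrix.

    The R diagonal's signs are folded back into Q (Mezzadri's recipe), which
    makes the distribution exactly rotation-invariant.
    """
    Z = rng.standard_normal((size, dim, dim))
    Q, R = np.linalg.qr(Z)
    signs = np.sign(np.einsum("...ii->...i", R))
    signs[signs == 0] = 1.0
    return Q * signs[:, None, :]


def random_rotation_draws(rows: np.ndarray, y, M: int, seed: int,
                          W: np.ndarray = None) -> RotationDraws:
    """Mean-preserving rotation resampling of the phenotype.

    Each draw replaces Y by Q Y with Q = (1/n) 1 1^T + W Q* W^T for a
    Haar-uniform (n-1)-dimensional rotation Q*, then recomputes beta~, T~
    and C~.  The rotated phenotype keeps its mean and sum of squares.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    yv = _as_values(y)
    n = yv.size
    if n < 3:
        raise ValueError("rotation sampling requires n >= 3")
    if W is None:
        W = contrast_matrix(n)
    rng = np.random.default_rng(seed)
    Qs = haar_rotations(n - 1, M, rng)
    yc = W.T @ yv                               # (n-1,)
    Yt = yv.mean() + (Qs @ yc) @ W.T            # (M, n)
    beta = Yt @ rows.T / n
    return RotationDraws(beta, beta.sum(axis=1), (beta ** 2).sum(axis=1),
                         M, seed)
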