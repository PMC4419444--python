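"""Centering/scaling of expression data and per-gene association statistics.

The package works with a genes x samples matrix X and a phenotype vector Y.
All downstream moment formulas assume both are centered:

    sum_i X_gi = 0  for every gene g,   sum_i Y_i = 0.

By default each gene row is additionally scaled so that sum_i X_gi^2 = n,
which makes the per-gene covariance ``beta_hat_g = (1/n) sum_i X_gi Y_i``
equal to a sample correlation (up to the scaling of Y, which cancels from
every p-value).  Scaling can be disabled, e.g. for probes whose low signal
would otherwise be inflated into noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .errors import (
    DegenerateGeneError,
    DegeneratePhenotypeError,
    ShapeError,
    WeightSignError,
)

__all__ = [
    "ExpressionMatrix",
    "Phenotype",
    "GeneSet",
    "GeneLevelStats",
    "center_scale",
    "beta_hats",
    "pseudo_gene",
    "t_and_taylor",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real matrix with row metadata.

    Parameters
    ----------
    gene_ids : tuple of str
        Unique row identifiers.
    sample_ids : tuple of str
        Column identifiers, one per sample.
    values : ndarray, shape (n_genes, n_samples)
    centered, scaled : bool
        Whether rows have been centered (row sums 0) and scaled
        (row sums of squares equal to n).
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray
    centered: bool = False
    scaled: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ShapeError("expression values must be a 2-d matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values; "
                             "the moment formulas assume complete data")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def rows(self, gene_ids) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return self.values[[index[g] for g in gene_ids]]


@dataclass(frozen=True)
class Phenotype:
    """Per-sample target values (binary group labels or a continuous trait)."""

    values: np.ndarray
    centered: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if values.size < 2:
            raise DegeneratePhenotypeError("need at least two samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("phenotype contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    def group_sizes(self) -> tuple:
        """Multiset of tie counts n_k (exact floating equality defines a tie)."""
        _, counts = np.unique(self.values, return_counts=True)
        return tuple(sorted(counts.tolist(), reverse=True))


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection with optional per-gene scalar weights."""

    name: str
    gene_ids: tuple
    weights: np.ndarray = None

    def __post_init__(self):
        genes = tuple(self.gene_ids)
        object.__setattr__(self, "gene_ids", genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} has duplicated members")
        w = self.weights
        w = np.ones(len(genes)) if w is None else np.asarray(w, dtype=float)
        if w.shape != (len(genes),):
            raise ShapeError(f"gene set {self.name!r}: one weight per gene required")
        object.__setattr__(self, "weights", w)

    def __len__(self):
        return len(self.gene_ids)

    def matched(self, X: ExpressionMatrix) -> "GeneSet":
        """Restrict to the genes present in ``X`` (order preserved)."""
        present = set(X.gene_ids)
        keep = [i for i, g in enumerate(self.gene_ids) if g in present]
        return GeneSet(self.name,
                       tuple(self.gene_ids[i] for i in keep),
                       self.weights[keep])


@dataclass(frozen=True)
class GeneLevelStats:
    """Per-gene association statistics between expression and phenotype."""

    beta_hat: np.ndarray    # sample covariance (1/n) sum_i X_gi Y_i
    rho_hat: np.ndarray     # sample correlation
    t_stat: np.ndarray
    t_taylor: np.ndarray
    n: int = field(default=0)


def _center_rows(values: np.ndarray) -> np.ndarray:
    return values - values.mean(axis=-1, keepdims=True)


def center_scale(X: ExpressionMatrix, Y: Phenotype, scale_genes: bool = True,
                 rank_transform: bool = False):
    """Center X rows and Y; optionally scale rows to sum of squares n.

    Idempotent: already centered/scaled input is returned unchanged (up to
    floating round-off).  Preprocessing of X never reads Y and vice versa.

    Parameters
    ----------
    scale_genes : bool
        If True (the default), scale each gene row so sum_i X_gi^2 = n.
    rank_transform : bool
        Replace each gene row by its (average-tie) ranks before centering;
        an outlier-robust option.

    Raises
    ------
    DegenerateGeneError
        A gene row is constant while ``scale_genes`` is on.
    DegeneratePhenotypeError
        Y is constant.
    """
    values = X.values
    if rank_transform:
        values = np.apply_along_axis(rankdata, 1, values)
    values = _center_rows(values)
    if scale_genes:
        ss = (values ** 2).sum(axis=1)
        bad = np.flatnonzero(ss == 0)
        if bad.size:
            raise DegenerateGeneError(
                f"constant gene row(s) cannot be scaled: "
                f"{[X.gene_ids[i] for i in bad[:5]]}"
            )
        values = values * np.sqrt(X.n_samples / ss)[:, None]

    y = Y.values - Y.values.mean()
    if np.all(y == 0):
        raise DegeneratePhenotypeError("phenotype is constant")

    Xc = ExpressionMatrix(X.gene_ids, X.sample_ids, values,
                          centered=True, scaled=scale_genes)
    return Xc, Phenotype(y, centered=True)


def beta_hats(X: ExpressionMatrix, Y: Phenotype) -> GeneLevelStats:
    """Per-gene sample covariances, correlations and t-statistics.

    ``beta_hat[g] = (1/n) sum_i X_gi Y_i``.  When gene rows and Y are both
    standardized to unit mean square, beta_hat equals the correlation.
    """
    if not (X.centered and Y.centered):
        raise ValueError("center_scale must be applied first")
    if X.n_samples != Y.n:
        raise ShapeError(f"X has {X.n_samples} samples but Y has {Y.n}")
    n = Y.n
    beta = X.values @ Y.values / n
    xbar_gg = (X.values ** 2).mean(axis=1)
    mu2 = (Y.values ** 2).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(xbar_gg > 0, beta / np.sqrt(xbar_gg * mu2), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(rho) < 1,
                     np.sqrt(n - 2) * rho / np.sqrt(1 - rho ** 2),
                     np.sign(rho) * np.inf)
    t_approx = np.sqrt(n - 2) * (rho + 0.5 * rho ** 3)
    return GeneLevelStats(beta, rho, t, t_approx, n=n)


def pseudo_gene(X: ExpressionMatrix, G: GeneSet, mode: str = "linear") -> np.ndarray:
    """Collapse a gene set for fast statistic computation.

    linear mode
        Returns the single profile ``X_Gi = sum_g w_g X_gi`` (weights
        absorbed); the linear statistic is then ``(1/n) sum_i X_Gi Y_i``.
    quadratic mode
        Returns the set's rows with each row g multiplied by sqrt(w_g),
        which reduces the weighted quadratic statistic to the unweighted
        one on the scaled rows.  Requires w_g >= 0.
    """
    rows = X.rows(G.gene_ids)
    if mode == "linear":
        return G.weights @ rows
    if mode == "quadratic":
        if np.any(G.weights < 0):
            raise WeightSignError(
                f"gene set {G.name!r}: quadratic statistic requires w >= 0")
        return np.sqrt(G.weights)[:, None] * rows
    raise ValueError(f"unknown mode {mode!r}")


def t_and_taylor(rho_hat: float, n: int):
    """The exact t-statistic and its fourth-order Taylor approximation.

    t = sqrt(n-2) rho / sqrt(1-rho^2);  t ~= sqrt(n-2) (rho + rho^3/2),
    with error O(rho^5).  For the small per-gene correlations where gene
    set testing is most useful, t is nearly proportional to rho, which is
    why the package sums covariances/correlations rather than t-statistics.
    """
    if n < 3:
        raise ValueError("n >= 3 required for a t-statistic")
    rho = float(rho_hat)
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    t = np.sqrt(n - 2) * rho / np.sqrt(1 - rho ** 2)
    t_approx = np.sqrt(n - 2) * (rho + 0.5 * rho ** 3)
    return t, t_approx


def drop_unusable_sets(sets, X: ExpressionMatrix, min_genes: int = 2):
    """Match sets against the matrix; drop sets with < ``min_genes`` matches.

    Returns the matched, usable sets.  Dropped sets trigger a warning, as do
    sets that lost members absent from the matrix.
    """
    usable = []
    for G in sets:
        m = G.matched(X)
        if len(m) < min_genes:
            warnings.warn(
                f"dropping gene set {G.name!r}: only {len(m)} gene(s) "
                f"matched the expression matrix", stacklevel=2)
            continue
        if len(m) < len(G):
            warnings.warn(
                f"gene set {G.name!r}: {len(G) - len(m)} member(s) absent "
                f"from the expression matrix were dropped", stacklevel=2)
        usable.append(m)
    return usable
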