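"""Orchestration: run the chosen statistic + approximation over gene sets.

``run_gene_sets`` takes preprocessed inputs, computes per-set statistics and
moment-based p-values, applies Benjamini-Hochberg adjustment across the
emitted sets, and returns one record per usable set.  Degenerate sets (zero
pseudo-gene) report p = 1 with a flag instead of aborting the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import approx as ap
from . import moments as mo
from .design import design_summary, LOW_COUNT_THRESHOLD
from .errors import DegenerateStatisticError, MomentGSAError
from .preprocess import (ExpressionMatrix, GeneSet, Phenotype,
                         drop_unusable_sets, pseudo_gene)
from .resampling import permutation_draws, perm_pvalues

__all__ = ["RunConfig", "GeneSetResult", "run_gene_sets"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis switches mirroring the command-line flags."""

    statistic: str = "linear"          # "linear" | "quadratic"
    approximation: str = "beta"        # "normal" | "beta" | "chisq"
    epsilon_adjust: bool = None        # default: on for the beta reference
    alpha: float = 0.05
    permutations: int = None           # oracle mode: sampled permutation p
    seed: int = 0

    def __post_init__(self):
        if self.statistic not in ("linear", "quadratic"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        approx = self.approximation
        if self.statistic == "quadratic" and approx not in ("chisq",):
            object.__setattr__(self, "approximation", "chisq")
        if self.statistic == "linear" and approx not in ("normal", "beta"):
            raise ValueError(f"approximation {approx!r} invalid for the "
                             "linear statistic")
        if self.epsilon_adjust is None:
            object.__setattr__(self, "epsilon_adjust",
                               self.approximation == "beta")


@dataclass
class GeneSetResult:
    set_name: str
    n_genes_matched: int
    statistic_kind: str
    stat_value: float
    p_left: float = None
    p_right: float = None
    p_central: float = None
    p_q: float = None
    p_adjusted: float = None
    epsilon_used: float = None
    degenerate: bool = False
    approx_params: object = None

    @property
    def p_two_sided(self) -> float:
        return self.p_q if self.statistic_kind == "quadratic" else self.p_central


def _pvalues_linear(X, Y, G, config, epsilon):
    xg = pseudo_gene(X, G, "linear")
    lin = mo.linear_moments(xg, Y)
    params = None
    if config.permutations:
        draws = permutation_draws(xg, Y, config.permutations,
                                  config.seed, "linear")
        pv = perm_pvalues(draws, lin.T_hat)
    elif lin.degenerate:
        pv = ap.PValueSet(p_left=1.0, p_right=1.0, p_central=1.0,
                          degenerate=True)
    elif config.approximation == "normal":
        pv = ap.normal_p(lin.T_hat, lin.var_T)
    else:
        try:
            params = ap.beta_fit(lin)
            pv = ap.beta_p(params, lin.T_hat)
        except DegenerateStatisticError:
            pv = ap.PValueSet(p_left=1.0, p_right=1.0, p_central=1.0,
                              degenerate=True)
    if config.epsilon_adjust and not pv.degenerate and pv.p_left is not None:
        pv = ap.epsilon_adjust(pv, epsilon)
    return lin.T_hat, pv, params


def _pvalues_quadratic(X, Y, G, config):
    rows = pseudo_gene(X, G, "quadratic")
    qm = mo.quad_moments(rows, Y)
    params = None
    if config.permutations:
        draws = permutation_draws(rows, Y, config.permutations,
                                  config.seed, "quadratic")
        pv = perm_pvalues(draws, qm.C_hat)
    else:
        params, pv = ap.chisq_fit_p(qm)
    return qm.C_hat, pv, params


def run_gene_sets(X: ExpressionMatrix, Y: Phenotype, sets,
                  config: RunConfig = None):
    """Per-set statistics, p-values and BH adjustment.

    Inputs must be preprocessed (see :func:`momentgsa.center_scale`).
    Deterministic given inputs and config.  Returns a list of
    :class:`GeneSetResult`, one per usable set (>= 2 matched genes).
    """
    config = config or RunConfig()
    if not (X.centered and Y.centered):
        raise ValueError("run_gene_sets expects centered inputs")
    usable = drop_unusable_sets(sets, X)
    if not usable:
        raise MomentGSAError("no usable gene sets (need >= 2 matched genes)")

    summary = design_summary(Y)
    if summary.warn_low_count:
        warnings.warn(
            f"only {summary.distinct_count:.0f} distinct phenotype "
            f"arrangements (< {LOW_COUNT_THRESHOLD}); the moment "
            "approximation may be unreliable and exhaustive enumeration "
            "may be feasible", stacklevel=2)
    epsilon = summary.epsilon

    results = []
    for G in usable:
        if config.statistic == "linear":
            stat, pv, params = _pvalues_linear(X, Y, G, config, epsilon)
        else:
            stat, pv, params = _pvalues_quadratic(X, Y, G, config)
        results.append(GeneSetResult(
            set_name=G.name,
            n_genes_matched=len(G),
            statistic_kind=config.statistic,
            stat_value=stat,
            p_left=pv.p_left,
            p_right=pv.p_right,
            p_central=pv.p_central,
            p_q=pv.p_q,
            epsilon_used=pv.epsilon_used,
            degenerate=pv.degenerate,
            approx_params=params,
        ))

    two_sided = np.array([r.p_two_sided for r in results])
    _, adjusted, _, _ = multipletests(two_sided, alpha=config.alpha,
                                      method="fdr_bh")
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results
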