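"""Seedable synthetic expression data for validation and demos.

The generator emulates the standardized inputs of a two-group or
continuous-phenotype expression study: Gaussian gene profiles with optional
within-set correlation (a shared latent factor per gene block) and an
optional phenotype-linked mean shift in designated signal sets.  Under the
self-contained null (no shift) genes are independent of the phenotype by
construction, so permutation-based rejection rates are exactly calibrated
and moment approximations can be judged against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ExpressionMatrix, GeneSet, Phenotype

__all__ = ["SynthSpec", "synth_generate"]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for a synthetic data set.

    Defaults describe a small expression study of the size this package
    targets: n = 20 samples (where distinct permutations are plentiful),
    200 genes partitioned into sets of 10.

    Parameters
    ----------
    rho_block : float in [0, 1)
        Within-set gene-gene correlation, induced by a shared factor.
    effect_size : float
        Mean shift per unit of (standardized) phenotype added to every gene
        of the sets named in ``signal_sets``.
    phenotype : "continuous" or ("binary", n1, n2)
    """

    n_samples: int = 20
    n_genes: int = 200
    set_size: int = 10
    rho_block: float = 0.0
    effect_size: float = 0.0
    signal_sets: tuple = ()
    phenotype_kind: object = "continuous"
    seed: int = 0

    def set_names(self):
        n_sets = self.n_genes // self.set_size
        return [f"set{j:03d}" for j in range(n_sets)]


def synth_generate(spec: SynthSpec):
    """Draw (ExpressionMatrix, Phenotype, sets) from the spec.

    Returns raw (uncentered) data; run :func:`momentgsa.center_scale` on the
    result as one would on real data.  All randomness flows from
    ``spec.seed``.
    """
    if not 0.0 <= spec.rho_block < 1.0:
        raise ValueError("rho_block must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    names = spec.set_names()
    unknown = set(spec.signal_sets) - set(names)
    if unknown:
        raise ValueError(f"signal_sets reference unknown sets: {sorted(unknown)}")

    kind = spec.phenotype_kind
    if kind == "continuous":
        y = rng.standard_normal(n)
    else:
        tag, n1, n2 = kind
        if tag != "binary" or n1 + n2 != n:
            raise ValueError("phenotype_kind must be 'continuous' or "
                             "('binary', n1, n2) with n1 + n2 = n_samples")
        y = rng.permutation(np.r_[np.zeros(n1), np.ones(n2)])

    X = rng.standard_normal((g, n))
    gene_ids = tuple(f"g{i:04d}" for i in range(g))
    sample_ids = tuple(f"s{i:02d}" for i in range(n))
    sets = []
    y_std = (y - y.mean()) / y.std()
    for j, name in enumerate(names):
        idx = np.arange(j * spec.set_size, (j + 1) * spec.set_size)
        if spec.rho_block > 0:
            shared = rng.standard_normal(n)
            X[idx] = (np.sqrt(1 - spec.rho_block) * X[idx]
                      + np.sqrt(spec.rho_block) * shared)
        if name in spec.signal_sets and spec.effect_size:
            X[idx] += spec.effect_size * y_std
        sets.append(GeneSet(name, tuple(gene_ids[i] for i in idx)))

    return (ExpressionMatrix(gene_ids, sample_ids, X),
            Phenotype(y), sets)
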