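# Methods

## Model and procedure

`momentgsa` tests the self-contained null hypothesis that a phenotype
vector Y is jointly independent of the expression profiles of the genes in
a set G.  The reference distribution is the permutation distribution of a
linear statistic T̃ = Σ_g w_g β̃_g or a quadratic statistic
C̃ = Σ_g w_g β̃_g², where β̃_g is the per-gene sample covariance recomputed
under a uniformly random relabeling Ỹ of the phenotype.  Rather than
sampling that distribution, the package evaluates its exact low-order
moments in closed form and fits a continuous reference:

* T̂ against N(0, var T̃), or against a scaled beta supported on the exact
  permutation range [A, B] and matching mean 0 and var T̃;
* Ĉ against σ²χ²₍ᵥ₎ matching E(C̃) and var(C̃) (a gamma distribution with
  possibly fractional degrees of freedom).

The moment formulas are exact finite-sample identities, not asymptotics.
Their inputs are the data moments μ₂ = (1/n)ΣY², μ₄ = (1/n)ΣY⁴, the gene
cross-moments X̄_gh = (1/n)Σᵢ X_gi X_hi, fourth cross-moments such as
X̄_gghh, and an n-dependent 5×2 matrix A mapping (μ₂², μ₄) to the five
distinct-index fourth moments of Ỹ (four of a kind, three of a kind, two
pair, one pair, none), combined with a constant 5×2 coefficient matrix B
through the 2×2 product AᵀB.  The identities require complete data and
centered inputs; they hold for any Y (binary, ordinal, continuous).

Assumptions worth stating plainly: preprocessing of X must not depend on Y
(and vice versa), gene sets are fixed in advance, and p-values are exact
only to the extent that the fitted two- or four-parameter family captures
the shape of the true permutation distribution (see Limitations).

## Parameters

* `scale_genes` (default on): scale each gene row to Σᵢ X²_gi = n, making
  β̂_g a correlation and the p-values invariant to the scaling of Y.
  Disable when low-signal probes should not be inflated to unit variance.
* `rank_transform` (default off): replace each gene's values by
  centered/scaled average ranks; an outlier-robust option.
* `weights w_g` (default 1 per gene): direction/importance weights.  For
  the quadratic statistic weights must be nonnegative and are absorbed as
  √w_g X_gi.  For the linear statistic the default 1 and the alternative
  1/|G| give identical p-values (the statistic and its null scale
  together), so the simpler convention is used.
* `epsilon_adjust` (default: on for the beta reference only): maps a
  bounded p-value onto [ε, 1−ε] via p̃ = ε + (1−2ε)p, with ε the data
  granularity ∏ₖ nₖ!/n!.  The normal and χ² references are unbounded and
  never return 0, so no adjustment is applied to them.
* Permutation-count planning: `min_k_for_power(ε, fraction, power)`
  returns the smallest k with Pr(Bin(k/ε − 1, fraction·ε) ≤ k−1) ≥ power
  by exact binomial summation, switching to the Poisson limit only beyond
  exact-integer range (M > 10¹⁵), where the two agree to double precision.
* A warning is emitted when the number of distinct phenotype arrangements
  is below 100,000: there, exhaustive enumeration is feasible and a smooth
  moment approximation to so discrete a distribution is questionable.

## Reference-distribution choices

A scaled-t reference for T̂ is deliberately not offered.  The diagnostic
E(T̃⁴) − 3 var(T̃)² is negative for most standardized fixtures (the
permutation distribution has lighter tails than the normal), and t
distributions can only add tail weight.  The beta support [A, B] is the
exact min/max of T̃ over permutations (rearrangement inequality: co-sort
and anti-sort X_G against Y), which guarantees the observed T̂ lies inside
the support — a four-moment Pearson fit cannot guarantee that.  The fit is
valid whenever var T̃ < −A·B, which the Bhatia–Davis inequality ensures
except in degenerate two-point cases; those raise a specific error, and in
batch runs degenerate sets (e.g. a zero pseudo-gene) report p = 1 with a
flag instead of aborting.

## Numerical choices

* var(C̃) is assembled as (μ₂², μ₄) AᵀB ((S₁+2S₃)/n², S₂/n³)ᵀ − μ₂²S₁/(n−1)²
  with S₁ = (Σ_g X̄_gg)², S₂ = (1/n)Σᵢ(Σ_g X²_gi)², S₃ = Σ_gh X̄²_gh.  The
  normalization was fixed against the exhaustive-enumeration oracle (all n!
  permutations at n ≤ 8), which the test suite re-runs; the two plausible
  stackings of the aggregation sums differ by a factor of n and only this
  one matches enumeration.
* S₃ is computed through the p×p Gram matrix when p ≤ n (O(np²)) and
  through the n×n sample Gram matrix otherwise (O(n²p)); the two routes
  are the same algebraic quantity evaluated in different orders.
* Round-off can make var(C̃) marginally negative for near-degenerate
  inputs; values above −10⁻¹⁰·max(E C̃, 1)² are clipped to zero, anything
  more negative raises.
* Tail probabilities go through `scipy.stats` (`norm`, `beta`, and the
  gamma upper tail for σ²χ²₍ᵥ₎ so fractional ν is exact).
* Granularity is computed in exact rational arithmetic
  (`fractions.Fraction`); distinct-arrangement counts beyond float range
  are reported in log₁₀ space.
* Exhaustive enumeration refuses n > 8 (40,320 permutations is the
  desk-scale cap).  Exact ties in Y (floating equality) define the tie
  groups for granularity.
* Uniform random rotations are generated by QR decomposition of a Gaussian
  matrix with the sign of the R diagonal folded back into Q, which yields
  exact Haar measure; every stochastic routine takes an explicit seed.

## Rotation oracle: what matches and what cannot

Mean-preserving rotation resampling (Ỹ = [(1/n)11ᵀ + WQ*Wᵀ]Y with a
contrast matrix W and Haar-uniform Q*) shares E(β̃_g), E(β̃_g β̃_h) — hence
E(T̃), var(T̃) and E(C̃) — with the permutation distribution, and the suite
verifies this by Monte Carlo.  Two further facts shape the tests: because
Haar measure is conjugation-invariant and any two valid contrast matrices
differ by an orthogonal factor, *all* rotation moments, including var(C̃),
are independent of the choice of W; and var(C̃) under rotation genuinely
differs from the permutation var(C̃) for n ≥ 4 (at n = 3 the two coincide
exactly, since the six permutations are equally spaced on the contrast
circle and C̃ has only even harmonics there).  This is why the quadratic
reference is fitted to permutation moments, and why rotation serves only
as a cross-checking oracle here.

## Synthetic data

`synth_generate` emulates a small standardized expression study: Gaussian
gene profiles (default 200 genes × 20 samples, sets of 10), optional
within-set correlation through a shared latent factor, a binary or
continuous phenotype, and an optional phenotype-linked mean shift δ in
designated signal sets.  Defaults put the study right at the regime the
method targets — n = 20 continuous (or 10+10 binary) labels, where
distinct permutations are plentiful but individual permutation runs are
costly.  It does not emulate heavy-tailed intensities, outliers,
batch effects, or realistic gene–gene correlation structure beyond the
block factor; passing tests therefore demonstrate correctness of the
moment machinery and calibration under clean conditions, not robustness to
real-data artifacts (for outliers, the rank transform is the intended
mitigation).

## Known limitations

* The p-value is only as good as the fitted family.  On the synthetic null
  at n = 20 the suite's own measurements show rank agreement with
  M = 49,999-permutation p-values of Spearman ρ > 0.999 for all three
  references, and per-set agreement typically within 0.005; but the worst
  of 200 sets deviates by up to ~0.01–0.03 in the moderate p range
  (skewness/kurtosis that two- or four-parameter fits cannot absorb).  The
  corresponding acceptance test pins the per-set band at 0.01 and
  documents the exceedance rather than widening the band.
* Two-sided type-I error at α = 0.05, n = 20, measured over 20,000 null
  replicates, is ≈ 0.046 (normal) and ≈ 0.048 (χ²) — slightly conservative,
  consistent with the light-tailed permutation distribution.
* Moments are exact, tails are not: far-tail beta p-values can be several
  fold smaller than the (granular) permutation bound can confirm; treat
  extreme p-values as ranking devices and spot-check with a moderate
  permutation run (`--permutations`) when they matter.
* Sampling permutations without replacement, generalized-extreme-value
  tail fits, competitive (gene-randomizing) nulls, and full rotation-based
  p-value production are out of scope.
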