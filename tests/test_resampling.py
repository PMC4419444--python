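import itertools
import math

import numpy as np
import pytest
from numpy.testing import assert_allclose

from momentgsa import (contrast_matrix, exhaustive_draws, exhaustive_moments,
                       haar_rotations, linear_moments, perm_pvalues,
                       permutation_draws, quad_moments,
                       random_rotation_draws)
from momentgsa.resampling import ResampleDraws

from conftest import centered_rows, centered_y


class TestPermPvalues:
    def test_plus_one_convention(self):
        draws = ResampleDraws("permutation", "linear",
                              np.linspace(-1, 0, 99), 99, 0)
        pv = perm_pvalues(draws, 0.5)   # no draw >= observed
        assert pv.p_right == pytest.approx(1.0 / 100)
        assert pv.p_left == pytest.approx(1.0)

    def test_all_draws_more_extreme(self):
        draws = ResampleDraws("permutation", "quadratic",
                              np.full(49, 10.0), 49, 0)
        assert perm_pvalues(draws, 1.0).p_q == pytest.approx(1.0)

    def test_empty_draws(self):
        with pytest.raises(ValueError):
            perm_pvalues(ResampleDraws("permutation", "linear",
                                       np.array([]), 0, 0), 0.0)

    def test_uniform_over_exhaustive_relabelings(self, rng):
        # continuous data: every relabeling is an equally likely "observed"
        # statistic, and its p against the remaining n!-1 draws is uniform
        x, y = centered_rows(rng, 1, 5)[0], centered_y(rng, 5)
        all_draws = exhaustive_draws(x, y, "linear").draws
        M = all_draws.size - 1
        ps = []
        for i, obs in enumerate(all_draws):
            others = np.delete(all_draws, i)
            ps.append(perm_pvalues(
                ResampleDraws("permutation", "linear", others, M, 0),
                obs).p_left)
        assert_allclose(np.sort(ps), np.arange(1, M + 2) / (M + 1),
                        atol=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        rows = centered_rows(rng, 2, 6)
        y = centered_y(rng, 6)
        qm = quad_moments(rows, y)
        p_ex = perm_pvalues(exhaustive_draws(rows, y, "quadratic"),
                            qm.C_hat).p_q
        M = 20000
        p_mc = perm_pvalues(permutation_draws(rows, y, M, seed=7,
                                              statistic="quadratic"),
                            qm.C_hat).p_q
        assert abs(p_mc - p_ex) < 3 * np.sqrt(p_ex * (1 - p_ex) / M)


class TestExhaustive:
    def test_mean_T_is_zero(self, rng):
        x, y = centered_rows(rng, 1, 4)[0], centered_y(rng, 4)
        assert abs(exhaustive_moments(x, y)["E_T"]) < 1e-14

    def test_refuses_large_n(self, rng):
        with pytest.raises(ValueError, match="n <= 8"):
            exhaustive_draws(centered_rows(rng, 1, 9)[0], centered_y(rng, 9))

    def test_enumeration_is_the_moment_arbiter(self, rng):
        rows = centered_rows(rng, 3, 6)
        y = centered_y(rng, 6)
        em = exhaustive_moments(rows, y)
        qm = quad_moments(rows, y)
        lm = linear_moments(rows.sum(0), y)
        assert_allclose(em["var_C"], qm.var_C, atol=1e-10)
        assert_allclose(em["var_T"], lm.var_T, atol=1e-10)

    def test_tied_values_distinct_arrangements_match_full(self):
        rows = np.array([[0.3, -1.2, 0.5, 0.4]])
        rows -= rows.mean(1, keepdims=True)
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        full = exhaustive_draws(rows, y, "linear").draws
        distinct = {tuple(p) for p in itertools.permutations(y)}
        dd = np.array([np.array(p) @ rows[0] / 4 for p in distinct])
        assert len(distinct) == 6  # C(4,2) arrangements
        assert_allclose(sorted(set(np.round(full, 12))),
                        sorted(set(np.round(dd, 12))))
        assert_allclose(full.mean(), dd.mean(), atol=1e-12)
        assert_allclose(full.var(), dd.var(), atol=1e-12)


class TestContrastMatrix:
    def test_printed_n3_matrix_is_valid(self):
        W = np.array([[1 / np.sqrt(2), 1 / np.sqrt(6)],
                      [-1 / np.sqrt(2), 1 / np.sqrt(6)],
                      [0.0, -2 / np.sqrt(6)]])
        assert_allclose(W.T @ W, np.eye(2), atol=1e-10)
        assert_allclose(W.T @ np.ones(3), 0.0, atol=1e-10)
        # our generator reproduces it (up to column signs)
        assert_allclose(np.abs(contrast_matrix(3)), np.abs(W), atol=1e-12)

    def test_quartic_coefficients_of_printed_matrix(self):
        # coefficient of Y_i^4 in sum_k (W^T Y)_k^4 is sum_k W_ik^4;
        # cross-checked against numeric polynomial evaluation at unit vectors
        W = contrast_matrix(3)
        coefs = (W ** 4).sum(axis=1)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            assert_allclose(((W.T @ e) ** 4).sum(), coefs[i], atol=1e-14)
        assert_allclose(coefs, [5 / 18, 5 / 18, 4 / 9], atol=1e-12)

    def test_generated_matrices_satisfy_constraints(self):
        for n in (2, 5, 10):
            W = contrast_matrix(n)
            assert W.shape == (n, n - 1)
            assert np.abs(W.T @ W - np.eye(n - 1)).max() < 1e-10
            assert np.abs(W.T @ np.ones(n)).max() < 1e-10


class TestRotation:
    def test_rotated_phenotype_preserves_mean_and_scale(self, rng):
        rows = centered_rows(rng, 2, 6)
        y = centered_y(rng, 6)
        W = contrast_matrix(6)
        Q = haar_rotations(5, 100, rng)
        yt = y.mean() + (Q @ (W.T @ y)) @ W.T
        assert np.abs(yt.sum(axis=1)).max() < 1e-10
        assert np.abs((yt ** 2).sum(axis=1) - (y ** 2).sum()).max() < 1e-10

    def test_first_and_second_moments_match_permutation(self, rng):
        n, M = 8, 60000
        rows = centered_rows(rng, 2, n)
        y = centered_y(rng, n)
        rot = random_rotation_draws(rows, y, M, seed=11)
        mu2 = (y ** 2).mean()
        xbar = rows @ rows.T / n
        for g, h in [(0, 0), (0, 1)]:
            target = mu2 * xbar[g, h] / (n - 1)
            prod = rot.betas[:, g] * rot.betas[:, h]
            se = prod.std() / np.sqrt(M)
            assert abs(prod.mean() - target) < 4 * se
        se0 = rot.betas[:, 0].std() / np.sqrt(M)
        assert abs(rot.betas[:, 0].mean()) < 4 * se0

    def test_haar_second_and_fourth_moments(self, rng):
        n, M = 6, 60000
        Q = haar_rotations(n, M, rng)
        checks = [
            (Q[:, 0, 0] ** 2, 1 / n),
            (Q[:, 0, 0] ** 4, 3 / (n * (n + 2))),
            (Q[:, 0, 0] ** 2 * Q[:, 1, 0] ** 2, 1 / (n * (n + 2))),
            (Q[:, 0, 0] ** 2 * Q[:, 1, 1] ** 2,
             (n + 1) / (n * (n - 1) * (n + 2))),
        ]
        for sample, target in checks:
            assert abs(sample.mean() - target) < 4 * sample.std() / np.sqrt(M)

    def test_quadratic_rotation_variance_w_invariant_and_off_permutation(
            self, rng):
        # Haar measure is conjugation-invariant, so the rotated phenotype's
        # distribution — hence every rotation moment — is the same for any
        # valid contrast matrix W.  At n=3 the rotation group is the circle
        # and var(C~) integrates deterministically over the angle; it also
        # happens to coincide with the permutation variance there (the six
        # permutations are equally spaced on the contrast circle and C~ has
        # only even harmonics).  For n >= 4 rotation var(C~) departs from
        # the permutation value while the lower moments still match.
        rows = centered_rows(rng, 2, 3)
        y = np.array([2.0, -0.5, -1.5])
        W1 = contrast_matrix(3)
        W2 = W1[[2, 0, 1]]           # row-permuted: still a valid contrast
        theta = np.linspace(0, 2 * np.pi, 8001)[:-1]

        def rot_moments(W):
            cos, sin = np.cos(theta), np.sin(theta)
            Qs = np.stack([np.stack([cos, -sin], -1),
                           np.stack([sin, cos], -1)], -2)
            C, T = [], []
            for Qg in (Qs, Qs @ np.diag([1.0, -1.0])):
                yt = (Qg @ (W.T @ y)) @ W.T
                beta = yt @ rows.T / 3
                C.append((beta ** 2).sum(-1))
                T.append(beta.sum(-1))
            return np.concatenate(C).var(), np.concatenate(T).var()

        (vc1, vt1), (vc2, vt2) = rot_moments(W1), rot_moments(W2)
        assert_allclose(vc1, vc2, rtol=1e-6)
        assert_allclose(vt1, vt2, rtol=1e-6)
        mu2 = (y ** 2).mean()
        assert_allclose(vt1, mu2 * (rows.sum(0) ** 2).mean() / 2, rtol=1e-6)

        # n = 4: rotation var(C~) is measurably off the permutation value
        n, M = 4, 200_000
        rows4 = centered_rows(rng, 2, n)
        y4 = centered_y(rng, n)
        perm_draws = exhaustive_draws(rows4, y4, "quadratic").draws
        rot = random_rotation_draws(rows4, y4, M, seed=21)
        se2 = (rot.C ** 2).std() / np.sqrt(M)
        assert abs((rot.C ** 2).mean() - (perm_draws ** 2).mean()) > 4 * se2
        se1 = rot.C.std() / np.sqrt(M)
        assert abs(rot.C.mean() - perm_draws.mean()) < 4 * se1

    def test_reproducible_given_seed(self, rng):
        rows = centered_rows(rng, 2, 5)
        y = centered_y(rng, 5)
        a = random_rotation_draws(rows, y, 50, seed=3)
        b = random_rotation_draws(rows, y, 50, seed=3)
        assert_allclose(a.T, b.T)
        c = permutation_draws(rows.sum(0), y, 50, seed=3)
        d = permutation_draws(rows.sum(0), y, 50, seed=3)
        assert_allclose(c.draws, d.draws)
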