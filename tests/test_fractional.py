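import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln, gammasgn

import aftvlrr as a
from aftvlrr.fractional import AFTVParams, FracDiffOperator, aftv_smoothed_energy


def gl_weights_gamma(beta, K):
    """Independent weight oracle via log-Gamma with explicit sign handling
    (Gamma(beta+1-k) alternates sign once its argument goes negative)."""
    k = np.arange(K)
    logc = gammaln(beta + 1) - gammaln(k + 1) - gammaln(beta + 1 - k)
    sign = gammasgn(beta + 1 - k)  # other Gamma factors are positive
    return (-1.0) ** k * sign * np.exp(logc)


def gl_diff_loops(H, w, boundary):
    """Direct loop evaluation of the GL sum along rows (independent oracle)."""
    N, M = H.shape
    out = np.zeros_like(H)
    for i in range(N):
        for j in range(M):
            for k, wk in enumerate(w):
                idx = i - k
                if idx < 0:
                    if boundary == "zero":
                        continue
                    idx = 0
                out[i, j] += wk * H[idx, j]
    return out


def materialised_matrix(op, N):
    """Dense operator matrix built in-test from unit-vector responses."""
    D = np.zeros((N, N))
    for j in range(N):
        e = np.zeros((N, 1))
        e[j] = 1.0
        D[:, j] = gl_diff_loops(e, op.weights, op.boundary).ravel()
    return D


class TestGLCoefficients:
    def test_w0_is_one_for_any_beta(self):
        for beta in (0.3, 1.0, 1.3, 1.9):
            assert a.gl_coefficients(beta, 1)[0] == 1.0

    def test_integer_beta_binomial(self):
        np.testing.assert_array_equal(a.gl_coefficients(1.0, 3), [1.0, -1.0, 0.0])
        np.testing.assert_array_equal(a.gl_coefficients(2.0, 4), [1.0, -2.0, 1.0, 0.0])

    def test_beta_1_5_derived_values(self):
        # Gamma(2.5)/(Gamma(3) Gamma(0.5)) = 0.375
        np.testing.assert_allclose(
            a.gl_coefficients(1.5, 3), [1.0, -1.5, 0.375], atol=1e-12
        )

    @pytest.mark.parametrize("beta", [0.5, 1.3, 1.7])
    def test_matches_gamma_oracle(self, beta):
        np.testing.assert_allclose(
            a.gl_coefficients(beta, 8), gl_weights_gamma(beta, 8), atol=1e-12
        )

    @pytest.mark.parametrize("beta", [0.5, 1.0, 1.3, 1.9])
    def test_partial_sums_shrink_toward_zero(self, beta):
        # sum_k w_k = 0 in the limit; truncated sums decay monotonically
        sums = [abs(a.gl_coefficients(beta, K).sum()) for K in (2, 4, 8, 16, 32)]
        assert all(s2 <= s1 + 1e-15 for s1, s2 in zip(sums, sums[1:]))
        assert sums[-1] < sums[0] or beta in (1.0, 2.0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            a.gl_coefficients(0.0, 3)
        with pytest.raises(ValueError):
            a.gl_coefficients(1.3, 0)


class TestFracDiff:
    def test_backward_difference_row_example(self):
        op = FracDiffOperator(beta=1.0, K=2)
        H = np.array([[1.0, 4.0, 6.0]]).T  # column grid [a, b, c]
        out = a.frac_diff(H, op, "rows")
        np.testing.assert_allclose(out.ravel(), [0.0, 3.0, 2.0])

    def test_order_one_annihilates_constants(self):
        op = FracDiffOperator(beta=1.0, K=5)
        H = np.full((6, 4), 3.7)
        np.testing.assert_allclose(a.frac_diff(H, op, "rows"), 0.0, atol=1e-14)
        np.testing.assert_allclose(a.frac_diff(H, op, "cols"), 0.0, atol=1e-14)

    def test_fractional_truncation_keeps_constants(self):
        # weights [1, -1.5, 0.375] sum to -0.125 on a constant grid
        op = FracDiffOperator(beta=1.5, K=3)
        H = np.ones((5, 5))
        np.testing.assert_allclose(a.frac_diff(H, op, "rows"), -0.125, atol=1e-14)

    @pytest.mark.parametrize("beta", [1.0, 1.3, 1.7])
    @pytest.mark.parametrize("boundary", ["replicate", "zero"])
    def test_matches_loop_oracle(self, beta, boundary, rng):
        op = FracDiffOperator(beta=beta, K=4, boundary=boundary)
        H = rng.standard_normal((7, 5))
        np.testing.assert_allclose(
            a.frac_diff(H, op, "rows"), gl_diff_loops(H, op.weights, boundary),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            a.frac_diff(H, op, "cols"), gl_diff_loops(H.T, op.weights, boundary).T,
            atol=1e-12,
        )

    def test_beta1_equals_numpy_backward_diff_interior(self, rng):
        op = FracDiffOperator(beta=1.0, K=2)
        for _ in range(20):
            H = rng.standard_normal((10, 8))
            out = a.frac_diff(H, op, "rows")
            np.testing.assert_allclose(out[1:], np.diff(H, axis=0), atol=1e-14)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, s, t):
        rng = np.random.default_rng(7)
        op = FracDiffOperator()
        U, V = rng.standard_normal((2, 6, 6))
        lhs = a.frac_diff(s * U + t * V, op, "rows")
        rhs = s * a.frac_diff(U, op, "rows") + t * a.frac_diff(V, op, "rows")
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestFracAdjoint:
    def test_1x1_grid_identity(self):
        op = FracDiffOperator(beta=1.3, K=3, boundary="zero")
        P = np.array([[2.5, 1.0]])
        np.testing.assert_allclose(a.frac_adjoint(P, op, "rows"), P)

    @pytest.mark.parametrize("beta", [1.0, 1.3, 1.7])
    @pytest.mark.parametrize("boundary", ["replicate", "zero"])
    def test_adjoint_identity(self, beta, boundary, rng):
        op = FracDiffOperator(beta=beta, K=3, boundary=boundary)
        U = rng.standard_normal((16, 16))
        P = rng.standard_normal((16, 16))
        for axis in ("rows", "cols"):
            lhs = np.sum(a.frac_diff(U, op, axis) * P)
            rhs = np.sum(U * a.frac_adjoint(P, op, axis))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    @pytest.mark.parametrize("boundary", ["replicate", "zero"])
    def test_adjoint_equals_transposed_matrix(self, boundary, rng):
        op = FracDiffOperator(beta=1.0, K=2, boundary=boundary)
        D = materialised_matrix(op, 9)
        np.testing.assert_allclose(
            a.frac_operator_matrix(op, 9), D, atol=1e-14
        )
        P = rng.standard_normal((9, 3))
        np.testing.assert_allclose(a.frac_adjoint(P, op, "rows"), D.T @ P, atol=1e-12)

    def test_adjoint_matrix_fractional(self, rng):
        op = FracDiffOperator(beta=1.7, K=4, boundary="replicate")
        D = materialised_matrix(op, 8)
        P = rng.standard_normal((8, 8))
        np.testing.assert_allclose(a.frac_adjoint(P, op, "rows"), D.T @ P, atol=1e-12)
        np.testing.assert_allclose(a.frac_adjoint(P, op, "cols"), P @ D, atol=1e-12)


class TestAFTVEnergy:
    def test_zero_matrix(self):
        assert a.aftv_energy(np.zeros((4, 4)), FracDiffOperator()) == 0.0

    def test_step_column_example(self):
        # rows constant, column step contributes |1| twice
        op = FracDiffOperator(beta=1.0, K=2)
        H = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert a.aftv_energy(H, op) == pytest.approx(2.0)

    @given(st.floats(-5, 5))
    def test_one_homogeneity(self, c):
        rng = np.random.default_rng(3)
        H = rng.standard_normal((6, 6))
        op = FracDiffOperator()
        assert a.aftv_energy(c * H, op) == pytest.approx(
            abs(c) * a.aftv_energy(H, op), rel=1e-9, abs=1e-9
        )


class TestAdaptiveExponent:
    def test_flat_region_clamps_to_two(self):
        field = a.adaptive_exponent(np.ones((8, 8)), kappa=1.0, delta=1e-3)
        np.testing.assert_allclose(field.L, 2 - 1e-3)

    def test_g_equals_kappa_gives_1_5(self):
        # linear ramp has constant gradient 1; kappa = 1 maps it to l = 1.5
        H = np.tile(np.arange(8.0)[:, None], (1, 8))
        field = a.adaptive_exponent(H, kappa=1.0, sigma=0.0)
        interior = field.L[2:-2, 2:-2]
        np.testing.assert_allclose(interior, 1.5, atol=1e-12)

    def test_monotone_decreasing_in_gradient(self, rng):
        H = rng.standard_normal((12, 12)).cumsum(axis=0)
        field = a.adaptive_exponent(H, kappa=0.5, sigma=0.0, delta=1e-3)
        gr, gc = np.gradient(H)
        g = np.sqrt(gr**2 + gc**2)
        order = np.argsort(g.ravel())
        l_sorted = field.L.ravel()[order]
        assert np.all(np.diff(l_sorted) <= 1e-12)

    def test_range_invariant(self, rng):
        for _ in range(5):
            H = rng.standard_normal((10, 10)) * rng.uniform(0.1, 50)
            field = a.adaptive_exponent(H)
            assert np.all(field.L > 1.0) and np.all(field.L < 2.0)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            a.adaptive_exponent(np.ones((3, 3)), kappa=-1.0)
        with pytest.raises(ValueError):
            a.adaptive_exponent(np.ones((3, 3)), delta=0.7)


class TestAFTVGradient:
    def test_constant_grid_zero_gradient(self):
        params = AFTVParams(operator=FracDiffOperator(beta=1.0, K=3))
        G = a.aftv_gradient(np.full((8, 8), 2.0), params)
        np.testing.assert_allclose(G, 0.0, atol=1e-12)

    @pytest.mark.parametrize("beta", [1.0, 1.3])
    def test_finite_difference_check(self, beta, rng):
        """Analytic gradient vs central differences of the smoothed energy."""
        H = rng.standard_normal((16, 16))
        op = FracDiffOperator(beta=beta, K=3)
        L = np.clip(1.2 + 0.6 * rng.random((16, 16)), 1.001, 1.999)
        eps = 1e-3
        params = AFTVParams(
            operator=op,
            exponent=a.AdaptiveExponentField(L=L, kappa=1.0, sigma=0.0, delta=1e-3),
            eps=eps,
        )
        G = a.aftv_gradient(H, params)
        V = rng.standard_normal((16, 16))
        h = 1e-6
        e_plus = aftv_smoothed_energy(H + h * V, op, L, eps)
        e_minus = aftv_smoothed_energy(H - h * V, op, L, eps)
        fd = (e_plus - e_minus) / (2 * h)
        analytic = float(np.sum(G * V))
        assert analytic == pytest.approx(fd, rel=1e-4)

    def test_gradient_step_reduces_energy(self, rng):
        H = rng.standard_normal((16, 16))
        op = FracDiffOperator(beta=1.3, K=3)
        L = np.ones((16, 16)) + 1e-3  # l ~ 1: TV-like regime
        params = AFTVParams(
            operator=op,
            exponent=a.AdaptiveExponentField(L=L, kappa=1.0, sigma=0.0, delta=1e-3),
            eps=1e-3,
        )
        G = a.aftv_gradient(H, params)
        before = aftv_smoothed_energy(H, op, L, params.eps)
        after = aftv_smoothed_energy(H - 0.01 * G, op, L, params.eps)
        assert after < before
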