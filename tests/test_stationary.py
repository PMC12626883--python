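import numpy as np
import pytest

from msinfo import (
    FAST_PROCESSING,
    NO_PROCESSING,
    SLOW_PROCESSING,
    CouplingSpec,
    F_quadrature,
    F_series,
    build_factorization,
    conditional_mean,
    effective_mean_int,
    effective_mean_ns,
    realize_system,
    sample_intra_matrix,
    solve_lyapunov,
)
from msinfo.dynamics import phi
from msinfo.stationary import lyapunov_residual


class TestLyapunov:
    def test_identity(self):
        assert solve_lyapunov(np.eye(3), np.eye(3)) == pytest.approx(np.eye(3))

    def test_diagonal(self):
        a = np.array([2.0, 5.0, 0.5])
        S = solve_lyapunov(np.diag(a), np.eye(3))
        assert S == pytest.approx(np.diag(1 / a))

    def test_random_residual(self, rng):
        A = sample_intra_matrix(5, 0.8, 17)
        D = np.diag(rng.uniform(0.5, 2.0, 5))
        S = solve_lyapunov(A, D)
        assert lyapunov_residual(A, D, S) < 1e-10 * np.abs(D).max()
        assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_unstable_rejected(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            solve_lyapunov(np.diag([1.0, -0.2]), np.eye(2))


class TestFFunction:
    def test_odd_in_x(self):
        xs = np.linspace(0.1, 5, 20)
        for v in (1e-3, 0.5, 4.0):
            assert F_series(-xs, v) == pytest.approx(-np.asarray(F_series(xs, v)))
        assert F_series(0.0, 3.0) == 0.0

    def test_zero_variance_limit_is_tanh(self):
        xs = np.array([-3.0, -0.5, 0.2, 3.0])
        assert F_series(xs, 0.0) == pytest.approx(np.tanh(xs))
        assert F_series(3.0, 1e-13) == pytest.approx(np.tanh(3.0), abs=1e-10)
        assert F_quadrature(xs, 0.0) == pytest.approx(np.tanh(xs))

    def test_series_equals_quadrature_on_grid(self):
        xs = np.linspace(-5, 5, 41)
        for v in (1e-4, 0.01, 0.1, 1.0, 5.0, 10.0):
            s = np.asarray(F_series(xs, v))
            q = np.asarray(F_quadrature(xs, v))
            assert np.max(np.abs(s - q)) < 1e-8

    def test_known_value_gaussian_average(self):
        # E[tanh(z)], z ~ N(1, 1): quadrature oracle frozen value
        assert F_series(1.0, 1.0) == pytest.approx(0.5504004907933, abs=1e-10)

    def test_quadrature_against_monte_carlo(self):
        rng = np.random.default_rng(12)
        mc = np.tanh(rng.normal(2.0, 2.0, 1_000_000)).mean()
        se = np.tanh(rng.normal(2.0, 2.0, 1000)).std() / 1000
        assert F_quadrature(2.0, 4.0) == pytest.approx(mc, abs=3e-3)

    def test_bounded_and_monotone_in_x(self):
        xs = np.linspace(-5, 5, 41)
        for v in (1e-4, 0.01, 0.1, 1.0, 10.0):
            vals = np.asarray(F_series(xs, v))
            assert np.all(np.abs(vals) < 1.0)
            assert np.all(np.diff(vals) > 0)

    def test_variance_damps_magnitude(self):
        vs = np.array([1e-4, 0.01, 0.1, 1.0, 5.0, 10.0])
        for x in (0.5, 2.0, 4.0):
            vals = np.abs(np.asarray(F_series(np.full(vs.shape, x), vs)))
            assert np.all(np.diff(vals) < 0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            F_series(1.0, -0.5)
        with pytest.raises(ValueError):
            F_quadrature(1.0, -0.5)

    def test_insufficient_term_budget_raises(self):
        # a hard point cannot meet tol with only a handful of terms
        with pytest.raises(RuntimeError, match="n_max"):
            F_series(0.5, 0.5, tol=1e-12, n_max=4)

    def test_large_v_no_overflow(self):
        # naive erfc evaluation overflows here; the erfcx rewrite must not
        val = F_series(1.0, 50.0)
        assert abs(val - F_quadrature(1.0, 50.0)) < 1e-8


class TestConditionalMean:
    def test_zero_coupling(self, rng):
        c = CouplingSpec("I", "O", 0.0, rng.normal(size=(2, 3)))
        assert conditional_mean(c, np.eye(2), rng.normal(size=3)) == pytest.approx(
            np.zeros(2)
        )

    @pytest.mark.parametrize("scheme", ["summation", "integration"])
    def test_scalar_chain_gives_g_tanh(self, scheme):
        c = CouplingSpec("I", "O", 2.5, np.array([[1.0]]), scheme=scheme)
        x = np.array([0.9])
        assert conditional_mean(c, np.array([[1.0]]), x) == pytest.approx(
            2.5 * np.tanh(0.9)
        )

    def test_matches_formula(self, rng):
        A_t = sample_intra_matrix(3, 0.5, 3)
        c = CouplingSpec("P", "O", 1.7, rng.normal(size=(3, 4)), scheme="integration")
        x = rng.normal(size=4)
        expected = 1.7 * np.linalg.inv(A_t) @ phi(c, x)
        assert conditional_mean(c, A_t, x) == pytest.approx(expected)

    def test_singular_target_rejected(self, rng):
        c = CouplingSpec("P", "O", 1.0, rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="singular"):
            conditional_mean(c, np.zeros((2, 2)), rng.normal(size=2))


class TestEffectiveMeans:
    """The effective means must equal the defining Gaussian average of phi."""

    def _instance(self, rng, M_P=3, M_O=1):
        A_O = sample_intra_matrix(M_O, 0.3, 5)
        A_OP = rng.normal(size=(M_O, M_P))
        m_PI = rng.normal(size=M_P)
        L = rng.normal(size=(M_P, M_P)) * 0.5
        Sigma_P = L @ L.T + 0.1 * np.eye(M_P)
        return A_O, A_OP, m_PI, Sigma_P

    def test_zero_coupling(self, rng):
        A_O, A_OP, m_PI, Sigma_P = self._instance(rng)
        for f in (effective_mean_ns, effective_mean_int):
            assert f(0.0, A_O, A_OP, m_PI, Sigma_P) == pytest.approx(np.zeros(1))

    @pytest.mark.parametrize("eff,scheme", [
        (effective_mean_ns, "summation"), (effective_mean_int, "integration"),
    ])
    def test_vanishing_fluctuations_reduce_to_conditional_mean(self, rng, eff, scheme):
        A_O, A_OP, m_PI, Sigma_P = self._instance(rng)
        c = CouplingSpec("P", "O", 1.3, A_OP, scheme=scheme)
        got = eff(1.3, A_O, A_OP, m_PI, 1e-16 * np.eye(3))
        assert got == pytest.approx(conditional_mean(c, A_O, m_PI), abs=1e-9)

    @pytest.mark.parametrize("eff,scheme", [
        (effective_mean_ns, "summation"), (effective_mean_int, "integration"),
    ])
    def test_matches_monte_carlo_average_of_phi(self, rng, eff, scheme):
        # the defining average: E_{x_P ~ N(m, Sigma_P)} [g A_O^{-1} phi(x_P)]
        A_O, A_OP, m_PI, Sigma_P = self._instance(rng)
        g = 2.0
        got = eff(g, A_O, A_OP, m_PI, Sigma_P)
        c = CouplingSpec("P", "O", g, A_OP, scheme=scheme)
        n = 400_000
        xs = rng.multivariate_normal(m_PI, Sigma_P, size=n)
        draws = conditional_mean(c, A_O, xs)
        mc = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(got - mc) < 3.5 * se)

    def test_sparse_counts_change_normalization(self, rng):
        A_O, A_OP, m_PI, Sigma_P = self._instance(rng)
        dense = effective_mean_ns(1.0, A_O, A_OP, m_PI, Sigma_P)
        halved = effective_mean_ns(1.0, A_O, A_OP, m_PI, Sigma_P,
                                   counts=np.array([6]))
        assert abs(halved[0]) < abs(dense[0])


class TestFactorization:
    def test_fast_zero_op_coupling_gives_centered_output(self, small_template):
        tpl = small_template.with_(g_OP=0.0)
        sys_ = realize_system(tpl, FAST_PROCESSING, 3)
        factors = build_factorization(sys_, FAST_PROCESSING)
        f_O = [f for f in factors if f.target == "O"][0]
        x_I = np.random.default_rng(0).normal(size=(10, 8))
        assert f_O.mean_map(x_I) == pytest.approx(np.zeros((10, 1)))
        S = solve_lyapunov(sys_.units["O"].A, sys_.units["O"].D)
        assert f_O.Sigma == pytest.approx(S)

    def test_slow_chain_is_markov(self, small_template):
        sys_ = realize_system(small_template, SLOW_PROCESSING, 3)
        factors = build_factorization(sys_, SLOW_PROCESSING)
        f_O = [f for f in factors if f.target == "O"][0]
        assert f_O.conditioning == "P"

    def test_input_factor_identical_across_regimes(self, small_template):
        sigmas = []
        for regime in (NO_PROCESSING, FAST_PROCESSING, SLOW_PROCESSING):
            sys_ = realize_system(small_template, regime, 99)
            f_I = build_factorization(sys_, regime)[0]
            sigmas.append(f_I.Sigma)
        # same seed -> same input matrix draw -> same Lyapunov covariance
        assert sigmas[0] == pytest.approx(sigmas[1])
        assert sigmas[1] == pytest.approx(sigmas[2])

    def test_factor_covariances_obey_lyapunov(self, small_fast_system):
        factors = build_factorization(small_fast_system, FAST_PROCESSING)
        for f in factors:
            u = small_fast_system.units[f.target]
            assert lyapunov_residual(u.A, u.D, f.Sigma) < 1e-10
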