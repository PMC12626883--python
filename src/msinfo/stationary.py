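"""Exact stationary factorizations of the multiscale Langevin system.

In the limits of well-separated timescales the stationary joint density
factorizes into conditional Gaussians whose covariances solve Lyapunov
equations, A Sigma + Sigma A^T = 2 D, and whose means carry all the
nonlinearity. Averaging the fast processing unit's Gaussian fluctuations
produces the effective output mean, expressed through the Gaussian-
smoothed hyperbolic tangent

    F(x, v) = E[tanh(z)],  z ~ N(x, v),

which has a closed series form in erf/erfc terms (``F_series``) and an
independent quadrature evaluation (``F_quadrature``) used to cross-check
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_continuous_lyapunov
from scipy.special import erf, erfcx, roots_hermite

from .dynamics import phi
from .ensembles import check_stability
from .units import (
    FAST_PROCESSING,
    NO_PROCESSING,
    SLOW_PROCESSING,
    CouplingSpec,
    SystemSpec,
)

__all__ = [
    "ConditionalGaussianFactor",
    "EffectiveMoments",
    "solve_lyapunov",
    "conditional_mean",
    "F_series",
    "F_quadrature",
    "effective_mean_ns",
    "effective_mean_int",
    "build_factorization",
]

#: below this variance the smoothing is numerically invisible: F(x, v) = tanh(x)
V_TINY = 1e-12


def solve_lyapunov(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Unique symmetric positive-definite solution of A S + S A^T = 2 D.

    Raises if A is unstable (the stationary covariance would not exist).
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    stable, margin = check_stability(A)
    if not stable:
        raise ValueError(
            f"A is not stable: min Re(eigenvalue) = {margin:g} <= 0; "
            "no stationary covariance exists"
        )
    S = solve_continuous_lyapunov(A, 2.0 * D)
    S = 0.5 * (S + S.T)
    resid = np.max(np.abs(A @ S + S @ A.T - 2.0 * D))
    scale = max(np.max(np.abs(D)), 1e-300)
    if resid > 1e-8 * scale:
        raise RuntimeError(f"Lyapunov residual {resid:g} unexpectedly large")
    return S


def lyapunov_residual(A: np.ndarray, D: np.ndarray, S: np.ndarray) -> float:
    """Max-abs entry of A S + S A^T - 2 D (diagnostic)."""
    return float(np.max(np.abs(A @ S + S @ A.T - 2.0 * D)))


def conditional_mean(
    coupling: CouplingSpec, A_target: np.ndarray, x_source: np.ndarray
) -> np.ndarray:
    """Stationary conditional mean m = g A_target^{-1} phi(x_source).

    Vectorized over leading axes of ``x_source``.
    """
    A_target = np.asarray(A_target, dtype=float)
    if A_target.shape[0] != A_target.shape[1]:
        raise ValueError("A_target must be square")
    p = phi(coupling, x_source)
    try:
        out = np.linalg.solve(A_target, p[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise ValueError("A_target is singular") from exc
    return coupling.g * out


# ---------------------------------------------------------------------------
# The Gaussian-smoothed tanh F(x, v)
# ---------------------------------------------------------------------------

def _series_terms(x: np.ndarray, v: np.ndarray, N: int) -> np.ndarray:
    """Stabilized series terms b_n, n = 1..N, stacked on the last axis.

    The raw terms are e^{2 n^2 v} [V_n^+ - V_n^-] with
    V_n^{+-} = e^{-+2nx} erfc((2nv -+ x)/sqrt(2v)); multiplying through,
    each product equals e^{-x^2/(2v)} erfcx(t) when the erfc argument t is
    nonnegative, and 2 e^{2n(nv -+ x)} - e^{-x^2/(2v)} erfcx(-t) otherwise
    (both exact algebraic rewrites; the surviving exponents are always
    nonpositive, so nothing overflows).
    """
    x = x[..., None]
    v = v[..., None]
    n = np.arange(1.0, N + 1.0)
    s2v = np.sqrt(2.0 * v)
    tm = (2.0 * n * v - x) / s2v
    tp = (2.0 * n * v + x) / s2v
    pref = np.exp(-(x**2) / (2.0 * v))
    em = np.exp(np.minimum(2.0 * n * (n * v - x), 0.0))
    ep = np.exp(np.minimum(2.0 * n * (n * v + x), 0.0))
    plus = np.where(tm >= 0, pref * erfcx(np.abs(tm)), 2.0 * em - pref * erfcx(np.abs(tm)))
    minus = np.where(tp >= 0, pref * erfcx(np.abs(tp)), 2.0 * ep - pref * erfcx(np.abs(tp)))
    return plus - minus


def _cvz_alternating_sum(a: np.ndarray) -> np.ndarray:
    """Cohen-Rodriguez Villegas-Zagier acceleration of sum_k (-1)^k a_k.

    ``a`` holds the terms on its last axis; the estimate converges like
    (3 + sqrt(8))^{-N} for totally monotone terms, which the erfcx
    differences here are to excellent approximation.
    """
    N = a.shape[-1]
    d = (3.0 + np.sqrt(8.0)) ** N
    d = (d + 1.0 / d) / 2.0
    b = -1.0
    c = -d
    s = np.zeros(a.shape[:-1])
    for k in range(N):
        c = b - c
        s = s + c * a[..., k]
        b = (k + N) * (k - N) * b / ((k + 0.5) * (k + 1.0))
    return s / d


def F_series(x, v, tol: float = 1e-12, n_max: int = 200) -> np.ndarray | float:
    """Series evaluation of F(x, v) = E[tanh(N(x, v))].

    Elements whose leading term already meets the alternating-series
    remainder bound keep the plain erf value; the rest are summed with
    CVZ acceleration over min(24, n_max) stabilized terms. The result lies
    strictly inside (-1, 1); at v = 0 the analytic limit tanh(x) is
    returned.
    """
    x_in, v_in = np.broadcast_arrays(np.asarray(x, float), np.asarray(v, float))
    if np.any(v_in < 0):
        raise ValueError("v must be nonnegative")
    scalar = x_in.ndim == 0
    x_a = np.atleast_1d(x_in).astype(float)
    v_a = np.atleast_1d(v_in).astype(float)
    out = np.empty_like(x_a)

    tiny = v_a <= V_TINY
    out[tiny] = np.tanh(x_a[tiny])

    live = ~tiny
    if np.any(live):
        xl, vl = x_a[live], v_a[live]
        res = erf(xl / np.sqrt(2.0 * vl))
        b1 = _series_terms(xl, vl, 1)[..., 0]
        hard = np.abs(b1) >= tol
        if np.any(hard):
            N = min(24, max(int(n_max), 1))
            if N < 8:
                raise RuntimeError(
                    f"series not converged within n_max={n_max} terms; "
                    f"largest remainder bound {np.max(np.abs(b1)):g} > tol={tol:g}"
                )
            terms = _series_terms(xl[hard], vl[hard], N)
            # sum_{n>=1} (-1)^n b_n = - sum_{k>=0} (-1)^k b_{k+1}
            res[hard] = res[hard] - _cvz_alternating_sum(terms)
        out[live] = res
    return float(out[0]) if scalar else out.reshape(x_in.shape)


_GH_NODES, _GH_WEIGHTS = roots_hermite(301)


def _F_quad_large_v(x: float, v: float) -> float:
    # erf term + adaptive quadrature of the exponentially small correction
    # tanh(z) - sign(z); segments split at the Gaussian peak and at z = 0.
    s = np.sqrt(v)
    u0 = -x / s  # z = 0 in standardized coordinates

    def f_corr(u: float) -> float:
        z = x + s * u
        return (np.tanh(z) - np.sign(z)) * np.exp(-u * u / 2.0) / np.sqrt(2.0 * np.pi)

    pts = sorted([u0, 0.0])
    total = 0.0
    for a, b in [(-np.inf, pts[0]), (pts[0], pts[1]), (pts[1], np.inf)]:
        val, _ = quad(f_corr, a, b, epsabs=1e-13, epsrel=1e-12, limit=300)
        total += val
    return float(erf(x / np.sqrt(2.0 * v)) + total)


def F_quadrature(x, v) -> np.ndarray | float:
    """Quadrature evaluation of F(x, v); the independent oracle for F_series.

    Uses 301-node Gauss-Hermite for v <= 2; for larger v (where the tanh
    poles at +-i pi/2 defeat polynomial quadrature) the bounded correction
    to the erf term is integrated adaptively. Absolute accuracy <= 1e-10
    for v <= 50.
    """
    x_in, v_in = np.broadcast_arrays(np.asarray(x, float), np.asarray(v, float))
    if np.any(v_in < 0):
        raise ValueError("v must be nonnegative")
    scalar = x_in.ndim == 0
    x_a = np.atleast_1d(x_in).astype(float).ravel()
    v_a = np.atleast_1d(v_in).astype(float).ravel()
    out = np.empty_like(x_a)

    tiny = v_a <= V_TINY
    out[tiny] = np.tanh(x_a[tiny])
    gh = (~tiny) & (v_a <= 2.0)
    if np.any(gh):
        z = x_a[gh, None] + np.sqrt(2.0 * v_a[gh, None]) * _GH_NODES
        out[gh] = (np.tanh(z) @ _GH_WEIGHTS) / np.sqrt(np.pi)
    big = (~tiny) & (v_a > 2.0)
    for i in np.nonzero(big)[0]:
        out[i] = _F_quad_large_v(x_a[i], v_a[i])
    return float(out[0]) if scalar else out.reshape(x_in.shape)


# ---------------------------------------------------------------------------
# Effective output means after averaging a fast processing unit
# ---------------------------------------------------------------------------

def _F_eval(x: np.ndarray, v: np.ndarray, activation: str) -> np.ndarray:
    if activation == "linear":
        return np.asarray(x, float)  # Gaussian average of the identity
    return np.asarray(F_series(x, v))


def _norm_factors(counts: np.ndarray | None, M_source: int, M_target: int) -> np.ndarray:
    if counts is None:
        return np.full(M_target, float(M_source))
    counts = np.asarray(counts, dtype=float).reshape(-1)
    return counts


def effective_mean_ns(
    g: float,
    A_O: np.ndarray,
    A_OP: np.ndarray,
    m_PI: np.ndarray,
    Sigma_P: np.ndarray,
    counts: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    activation: str = "tanh",
) -> np.ndarray:
    """Effective output mean, nonlinear-summation scheme.

    Componentwise F over the processing means and the *diagonal* of
    Sigma_P, weighted by A_OP rows (normalized by the connection counts)
    and mapped through g A_O^{-1}. Vectorized over leading axes of m_PI.
    """
    A_O = np.asarray(A_O, float)
    A_OP = np.atleast_2d(np.asarray(A_OP, float))
    m_PI = np.asarray(m_PI, float)
    M_O, M_P = A_OP.shape
    C = _norm_factors(counts, M_P, M_O)
    safe = np.where(C > 0, C, 1.0)
    arg = m_PI if theta is None else m_PI - np.asarray(theta, float)
    Fv = _F_eval(arg, np.diag(Sigma_P), activation)
    s = (Fv @ A_OP.T) / safe
    s = np.where(C > 0, s, 0.0)
    try:
        out = np.linalg.solve(A_O, s[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise ValueError("A_O is singular") from exc
    return g * out


def effective_moments(
    A_OP: np.ndarray,
    m_PI: np.ndarray,
    Sigma_P: np.ndarray,
    counts: np.ndarray | None = None,
    theta: np.ndarray | None = None,
) -> "EffectiveMoments":
    """Integrated mean and variance seen by each output dof.

    m_int = (1/C) A_OP (m_PI - theta); v_int = (1/C^2) diag(A_OP Sigma_P
    A_OP^T) — the full quadratic form, not just the diagonal of Sigma_P.
    """
    A_OP = np.atleast_2d(np.asarray(A_OP, float))
    M_O, M_P = A_OP.shape
    C = _norm_factors(counts, M_P, M_O)
    safe = np.where(C > 0, C, 1.0)
    arg = m_PI if theta is None else m_PI - np.asarray(theta, float)
    m_int = (arg @ A_OP.T) / safe
    m_int = np.where(C > 0, m_int, 0.0)
    v_int = np.einsum("ij,jk,ik->i", A_OP, Sigma_P, A_OP) / safe**2
    if np.any(v_int < -1e-10 * max(np.max(np.abs(Sigma_P)), 1e-300)):
        raise RuntimeError(
            "negative integrated variance beyond round-off; Sigma_P is not PSD"
        )
    v_int = np.where(C > 0, np.maximum(v_int, 0.0), 0.0)
    return EffectiveMoments(m_int=m_int, v_int=v_int)


def effective_mean_int(
    g: float,
    A_O: np.ndarray,
    A_OP: np.ndarray,
    m_PI: np.ndarray,
    Sigma_P: np.ndarray,
    counts: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    activation: str = "tanh",
) -> np.ndarray:
    """Effective output mean, nonlinear-integration scheme.

    F is evaluated once per output dof on the integrated moments, then
    mapped through g A_O^{-1}. Vectorized over leading axes of m_PI.
    """
    A_O = np.asarray(A_O, float)
    mom = effective_moments(A_OP, np.asarray(m_PI, float), Sigma_P, counts, theta)
    Fv = _F_eval(mom.m_int, mom.v_int, activation)
    try:
        out = np.linalg.solve(A_O, Fv[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise ValueError("A_O is singular") from exc
    return g * out


@dataclass
class EffectiveMoments:
    m_int: np.ndarray
    v_int: np.ndarray


# ---------------------------------------------------------------------------
# Factor chains
# ---------------------------------------------------------------------------

@dataclass
class ConditionalGaussianFactor:
    """One Gaussian factor of the stationary chain.

    ``mean_map`` maps the conditioning variable (vectorized over leading
    axes) to the factor's mean; for the input factor it ignores its
    argument and returns zero.
    """

    target: str
    conditioning: str | None
    Sigma: np.ndarray
    mean_map: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, float)
        self._chol = np.linalg.cholesky(self.Sigma)

    @property
    def chol(self) -> np.ndarray:
        return self._chol


def _zero_mean_map(M: int):
    def mean(x_cond: np.ndarray | None = None) -> np.ndarray:
        if x_cond is None:
            return np.zeros(M)
        x_cond = np.asarray(x_cond)
        return np.zeros(x_cond.shape[:-1] + (M,))

    return mean


def build_factorization(system: SystemSpec, regime: str) -> list[ConditionalGaussianFactor]:
    """Assemble the regime-appropriate chain of conditional Gaussian factors.

    - no processing:   p(x_I) p(x_O | x_I)
    - fast processing: p(x_I) p(x_P | x_I) p(x_O | x_I)  [effective mean]
    - slow processing: p(x_I) p(x_P | x_I) p(x_O | x_P)  [Markov chain]
    """
    Sigma = {
        lb: solve_lyapunov(system.units[lb].A, system.units[lb].D)
        for lb in system.labels
    }
    factors = [
        ConditionalGaussianFactor("I", None, Sigma["I"], _zero_mean_map(system.units["I"].M))
    ]

    if regime == NO_PROCESSING:
        c_OI = system.coupling("O", "I")
        A_O = system.units["O"].A
        factors.append(
            ConditionalGaussianFactor(
                "O", "I", Sigma["O"], lambda x_I, c=c_OI, A=A_O: conditional_mean(c, A, x_I)
            )
        )
        return factors

    if not system.has_processing():
        raise ValueError(f"regime {regime!r} requires a processing unit")
    c_PI = system.coupling("P", "I")
    c_OP = system.coupling("O", "P")
    A_P = system.units["P"].A
    A_O = system.units["O"].A
    factors.append(
        ConditionalGaussianFactor(
            "P", "I", Sigma["P"], lambda x_I, c=c_PI, A=A_P: conditional_mean(c, A, x_I)
        )
    )

    if regime == SLOW_PROCESSING:
        factors.append(
            ConditionalGaussianFactor(
                "O", "P", Sigma["O"], lambda x_P, c=c_OP, A=A_O: conditional_mean(c, A, x_P)
            )
        )
        return factors

    if regime == FAST_PROCESSING:
        eff = effective_mean_ns if c_OP.scheme == "summation" else effective_mean_int
        Sigma_P = Sigma["P"]

        def mean_O_given_I(x_I, c_PI=c_PI, c_OP=c_OP, A_P=A_P, A_O=A_O, Sigma_P=Sigma_P):
            m_PI = conditional_mean(c_PI, A_P, x_I)
            return eff(
                c_OP.g, A_O, c_OP.A_inter, m_PI, Sigma_P,
                counts=c_OP.norm_counts, theta=c_OP.theta, activation=c_OP.activation,
            )

        factors.append(ConditionalGaussianFactor("O", "I", Sigma["O"], mean_O_given_I))
        return factors

    raise ValueError(f"unknown regime {regime!r}")
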