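"""Exact sampling from the stationary factor chains.

Because every factor is Gaussian with a nonlinear *mean*, sampling is a
sequence of affine transforms of standard normals: draw the input from
N(0, Sigma_I), push each conditioning value through the mean map, add
correlated Gaussian noise from the cached Cholesky factor. The slow
regime keeps the nested (input x inner) structure needed to estimate the
conditional entropy per input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stationary import ConditionalGaussianFactor, build_factorization
from .units import FAST_PROCESSING, NO_PROCESSING, SLOW_PROCESSING, SystemSpec


@dataclass
class SampleBatch:
    """Stationary samples with regime metadata.

    For the slow regime ``x_O`` has shape (N_I, N_inner, M_O) and ``x_I``
    (N_I, M_I); otherwise both are flat (N, M). ``Sigma_O`` is the output
    factor's covariance (the conditional covariance, independent of the
    conditioning value).
    """

    regime: str
    x_I: np.ndarray
    x_O: np.ndarray
    Sigma_O: np.ndarray
    seed: int | None = None
    x_P: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arr in (self.x_I, self.x_O):
            if not np.all(np.isfinite(arr)):
                raise ValueError("sample batch contains non-finite values")

    @property
    def pooled_output(self) -> np.ndarray:
        """All output samples flattened to (N_total, M_O)."""
        return self.x_O.reshape(-1, self.x_O.shape[-1])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _factor(factors: list[ConditionalGaussianFactor], target: str) -> ConditionalGaussianFactor:
    for f in factors:
        if f.target == target:
            return f
    raise KeyError(f"no factor for unit {target}")


def _gaussian_draw(rng, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
    z = rng.standard_normal(mean.shape)
    return mean + z @ chol.T


def sample_no_processing(
    system: SystemSpec,
    N: int,
    seed,
    factors: list[ConditionalGaussianFactor] | None = None,
) -> SampleBatch:
    """Joint stationary samples of a direct input-output system."""
    if factors is None:
        factors = build_factorization(system, NO_PROCESSING)
    rng = _rng(seed)
    f_I = _factor(factors, "I")
    f_O = _factor(factors, "O")
    x_I = _gaussian_draw(rng, np.zeros((N, f_I.Sigma.shape[0])), f_I.chol)
    x_O = _gaussian_draw(rng, f_O.mean_map(x_I), f_O.chol)
    return SampleBatch(
        regime=NO_PROCESSING, x_I=x_I, x_O=x_O, Sigma_O=f_O.Sigma,
        meta={"N": N},
    )


def sample_fast_processing(
    system: SystemSpec,
    N: int,
    seed,
    factors: list[ConditionalGaussianFactor] | None = None,
    keep_processing: bool = False,
) -> SampleBatch:
    """Stationary samples with a fast processing unit.

    Follows the effective-mean recipe: draw x_I from the input Gaussian,
    evaluate the effective output mean m_O|I(x_I), draw x_O around it with
    covariance Sigma_O. Optionally also draws diagnostic processing
    samples from p(x_P | x_I).
    """
    if factors is None:
        factors = build_factorization(system, FAST_PROCESSING)
    rng = _rng(seed)
    f_I = _factor(factors, "I")
    f_O = _factor(factors, "O")
    if f_O.conditioning != "I":
        raise ValueError("factor chain is not a fast-processing chain")
    x_I = _gaussian_draw(rng, np.zeros((N, f_I.Sigma.shape[0])), f_I.chol)
    x_O = _gaussian_draw(rng, f_O.mean_map(x_I), f_O.chol)
    x_P = None
    if keep_processing:
        f_P = _factor(factors, "P")
        x_P = _gaussian_draw(rng, f_P.mean_map(x_I), f_P.chol)
    return SampleBatch(
        regime=FAST_PROCESSING, x_I=x_I, x_O=x_O, Sigma_O=f_O.Sigma, x_P=x_P,
        meta={"N": N},
    )


def sample_slow_processing(
    system: SystemSpec,
    N_I: int = 2000,
    N_inner: int = 2000,
    seed=None,
    factors: list[ConditionalGaussianFactor] | None = None,
    keep_processing: bool = False,
    chunk: int = 64,
) -> SampleBatch:
    """Nested stationary samples with a slow processing unit.

    For each of ``N_I`` input draws, ``N_inner`` processing draws from
    p(x_P | x_I) and one output draw per processing draw from p(x_O | x_P);
    the (N_I, N_inner) nesting is preserved so per-input conditional
    entropies can be estimated. Processing samples are discarded chunk by
    chunk unless ``keep_processing`` (memory grows with N_I*N_inner*M_P).
    """
    if factors is None:
        factors = build_factorization(system, SLOW_PROCESSING)
    rng = _rng(seed)
    f_I = _factor(factors, "I")
    f_P = _factor(factors, "P")
    f_O = _factor(factors, "O")
    if f_O.conditioning != "P":
        raise ValueError("factor chain is not a slow-processing chain")
    M_I = f_I.Sigma.shape[0]
    M_P = f_P.Sigma.shape[0]
    M_O = f_O.Sigma.shape[0]
    x_I = _gaussian_draw(rng, np.zeros((N_I, M_I)), f_I.chol)
    m_PI = f_P.mean_map(x_I)  # (N_I, M_P)
    x_O = np.empty((N_I, N_inner, M_O))
    kept_P = np.empty((N_I, N_inner, M_P)) if keep_processing else None
    for start in range(0, N_I, chunk):
        sl = slice(start, min(start + chunk, N_I))
        n_c = sl.stop - sl.start
        zP = rng.standard_normal((n_c, N_inner, M_P))
        x_P = m_PI[sl, None, :] + zP @ f_P.chol.T
        x_O[sl] = _gaussian_draw(rng, f_O.mean_map(x_P), f_O.chol)
        if keep_processing:
            kept_P[sl] = x_P
    return SampleBatch(
        regime=SLOW_PROCESSING, x_I=x_I, x_O=x_O, Sigma_O=f_O.Sigma, x_P=kept_P,
        meta={"N_I": N_I, "N_inner": N_inner},
    )
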