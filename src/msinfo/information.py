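"""Entropy, mutual information, and bimodality estimators.

Mutual information between input and output is I = H_O - <h_O|I>. In the
no-processing and fast-processing regimes the conditional entropy is the
closed-form Gaussian value; only the output entropy H_O needs a numerical
estimator. In the slow regime the conditional density is itself a mixture,
so per-input conditional entropies are estimated from the nested samples
and averaged. The default 1-D differential entropy estimator is
Kozachenko-Leonenko k-nearest-neighbor (k = 4); a plug-in histogram
estimator (Freedman-Diaconis bins) is kept as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .sampling import (
    SampleBatch,
    sample_fast_processing,
    sample_no_processing,
    sample_slow_processing,
)
from .stationary import build_factorization
from .systems import SystemTemplate, realize_system
from .units import FAST_PROCESSING, NO_PROCESSING, SLOW_PROCESSING

LOG2E = 1.0 / math.log(2.0)


@dataclass
class MIEstimate:
    """Mutual information in bits with estimator metadata.

    ``h_or_H_cond`` is the conditional term: the closed-form Gaussian
    h_O|I in the no-processing/fast regimes, the Monte-Carlo H_O|I in the
    slow regime. ``value = H_O - h_or_H_cond`` exactly.
    """

    value: float
    H_O: float
    h_or_H_cond: float
    estimator: str
    n_samples: int
    se: float = float("nan")


@dataclass
class BimodalityReport:
    """Sarle's bimodality coefficient b = (s^2 + 1)/(kappa + q(n))."""

    b: float
    s: float
    kappa: float
    n: int


# ---------------------------------------------------------------------------
# 1-D differential entropy
# ---------------------------------------------------------------------------

def _knn_log_eps(x: np.ndarray, k: int = 4) -> np.ndarray:
    """log of k-th nearest-neighbour distances per point, per row of (R, N).

    In one dimension the k-th nearest neighbour of a point in a sorted
    sample sits at the edge of one of the k+1 windows of k neighbours
    around it, so the search vectorizes into O(N k) window comparisons.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    R, N = x.shape
    if N <= k:
        raise ValueError(f"need more than k={k} samples, got {N}")
    xs = np.sort(x, axis=1)
    pad = np.full((R, k), np.inf)
    xp = np.concatenate([-pad, xs, pad], axis=1)  # index i -> xp[:, i+k]
    idx = np.arange(N)
    eps = np.full((R, N), np.inf)
    for a in range(k + 1):
        right = xp[:, idx + k + a] - xs
        left = xs - xp[:, idx + a]
        eps = np.minimum(eps, np.maximum(right, left))
    eps = np.maximum(eps, np.finfo(float).tiny)
    return np.log(eps)


def _knn_entropy_rows(x: np.ndarray, k: int = 4) -> np.ndarray:
    """Kozachenko-Leonenko entropy (bits) of each row of a (R, N) array."""
    log_eps = _knn_log_eps(x, k=k)
    N = log_eps.shape[1]
    h_nats = digamma(N) - digamma(k) + np.log(2.0) + np.mean(log_eps, axis=1)
    return h_nats * LOG2E


def _hist_entropy(x: np.ndarray) -> float:
    counts, edges = np.histogram(x, bins="fd")
    width = edges[1] - edges[0]
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum() + np.log2(width))


def entropy_1d(
    samples: np.ndarray, estimator: str = "knn", k: int = 4
) -> float:
    """Differential entropy in bits of a 1-D sample.

    ``estimator='knn'`` is Kozachenko-Leonenko with ``k`` neighbours
    (small negative bias, O(1/N)); ``'histogram'`` is the plug-in estimate
    with Freedman-Diaconis bins (biased down for curved densities).
    A degenerate zero-variance sample returns -inf.
    """
    x = np.asarray(samples, dtype=float).reshape(-1)
    if x.size < 100:
        raise ValueError("need at least 100 samples for a usable entropy estimate")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0.0:
        return float("-inf")
    if estimator == "knn":
        return float(_knn_entropy_rows(x[None, :], k=k)[0])
    if estimator == "histogram":
        return _hist_entropy(x)
    raise ValueError(f"unknown estimator {estimator!r}")


def gaussian_entropy_bits(Sigma: np.ndarray) -> float:
    """Closed-form entropy of N(., Sigma) in bits: (M log2(2 pi e) + log2 det Sigma)/2."""
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    M = Sigma.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be positive definite")
    return 0.5 * (M * math.log2(2.0 * math.pi * math.e) + logdet * LOG2E)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _pooled_1d(batch: SampleBatch) -> np.ndarray:
    out = batch.pooled_output
    if out.shape[1] != 1:
        raise ValueError(
            "numerical entropy estimation is restricted to one-dimensional outputs"
        )
    return out[:, 0]


def mi_direct_or_fast(
    batch: SampleBatch, Sigma_O: np.ndarray | None = None, estimator: str = "knn"
) -> MIEstimate:
    """I = H_O - h_O|I with the conditional term in closed form.

    Valid for the no-processing and fast-processing regimes, where the
    output conditional covariance does not depend on the input.
    """
    if batch.regime not in (NO_PROCESSING, FAST_PROCESSING):
        raise ValueError(f"batch regime {batch.regime!r} has no closed-form conditional entropy")
    if Sigma_O is None:
        Sigma_O = batch.Sigma_O
    x = _pooled_1d(batch)
    H_O = entropy_1d(x, estimator=estimator)
    h = gaussian_entropy_bits(Sigma_O)
    if estimator == "knn":
        # dispersion of the pointwise log-spacing contributions
        terms = _knn_log_eps(x[None, :])[0] * LOG2E
        se = float(np.std(terms, ddof=1) / math.sqrt(x.size))
    else:
        se = float("nan")
    return MIEstimate(
        value=H_O - h, H_O=H_O, h_or_H_cond=h,
        estimator=estimator, n_samples=x.size, se=se,
    )


def mi_slow(batch: SampleBatch, estimator: str = "knn") -> MIEstimate:
    """I = H_O - H_O|I from nested slow-regime samples.

    Per-input conditional entropies are estimated on the inner output
    samples and averaged over inputs; the standard error is the jackknife
    (leave-one-input-out) error of that average.
    """
    if batch.regime != SLOW_PROCESSING:
        raise ValueError("mi_slow requires a slow-processing batch")
    if batch.x_O.ndim != 3:
        raise ValueError("slow-regime batch lost its nesting structure")
    N_I, N_inner, M_O = batch.x_O.shape
    if M_O != 1:
        raise ValueError("numerical entropy estimation is restricted to M_O = 1")
    if N_inner < 100:
        raise ValueError("N_inner < 100: per-input entropy estimates would be too biased")
    if estimator == "knn":
        h_i = _knn_entropy_rows(batch.x_O[:, :, 0], k=4)
    elif estimator == "histogram":
        h_i = np.array([_hist_entropy(row) for row in batch.x_O[:, :, 0]])
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    H_cond = float(np.mean(h_i))
    pooled = _pooled_1d(batch)
    if pooled.size > 200_000:  # entropy estimate saturates well before this
        stride = pooled.size // 200_000 + 1
        pooled = pooled[::stride]
    H_O = entropy_1d(pooled, estimator=estimator)
    se = float(np.std(h_i, ddof=1) / math.sqrt(N_I))
    return MIEstimate(
        value=H_O - H_cond, H_O=H_O, h_or_H_cond=H_cond,
        estimator=estimator, n_samples=N_I * N_inner, se=se,
    )


def mutual_information(
    system,
    regime: str,
    seed,
    N: int = 10_000,
    N_I: int = 2000,
    N_inner: int = 2000,
    estimator: str = "knn",
    factors=None,
) -> MIEstimate:
    """Sample the stationary chain of ``system`` and estimate I_IO."""
    if factors is None:
        factors = build_factorization(system, regime)
    if regime == NO_PROCESSING:
        batch = sample_no_processing(system, N, seed, factors=factors)
        return mi_direct_or_fast(batch, estimator=estimator)
    if regime == FAST_PROCESSING:
        batch = sample_fast_processing(system, N, seed, factors=factors)
        return mi_direct_or_fast(batch, estimator=estimator)
    if regime == SLOW_PROCESSING:
        batch = sample_slow_processing(system, N_I, N_inner, seed, factors=factors)
        return mi_slow(batch, estimator=estimator)
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# Bimodality
# ---------------------------------------------------------------------------

def sarle_b(samples: np.ndarray) -> BimodalityReport:
    """Sarle's bimodality coefficient with 1/n moment estimators.

    b = (s^2 + 1) / (kappa + q(n)), q(n) = 3 (n-1)^2 / ((n-2)(n-3));
    s is the 1/n sample skewness and kappa the 1/n excess kurtosis. A
    Gaussian gives b -> 1/3, a symmetric two-point mixture b -> 1.
    """
    x = np.asarray(samples, dtype=float).reshape(-1)
    n = x.size
    if n <= 3:
        raise ValueError("need more than 3 samples")
    mu = x.mean()
    var = np.mean(x**2) - mu**2
    if var <= 0:
        raise ValueError("zero-variance sample has no bimodality coefficient")
    d = x - mu
    s = float(np.sum(d**3) / n / var**1.5)
    kappa = float(np.sum(d**4) / n / var**2 - 3.0)
    q = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return BimodalityReport(b=(s**2 + 1.0) / (kappa + q), s=s, kappa=kappa, n=n)


# ---------------------------------------------------------------------------
# Ensemble averaging over matrix realizations
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMIResult:
    """Per-realization MI values (bits) with their mean and spread."""

    values: np.ndarray
    mean: float
    sd: float
    b_values: np.ndarray | None = None

    @property
    def sem(self) -> float:
        return float(self.sd / math.sqrt(len(self.values)))


def realization_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based seed fan-out: independent of evaluation order."""
    return np.random.SeedSequence((int(master_seed), int(index)))


def ensemble_mi(
    template: SystemTemplate,
    regime: str,
    n_realizations: int,
    seed: int,
    N: int = 4000,
    N_I: int = 300,
    N_inner: int = 300,
    estimator: str = "knn",
    with_bimodality: bool = False,
) -> EnsembleMIResult:
    """Average I_IO over realizations of the random interaction matrices.

    Each realization redraws every matrix (rejecting unstable intra-unit
    draws) and the sampling noise, from a counter-based seed so results do
    not depend on evaluation order.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    values = np.empty(n_realizations)
    b_vals = np.empty(n_realizations) if with_bimodality else None
    failures = 0
    for r in range(n_realizations):
        rng = np.random.default_rng(realization_seed(seed, r))
        try:
            system = realize_system(template, regime, rng)
        except RuntimeError:
            failures += 1
            values[r] = np.nan
            continue
        factors = build_factorization(system, regime)
        if regime == SLOW_PROCESSING:
            batch = sample_slow_processing(system, N_I, N_inner, rng, factors=factors)
            est = mi_slow(batch, estimator=estimator)
        elif regime == FAST_PROCESSING:
            batch = sample_fast_processing(system, N, rng, factors=factors)
            est = mi_direct_or_fast(batch, estimator=estimator)
        else:
            batch = sample_no_processing(system, N, rng, factors=factors)
            est = mi_direct_or_fast(batch, estimator=estimator)
        values[r] = est.value
        if with_bimodality:
            b_vals[r] = sarle_b(batch.pooled_output[:, 0]).b
    if failures > 0.5 * n_realizations:
        raise RuntimeError(
            f"{failures}/{n_realizations} realizations had no stable matrices; "
            "lower the intra-unit sigma"
        )
    ok = values[np.isfinite(values)]
    return EnsembleMIResult(
        values=values,
        mean=float(np.mean(ok)),
        sd=float(np.std(ok, ddof=1)),
        b_values=b_vals,
    )
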