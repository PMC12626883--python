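"""Random interaction ensembles and stability checks.

Intra-unit matrices have unit diagonal and i.i.d. Gaussian off-diagonal
entries with standard deviation sigma/sqrt(M); by the circular law the
spectrum of the off-diagonal part concentrates in a disk of radius sigma,
so the drift matrix stays stable (all eigenvalues with positive real part)
with overwhelming probability when sigma < 1. Inter-unit matrices have
i.i.d. N(0, sigma^2) entries masked by independent Bernoulli(p_unit)
connections; the per-row connection counts normalize the activations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    """Parameters of the random-matrix ensembles used in every experiment."""

    sigma_intra: float = 0.9
    sigma_inter: float = 1.0
    p_unit: float = 1.0
    intra_topology: str = "dense"  # "dense" or "barabasi_albert"
    ba_attachment: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_unit <= 1.0:
            raise ValueError("p_unit must lie in [0, 1]")
        if self.sigma_intra < 0 or self.sigma_inter < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.intra_topology not in ("dense", "barabasi_albert"):
            raise ValueError(f"unknown intra_topology {self.intra_topology!r}")


class StabilityResult(NamedTuple):
    stable: bool
    margin: float  # min over eigenvalues of Re(lambda)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_intra_matrix(M: int, sigma: float, seed) -> np.ndarray:
    """Dense intra-unit matrix: diagonal exactly 1, off-diagonal N(0, (sigma/sqrt(M))^2)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = _rng(seed)
    A = rng.normal(0.0, sigma / np.sqrt(M), size=(M, M))
    np.fill_diagonal(A, 1.0)
    return A


def sample_inter_matrix(
    M_target: int, M_source: int, sigma: float, p_unit: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-unit weights with Bernoulli(p_unit) connection mask.

    Returns the masked weight matrix and the per-target-row connection
    counts C^i used to normalize the activations.
    """
    if M_target < 1 or M_source < 1:
        raise ValueError("dimensions must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not 0.0 <= p_unit <= 1.0:
        raise ValueError("p_unit must lie in [0, 1]")
    rng = _rng(seed)
    W = rng.normal(0.0, sigma, size=(M_target, M_source))
    if p_unit < 1.0:
        mask = rng.random(size=(M_target, M_source)) < p_unit
        W = np.where(mask, W, 0.0)
        counts = mask.sum(axis=1).astype(int)
    else:
        counts = np.full(M_target, M_source, dtype=int)
    return W, counts


def sample_ba_intra_matrix(M: int, attachment: int, sigma: float, seed) -> np.ndarray:
    """Intra-unit matrix on a Barabasi-Albert graph with Gaussian weights.

    The undirected BA adjacency fixes which off-diagonal entries may be
    nonzero; each directed entry (i,j) on a present edge draws its weight
    independently from N(0, (sigma/sqrt(M))^2). Diagonal entries are 1.
    """
    import networkx as nx

    if M < 1:
        raise ValueError("M must be >= 1")
    if attachment >= M or attachment < 1:
        raise ValueError("attachment must satisfy 1 <= attachment < M")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = _rng(seed)
    graph_seed = int(rng.integers(0, 2**31 - 1))
    G = nx.barabasi_albert_graph(M, attachment, seed=graph_seed)
    A = np.zeros((M, M))
    scale = sigma / np.sqrt(M)
    for i, j in G.edges:
        A[i, j] = rng.normal(0.0, scale) if scale > 0 else 0.0
        A[j, i] = rng.normal(0.0, scale) if scale > 0 else 0.0
    np.fill_diagonal(A, 1.0)
    return A


def check_stability(A: np.ndarray) -> StabilityResult:
    """Whether the drift -A x is linearly stable, and the stability margin.

    Returns ``(min Re(eig(A)) > 0, min Re(eig(A)))``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    margin = float(np.min(np.real(np.linalg.eigvals(A))))
    return StabilityResult(margin > 0.0, margin)


def stable_intra_matrix(
    M: int,
    sigma: float,
    seed,
    max_tries: int = 100,
    topology: str = "dense",
    attachment: int = 2,
) -> np.ndarray:
    """Draw an intra-unit matrix, rejecting unstable draws.

    Unstable draws (rare for sigma < 1) are resampled from the advanced
    generator state; each rejection is logged.
    """
    rng = _rng(seed)
    for attempt in range(max_tries):
        if topology == "dense":
            A = sample_intra_matrix(M, sigma, rng)
        elif topology == "barabasi_albert":
            A = sample_ba_intra_matrix(M, attachment, sigma, rng)
        else:
            raise ValueError(f"unknown topology {topology!r}")
        res = check_stability(A)
        if res.stable:
            return A
        logger.info(
            "rejected unstable intra-unit draw (M=%d, sigma=%g, attempt=%d, margin=%g)",
            M, sigma, attempt, res.margin,
        )
    raise RuntimeError(
        f"no stable intra-unit matrix in {max_tries} draws (M={M}, sigma={sigma}); "
        "consider lowering sigma"
    )
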