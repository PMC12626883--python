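"""Core data types for multiscale input-processing-output systems.

A system is a set of stochastic *units* (input ``I``, processing ``P``,
output ``O``), each a group of degrees of freedom sharing one timescale
tau and linearly coupled inside the unit, connected by directed nonlinear
couplings (nonlinear summation or integration of the source activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

UNIT_LABELS = ("I", "P", "O")

Scheme = Literal["summation", "integration"]
Activation = Literal["tanh", "linear"]

#: timescale regimes; each fixes the ordering of the unit timescales
NO_PROCESSING = "no_processing"
FAST_PROCESSING = "fast_processing"
SLOW_PROCESSING = "slow_processing"
REGIMES = (NO_PROCESSING, FAST_PROCESSING, SLOW_PROCESSING)


@dataclass
class UnitSpec:
    """One unit: dimension M, timescale tau, intra-unit coupling A, diffusion D.

    The drift of the unit is ``-A x`` (plus incoming couplings), so linear
    stability requires every eigenvalue of ``A`` to have positive real part.
    ``D`` is the diagonal diffusion matrix; the default is the identity.
    """

    label: str
    M: int
    tau: float
    A: np.ndarray
    D: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in UNIT_LABELS:
            raise ValueError(f"unit label must be one of {UNIT_LABELS}, got {self.label!r}")
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.M, self.M):
            raise ValueError(f"A must be {self.M}x{self.M}, got {self.A.shape}")
        if self.D is None:
            self.D = np.eye(self.M)
        else:
            self.D = np.asarray(self.D, dtype=float)
            if self.D.shape != (self.M, self.M):
                raise ValueError(f"D must be {self.M}x{self.M}")
            if np.any(self.D != np.diag(np.diag(self.D))):
                raise ValueError("D must be diagonal")
            if np.any(np.diag(self.D) <= 0):
                raise ValueError("D must have strictly positive diagonal entries")


@dataclass
class CouplingSpec:
    """Directed inter-unit link with strength g and activation scheme.

    ``A_inter`` holds the weights A^{ij} from source dof j to target dof i.
    ``norm_counts[i]`` is the number of connections feeding target dof i
    (C^i); in the dense case it equals the source dimension, and rows with
    zero connections contribute a vanishing activation. ``theta`` is the
    per-source-dof processing bias; ``activation='linear'`` replaces tanh by
    the identity (a test stub that makes the whole chain Gaussian).
    """

    source: str
    target: str
    g: float
    A_inter: np.ndarray
    scheme: Scheme = "summation"
    theta: np.ndarray | None = None
    norm_counts: np.ndarray | None = None
    activation: Activation = "tanh"

    def __post_init__(self) -> None:
        self.A_inter = np.atleast_2d(np.asarray(self.A_inter, dtype=float))
        m_t, m_s = self.A_inter.shape
        if self.scheme not in ("summation", "integration"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.theta is None:
            self.theta = np.zeros(m_s)
        else:
            self.theta = np.asarray(self.theta, dtype=float).reshape(-1)
            if self.theta.shape != (m_s,):
                raise ValueError(f"theta must have length {m_s}")
        if self.norm_counts is None:
            self.norm_counts = np.full(m_t, m_s, dtype=int)
        else:
            self.norm_counts = np.asarray(self.norm_counts, dtype=int).reshape(-1)
            if self.norm_counts.shape != (m_t,):
                raise ValueError(f"norm_counts must have length {m_t}")
            if np.any(self.norm_counts < 0):
                raise ValueError("norm_counts must be nonnegative")

    @property
    def M_target(self) -> int:
        return self.A_inter.shape[0]

    @property
    def M_source(self) -> int:
        return self.A_inter.shape[1]


@dataclass
class SystemSpec:
    """A full architecture: units keyed by label plus directed couplings."""

    units: dict[str, UnitSpec]
    couplings: list[CouplingSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, u in self.units.items():
            if u.label != label:
                raise ValueError(f"unit keyed {label!r} carries label {u.label!r}")
        for c in self.couplings:
            if c.source not in self.units or c.target not in self.units:
                raise ValueError(f"coupling {c.source}->{c.target} references unknown unit")
            if c.A_inter.shape != (self.units[c.target].M, self.units[c.source].M):
                raise ValueError(
                    f"coupling {c.source}->{c.target} has shape {c.A_inter.shape}, "
                    f"expected ({self.units[c.target].M}, {self.units[c.source].M})"
                )
        if "I" in self.units:
            incoming_I = [c for c in self.couplings if c.target == "I"]
            if incoming_I:
                raise ValueError("the input unit evolves independently; it accepts no coupling")

    @property
    def labels(self) -> list[str]:
        return [lb for lb in UNIT_LABELS if lb in self.units]

    def couplings_into(self, target: str) -> list[CouplingSpec]:
        return [c for c in self.couplings if c.target == target]

    def coupling(self, target: str, source: str) -> CouplingSpec:
        for c in self.couplings:
            if c.target == target and c.source == source:
                return c
        raise KeyError(f"no coupling {source}->{target}")

    def has_processing(self) -> bool:
        return "P" in self.units

    def with_activation(self, activation: Activation) -> "SystemSpec":
        """Return a copy with every coupling's activation replaced (test stub)."""
        return SystemSpec(
            units=dict(self.units),
            couplings=[replace(c, activation=activation) for c in self.couplings],
        )
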