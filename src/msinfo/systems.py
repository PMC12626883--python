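"""Templates that realize full systems from the random ensembles.

A :class:`SystemTemplate` collects the scalar parameters of a study
condition (unit sizes, coupling strengths g, heterogeneities sigma,
sparsity, bias); :func:`realize_system` draws the random matrices and
assigns timescales for the requested regime. Timescales follow the
convention that the slowest unit (always the input) has tau = 1 and each
successively faster unit is a factor ``delta_tau`` faster:

- no processing:   tau_I = 1, tau_O = delta_tau
- fast processing: tau_I = 1, tau_O = delta_tau, tau_P = delta_tau**2
- slow processing: tau_I = 1, tau_P = delta_tau, tau_O = delta_tau**2
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensembles import sample_inter_matrix, stable_intra_matrix
from .units import (
    FAST_PROCESSING,
    NO_PROCESSING,
    REGIMES,
    SLOW_PROCESSING,
    CouplingSpec,
    SystemSpec,
    UnitSpec,
)


@dataclass
class SystemTemplate:
    """Study-condition parameters for a (possibly processing-free) system.

    ``M_P = 0`` describes a direct input-output system driven by the
    ``g_OI``/``sigma_OI`` coupling; otherwise the chain is I -> P -> O with
    couplings ``g_PI`` and ``g_OP``. ``theta_std`` > 0 draws a random
    processing bias theta ~ N(0, theta_std^2) per source dof.
    """

    M_I: int = 50
    M_P: int = 50
    M_O: int = 1
    sigma_I: float = 0.9
    sigma_P: float = 0.9
    sigma_O: float = 0.0
    g_PI: float = 1.0
    g_OP: float = 1.0
    g_OI: float = 1.0
    sigma_PI: float = 1.0
    sigma_OP: float = 1.0
    sigma_OI: float = 1.0
    scheme: str = "integration"
    activation: str = "tanh"
    p_unit: float = 1.0
    processing_topology: str = "dense"  # intra-P topology: "dense" | "barabasi_albert"
    ba_attachment: int = 2
    theta_std: float = 0.0
    delta_tau: float = 1e-2

    def with_(self, **kwargs) -> "SystemTemplate":
        return replace(self, **kwargs)


def regime_timescales(regime: str, delta_tau: float) -> dict[str, float]:
    if regime == NO_PROCESSING:
        return {"I": 1.0, "O": delta_tau}
    if regime == FAST_PROCESSING:
        return {"I": 1.0, "O": delta_tau, "P": delta_tau**2}
    if regime == SLOW_PROCESSING:
        return {"I": 1.0, "P": delta_tau, "O": delta_tau**2}
    raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")


def realize_system(template: SystemTemplate, regime: str, seed) -> SystemSpec:
    """Draw all random matrices of a template and wire the system for a regime."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taus = regime_timescales(regime, template.delta_tau)
    with_P = regime != NO_PROCESSING
    if with_P and template.M_P < 1:
        raise ValueError("processing regimes require M_P >= 1")

    units: dict[str, UnitSpec] = {}
    units["I"] = UnitSpec(
        "I", template.M_I, taus["I"],
        stable_intra_matrix(template.M_I, template.sigma_I, rng),
    )
    if with_P:
        units["P"] = UnitSpec(
            "P", template.M_P, taus["P"],
            stable_intra_matrix(
                template.M_P, template.sigma_P, rng,
                topology=template.processing_topology,
                attachment=template.ba_attachment,
            ),
        )
    units["O"] = UnitSpec(
        "O", template.M_O, taus["O"],
        stable_intra_matrix(template.M_O, template.sigma_O, rng),
    )

    def _theta(M_src: int) -> np.ndarray | None:
        if template.theta_std > 0:
            return rng.normal(0.0, template.theta_std, size=M_src)
        return None

    couplings: list[CouplingSpec] = []
    if with_P:
        W_PI, C_PI = sample_inter_matrix(
            template.M_P, template.M_I, template.sigma_PI, template.p_unit, rng
        )
        W_OP, C_OP = sample_inter_matrix(
            template.M_O, template.M_P, template.sigma_OP, template.p_unit, rng
        )
        couplings.append(CouplingSpec(
            "I", "P", template.g_PI, W_PI, scheme=template.scheme,
            theta=_theta(template.M_I), norm_counts=C_PI, activation=template.activation,
        ))
        couplings.append(CouplingSpec(
            "P", "O", template.g_OP, W_OP, scheme=template.scheme,
            theta=_theta(template.M_P), norm_counts=C_OP, activation=template.activation,
        ))
    else:
        W_OI, C_OI = sample_inter_matrix(
            template.M_O, template.M_I, template.sigma_OI, template.p_unit, rng
        )
        couplings.append(CouplingSpec(
            "I", "O", template.g_OI, W_OI, scheme=template.scheme,
            theta=_theta(template.M_I), norm_counts=C_OI, activation=template.activation,
        ))
    return SystemSpec(units=units, couplings=couplings)


def save_system(system: SystemSpec, path) -> None:
    """Persist a realized system: arrays in one .npz, metadata in a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"units": {}, "couplings": []}
    for lb, u in system.units.items():
        arrays[f"A_{lb}"] = u.A
        arrays[f"D_{lb}"] = u.D
        meta["units"][lb] = {"M": u.M, "tau": u.tau}
    for i, c in enumerate(system.couplings):
        arrays[f"W_{i}"] = c.A_inter
        arrays[f"theta_{i}"] = c.theta
        arrays[f"counts_{i}"] = c.norm_counts
        meta["couplings"].append({
            "source": c.source, "target": c.target, "g": c.g,
            "scheme": c.scheme, "activation": c.activation,
        })
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_system(path) -> SystemSpec:
    """Inverse of :func:`save_system`."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    units = {
        lb: UnitSpec(lb, m["M"], m["tau"], arrays[f"A_{lb}"], arrays[f"D_{lb}"])
        for lb, m in meta["units"].items()
    }
    couplings = [
        CouplingSpec(
            m["source"], m["target"], m["g"], arrays[f"W_{i}"],
            scheme=m["scheme"], theta=arrays[f"theta_{i}"],
            norm_counts=arrays[f"counts_{i}"], activation=m["activation"],
        )
        for i, m in enumerate(meta["couplings"])
    ]
    return SystemSpec(units=units, couplings=couplings)


def fig1_template() -> SystemTemplate:
    """The small illustrative system: M_I=5, M_P=3, M_O=1, inter-unit N(0,1),
    intra-unit N(0, 0.9/sqrt(M)), unit coupling strengths, delta_tau=1e-2."""
    return SystemTemplate(
        M_I=5, M_P=3, M_O=1,
        sigma_I=0.9, sigma_P=0.9, sigma_O=0.0,
        sigma_PI=1.0, sigma_OP=1.0,
        g_PI=1.0, g_OP=1.0,
        delta_tau=1e-2,
    )
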