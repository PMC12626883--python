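"""Config-driven parameter sweeps and figure-level experiment drivers.

A sweep evaluates the ensemble-averaged input-output mutual information
(and optionally the output bimodality coefficient) on a grid of template
parameters, for one or more timescale regimes and activation schemes,
writing one tidy row per grid point x realization. The ``reproduce``
driver bundles the named study designs (``fig1`` ... ``fig6a``) at a
caller-chosen scale.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import langevin_stationary_ensemble
from .information import ensemble_mi
from .sampling import sample_fast_processing, sample_slow_processing
from .stationary import build_factorization
from .systems import SystemTemplate, fig1_template, realize_system
from .units import FAST_PROCESSING, NO_PROCESSING, SLOW_PROCESSING

KEY_COLS = ["regime", "scheme", "realization"]


@dataclass
class SweepSpec:
    """A grid of template-parameter axes to evaluate.

    ``grid`` maps template field names (e.g. ``g_OP``, ``sigma_OI``,
    ``M_P``) to the values to scan. Results are deterministic under
    ``master_seed`` and independent of evaluation order.
    """

    template: SystemTemplate
    grid: dict[str, list] = field(default_factory=dict)
    regimes: list[str] = field(default_factory=lambda: [FAST_PROCESSING])
    schemes: list[str] = field(default_factory=lambda: ["summation", "integration"])
    n_realizations: int = 50
    master_seed: int = 0
    N: int = 4000
    N_I: int = 300
    N_inner: int = 300
    with_bimodality: bool = False
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for name in self.grid:
            if not hasattr(self.template, name):
                raise ValueError(f"grid axis {name!r} is not a template parameter")


def _grid_points(grid: dict[str, list]):
    if not grid:
        yield {}
        return
    names = list(grid)
    for combo in itertools.product(*(grid[n] for n in names)):
        yield dict(zip(names, combo))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; returns (and optionally persists) a tidy table.

    One row per grid point x regime x scheme x realization. If
    ``spec.output_dir`` is set, the table is written to ``sweep.csv`` and
    a rerun skips grid cells already present (resumable).
    """
    out_path = None
    done: pd.DataFrame | None = None
    if spec.output_dir is not None:
        out_path = Path(spec.output_dir) / "sweep.csv"
        out_path.parent.mkdir(parents=True, exist_ok=True)
        if out_path.exists():
            done = pd.read_csv(out_path)

    axis_names = list(spec.grid)
    rows: list[dict] = []
    for gp_index, point in enumerate(_grid_points(spec.grid)):
        for regime in spec.regimes:
            for scheme in spec.schemes:
                if done is not None and len(done):
                    m = (done["regime"] == regime) & (done["scheme"] == scheme)
                    for k, v in point.items():
                        m &= done[k] == v
                    if m.sum() >= spec.n_realizations:
                        rows.extend(done[m].to_dict("records"))
                        continue
                tpl = replace(spec.template, scheme=scheme, **point)
                cell_seed = int(
                    np.random.SeedSequence(
                        (spec.master_seed, gp_index, spec.regimes.index(regime),
                         0 if scheme == "summation" else 1)
                    ).generate_state(1)[0] % (2**31)
                )
                res = ensemble_mi(
                    tpl, regime, spec.n_realizations, cell_seed,
                    N=spec.N, N_I=spec.N_I, N_inner=spec.N_inner,
                    with_bimodality=spec.with_bimodality,
                )
                for r, v in enumerate(res.values):
                    row = dict(point)
                    row.update(regime=regime, scheme=scheme, realization=r, mi=v)
                    if spec.with_bimodality:
                        row["b"] = res.b_values[r]
                    rows.append(row)
    df = pd.DataFrame(rows)
    ordered = axis_names + KEY_COLS + [c for c in ("mi", "b") if c in df.columns]
    df = df[[c for c in ordered if c in df.columns]]
    df = df.sort_values(axis_names + KEY_COLS).reset_index(drop=True)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


@dataclass
class OptimalMpResult:
    """Per input size: MI-maximizing processing dimension with a bootstrap CI."""

    M_I: int
    M_P_star: int
    ci_low: int
    ci_high: int
    tied: list[int]
    degenerate: bool


def find_optimal_Mp(
    df: pd.DataFrame, n_boot: int = 500, seed: int = 0
) -> list[OptimalMpResult]:
    """Locate the processing dimension maximizing ensemble-mean MI per M_I.

    Expects columns ``M_I``, ``M_P``, ``realization``, ``mi``. The
    bootstrap resamples realizations; a profile flat within errors is
    returned as the full tied set, flagged degenerate.
    """
    for col in ("M_I", "M_P", "realization", "mi"):
        if col not in df.columns:
            raise ValueError(f"results table lacks column {col!r}")
    rng = np.random.default_rng(seed)
    out: list[OptimalMpResult] = []
    for M_I, sub in df.groupby("M_I"):
        prof = sub.groupby("M_P")["mi"].agg(["mean", "sem", "count"])
        mps = prof.index.to_numpy()
        if len(mps) == 1:
            out.append(OptimalMpResult(int(M_I), int(mps[0]), int(mps[0]),
                                       int(mps[0]), [int(mps[0])], True))
            continue
        best = int(mps[np.argmax(prof["mean"].to_numpy())])
        # realization-resampled argmax
        wide = sub.pivot_table(index="realization", columns="M_P", values="mi")
        arr = wide.to_numpy()
        n = arr.shape[0]
        boots = np.empty(n_boot, dtype=int)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = mps[np.argmax(np.nanmean(arr[idx], axis=0))]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        means = prof["mean"].to_numpy()
        sems = np.nan_to_num(prof["sem"].to_numpy())
        top_idx = int(np.argmax(means))
        top, top_se = means[top_idx], sems[top_idx]
        tied = [int(m) for m, mu, se in zip(mps, means, sems)
                if top - mu <= 3 * math.hypot(se, top_se)]
        degenerate = len(tied) == len(mps)
        out.append(OptimalMpResult(int(M_I), best, int(lo), int(hi), tied, degenerate))
    return out


# ---------------------------------------------------------------------------
# Figure-level drivers
# ---------------------------------------------------------------------------

FIGURES = ("fig1", "fig2", "fig3", "fig4e", "fig5a", "fig6a")


def _scaled(n: int, scale: float, floor: int = 2) -> int:
    return max(floor, int(round(n * scale)))


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import ks_2samp

    return float(ks_2samp(a, b).statistic)


def reproduce(
    figure_id: str,
    scale: float = 1.0,
    seed: int = 0,
    output_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict:
    """Run the experiment design behind one figure at a reduced scale.

    ``scale`` multiplies realization counts and grid resolutions; tables
    (CSV) and a JSON summary are written to ``output_dir`` when given.
    Returns the summary dict.
    """
    if figure_id not in FIGURES:
        raise ValueError(f"unknown figure id {figure_id!r}; expected one of {FIGURES}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if figure_id == "fig1":
        summary = _reproduce_fig1(scale, seed, outdir)
    elif figure_id == "fig2":
        summary = _reproduce_fig2(scale, seed, outdir)
    elif figure_id == "fig3":
        summary = _reproduce_fig3(scale, seed, outdir)
    elif figure_id == "fig4e":
        summary = _reproduce_fig4e(scale, seed, outdir)
    elif figure_id == "fig5a":
        summary = _reproduce_fig5a(scale, seed, outdir)
    else:
        summary = _reproduce_fig6a(scale, seed, outdir)

    if outdir is not None:
        with open(outdir / f"{figure_id}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        if make_plots:
            _plot_summary(figure_id, summary, outdir)
    return summary


def fig1_marginals(
    scheme: str,
    regime: str,
    seed: int = 0,
    n_samples: int = 10_000,
    t_burn: float = 0.15,
    dt: float = 8e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Langevin vs exact-sampling output marginals for the small system.

    Returns (langevin outputs, exact outputs, KS distance).
    """
    tpl = fig1_template().with_(scheme=scheme)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 91)))
    system = realize_system(tpl, regime, rng)
    state = langevin_stationary_ensemble(system, n_samples, t_burn, dt, rng)
    lv = state["O"][:, 0]
    factors = build_factorization(system, regime)
    if regime == FAST_PROCESSING:
        batch = sample_fast_processing(system, n_samples, rng, factors=factors)
    else:
        batch = sample_slow_processing(
            system, N_I=n_samples, N_inner=1, seed=rng, factors=factors
        )
    ex = batch.pooled_output[:, 0]
    return lv, ex, _ks_distance(lv, ex)


def _reproduce_fig1(scale, seed, outdir):
    n = _scaled(10_000, scale, floor=500)
    panels = {}
    rows = []
    for regime in (SLOW_PROCESSING, FAST_PROCESSING):
        for scheme in ("summation", "integration"):
            lv, ex, ks = fig1_marginals(scheme, regime, seed=seed, n_samples=n)
            key = f"{regime}/{scheme}"
            panels[key] = ks
            rows.append(pd.DataFrame({
                "regime": regime, "scheme": scheme,
                "langevin": lv, "exact": ex,
            }))
    df = pd.concat(rows, ignore_index=True)
    if outdir is not None:
        df.to_csv(outdir / "fig1_samples.csv", index=False)
    return {"figure": "fig1", "n_samples": n, "ks": panels}


def _reproduce_fig2(scale, seed, outdir):
    # no-processing system: MI over g_OI x sigma_OI, both schemes
    n_side = _scaled(5, scale, floor=2)
    tpl = SystemTemplate(M_I=20, M_P=0, sigma_I=0.9)
    spec = SweepSpec(
        template=tpl,
        grid={
            "g_OI": list(np.linspace(1.0, 10.0, n_side)),
            "sigma_OI": list(np.geomspace(0.5, 10.0, n_side)),
        },
        regimes=[NO_PROCESSING],
        n_realizations=_scaled(50, scale, floor=4),
        master_seed=seed,
        output_dir=outdir,
    )
    df = run_sweep(spec)
    piv = df.groupby(["g_OI", "sigma_OI", "scheme"])["mi"].mean().unstack("scheme")
    diff = (piv["integration"] - piv["summation"]).reset_index()
    diff.columns = ["g_OI", "sigma_OI", "mi_int_minus_ns"]
    lo = diff[diff.sigma_OI == diff.sigma_OI.min()]["mi_int_minus_ns"].mean()
    hi = diff[diff.sigma_OI == diff.sigma_OI.max()]["mi_int_minus_ns"].mean()
    return {
        "figure": "fig2", "n_realizations": spec.n_realizations,
        "diff_at_small_sigma_OI": lo, "diff_at_large_sigma_OI": hi,
        "integration_wins_small_sigma": bool(lo > 0),
        "summation_wins_large_sigma": bool(hi < 0),
    }


def _reproduce_fig3(scale, seed, outdir):
    n_side = _scaled(3, scale, floor=2)
    tpl = SystemTemplate(M_I=20, M_P=20, sigma_PI=1.0, sigma_OP=1.0)
    spec = SweepSpec(
        template=tpl,
        grid={
            "g_PI": list(np.linspace(2.0, 10.0, n_side)),
            "g_OP": list(np.linspace(2.0, 10.0, n_side)),
        },
        regimes=[FAST_PROCESSING, SLOW_PROCESSING],
        n_realizations=_scaled(50, scale, floor=4),
        master_seed=seed,
        output_dir=outdir,
    )
    df = run_sweep(spec)
    g = df.groupby(["regime", "scheme"])["mi"].mean()
    return {
        "figure": "fig3", "n_realizations": spec.n_realizations,
        "mi_mean": {f"{r}/{s}": v for (r, s), v in g.items()},
        "fast_beats_slow": bool(
            g[FAST_PROCESSING].mean() > g[SLOW_PROCESSING].mean()
        ),
        "integration_beats_summation_fast": bool(
            g[(FAST_PROCESSING, "integration")] > g[(FAST_PROCESSING, "summation")]
        ),
    }


def _reproduce_fig4e(scale, seed, outdir):
    n_side = _scaled(3, scale, floor=2)
    results = {}
    for M_P, p_unit in [(2, 1.0), (20, 1.0), (20, 0.5)]:
        tpl = SystemTemplate(
            M_I=20, M_P=M_P, sigma_PI=1.0, sigma_OP=10.0, p_unit=p_unit
        )
        spec = SweepSpec(
            template=tpl,
            grid={
                "g_PI": list(np.linspace(2.0, 10.0, n_side)),
                "g_OP": list(np.linspace(2.0, 10.0, n_side)),
            },
            regimes=[FAST_PROCESSING],
            n_realizations=_scaled(50, scale, floor=4),
            master_seed=seed,
        )
        df = run_sweep(spec)
        piv = df.groupby("scheme")["mi"].mean()
        results[f"M_P={M_P},p={p_unit}"] = float(
            piv["integration"] - piv["summation"]
        )
    return {"figure": "fig4e", "mi_int_minus_ns": results}


def _reproduce_fig5a(scale, seed, outdir):
    tpl = SystemTemplate(
        M_I=10, sigma_PI=1.0, sigma_OP=1.0, g_PI=10.0, g_OP=10.0,
        scheme="integration",
    )
    spec = SweepSpec(
        template=tpl,
        grid={"M_I": [10, 40], "M_P": [2, 5, 10, 20, 40]},
        regimes=[FAST_PROCESSING],
        schemes=["integration"],
        n_realizations=_scaled(100, scale, floor=6),
        master_seed=seed,
        output_dir=outdir,
    )
    df = run_sweep(spec)
    opt = find_optimal_Mp(df)
    return {
        "figure": "fig5a",
        "optimal_M_P": {str(o.M_I): o.M_P_star for o in opt},
        "nonincreasing_in_M_I": bool(
            opt[0].M_P_star >= opt[-1].M_P_star
        ),
    }


def _reproduce_fig6a(scale, seed, outdir):
    tpl = SystemTemplate(
        g_PI=10.0, g_OP=10.0, sigma_PI=1.0, sigma_OP=1.0,
    )
    spec = SweepSpec(
        template=tpl,
        grid={"M_I": [5, 20], "M_P": [5, 20]},
        regimes=[FAST_PROCESSING],
        n_realizations=_scaled(60, scale, floor=4),
        master_seed=seed,
        with_bimodality=True,
        output_dir=outdir,
    )
    df = run_sweep(spec)
    piv = df.groupby(["M_I", "M_P", "scheme"])["b"].mean().unstack("scheme")
    diff = piv["integration"] - piv["summation"]
    return {
        "figure": "fig6a",
        "b_int_minus_ns": {f"{i},{j}": v for (i, j), v in diff.items()},
        "integration_more_bimodal_everywhere": bool((diff >= 0).all()),
    }


def _plot_summary(figure_id: str, summary: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    if figure_id == "fig1":
        items = summary["ks"]
        ax.bar(range(len(items)), list(items.values()))
        ax.set_xticks(range(len(items)), list(items.keys()), rotation=30, ha="right")
        ax.axhline(0.05, ls="--", c="k")
        ax.set_ylabel("KS distance")
    else:
        ax.text(0.05, 0.5, json.dumps(summary, indent=1, default=float)[:800],
                fontsize=6, family="monospace", va="center")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / f"{figure_id}.png", dpi=120)
    plt.close(fig)
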