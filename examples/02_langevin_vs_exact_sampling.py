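"""Stochastic simulation versus exact stationary sampling.

Integrates the full multiscale Langevin system (timescale ratio 1e-2) for
an ensemble of independent trajectories and compares the output marginal
with draws from the exact factorized stationary distribution. A small
Kolmogorov-Smirnov distance confirms the timescale-separated solution.

Takes ~1 minute (reduce n_samples for a quicker look).
"""

from msinfo.experiments import fig1_marginals

for scheme in ("summation", "integration"):
    lv, ex, ks = fig1_marginals(
        scheme, "fast_processing", seed=0, n_samples=4000
    )
    print(f"fast processing, {scheme:12s}: "
          f"Langevin var={lv.var():.3f}, exact var={ex.var():.3f}, KS={ks:.3f}")
print("-> KS well below 0.05: the factorized solution reproduces the")
print("   simulated stationary output distribution in the fast-processing limit.")
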