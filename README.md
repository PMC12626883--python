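# msinfo — multiscale stochastic information processing

`msinfo` studies how nonlinear activations and timescale separation shape
information flow in stochastic networks built from three units — an input
*I*, a processing layer *P*, and an output *O* — each a group of M_μ
degrees of freedom with a shared timescale τ_μ, evolving under coupled
Langevin dynamics

    τ_μ ẋ_μ = −Â_μ x_μ + Σ_ν g_μν φ_μν(Â_μν; x_ν) + √(2 τ_μ) σ̂_μ ξ_μ .

The inter-unit activation φ implements one of two widely used schemes:

- **nonlinear summation (ns)** — saturate each source signal, then
  average: φ_i = (1/C_i) Σ_j A_ij tanh(x_j − θ_j);
- **nonlinear integration (int)** — average first, then saturate:
  φ_i = tanh((1/C_i) Σ_j A_ij (x_j − θ_j)),

where C_i counts the connections feeding target dof i (sparse couplings)
and θ is an optional processing bias. Interactions are drawn from random
ensembles: intra-unit matrices with unit diagonal and N(0, (σ_μ/√M_μ)²)
off-diagonal entries (stable for σ_μ < 1 by the circular law), inter-unit
entries N(0, σ_μν²) with Bernoulli(p_unit) masks, and optionally a
Barabási–Albert processing topology.

The package is aimed at researchers in statistical physics, theoretical
neuroscience, and systems biology who want a workbench for the following
questions: when does a fast processing layer transmit more input
information than a slow one? When does integrating before the
nonlinearity beat summing saturated signals? How do unit sizes, coupling
strength g, heterogeneity σ, and sparsity trade off — and when does the
output turn bimodal?

## What it computes

When timescales separate (slow input; processing either much faster or
much slower than the output), the stationary joint density factorizes
into conditional Gaussians whose covariances solve Lyapunov equations
Â Σ̂ + Σ̂ Âᵀ = 2 D̂ and whose *means* carry all the nonlinearity. For a
fast processing unit the output mean involves the Gaussian-smoothed
activation

    𝓕(x, v) = E[tanh(z)],  z ~ N(x, v),

implemented both as a stabilized erf/erfcx series (`F_series`) and as an
independent quadrature (`F_quadrature`). This makes *exact* stationary
sampling cheap, and the input-output mutual information

    I(I;O) = H_O − ⟨h_O|I⟩_I     (bits)

computable with only a one-dimensional entropy estimator
(Kozachenko–Leonenko k-NN by default). Output bimodality is quantified by
Sarle's coefficient b = (s² + 1)/(κ + q(n)).

## Worked example

```python
from msinfo import (SystemTemplate, realize_system, mutual_information,
                    FAST_PROCESSING, SLOW_PROCESSING)

template = SystemTemplate(M_I=20, M_P=20, g_PI=5.0, g_OP=5.0,
                          sigma_PI=1.0, sigma_OP=1.0, scheme="integration")
for regime in (FAST_PROCESSING, SLOW_PROCESSING):
    system = realize_system(template, regime, seed=3)
    est = mutual_information(system, regime, seed=4, N=20_000,
                             N_I=500, N_inner=500)
    print(regime, round(est.value, 3), "bits")
```

prints

```
fast_processing 0.887 bits
slow_processing 0.624 bits
```

The same interaction matrices transmit ~0.26 bits more when the
processing unit is faster than the output: its fluctuations average into
an effective mean instead of injecting noise downstream. The
`examples/` directory contains one short script per capability
(stationary solutions, simulation-vs-exact-sampling, mutual information,
scheme comparison, bimodality), and the `msinfo` command line exposes
`describe`, `simulate`, `sample`, `mi`, `sweep`, and `reproduce`
subcommands for shell use.

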