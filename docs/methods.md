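# Methods

## Model

The system is a set of stochastic units μ ∈ {I, P, O} (input, processing,
output), each with M_μ degrees of freedom x_μ, an intra-unit coupling
matrix Â_μ, a diagonal diffusion D̂_μ = σ̂_μσ̂_μᵀ (identity by default), and
a shared timescale τ_μ:

    τ_μ ẋ_μ = −Â_μ x_μ + Σ_{ν≠μ} g_μν φ_μν(Â_μν; x_ν) + √(2 τ_μ) σ̂_μ ξ_μ .

The input evolves autonomously (no incoming couplings); the signal flows
I → P → O (or I → O directly in the processing-free configuration). The
activation φ is either nonlinear summation, (1/C_i) Σ_j A_ij tanh(x_j − θ_j),
or nonlinear integration, tanh((1/C_i) Σ_j A_ij (x_j − θ_j)); C_i is the
number of connections feeding target dof i and equals the source size for
dense couplings. Rows with C_i = 0 contribute zero. A per-source-dof bias
θ shifts the argument of the saturation.

Interaction ensembles: intra-unit entries ~ N(0, (σ_μ/√M_μ)²) with
diagonal fixed to 1 — the second ensemble parameter is a *standard
deviation*, which is the reading under which the circular-law stability
threshold σ_μ < 1 holds for the unit-diagonal drift. Inter-unit entries ~
N(0, σ_μν²), masked by independent Bernoulli(p_unit) connections.
Unstable intra-unit draws (a few percent at σ = 0.9 for M ≈ 20–50,
because the spectral edge fluctuates at finite M) are rejected and
redrawn from the advanced generator state; stationary covariances exist
only for stable drifts. The Barabási–Albert processing topology draws an
undirected BA graph and gives each *directed* edge an independent
N(0, (σ/√M)²) weight (the two directions are drawn separately; this is a
convention, as is keeping the 1/√M scaling for comparability with the
dense ensemble).

## Timescale regimes and exact stationary factorization

With a slow input, two orderings admit exact stationary solutions:

- **fast processing** (τ_I ≫ τ_O ≫ τ_P): p = p(x_I) p(x_P|x_I) p(x_O|x_I),
  where the output factor is the *effective* conditional obtained by
  averaging over the fast processing fluctuations;
- **slow processing** (τ_I ≫ τ_P ≫ τ_O): p = p(x_I) p(x_P|x_I) p(x_O|x_P),
  a Markov chain I → P → O.

Every factor is Gaussian with covariance solving Â Σ̂ + Σ̂ Âᵀ = 2 D̂
(Bartels–Stewart via `scipy.linalg.solve_continuous_lyapunov`; residuals
are checked below 1e-10 of the diffusion scale) and a mean carrying the
nonlinearity: m_μ|ν = g Â_μ⁻¹ φ_μν(x_ν). The fast-regime output mean uses
the Gaussian-smoothed activation 𝓕(x, v) = E[tanh(N(x, v))]:

- summation: componentwise 𝓕 over the processing conditional means and
  the *diagonal* of Σ̂_P, then averaged with the Â_OP weights (1/C_i
  normalization) and mapped through g Â_O⁻¹;
- integration: 𝓕 of the integrated moments m_int = (1/C) Â_OP m_P|I and
  v_int = (1/C²) diag(Â_OP Σ̂_P Â_OPᵀ) — the full quadratic form, not just
  the diagonal of Σ̂_P.

The asymmetry (diagonal for summation, full quadratic form for
integration) is intentional: each expression is the exact Gaussian
average of the corresponding activation, and both are verified in the
tests against brute-force Monte-Carlo averages of φ. With a bias θ the
smoothing argument is m − θ. Timescale values are assigned as τ_slowest
= 1 with each faster unit a factor Δτ = 1e-2 faster by default (fast
processing: 1, Δτ, Δτ²; only the ordering matters for the theory).

## Evaluating 𝓕

`F_series` evaluates the closed series: erf(x/√(2v)) plus an alternating
sum of terms e^{2n²v}[e^{−2nx} erfc((2nv−x)/√(2v)) − e^{2nx}
erfc((2nv+x)/√(2v))]. Two numerical measures are essential:

1. **erfcx stabilization.** Each product is rewritten exactly as
   e^{−x²/(2v)} erfcx(t) when the erfc argument t ≥ 0, and as
   2 e^{2n(nv∓x)} − e^{−x²/(2v)} erfcx(−t) when t < 0; all surviving
   exponents are nonpositive, so nothing overflows at any v.
2. **Series acceleration.** The terms decay only like n⁻², so plain
   truncation converges far too slowly for oracle-grade accuracy at
   v ≲ 1. Elements whose leading term already meets the alternating-series
   remainder bound (tol = 1e-12) keep the erf value; the rest are summed
   with Cohen–Rodriguez Villegas–Zagier acceleration over the first ≤ 24
   terms, which is accurate to machine precision over x ∈ [−5, 5],
   v ∈ [1e-6, 50] (verified against adaptive quadrature).

For v ≤ 1e-12 the analytic limit tanh(x) is returned. `F_quadrature` is
the independent oracle: 301-node Gauss–Hermite for v ≤ 2; for larger v
(where the tanh poles at ±iπ/2 defeat polynomial quadrature) it
integrates the exponentially decaying correction tanh(z) − sign(z)
adaptively around the erf term, giving ≤ 1e-10 absolute error up to
v = 50. The two implementations share no code path beyond erf itself.

## Simulation

`integrate` is fixed-step Euler–Maruyama (additive noise, weak order 1 —
sufficient for histogram-level comparisons), with a stiffness guard
dt < min τ/10, an overflow guard at |x| = 1e6, and thinning at the
slowest timescale. For simulation-versus-exact-sampling checks a single
path cannot decorrelate 1e4 output samples (the input correlation time
is 1e4 fast-unit timescales), so `langevin_stationary_ensemble` runs many
independent paths: the input starts in its own Ornstein–Uhlenbeck
stationary law N(0, Σ̂_I) — exact, since the input is autonomous and
linear — the other units start at zero, and the coupled nonlinear system
is integrated for t_burn = 0.15 (≈ 15 relaxation times of the middle
unit) at dt = 8e-6 before the final state is kept. Noise increments are
drawn in single precision (the sampling error this introduces is orders
of magnitude below the Euler–Maruyama bias). Kolmogorov–Smirnov distances
between the simulated and exactly sampled output marginals are ≈ 0.01 at
1e4 samples for both schemes and both orderings at Δτ = 1e-2. The
coupling strengths of the small illustrative configuration (M_I = 5,
M_P = 3, M_O = 1, inter-unit σ = 1, intra-unit σ = 0.9) are g_PI =
g_OP = 1.

## Mutual information

I(I;O) = H_O − ⟨h_O|I⟩ in bits. In the no-processing and fast-processing
regimes the output conditional covariance is input-independent, so the
conditional term is the closed-form Gaussian entropy ½[M log₂(2πe) +
log₂ det Σ̂_O] and only H_O is estimated numerically. In the slow regime
the conditional is a mixture: nested sampling (N_I inputs × N_inner inner
draws, defaults 2000 × 2000) estimates h_O|I per input, averaged with a
jackknife standard error; N_inner < 100 is refused. Entropy estimation is
restricted to one-dimensional outputs, matching the scope of reliable
differential-entropy estimators.

The default estimator is Kozachenko–Leonenko k-NN with k = 4 (in one
dimension the k-th neighbour search vectorizes into sorted-window
comparisons, so thousands of per-input entropies cost milliseconds); a
Freedman–Diaconis histogram plug-in is retained as a cross-check and the
two agree within 0.05 bits on Gaussian calibration fixtures. MI point
estimates are reported as computed, including slightly negative values —
transparency over cosmetic clipping.

A linear-activation stub (identity in place of tanh) turns every
pipeline into an exactly solvable Gaussian chain; all three regime
pipelines reproduce the covariance-algebra closed form within 0.05 bits,
the strongest end-to-end oracle in the suite. Note the fast-regime
conditional noise is Σ̂_O alone (processing fluctuations average out),
whereas the slow regime adds the propagated processing covariance — the
mechanism behind "fast beats slow".

Ensemble averages redraw all matrices per realization with counter-based
seed fan-out (SeedSequence((master, index))), so results are independent
of evaluation order and bit-reproducible. Comparisons between schemes use
the *same* seeds, hence the same matrix draws: paired differences, which
removes most realization-to-realization variance.

## Bimodality

Sarle's coefficient b = (s² + 1)/(κ + q(n)) with 1/n moment estimators
exactly as defined — biased skewness s, excess kurtosis κ, and the
finite-sample factor q(n) = 3(n−1)²/((n−2)(n−3)). A Gaussian gives 1/3, a
symmetric two-point mixture 1. No small-sample moment corrections are
applied; q(n) carries the finite-n behaviour.

## Reduced problem sizes

The ensemble-level orderings are established at M = 20 (M_P = 2 where the
small-processing regime is the point), 40–120 matrix realizations,
N = 4000 samples per fast/no-processing MI estimate and 300 × 300 nested
samples per slow estimate; the optimal-processing-size scan uses
M_P ∈ {2, 5, 10, 20, 40} at 120 realizations. These sizes give paired
effect sizes of 3–20 standard errors for every ordering checked. The
full-scale study conditions (M = 50, 10³–2×10⁴ realizations) are
available through the same templates by changing the arguments.

At reduced scale the optimal processing dimension M_P*(M_I) is resolved
only where the MI profile is peaked; flat profiles (within 3 SE) are
reported as tied sets flagged degenerate, and ordering statements about
M_P* are made against the tied sets rather than raw argmaxes.

## What the generator does and does not emulate

The synthetic ensembles reproduce the study conditions exactly:
Gaussian interaction statistics, unit-diagonal intra-unit couplings,
Bernoulli sparsity, BA topology, Gaussian random biases, identity
diffusion. They do not emulate structured real-world connectivity,
non-Gaussian weight distributions, state-dependent noise, or comparable
input/output timescales; conclusions from passing tests are statements
about this model class in its timescale-separated limits, not about any
particular biological circuit.

## Known limitations

- Mutual information is estimated only for 1-D outputs; the analytic
  pieces support any M_O.
- The exact factorizations hold in the limits of infinite timescale
  separation; at Δτ = 1e-2 the residual discrepancy is visible only as a
  ≈ 0.01 KS distance.
- Euler–Maruyama with fixed step: no adaptive stiffness handling beyond
  the dt guard.
- The slow-regime conditional entropy inherits the k-NN estimator's
  O(1/N_inner) bias; N_inner ≥ 100 keeps it below the reported standard
  errors but very small inner counts would bias I_IO upward.
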