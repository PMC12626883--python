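"""Exact stationary structure of a small input-processing-output system.

Builds a three-unit system from the random ensembles, solves the Lyapunov
equations for each unit's stationary covariance, and evaluates the
Gaussian-smoothed activation F(x, v) that closes the fast-processing
factorization.
"""

import numpy as np

from msinfo import (
    FAST_PROCESSING,
    F_quadrature,
    F_series,
    SystemTemplate,
    build_factorization,
    realize_system,
)
from msinfo.stationary import lyapunov_residual

template = SystemTemplate(M_I=8, M_P=4, M_O=1, g_PI=2.0, g_OP=2.0)
system = realize_system(template, FAST_PROCESSING, seed=0)
factors = build_factorization(system, FAST_PROCESSING)

print("Stationary covariances (A S + S A^T = 2 D):")
for f in factors:
    unit = system.units[f.target]
    resid = lyapunov_residual(unit.A, unit.D, f.Sigma)
    print(f"  unit {f.target}: M={unit.M:2d}, tr(Sigma)={np.trace(f.Sigma):7.3f}, "
          f"residual={resid:.2e}")
print("  -> residuals at machine precision: the covariances are exact,")
print("     all nonlinearity lives in the conditional means.")

print("\nGaussian-smoothed tanh F(x, v) = E[tanh(N(x, v))]:")
for x, v in ((1.0, 0.0), (1.0, 1.0), (1.0, 10.0)):
    print(f"  F({x}, {v:4.1f}) = {F_series(x, v):+.6f}   "
          f"(quadrature check {F_quadrature(x, v):+.6f})")
print("  -> growing processing fluctuations v damp the transmitted mean;")
print("     series and quadrature evaluations agree to machine precision.")
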