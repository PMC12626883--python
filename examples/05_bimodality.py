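"""Emergent and tunable output bimodality.

With strong couplings the saturating activation can split the stationary
output density into two modes even for a Gaussian input. Sarle's
coefficient b quantifies this (Gaussian: 1/3; two-point mixture: 1).
A random processing bias theta skews the mode occupation.
"""

from msinfo import (
    FAST_PROCESSING,
    SystemTemplate,
    realize_system,
    sample_fast_processing,
    sarle_b,
)

base = SystemTemplate(M_I=5, M_P=10, g_PI=10.0, g_OP=10.0,
                      sigma_PI=1.0, sigma_OP=1.0)
for scheme in ("summation", "integration"):
    for theta_std, tag in ((0.0, "no bias"), (1.0, "random bias")):
        tpl = base.with_(scheme=scheme, theta_std=theta_std)
        system = realize_system(tpl, FAST_PROCESSING, seed=5)
        batch = sample_fast_processing(system, 40_000, seed=6)
        x = batch.pooled_output[:, 0]
        rep = sarle_b(x)
        print(f"{scheme:12s} {tag:12s}: b = {rep.b:5.3f}  "
              f"skew = {rep.s:+5.2f}  mean = {x.mean():+5.2f}")
print("-> integration pushes b above the Gaussian value 1/3 (bimodal")
print("   output); the bias tilts the distribution toward one mode.")
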