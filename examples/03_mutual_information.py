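"""Input-output mutual information: fast versus slow processing.

Estimates I(I;O) for the same interaction matrices under the two timescale
orderings. With a fast processing unit the conditional entropy is closed
form; with a slow one it is estimated from nested exact samples.
"""

from msinfo import (
    FAST_PROCESSING,
    SLOW_PROCESSING,
    SystemTemplate,
    mutual_information,
    realize_system,
)

template = SystemTemplate(M_I=20, M_P=20, g_PI=5.0, g_OP=5.0,
                          sigma_PI=1.0, sigma_OP=1.0, scheme="integration")

for regime in (FAST_PROCESSING, SLOW_PROCESSING):
    system = realize_system(template, regime, seed=3)
    est = mutual_information(system, regime, seed=4, N=20_000,
                             N_I=500, N_inner=500)
    print(f"{regime:16s}: I(I;O) = {est.value:5.3f} bits "
          f"(H_O = {est.H_O:5.3f}, conditional = {est.h_or_H_cond:5.3f})")
print("-> the fast processing unit transmits more information: its")
print("   fluctuations average out instead of adding noise to the output.")
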