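"""Unmix an IRM acquisition curve into coercivity components.

Generates a noisy three-component curve (biogenic magnetite + soft and
hard detrital assemblages) and recovers the component parameters used as
down-core proxies: the biogenic fraction, its median acquisition field
B1/2 and dispersion DP.
"""

import numpy as np

from magnetofossil import (
    IrmComponentSpec,
    component_fraction,
    fit_components,
    generate_irm_curve,
)

truth = [
    IrmComponentSpec(0.76, np.log10(60.0), 0.15),   # biogenic: narrow DP
    IrmComponentSpec(0.09, np.log10(25.0), 0.35),   # detrital soft
    IrmComponentSpec(0.15, np.log10(400.0), 0.30),  # detrital hard
]
curve = generate_irm_curve(truth, n_points=80, noise_sd=0.01, seed=21)
fit = fit_components(curve, n_components=3, seed=0)

print(f"fit residual RMS: {fit.residual_rms:.4f} (curve units)")
for i, c in enumerate(fit.components):
    print(
        f"component {i}: B1/2 = {c.b_half_mT:6.1f} mT, DP = {c.dp:.3f}, "
        f"fraction = {component_fraction(fit, i):.2f}"
    )
narrowest = min(range(3), key=lambda i: fit.components[i].dp)
print(f"narrowest-DP component (index {narrowest}) is the biogenic candidate")
print("-> the dominant narrow-DP component is the magnetofossil signal; its")
print("   fraction tracks biogenic magnetite abundance, while B1/2 and DP")
print("   track crystal size/elongation and population uniformity.")
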