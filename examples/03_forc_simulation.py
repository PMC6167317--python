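"""Simulate and process a FORC diagram for a magnetofossil assemblage.

Builds chains from a synthetic crystal population, runs a first-order
reversal curve protocol, processes the grid with variable smoothing, and
reports the central-ridge share — the FORC fingerprint of intact
(non-interacting) single-domain chains.
"""

import numpy as np

from magnetofossil import (
    ChainConfig,
    CrystalPopulationSpec,
    FieldProtocol,
    build_assemblage,
    compute_forc_distribution,
    extract_backfield_profile,
    extract_central_ridge,
    generate_crystal_population,
    run_forc,
)

pop = generate_crystal_population(
    CrystalPopulationSpec(
        n_crystals=500, length_logmean=np.log(60.0), length_logsd=0.25,
        axial_ratio_mean=0.8, axial_ratio_sd=0.08, seed=3,
    )
)
# isolated crystals: the ideal central-ridge end-member
asm = build_assemblage(pop, ChainConfig(1, 300, packing_fraction=1e-4, seed=7))
protocol = FieldProtocol(kind="forc", n_forcs=50, bc_max=160, bu_max=60)
dataset = run_forc(asm, protocol, n_realizations=5, seed=11, interactions=False)

dist = compute_forc_distribution(dataset)  # VARIFORC-style {7,7,2,7,0.1,0.1}
ridge = extract_central_ridge(dist, bu_halfwidth=2 * dist.bu_step)
backfield = extract_backfield_profile(dataset)
peak_bc = backfield.field_mT[np.argmax(backfield.density)]

print(f"grid: {len(dataset.ba)} FORCs, field step {dataset.field_step:.2f} mT")
print(f"central-ridge fraction (|Bu| <= 2 steps): {ridge.ridge_fraction:.2f}")
print(f"backfield profile peak: {peak_bc:.1f} mT, Bcr = {backfield.bcr_mT:.1f} mT")
print("-> a ridge fraction near 1 is the magnetofossil signature; the")
print("   backfield peak tracks the coercivity of the crystal population.")
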