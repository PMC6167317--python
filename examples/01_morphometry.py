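"""Characterize a magnetofossil crystal population.

Builds a synthetic TEM-style measurement table (log-normal lengths, a
small bullet-shaped share), classifies morphologies, and prints the
statistics a down-core magnetofossil study would report.
"""

import numpy as np

from magnetofossil import (
    CrystalPopulationSpec,
    bullet_fraction,
    classify_morphology,
    generate_crystal_population,
    ks_two_sample,
    summarize,
)

# PETM-onset-like population: median length 55 nm, near-equant on average
onset = generate_crystal_population(
    CrystalPopulationSpec(
        n_crystals=600, length_logmean=np.log(55.0), length_logsd=0.25,
        axial_ratio_mean=0.85, axial_ratio_sd=0.08, bullet_fraction=0.008, seed=1,
    )
)
# PETM-peak-like population: longer and more elongated crystals
peak = generate_crystal_population(
    CrystalPopulationSpec(
        n_crystals=600, length_logmean=np.log(75.0), length_logsd=0.25,
        axial_ratio_mean=0.70, axial_ratio_sd=0.08, bullet_fraction=0.004, seed=2,
    )
)

for name, pop in [("onset", onset), ("peak", peak)]:
    labelled = classify_morphology(pop, axial_ratio_cutoff=0.9)
    s = summarize(labelled, exclude_bullets=True)
    print(f"{name}: n={s.n_total}, bullets={bullet_fraction(labelled):.1f}%")
    print(f"  length median {s.length_stats.median:.1f} nm "
          f"(IQR {s.length_stats.q1:.1f}-{s.length_stats.q3:.1f})")
    print(f"  axial ratio median {s.axial_ratio_stats.median:.2f}")

ks = ks_two_sample([c.length for c in onset], [c.length for c in peak])
print(f"KS test on lengths: D={ks.d_statistic:.3f}, p={ks.p_value:.2e}")
print("-> D near 0 would mean indistinguishable size distributions; a tiny p")
print("   confirms the two populations differ, the basis for using size")
print("   statistics as a stratigraphic fingerprint.")
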