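"""Chain architecture controls bulk coercivity.

Simulates hysteresis loops for the same crystals arranged as isolated
grains, straight chains, and collapsed chains, and prints the bulk
parameters.  Intact magnetosome chains act as magnetic 'super-particles'
whose anisotropy raises coercivity well above that of the isolated
crystals.
"""

from magnetofossil import (
    ChainConfig,
    CrystalMeasurement,
    FieldProtocol,
    build_assemblage,
    run_hysteresis,
    switching_field,
)

crystal = [CrystalMeasurement("demo", 60.0, 48.0)]  # 60x48 nm magnetosome
print(f"single-particle switching field: {switching_field(build_assemblage(crystal, ChainConfig(1, 1, seed=0)).delta_n[0]):.1f} mT")

protocol = FieldProtocol(kind="hysteresis", saturation_field=300, field_step=2.0)
cases = {
    "isolated grains": ChainConfig(1, 150, packing_fraction=1e-4, seed=5),
    "straight chains of 5": ChainConfig(5, 30, bending_factor=0.0, seed=5),
    "collapsed chains of 5": ChainConfig(5, 30, bending_factor=1.0, seed=5),
}
for name, cfg in cases.items():
    asm = build_assemblage(crystal, cfg)
    res = run_hysteresis(asm, protocol)
    print(f"{name:24s} Bc = {res.bc_mT:5.1f} mT   Mrs/Ms = {res.mrs_over_ms:.3f}")
print("-> coercivity rises from isolated grains to straight chains and falls")
print("   again as chains collapse: measured Bc constrains chain preservation.")
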