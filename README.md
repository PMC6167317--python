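# magnetofossil

Micromagnetic simulation and rock-magnetic characterization of
**magnetofossils** — the fossil magnetite nanocrystals biomineralized by
magnetotactic bacteria — for geobiologists and environmental magnetists who
use them as sediment archives of past ocean conditions.

Magnetotactic bacteria grow chains of single-domain (SD) magnetite crystals;
after burial, the crystals' sizes, shapes, and chain architectures leave a
characteristic magnetic fingerprint. This package closes the loop between
microscopy and magnetometry:

* **morphometry** — statistics of TEM-derived crystal measurements: the
  three morphology groups (near-isotropic cubo-octahedra, elongated
  prisms, bullet-shaped crystals), length/axial-ratio histograms and Tukey
  box-whisker summaries, two-sample Kolmogorov–Smirnov comparisons;
* **assemblage + micromag** — builds 3-D magnetosome-chain geometries from
  crystal populations (particles per chain, bending factor, grain
  separation, packing fraction) and computes equilibrium magnetization of
  the interacting SD ensemble by iterative Stoner–Wohlfarth relaxation
  with exact dipolar sums, simulating hysteresis, backfield, and FORC
  protocols;
* **forcproc** — FORC distributions ρ = −½ ∂²M/∂Ba∂Bb by local polynomial
  regression with variable (ridge-preserving) smoothing, central-ridge and
  backfield coercivity profiles;
* **unmix** — IRM acquisition-curve decomposition into cumulative
  log-Gaussian coercivity components (amplitude, B½, DP);
* **proxies** — S-ratio, HIRM, carbonate-free normalization, Verwey/Morin
  transition detection, down-core profile assembly;
* **synthetic** — seeded generators for all input kinds, so the entire
  pipeline is testable without measured data.

The core physical relations: an elongated SD particle switches at
`B_sw = μ0·ΔN·Ms` (ΔN from the analytic demagnetizing-factor formula for a
square-cross-section parallelepiped, Ms = 480 kA/m for magnetite), and
intact chains behave as non-interacting uniaxial "super-particles" whose
FORC signature is a sharp central ridge along Bu = 0.

## Worked example

```bash
python examples/02_chain_coercivity.py
```

```
single-particle switching field: 43.4 mT
isolated grains          Bc =  20.1 mT   Mrs/Ms = 0.492
straight chains of 5     Bc =  45.5 mT   Mrs/Ms = 0.493
collapsed chains of 5    Bc =  22.8 mT   Mrs/Ms = 0.458
```

The same 60×48 nm crystals more than double their bulk coercivity when
arranged in straight chains (chain dipolar coupling adds effective uniaxial
anisotropy), and lose that hardening again when the chains collapse —
which is why measured coercivities constrain how well magnetosome chains
survived burial. `Mrs/Ms ≈ 0.5` is the Stoner–Wohlfarth value for randomly
oriented uniaxial SD particles.

The other example scripts cover morphometry (`01`), FORC simulation and
central-ridge extraction (`03`), IRM unmixing (`04`), and down-core proxy
profiles (`05`); each prints its numbers with a line on what they mean.

A thin CLI mirrors the workflow for shell use:

```bash
magnetofossil make-fixtures --out-dir work --seed 1
magnetofossil morphometry work/crystals.csv --out work/summary.csv
magnetofossil simulate-forc work/crystals.csv --out work/forc.csv
magnetofossil process-forc work/forc.csv --out work/dist.csv
magnetofossil unmix-irm work/irm.csv --out work/components.csv
```

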