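# Methods

`magnetofossil` models the rock-magnetic expression of fossil
magnetotactic-bacteria magnetite and the measurement pipeline used to trace
it through sediment sections: crystal morphometry, chain-assemblage
micromagnetics, FORC simulation and processing, IRM unmixing, and bulk
proxies. This note records the models, the numerical choices, and what the
synthetic tests do and do not establish.

## Single-domain particle model

Crystals are treated as uniformly magnetized (single-domain, SD)
parallelepipeds of square cross-section, width W × W × length L (L ≥ W),
with saturation magnetization Ms = 480 kA/m (room-temperature magnetite).
Shape anisotropy is uniaxial along the elongation axis with switching field

    B_sw = μ0 · ΔN · Ms,

where ΔN = N_transverse − N_longitudinal is computed from the analytic
closed form for the magnetometric demagnetizing factor of a rectangular
prism (Aharoni's expression), using N_trans = (1 − N_long)/2 for the square
cross-section. ΔN is 0 for a cube and → 1/2 for an infinite rod; a 60×48 nm
magnetosome has B_sw ≈ 43 mT.

Cubic magnetocrystalline anisotropy is neglected. The package computes the
justification: equating the shape-anisotropy energy density
0.5·μ0·ΔN(r)·Ms² with the effective uniaxial barrier |K1|/12 of cubic
magnetite (K1 = −1.1×10⁴ J/m³) gives a critical elongation r ≈ 1.02, so any
crystal elongated beyond ~2% is shape-dominated. Exactly equant particles,
which would have zero anisotropy and an undefined easy axis, receive a
nominal ΔN floor of 10⁻⁴ (configurable; a strict mode rejects them
instead). The model is athermal (0 K): no thermal activation, so hysteresis
is purely the history of well occupancy. Temperature-dependent behaviour
and non-SD (vortex/multidomain) states are out of scope.

## Chain assemblages

Chains are built by drawing crystals with replacement from a measured or
synthetic population and placing them along a directed random walk:

    d_{i+1} = normalize((1 − b)·d_i + b·u),   u ~ uniform on the sphere,

with bending factor b ∈ [0, 1]: b = 0 gives straight chains, b = 1 an
isotropic random walk ("collapsed" chains). Centre-to-centre spacing is the
adjacent half-lengths plus a surface-to-surface grain separation (default
20 nm, the magnetosome-membrane scale); each particle's easy axis follows
the local step direction (elongation along the chain, as observed in
magnetotactic bacteria). Chains are dropped with uniform random position
and orientation into a cubic box sized so that total particle volume over
box volume equals the packing fraction (default 10⁻³), which sets the mean
inter-chain dipolar coupling. Chains may protrude through box faces but may
not approach another chain closer than one minimum particle width
(rejection sampling, 10⁴ retries). The bending rule is a documented
surrogate: it has the correct end-members (straight / isotropic) and a
monotone interpolation between them, but no claim is made that b matches
any particular published bending parameterization numerically.

## Equilibrium solver

Following the rapid approximate scheme appropriate for SD ensembles, the
Landau–Lifshitz–Gilbert equation is *not* integrated in time (γ and α are
carried as documentation constants only). Instead the ensemble is relaxed
by fixed-point sweeps: for each particle, the local field is the applied
field plus the exact all-pairs dipolar field (dense precomputed 3N×3N
coupling matrix; no periodic images or cutoffs at the ≤10³-particle sizes
used), and the moment is placed at the Stoner–Wohlfarth energy minimum
nearest its current orientation, in the plane spanned by the easy axis and
the local field. The in-plane energy

    e(θ) = ½ sin²θ − h∥ cosθ − h⊥ sinθ,   h = B_loc / B_sw,

has at most two minima; they are located on a 5° grid and polished with
guarded Newton steps (≈ machine precision). Retaining the nearest well
makes the dynamics hysteretic; at an exact switching bifurcation the
current well is kept, for reproducible paths.

Synchronous (Jacobi) sweeps develop two-sublattice oscillations under
strong dipolar coupling, so each sweep is mixed with the previous state,
m ← normalize(m + 0.7·(m_SW − m)); convergence is judged on the *undamped*
update angle (default tolerance 10⁻⁴ rad, max 1000 sweeps), so the fixed
point is unchanged while iteration counts drop about fivefold. A
non-converged relax is flagged on the state rather than raised. For
non-interacting ensembles one sweep is exact. Oracle tests for
isotropically oriented ensembles use a spherical Fibonacci lattice of easy
axes rather than random draws: at n = 1000 the Monte-Carlo orientation
noise on Mrs/Ms (σ ≈ 0.009) would otherwise be as large as the quantity
being checked, and the lattice reduces it to O(1/n) while still
representing an isotropic ensemble.

## Field protocols

Fields are reported as B = μ0·H in mT; magnetization is normalized by
ensemble saturation (volume-weighted). Hysteresis sweeps saturation
(default 300 mT) → −saturation → saturation carrying state; Bc is the
interpolated descending-branch zero crossing, Mrs/Ms the zero-field
descending remanence, and Bcr the zero crossing of the backfield remanence
curve (state carried down the descending branch; a zero-field relax
measures each remanence). The FORC protocol covers Bc ∈ [0, bc_max],
Bu ∈ [−bu_max, bu_max] (defaults 160 and 60 mT) with reversal fields
Ba ∈ [−(bc_max+bu_max), bu_max] and measurement fields Bb ∈ [Ba,
bc_max+bu_max] on a common lattice anchored at zero field, so the Bb = 0
backfield column exists exactly. Repeated realizations redraw particles
and geometry from the population (fresh seeds) and average the grids
pointwise, emulating repeated sampling from TEM observations; whether
orientations are also re-randomized per realization is a free choice here,
and they are. A `bb_max` option truncates each reversal curve early (e.g.
at Bb = 0) when only the backfield column is needed, at ~3× lower cost.

## FORC processing

The FORC distribution ρ = −½ ∂²M/∂Ba∂Bb is estimated by local second-order
polynomial least squares with variable smoothing. Window half-widths in
rotated coordinates (Bc = (Bb−Ba)/2, Bu = (Bb+Ba)/2; rotated lattice step
δ/2) follow s(B) = min(s₁, s₀ + λ·|B|/δ) per axis, with the default
parameter set {s_c0, s_c1, s_b0, s_b1, λ_c, λ_b} = {7, 7, 2, 7, 0.1, 0.1};
the small s_b0 floor near Bu = 0 preserves the central ridge. Windows
shrink at data edges (out-of-support points are dropped; fewer than 8
points leaves the estimate undefined). The distribution is regridded to a
regular (Bc, Bu) grid at the raw resolution by linear interpolation.

Two estimator properties worth knowing: (i) the estimate is exact for
surfaces quadratic in (Ba, Bb) — the basis of the closed-form test
M = Ba·Bb → ρ = −0.5; (ii) because the ridge-preserving windows are
diamonds in index space, the mixed term couples weakly to cubic
pure-Bb structure (Σ di·dj³ ≠ 0), giving a truncation bias of order
h³·M''' — about 10⁻⁴ in the smooth-surface tests, far below genuine
distribution amplitudes. This bias is inherent to variable-smoothing
window geometry, not a defect of the solver.

The central-ridge fraction is defined as the *net* (signed) integral of ρ
over |Bu| ≤ halfwidth divided by the net integral over the whole plane.
Exact SW hysterons produce, besides the Bu = 0 ridge, a reversible-
difference lobe at Bu < 0 that carries roughly half the |ρ| mass but zero
net mass (verified against an independent brute-force hysteron oracle), so
the signed fraction — not the |ρ| fraction — is the quantity that is ≈ 1
for non-interacting SD assemblages and falls when collapsed chains or
strong interactions spread irreversible signal in Bu. Values slightly
above 1 can occur when the outside-band net mass is slightly negative.

Backfield coercivity profiles are the negative derivative (3-point local
linear regression) of the M(Ba, Bb = 0) column versus reversal-field
magnitude; Bcr is the interpolated zero crossing of that column.

## IRM unmixing

IRM acquisition curves are modelled as sums of cumulative log-Gaussians
A_j·Φ((log₁₀B − log₁₀B½_j)/DP_j) — the classic B½/DP parameterization;
a skewed family is deliberately omitted since B½ and DP are the quantities
carried downstream. Fitting is bounded nonlinear least squares (lmfit) on
the unit-normalized curve (making fractions exactly scale-invariant), with
multi-start: starting medians at quantiles of the positive derivative
spectrum, seeded jitter, default 20 restarts, best fit kept, components
ordered by B½. Bounds: amplitudes ≥ 0, log₁₀B½ within the data range ± 1
decade, DP ∈ [0.02, 1.5]. The number of components is user-set (three for
the biogenic + soft/hard detrital decomposition); a request with fewer
than 3 data points per free parameter is refused. Optional isotonic
(cumulative-maximum) pre-repair handles non-monotone measured curves and
is flagged in the diagnostics.

## Proxies and low-temperature curves

S-ratio = −IRM₋₀.₃T/IRM₁T with the backfield remanence stored signed
(negative). HIRM = (IRM₁T − |IRM₋₀.₃T|)/2, written with an absolute value
so that a fully soft assemblage gives exactly 0 under either sign
convention for the −0.3 T remanence. Carbonate-free values divide by the
non-carbonate mass fraction (1 − carbonate_fraction) — the package's
reading of the "carbonate-free basis" convention. Low-temperature curves
are normalized to a stated reference (ZFC/FC warming to the FC moment at
10 K; room-temperature-SIRM cycling to its initial value), and transitions
(Verwey window default 90–130 K, Morin 240–270 K) are located as the
extremum of dM/dT with a three-point quadratic refinement; featureless
windows return the boundary with a warning flag rather than a spurious
peak.

## Synthetic data

The generators produce the four input kinds the pipeline consumes, with
the statistical structure the analysis assumes: log-normal crystal lengths
with normal axial ratios clipped to (0, 1] and an exact-quota bullet share
(round(n·fraction), so small fixtures carry exact percentages); IRM curves
as component sums on 80 log-spaced fields with multiplicative Gaussian
noise; depth-ordered down-core tables with linear trend segments plus
noise. Everything is deterministic under a fixed seed. The generators do
not emulate TEM imaging artefacts, 2D projection bias of 3D crystals,
instrument drift, or measurement-time effects — so passing tests establish
correctness of the computational chain under the stated statistical
assumptions, not robustness to those real-data complications.

Population parameters for the three-stage demonstrations (median lengths
55/65/75 nm, log-sd 0.25, mean axial ratios 0.85/0.78/0.70, sd 0.08,
bullet shares ≲ 1%) are fixed, field-plausible choices for pelagic
magnetofossil assemblages whose size increases and elongation grows across
a warming interval; they are inputs to the trend tests, not fitted values.

## Problem sizes

Simulation sizes are chosen so the full suite runs in minutes on one CPU
while keeping each scientific contrast well resolved: hysteresis trend
tests use 30 chains per configuration (30–300 particles); central-ridge
runs use 300 isolated particles, 50 FORCs, 10 realizations; the
size-to-coercivity trend uses 10 chains of 10 at 32 FORCs, 10
realizations, with reversal curves truncated at Bb = 0. Production-scale
settings (60 chains, 100 FORCs, 100 realizations) are available through
the same interfaces.

## Known limitations

* The bending-factor rule is a surrogate with correct end-members; absolute
  coercivities at intermediate b are parameterization-dependent.
* The asymptotic KS p-value is used; figure-level "statistically different"
  statements are reproduced qualitatively, and exact small-sample p-values
  are not computed.
* The dense dipole matrix costs O(N²) memory; ensembles beyond ~5×10³
  particles need a different interaction backend.
* Measured-instrument FORC files are supported only as a plain
  comment-header triple format; drift and first-point corrections are
  pass-through hooks, not implemented corrections.
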