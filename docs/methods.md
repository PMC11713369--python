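# Methods

`brachyq` computes beam-quality correction factors for detectors used in
dosimetry around high-dose-rate ¹⁹²Ir brachytherapy sources, together
with the surrounding measurement formalism (TG-43 comparison, influence
corrections, GUM uncertainty budget) and the synthetic data needed to
exercise all of it.  This note records the models, the approximations,
and the choices made where the design was genuinely open.

## The dosimetric model

A detector calibrated in a ⁶⁰Co reference field measures dose to water
around an ¹⁹²Ir source through

D_w,Q = M_Q · N_D,w,Qo · k_Q,Qo,

where M_Q is the influence-corrected reading and the beam-quality
correction is the double dose ratio

k_Q,Qo = [D_w / D̄_det]_Q / [D_w / D̄_det]_Qo · (R_Qo / R_Q).

Both ratios are evaluated by Monte Carlo photon transport: the user
quality Q is an isotropic ¹⁹²Ir point source centered in a 30 cm
diameter water sphere with the detector on the transverse bisector at
an away-distance y ∈ [1, 10] cm; the reference quality Qo is a
collimated ⁶⁰Co point source forming a 10 × 10 cm² field at 100 cm,
with the detector at 5 cm depth in a 30 cm water cube.  D_w is scored
in a 0.5 mm cubic water voxel at the same point with the detector
removed.  The intrinsic energy-response ratio R_Qo/R_Q is an explicit
constant (default 1) so users can override it.

The detector-response decomposition removes one component class at a
time (stem → electrode → wall → bare cavity), each removed solid
reverting to the medium that surrounds it (stem/wall to phantom water,
electrode to cavity gas).  The sequential factors

p_stem = D_cel,wall/D_det, p_cel = D_wall/D_cel,wall,
p_wall = D_air/D_wall, p_repl = D_w/D_air

telescope exactly to D_w/D̄_det when computed from shared tallies; the
replacement rung for detectors without an electrode (the microdiamond)
is skipped and p_cel ≡ 1.

## Transport engine

Photons are transported analogically by optical-depth ray marching
through a constructive-solid-geometry scene (spheres, finite cylinders,
boxes; innermost-first priority with boundary points resolved inward).
Interaction channels are sampled from the bundled partial cross
sections; Compton scattering uses Klein–Nishina rejection sampling,
coherent scattering the Thomson angular law (direction change only),
photoelectric and pair events absorb the photon (annihilation quanta
are dropped and ledgered).  The photon cutoff is 1 keV.  An analog
energy ledger (emitted = transferred + escaped + discarded) is checked
to floating precision in the tests.

Doses use the track-length collision-kerma estimator; an analog
collision-site estimator is accumulated as an internal cross-check.
Statistical errors come from 20 batches.  Randomness is a counter-based
SplitMix64 stream per history, so results are bit-reproducible for a
seed and paired runs consume identical numbers wherever their
geometries coincide.  Ratios from such correlated runs are formed batch
by batch (the shared noise cancels); their quoted value is the ratio of
overall means so sequential perturbation factors telescope exactly.
This supersedes plain quadrature propagation, which was measured to
overstate ladder-factor errors by an order of magnitude; quadrature is
still used across independent beam qualities.

Variance reduction is mixture importance sampling of the emission
direction: a cone (or, for the collimated source, a tangent-plane
square) aimed at the detector with probability q = 0.6–0.8, the
remainder isotropic/full-field, with exact weight restoration.  The aim
radius grows with away-distance so near-detector scatter sources are
also sampled at low weight.  For the detector-absent D_w in the
spherically symmetric ¹⁹²Ir phantom the default scorer is a spherical
shell with the voxel's 0.5 mm radial width: its expectation equals the
on-axis voxel dose by symmetry (transverse voxel extent contributes
< 10⁻⁴ relative) while every history can score.  The literal cube
scorer remains available (`voxel_scorer="cube"`).  The ⁶⁰Co reference
D_w scorer is a thin disc (radius 1.25 cm, 0.5 mm thick) at 5 cm depth,
face-on to the beam: the field is laterally flat there, and the disc
intercepts ~10³ times more histories than a 0.5 mm cube.

### Electron physics

The default physics level is the kerma approximation: secondary
electrons deposit locally, so doses equal collision kerma.  Near an
¹⁹²Ir source the secondary ranges (≲ 2 mm in water) are comparable to
cavity sizes, so quantities that hinge on electron transport are
reproduced in direction, not magnitude.

The optional `simple_csda` level adds a first-moment electron kernel:
every photon chord within reach of the scoring regions emits its
*expected* secondary current — a photoelectron component carrying the
full photon energy and a Compton component carrying the mean
Klein–Nishina recoil energy — from a uniformly sampled point on the
chord, directed forward, depositing uniformly over the water CSDA range
(Berger–Seltzer collision stopping power, I = 75 eV, density-scaled in
other media).  Under charged-particle equilibrium this reproduces
collision kerma to ~2% (tested); around a silver-bearing electrode it
reproduces the sign of the overresponse (p_cel < 1).  The published
magnitude of that effect and its strong growth with distance require
condensed-history transport with angular deflection and delta rays,
which is outside this engine's scope — the acceptance suite therefore
checks sign and trend-consistency only.

## Physics data

Coefficient tables (μ/ρ, μ_en/ρ and four partial channels on an 81-node
log grid, 1 keV–3 MeV) are generated once by an analytic compilation
and shipped as plain text: exact free-electron Klein–Nishina for the
incoherent channel (total closed form; energy-transfer moment by
quadrature), and power laws anchored on accepted water values for
photoelectric (Z⁴·⁵E⁻³·², no edge structure), coherent (Z²·⁵E⁻²) and
near-threshold pair production (Z²).  μ_en is assembled consistently
from the same channels with radiative losses neglected.  Spot checks
against accepted water data agree within ~2% over 30 keV–2 MeV, which
propagates into k_Q,Qo far more weakly because both qualities share the
same tables.  Electron binding (incoherent scattering function) is
neglected; below ~30 keV in high-Z media the tables are qualitative.

The ¹⁹²Ir spectrum is the bare-nuclide gamma line table (16 lines,
weighted mean 0.372 MeV); an encapsulation-hardened variant (effective
0.4 mm steel filter) ships alongside.  The fluence spectrum of an
encapsulated clinical source would differ mainly through a scattered
low-energy tail; this is a declared fidelity gap.  ⁶⁰Co is its two
gamma lines.

## Detector models

The ten detectors are parametric builds from their published cavity
dimensions: cylindrical (or, for the CC003, spherical) air cavities,
full-length coaxial electrodes of the stated diameter, concentric wall
shells (graphite inner + PMMA outer for the PTW chambers, single C552
for IBA/Exradin), and — vendor blueprints being unavailable — a stem
modeled as a wall-material cylinder of the outer wall radius and three
cavity lengths, abutting the cavity.  The microdiamond is a 2.2 mm
disc of ~1 μm thickness (matching its 4·10⁻³ mm³ volume) with diamond
window and epoxy in front, and its diamond base as the "stem", facing
the source along the transverse axis.  Chamber stems are parallel to
the source long axis in the ¹⁹²Ir phantom and perpendicular to the
beam in the reference field.  Cavity volumes computed from these models
agree with nominal values within the documented 25–30%.

## Measurement protocol and synthetic data

Influence corrections follow the standard conventions: k_TP to
T₀ = 20 °C, P₀ = 101.325 kPa (reference conditions are not part of the
published record; the TRS-398 convention is adopted), polarity as the
mean-of-magnitudes ratio, and ion recombination by the two-voltage
method in its continuous-beam near-saturation form
k_ion = ((V₁/V₂)² − 1)/((V₁/V₂)² − M₁/M₂).  Budget components combine
in quadrature; the bundled reference budget reproduces the published
1.55% (k = 1) combined uncertainty at the 1 cm away-distance.

The synthetic generator emulates repeated timed charge collections in
the TG-43 field of a source of known air-kerma strength: four 5-minute
repeats per point, multiplicative reading noise (0.1%), and isotropic
per-reading positioning offsets of 0.12 mm so that the standard error
of a four-repeat mean at 1 cm reproduces the documented 1.2% dose
scatter.  Environmental, polarity and two-voltage fields are generated
self-consistently so the correction chain recovers the truth exactly
at zero noise.  What the generator does not emulate: correlated
repositioning errors between repeats, electrometer drift and leakage,
catheter sag, or scatter-condition differences between phantoms — so
passing round-trip tests demonstrate the correctness of the analysis
chain, not the absence of systematic effects in a real water tank.

Scan alignment fits a parabola over up to nine points around the peak
of a symmetric profile; monotone or flat profiles raise.

## Problem sizes and numerical choices

Desk-scale defaults: 4·10⁵ histories per run in the test suite and
2·10⁶ (5·10⁶ for the 10 cm ¹⁹²Ir geometry) in the reproduction script,
20 batches, chunked vectorized transport (2¹⁸ photons per chunk).
These sizes put ~0.3–1% statistical errors on the Farmer-chamber
k_Q,Qo values.  Log-log interpolation is used on all coefficient
tables with hard range errors instead of extrapolation; surface
crossings push 10⁻⁷ cm past boundaries; ray-marching is capped at 3000
segments per flight set (stragglers are retired to the escaped-energy
ledger).

## Known limitations

* Kerma-level physics cannot reproduce electron-transport-sensitive
  results: stopping-power ratios are replaced by μ_en/ρ ratios (the two
  differ by ~2% between these qualities), effective-point-of-measurement
  and gradient effects inside cavities are absent, and the high-Z
  electrode overresponse is reproduced in sign only.  Farmer-chamber
  k_Q,Qo at 1 cm consequently lands a few percent above the published
  values: the volume-averaging part (the dominant physics) is captured,
  the electron-transport corrections that pull it down are not.
* The coefficient compilation has no absorption edges and free-electron
  Compton only.
* Point-source TG-43 with identity radial-dose function by default;
  line-source geometry factors and 2D anisotropy are out of scope.
* The stem and internal electrode geometries are approximations to
  unpublished blueprints.
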