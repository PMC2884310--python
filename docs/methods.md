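# Methods

`brachykernel` computes photon dose rates around encapsulated Cs-137 and
Ir-192 brachytherapy sources placed inside heterogeneous applicators, using
a deterministic point-kernel ray-tracing model rather than stochastic
transport.  This note records the model, its data, the reconstruction
assumptions behind the packaged applicators, and the numerical choices.

## The point-kernel model

A volumetric source is replaced by a set of weighted point emitters.  For
an emitter at r' with per-line emission rate R_i = A·p_i (activity times
line yield), the dose rate at r is

    D(r) = Σ_i  R_i E_i · exp(−Σ_j μ_j(E_i) s_j) · B(path, E_i) / (4π|r−r'|²)
           · (μ_en/ρ)_water(E_i) · 1.602·10⁻¹³ J/MeV · 10³ g/kg · 3600 s/h

summed over emitters and spectrum lines.  The segments s_j are the
per-material physical path lengths returned by the ray tracer, μ_j the
linear attenuation coefficients, and B the effective buildup factor of the
layered path.  The dose quantity is collision kerma in water (the kerma
approximation — valid where charged-particle equilibrium holds, i.e.
everywhere outside the first millimetre around the source at these
energies).  One conversion chain is used throughout; the constants are
dimensionally assembled as above.

### Buildup factors

Single-material buildup uses the five-parameter geometric-progression (GP)
form: B(x) = 1 + (b−1)(K^x−1)/(K−1), with

    K(x) = c·x^a + d·[tanh(x/x_K − 2) − tanh(−2)] / [1 − tanh(−2)]

and the linear branch B = 1 + (b−1)x when |K−1| < 1e−9.  b is the buildup
at 1 mean free path; B(0)=1; results are clamped to ≥ 1.

Two stacked materials are composed with the two-region rule, branch chosen
by effective atomic number (layers numbered source → detector):

* Z1 > Z2 (the usual capsule-then-tissue case):
  B = B2(l2) + [B1(l1)−1]/[B2(l1)−1] · [B2(l1+l2) − B2(l2)]
* Z2 > Z1 adds a Compton-fraction transfer term weighted by exp(−1.7·l2)
  and (μC/μ)₁/(μC/μ)₂·(1 − exp(−l2)).

Note the second branch is sometimes printed in the literature with
"B2(l2+l2)" in the bracketed difference; this implementation follows the
classical two-region reading B2(l1+l2).

Paths with more than two layers are collapsed by a left fold from the
source side: the two innermost layers are combined, the pair is treated as
a pseudo-layer of the outer material carrying the summed optical
thickness, and the running factor is corrected by the ratio of the
combined factor to the pseudo-layer's own GP factor,
B ← kalos(m₂, l₁+l₂, m₃, l₃) · [B₁₂ / B_m₂(l₁+l₂)].  This fold is the
package's own approximation — the two-region rule itself says nothing
about N > 2 — and is exercised by tests but not claimed from any
reference.  Layers thinner than 1e−4 mfp (mm-scale air channels) are
dropped before composition because they destabilize the ratio term while
being optically negligible; their attenuation is still counted exactly.
The ratio is also guarded below l1 = 1e−6 mfp, where the exact limit (the
outer layer's own factor) is returned.

### Physics data

The packaged tables (`src/brachykernel/data/*.tsv`, regenerable with
`scripts/make_physics_tables.py`) cover 0.05–1.5 MeV for water, air,
stainless steel (8.02 g/cm³, iron photon data), tungsten, the 80%Pt/20%Fe
capsule alloy (21.644 g/cm³, density-weighted mixture μ), PMMA, a Cs-glass
pellet surrogate ("pollucite", 2.9 g/cm³) and iridium metal:

* μ/ρ and μ_en/ρ are transcribed from the standard photon-attenuation
  compilations (accuracy ~1–2%); μ interpolates log-log in energy,
  exact at nodes.
* Compton fractions μC/μ are computed from the Klein–Nishina cross-section
  and the tabulated μ/ρ (clamped to ≤ 0.999); they only enter the rarely
  used low-Z-over-high-Z branch.
* GP coefficients are approximate values assembled from the shielding
  literature: smooth in energy, anchored so that b = B(1 mfp) matches
  published point-isotropic buildup magnitudes.  No GP data for platinum
  or iridium could be vendored with confidence, so the alloy and iridium
  use tungsten's coefficients (adjacent Z) — a documented stand-in.  GP
  coefficients interpolate component-wise, linearly in log(E).
  Buildup interpolation/extrapolation is the dominant model uncertainty
  (several percent on absolute dose rates).
* Spectra: Cs-137 is the single 0.662 MeV line with yield 0.851 (the Ba K
  X-rays contribute < 0.5% and are folded into that convention); Ir-192 is
  a 25-line gamma + K X-ray spectrum with yields rescaled by one common
  factor so the total is exactly 2.364 photons per decay.

### Source strength

Air-kerma strength S_k (μGy·h⁻¹·m²) converts to contained activity through
the unfiltered spectrum-weighted air-kerma rate constant
Γ = Σ p_i E_i (μ_en/ρ)_air(E_i)/(4π·1 m²), ≈ 0.0757 μGy·h⁻¹·m²/MBq for
Cs-137 and 0.1126 for Ir-192 with the packaged data.  Capsule filtration is
then applied by the ray trace through the capsule geometry.  Because a
measured S_k already includes capsule filtration, this chain slightly
overcounts the capsule (~3–5% transversally); it is kept because it needs
no per-source filtration corrections and stays inside the comparison bands.
Linear reference air-kerma rates (μGy·h⁻¹·m²·cm⁻¹) are multiplied by the
physical capsule length — for the CDC-type source (2.0 cm capsule, 1.35 cm
active) this reproduces both the published reference-point dose rates and
the classical 15/10/10 + 10/10 mg-Ra-eq loading; multiplying by the active
length instead would underpredict by ~30%.

Line sources are discretized into ceil(L/Δl) equally weighted emitters at
segment centers on the axis.  Δl = 0.005 cm (the paper-scale value) is the
reference-point default; grids default to Δl = 0.05 cm for speed, which
changes near-field doses by well under the refinement convergence bound
checked in the tests.  Self-absorption in the active pellet is handled by
the trace (the pellet is a geometry region); no separate anisotropy
function is applied — the kernel is purely line-of-sight.

## Applicator reconstructions

Coordinate frame: origin at the external os on the tandem axis, +y
superior, +x lateral, +z anterior.  Angles are degrees in all public
interfaces.

The published tables do not print the axial source positions, so the
stacking is reconstructed and fixed: capsules sit gap-free from the inner
fundus end downward, the capsule physical length (2.0 cm for CSA-1/CSA-2
and CDC-J) setting the pitch, with the train top 6.2 cm (long tube) or
4.2 cm (medium tube) above the os.  This is the dominant uncertainty in
reference-point comparisons and is why those comparisons carry a 10% band.
Ovoid sources sit at (±separation/2, −depth, 0) with axes tilted in the
sagittal plane (−40° BRIT, +30° Fletcher).

Manchester points A (±2, 2, 0) and B (±5, 2, 0) are defined in the tandem
frame and rotate with tandem angulation — the only reading under which the
tandem contribution at point A is insensitive to angulation, as the
published angulation sweep shows.  ICRU bladder/rectum points are
anatomy-dependent and are plain user inputs with no claimed default.

With-applicator geometries add the steel tube shells (tandem ID 0.5 / OD
0.6 cm for the BRIT type; ID 0.4 for the Fletcher tandem; ovoid tubes ID
0.5 / OD 0.6).  Tube interiors are treated as water-equivalent rather than
air-filled, matching the homogenized applicator treatment the engine
reproduces; modeling the lumen as air would *reduce* the apparent wall
effect by ~0.8 percentage points because the air path displaces water
attenuation.

The shielded vaginal cylinder is a 15 cm PMMA shell (OD 3.0 cm, 0.5 cm
wall) on a 0.4 cm OD steel tube, with an optional 0.8 cm thick tungsten
sector (90/180/270°, 10 cm long, centered on the source plane) in the air
gap.  Azimuth 0° is the open +z reference direction; the shield is
centered on 180°.  The mHDR source (1 Ci default) sits on the axis 4.5 cm
from the tip.

The HDR stepping-source plan (20 dwells: 14 tandem, 3 per ovoid, 5 mm
step) represents each dwell as a source instance; reported plan dose rates
are dwell-time-weighted averages, and the prescription utility rescales to
a prescribed dose at the mean of the left/right A points.  The absolute
HDR source strength is configurable (default 40800 μGy·h⁻¹·m², a nominal
10 Ci source) and cancels out of normalized outputs.

## Numerical choices

* Ray tracing: all surface-crossing parameters of every primitive are
  collected along the chord, crossings closer than 1e−9 cm are merged, and
  interval midpoints are classified against the prioritized region stack;
  adjacent same-material segments merge.  Segment lengths therefore sum to
  the chord length to float precision, and grazing rays resolve
  deterministically.
* Interpolation: log-log for μ and μ_en/ρ; linear-in-log(E) for GP
  coefficients; both exact at grid nodes.
* Grid nodes inside active pellets are masked NaN, never extrapolated;
  contour extraction (marching squares with linear edge interpolation,
  scikit-image) skips masked cells.
* Percent isodose levels are scaled by the trilinearly interpolated grid
  dose at the normalization point.
* Output units: cGy/h for LDR tables, Gy/h selectable for HDR.
* The engine contains no randomness; identical inputs give byte-identical
  outputs.

## Problem sizes used in the shipped checks

Reference-point evaluations run at Δl = 0.005 cm (1100 emitters for the
five-source BRIT loading, 1350 for the Fletcher loading).  Demonstration
grids use Δl = 0.05–0.1 cm and 21–41 nodes per axis; the ray-length
conservation property is exercised on 10⁴ random chords per applicator.

## Limitations

* Line-of-sight kernel: no angular-dependent buildup, no slant-path
  corrections beyond the traced chord, no electron transport, no
  TG-43-style anisotropy function.
* The GP coefficient tables are approximate vendored constants, not a
  certified copy of a standard library; absolute buildup is good to a few
  percent in the Compton regime, and worse below ~0.1 MeV.
* The N>2-layer fold and the tungsten-for-platinum GP stand-in are
  documented approximations.
* Validation targets are reference-point dose rates of idealized applicator
  loadings; patient anatomy, applicator fixtures and shielded ovoids are
  out of scope.  Passing tests demonstrate consistency with the published
  idealized-geometry values, not clinical accuracy in tissue of
  heterogeneous density.
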