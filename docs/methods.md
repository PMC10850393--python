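# Methods

## Scope and units

`pedimpact` implements the analysis layer of a pedestrian-impact head-injury
study: everything between a crash solver's outputs and the injury
conclusions. It performs no finite-element solving, contact mechanics or
material modeling; solver outputs are emulated by seeded generators so the
whole chain is testable offline. Internal units throughout: time ms, length
mm, linear acceleration g (1 g = 9.80665 m/s²), angular velocity rad/s,
stress MPa, strain dimensionless, mass kg. A velocity in mm/ms is
numerically an m/s, and ×3.6 converts it to km/h.

## Injury criteria

**HIC15.** For a non-negative resultant head acceleration a(t) in g,
HIC = max over t₁ < t₂, t₂−t₁ ≤ 15 ms of (t₂−t₁)·[mean a over (t₁,t₂)]^2.5,
with the duration factor in seconds. The search is exact over all sample
pairs: a trapezoid running integral gives every window mean, and all window
widths up to the 15 ms cap are scanned. Ties break toward the earliest
window start. The implementation is validated against a brute-force O(n²)
enumeration, and against the closed form 0.015·a^2.5 for constant pulses.
By default the resultant is computed after zero-phase CFC 1000 low-pass
filtering of the axis channels (a 2-pole Butterworth run forward and
backward, i.e. a 4-pole zero-phase response with unit DC gain; class
cutoffs 100/300/1000/1650 Hz for CFC 60/180/600/1000). Whether the original
study filtered before HIC is not stated in its text; the filter class is
configurable and can be disabled.

**BrIC.** √Σ_axis (max_t |ω_axis(t)| / ω_critical,axis)². The critical
values default to (66.25, 56.45, 42.87) rad/s about x, y, z — the values
from the rotational-criterion literature; the study itself never prints
them, so they are exposed in configuration. BrIC is invariant to sign flips
and time reversal by construction.

**MPS.** The global maximum of the first-principal-strain field over
elements and time, reported with its arg-max element and instant. Strain
arrives as per-element scalars; tensor eigen-decomposition is upstream
(solver-side) and out of scope.

**CSDM.** The volume fraction of brain elements whose strain ever strictly
exceeds a threshold (default 0.25). "Ever" makes the measure cumulative: an
element that exceeds transiently and relaxes still counts, so CSDM is
non-decreasing over growing time prefixes.

**Skull fracture area.** The summed shell area of elements whose von Mises
stress ever strictly exceeds the cortical-bone fracture stress (default
65 MPa), each element counted once. Reported fracture stresses for skull
bone span roughly 32–128 MPa depending on bone type; 65 MPa is the
conventional single-value threshold.

**Flags.** Strict `>` is used where thresholds are worded as exceedance
(HIC 700 reference, 0.30 tissue-damage strain, 65 MPa stress); the diffuse
axonal injury flag uses `CSDM ≥ 0.49` because that criterion is worded as a
fraction being reached.

## Risk model

AIS4+ risk is a two-parameter Weibull CDF P(x) = 1 − exp(−(x/λ)^k). Two
anchors determine it in closed form:
k = ln(ln(1−p₁)/ln(1−p₂)) / ln(x₁/x₂), λ = x₁/(−ln(1−p₁))^(1/k).
The BrIC curve uses the two published anchors (1.0, 50%) and (1.5, 80%),
giving λ ≈ 1.193, k ≈ 2.078. The MPS curve has a single published anchor
(0.89, 50%); a one-anchor family is underdetermined, so by default its
shape is borrowed from the fitted BrIC curve and its scale solved from the
anchor. This is a deliberately minimal assumption — the anchor is the
median regardless of the borrowed shape — and both the shape source and the
anchors are configurable. No CSDM risk curve ships by default (only the
0.49 DAI flag); the slot accepts user anchors.

## Kriging mesh morphing

The transform is a dual radial-basis interpolant per output coordinate:
f(x) = c₀ + Cx + Σᵢ wᵢ k(|x − pᵢ|), with the side conditions Σwᵢ = 0 and
Σwᵢpᵢ = 0 that make the polynomial drift absorb the affine part. Kernels
offered: |r| (linear), |r|³ (cubic, default) and r²log r (thin-plate). The
cubic default follows common practice in FE-mesh parameterization; the
source study names only "Kriging interpolation", so the kernel and drift
order are configuration, not claims about that study. Control points are
centered and isotropically scaled before the solve for conditioning, and
the fit verifies landmark exactness to 1e-6 mm. With linear drift, any
affine landmark correspondence is reproduced exactly everywhere — which is
why morphing a stylized humanoid between two statures (a uniform or
diagonal-affine correspondence) reproduces target anthropometry to within
mesh tolerance. Coplanar or duplicate control points make the system
singular and are rejected by name. Transforms are applied to node blocks in
chunks; chunking cannot change results since each node maps independently.

Surface averaging assumes template-registered (vertex-corresponding)
meshes; registration itself is out of scope. Anthropometric widths are
measured as landmark separations (shoulder left–right along Y, thorax
front–back along X), heights as landmark Z above the mesh floor, stature as
the bounding-box vertical extent. The optional weight estimate is enclosed
volume (divergence theorem on the closed surface) times a uniform
1000 kg/m³ density and is flagged approximate: how the original morphed
model's mass was computed is unstated.

## Biofidelity corridors

Cadaver response curves are normalized to a standard body mass with
mass-ratio cube-root scaling: λ = (m_std/m_subj)^⅓, force × λ², deflection
× λ (equal-density, equal-modulus assumptions), so absorbed energy scales
by λ³ and the operation is exactly invertible. The exponent set is the
literature-standard one; the study defers its exact normalization to
supplementary material that is not reproduced, so alternative exponents are
accepted in configuration. Corridors resample pooled curves onto a uniform
200-point grid over the common abscissa; the reference is the pointwise
mean and the band either mean ± width·SD (default width 1, the most common
convention — the study states no width) or the min/max envelope. A
surrogate curve passes when at least a configured fraction (default 0.9) of
its resampled points lies inside the band. The component validation
presets (head ball 1.213 kg / 48 mm / 8.0 m/s; head rotation 7400 rad/s²;
chest pendulum 23 kg / 152 mm / 2.76 m/s; lower-limb shear and bending
6.25 kg / 40 km/h with 400 N axial preload and their published reference
ranges) are shipped as serializable catalog entries.

## Impact kinematics

Contact is the first time the tracked head point reaches within a tolerance
(default 5 mm) of the vehicle surface. For planes, when the approach
carries through the surface the event is attributed to the sample nearest
the geometric crossing (robust to the tolerance triggering a sample or two
early); a grazing pass that never crosses uses the first within-tolerance
sample; no contact is a result, not an error. Velocity at contact is a
central finite difference (one-sided at ends). The intrusion angle is
measured between the velocity vector and the horizontal plane — matching
the regulatory 60° headform convention — with a surface-normal-relative
variant behind a flag, since the source study does not state its
convention. Rotation radius is an algebraic (Kåsa) least-squares circle fit
on the SVD best-fit plane of the pre-contact path segment; collinear
segments return an infinite-radius sentinel.

## Synthetic generators

Every generator is a pure function of (spec, seed) and returns
machine-readable ground truth so its consumer can be tested closed-loop.

- **Crash pulses**: haversine (default — the standard smooth band-limited
  crash idealization), triangular or constant resultant shapes, distributed
  over three axes along a seed-drawn unit direction so the per-sample
  resultant equals the shape exactly. Default 10 samples/ms.
- **Angular velocity**: per-axis band-limited waveforms (windowed sinusoid
  sums) rescaled so each axis peak is met exactly on the grid.
- **Brain strain fields**: Gaussian rise-then-fall bumps per element. The
  exceedance subset is chosen so the crossing volume fraction matches the
  requested value to within one element's volume share (exactly, for equal
  volumes and representable fractions); one designated element carries the
  field maximum precisely at contact_time − peak_lead. The lead defaults to
  3 ms and must lie in the 1–5 ms band in which rotational loading peaks
  before head contact. Rise-then-fall traces make the cumulative semantics
  of CSDM observable.
- **Skull stress fields**: same bump construction with a caller-specified
  supra-threshold element subset — the fracture-area ground truth.
- **Humanoid surface**: a loft of elliptical cross-sections with apex caps,
  proportioned from 50th-percentile male reference dimensions (stature
  1690 mm; eye 1568, shoulder 1387, perineum 790, tibia 444 mm; shoulder
  width 431, thorax depth 280 mm) and scaled linearly with stature, with
  lateral girth additionally scaled by √(m/m_isometric). Vertical extent
  equals the requested stature exactly; seeds jitter only local lateral
  vertex positions (±1 mm), never landmarks or global dimensions. This is a
  stylized fixture — only landmark geometry and global dimensions matter to
  the morphing stage — with no anatomical realism.
- **Cadaver curves**: the base curve plus additive Gaussian noise truncated
  at 4 SD (bounded), one subject mass per curve about the pool mean
  (the reference pool is 68 kg at 169 cm).
- **Wrap trajectories**: a planar sagittal rigid-link chain. The head
  travels at the chain tip (radius = Σ segment lengths, default
  tibia/femur/torso+head split of the reference stature); the pivot is
  carried forward at a seed-jittered fraction (0.3–0.7) of vehicle speed,
  which is what lets realistic target combinations (e.g. 81° at 118 ms with
  head speed ≈ vehicle speed) be met — a strictly fixed ground pivot with
  the full-chain radius cannot reach them, since they require a mean
  angular rate above the terminal rate. The chain angle follows a linear
  angular-rate profile solved in closed form from the contact targets;
  infeasible targets (terminal rate above twice the mean rate, or a 0°
  angle from an upright start) are rejected. The scene is translated so the
  head meets the configured contact plane exactly at the target time, and
  the exact targets are returned as ground truth. Default sampling is
  8 samples/ms, chosen so finite-difference velocity recovery is accurate
  to well under 0.2 km/h and 1°.

What the generators do **not** emulate: solver noise spectra, mesh-dependent
spatial correlation of stress/strain, multi-body joint kinematics, vehicle
deformation, or any coupling between the kinematic channels and the field
histories. Passing tests therefore demonstrate the correctness of the
analysis operations and their closed-loop consistency with controlled
inputs — not the biofidelity of any real impact simulation, which requires
a validated solver and human model.

## Pipeline and configuration

One sectioned flat key-value config drives the end-to-end run; every
threshold has a default and unknown sections/keys fail loudly. Named
scenarios (sedan / suv / mpv) preset the head-contact targets to the
published 40 km/h values (118 ms/81°/40.4 km/h, 94/87/40.8, 90/51/23.4);
`custom` leaves them to the user. Runs are deterministic in (config, seed);
per-stage sub-seeds are fixed offsets of the run seed. Stage failures are
recorded with the stage name and an input digest, and the partial bundle is
retained. The published head-injury response peaks of the original
simulations are carried as display-only reference constants for the
comparison layer; they are solver outputs on proprietary vehicle and human
models and nothing in this package recomputes them.

## Known limitations

- The MPS risk curve's borrowed shape is an assumption; only its median is
  anchored by published data.
- The humanoid fixture's widths and depths below the named landmarks are
  plausible but arbitrary; only landmark-level dimensions are meaningful.
- Corridor construction and the normalization exponents mirror the common
  conventions, not the (unpublished) exact procedure of the source study.
- The trajectory generator reproduces wrap kinematics only qualitatively;
  it is a target-hitting idealization, not a dynamic model.
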