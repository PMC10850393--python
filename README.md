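# pedimpact

Analysis machinery for pedestrian–vehicle head impact studies built on
full-body finite-element human models. When a passenger car strikes a
pedestrian, the body wraps over the front end and the head strikes the hood
or windshield; whether the outcome is a skull fracture, focal brain injury
or diffuse axonal injury depends on the head's contact time, speed and
angle, on its linear and rotational kinematics, and on the stress and strain
fields those induce in the skull and brain. `pedimpact` implements the
post-solver half of such a study — everything downstream of the crash
solver — as a tested, reusable Python library with seeded synthetic
generators standing in for solver output, so every stage can be exercised
and validated at desk scale.

It is intended for injury-biomechanics researchers and vehicle-safety
engineers who need reproducible implementations of:

- **Anthropometric mesh morphing.** Vertex-corresponding body surfaces are
  averaged, and a Kriging transform (radial-basis covariance with linear
  polynomial drift, kernels |r|, |r|³ or thin-plate) is fitted from baseline
  to target anatomical landmarks and applied to every mesh node. The
  transform interpolates the landmarks exactly and reproduces any affine
  landmark correspondence globally; connectivity is untouched. Anthropometry
  (stature, eye/shoulder/perineal/tibial levels, shoulder and thorax widths)
  is measured off the morphed surface.
- **Head injury criteria.** HIC15
  (max over windows t₂−t₁ ≤ 15 ms of (t₂−t₁)·ā^2.5, exact window search),
  BrIC (√Σ(max|ω_i|/ω_ci)² with critical values 66.25/56.45/42.87 rad/s),
  maximum principal strain (MPS), the cumulative strain damage measure
  (CSDM: volume fraction of brain elements whose strain *ever* exceeds
  0.25), and skull fracture area (total shell area ever above the 65 MPa
  cortical-bone fracture stress). Signals can be conditioned with
  zero-phase 4-pole CFC low-pass filters.
- **AIS4+ risk curves.** Two-parameter Weibull CDFs
  P(x) = 1 − exp(−(x/λ)^k) anchored on the published points — BrIC 1.0 → 50%
  and 1.5 → 80%; MPS 0.89 → 50% — plus threshold classification
  (HIC > 700, strain > 0.30, CSDM ≥ 0.49 for DAI).
- **Biofidelity corridors.** Mertz–Viano cadaver-response normalization
  (λ = (m_std/m_subj)^⅓; force × λ², deflection × λ) and Lobdell-style
  mean ± SD or envelope corridors with pass/fail coverage checks, with the
  component validation presets (head ball, head rotation, chest pendulum,
  knee shear/bending) as machine-readable catalog entries.
- **Impact kinematics.** First-contact detection of a head path against a
  plane or triangulated patch, intrusion speed (km/h) and intrusion angle
  (degrees from horizontal), and least-squares rotation radius of the
  pre-contact path, with the regulatory 40 km/h / 60° headform preset for
  comparison.

## Worked example

```python
from pedimpact import (fit_kriging, measure_anthropometry, morph_mesh,
                       default_risk_functions, risk_at)
from pedimpact.synthetic import gen_body_surface
from pedimpact.meshes import LandmarkSet
from pedimpact.morphing import apply_transform

# stylized 1786 mm / 77.6 kg baseline morphed to 1690 mm / 67.6 kg targets
mesh, lm = gen_body_surface(1786.0, 77.6, seed=0)
_, lm_target = gen_body_surface(1690.0, 67.6, seed=0)
transform = fit_kriging(lm, lm_target, kernel="cubic")
morphed = morph_mesh(mesh, transform)
moved = LandmarkSet(lm.names, apply_transform(transform, lm.coordinates))
table = measure_anthropometry(morphed, moved)
print(f"height {table.height:.1f} mm, shoulder width {table.shoulder_width:.1f} mm")

bric_curve = default_risk_functions()["BrIC"]
print(f"AIS4+ risk at BrIC 1.7: {100 * risk_at(bric_curve, 1.7):.0f}%")
```

prints

```
height 1690.0 mm, shoulder width 431.0 mm
AIS4+ risk at BrIC 1.7: 88%
```

— the morphed surface hits the target stature and shoulder breadth exactly
(the landmark correspondence is affine, which the Kriging drift reproduces),
and a BrIC of 1.7 (a sedan-impact level) sits high on the anchored risk
curve.

The end-to-end pipeline is driven by one sectioned config file:

```sh
pedimpact run --seed 2 --out report.json
pedimpact risk --criterion BrIC --value 1.0
pedimpact morph fit --source src.csv --target tgt.csv --out transform.npz
```

`pedimpact run` generates a full synthetic scenario (crash pulse, angular
velocity, brain strain and skull stress fields, wrap trajectory), computes
every criterion, attaches risks and flags, extracts the head contact event,
and emits a text table using the standard row labels (HIC_15, BRIC, Brain
tissue MPS, Brain tissue CSDM, ...) alongside the JSON report.

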