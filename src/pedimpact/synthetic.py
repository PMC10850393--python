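"""Seeded generators emulating crash-solver outputs at desk scale.

A full pedestrian-impact simulation produces head kinematics (tri-axial
linear acceleration and angular velocity), element-level stress/strain field
histories on the skull and brain, body surface geometry, cadaver response
curves, and multi-segment wrap trajectories. The generators here produce
structurally faithful stand-ins for each of those input classes, with
machine-readable ground truth attached so every downstream stage can be
tested closed-loop. Every generator is a pure function of (spec, seed).

Units: time ms, length mm, linear acceleration g, angular velocity rad/s,
stress MPa, strain dimensionless, mass kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corridors import ResponseCurve
from .fields import ElementFieldHistory
from .kinematics import KMH_PER_MM_MS, ContactEvent, ContactPlane
from .meshes import LandmarkSet, Mesh
from .signals import TimeSeriesChannel

PULSE_SHAPES = ("haversine", "triangular", "constant")

#: band (ms) within which the brain-strain peak must precede head contact
DEFAULT_PEAK_LEAD_BAND = (1.0, 5.0)

# reference anthropometry driving the stylized humanoid (50th-percentile
# male dimensions, mm / kg); all other dimensions scale linearly with stature
REFERENCE_STATURE_MM = 1690.0
REFERENCE_MASS_KG = 67.6
REFERENCE_PROPORTIONS = {
    "eye_level": 1568.0 / 1690.0,
    "shoulder_height": 1387.0 / 1690.0,
    "perineal_height": 790.0 / 1690.0,
    "tibial_height": 444.0 / 1690.0,
    "shoulder_width": 431.0 / 1690.0,
    "thorax_width": 280.0 / 1690.0,
}


# ---------------------------------------------------------------------------
# crash pulses and angular velocity

@dataclass(frozen=True)
class PulseSpec:
    """Idealized crash pulse: resultant linear acceleration of the head."""

    peak: float               # g
    duration: float           # ms
    shape: str = "haversine"
    sample_rate: float = 10.0  # samples per ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError("peak acceleration must be >= 0")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.shape not in PULSE_SHAPES:
            raise ValueError(f"shape must be one of {PULSE_SHAPES}")


def _pulse_time_grid(duration: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    return np.arange(n + 1) / sample_rate


def gen_crash_pulse(spec: PulseSpec) -> tuple[TimeSeriesChannel, TimeSeriesChannel, TimeSeriesChannel]:
    """Tri-axial linear acceleration whose resultant follows the spec shape.

    The pulse magnitude is distributed over the three axes along a fixed
    seed-drawn unit direction, so the per-sample resultant equals the shape
    exactly and attains the configured peak.
    """
    t = _pulse_time_grid(spec.duration, spec.sample_rate)
    if spec.shape == "haversine":
        mag = spec.peak * np.sin(np.pi * t / spec.duration) ** 2
    elif spec.shape == "triangular":
        mag = spec.peak * (1.0 - np.abs(2.0 * t / spec.duration - 1.0))
    else:  # constant
        mag = np.full_like(t, spec.peak)
    rng = np.random.default_rng(spec.seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    channels = []
    for axis, name in enumerate(("ax", "ay", "az")):
        channels.append(TimeSeriesChannel(t, direction[axis] * mag, "g", name=name))
    return tuple(channels)


def gen_angular_velocity(peaks: tuple[float, float, float], duration: float,
                         seed: int = 0, sample_rate: float = 10.0,
                         ) -> tuple[TimeSeriesChannel, TimeSeriesChannel, TimeSeriesChannel]:
    """Tri-axial head angular velocity with exact per-axis peak magnitudes.

    Each axis is a seed-drawn band-limited waveform (sum of a few windowed
    sinusoids) rescaled so its maximum absolute value equals the requested
    peak exactly on the sample grid.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if any(p < 0 for p in peaks):
        raise ValueError("per-axis peaks must be >= 0")
    rng = np.random.default_rng(seed)
    t = _pulse_time_grid(duration, sample_rate)
    channels = []
    for peak, name in zip(peaks, ("wx", "wy", "wz")):
        if peak == 0:
            w = np.zeros_like(t)
        else:
            raw = np.zeros_like(t)
            for _ in range(4):
                freq = rng.uniform(0.5, 3.0)       # cycles over the duration
                phase = rng.uniform(0, 2 * np.pi)
                amp = rng.uniform(0.3, 1.0)
                raw += amp * np.sin(2 * np.pi * freq * t / duration + phase)
            raw *= np.sin(np.pi * t / duration)    # vanish at both ends
            w = peak * raw / np.max(np.abs(raw))
        channels.append(TimeSeriesChannel(t, w, "rad/s", name=name))
    return tuple(channels)


# ---------------------------------------------------------------------------
# brain strain and skull stress fields

@dataclass(frozen=True)
class StrainFieldSpec:
    """Brain principal-strain field with a controlled exceedance fraction.

    ``exceed_fraction`` is the volume fraction whose strain trace ever
    crosses the evaluation level; the field-wide strain maximum occurs
    ``peak_lead`` ms before ``contact_time`` (strain peaks precede head
    contact because rotational inertial loading peaks first).
    """

    n_elements: int
    exceed_fraction: float
    peak_strain: float = 0.9
    contact_time: float = 118.0   # ms
    peak_lead: float = 3.0        # ms before contact
    volume_model: str = "equal"   # or "lognormal"
    seed: int = 0
    sample_interval: float = 0.5  # ms

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if not 0.0 <= self.exceed_fraction <= 1.0:
            raise ValueError("exceed_fraction must be in [0, 1]")
        if self.peak_strain <= 0:
            raise ValueError("peak_strain must be positive")
        if self.volume_model not in ("equal", "lognormal"):
            raise ValueError("volume_model must be 'equal' or 'lognormal'")


@dataclass(frozen=True)
class StrainFieldTruth:
    """Ground truth attached to a generated strain field."""

    exceeding_ids: np.ndarray
    achieved_fraction: float
    peak_time: float
    peak_element: int


def _bump_traces(rng: np.random.Generator, times: np.ndarray, peaks: np.ndarray,
                 peak_times: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Gaussian rise-then-fall bumps, one row per element."""
    return peaks[:, None] * np.exp(
        -0.5 * ((times[None, :] - peak_times[:, None]) / widths[:, None]) ** 2)


def gen_brain_strain_field(spec: StrainFieldSpec, level: float = 0.25,
                           lead_band: tuple[float, float] = DEFAULT_PEAK_LEAD_BAND,
                           ) -> tuple[ElementFieldHistory, StrainFieldTruth]:
    """Per-element principal-strain histories on a toy brain mesh.

    Exactly the labeled subset of elements crosses ``level`` at some time
    (cumulatively — traces rise then fall), the crossing volume fraction
    matches ``spec.exceed_fraction`` to within one element's volume share,
    and the field-wide maximum lands ``spec.peak_lead`` ms before contact.
    """
    if not 0 < level < spec.peak_strain:
        raise ValueError("level must satisfy 0 < level < peak_strain")
    if not lead_band[0] <= spec.peak_lead <= lead_band[1]:
        raise ValueError(
            f"peak_lead {spec.peak_lead} ms outside the configured band {lead_band}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_elements

    if spec.volume_model == "equal":
        volumes = np.full(n, 1000.0)  # mm^3
    else:
        volumes = 1000.0 * rng.lognormal(mean=0.0, sigma=0.3, size=n)

    total = volumes.sum()
    order = rng.permutation(n)
    if spec.volume_model == "equal":
        k = int(round(spec.exceed_fraction * n))
        chosen = order[:k]
    else:
        cum = np.cumsum(volumes[order])
        k = int(np.searchsorted(cum, spec.exceed_fraction * total))
        if k < n and abs(cum[k] - spec.exceed_fraction * total) <= \
                abs((cum[k - 1] if k else 0.0) - spec.exceed_fraction * total):
            k += 1
        chosen = order[:k]
    achieved = volumes[chosen].sum() / total
    if abs(achieved - spec.exceed_fraction) > volumes.max() / total + 1e-12:
        raise ValueError(
            f"exceed_fraction {spec.exceed_fraction} unattainable with "
            f"{n} elements (closest achievable {achieved:.4f})")

    dt = spec.sample_interval
    t_end = spec.contact_time + 5.0
    times = np.arange(0.0, t_end + dt / 2, dt)
    # snap the field-wide peak instant onto the grid
    i_star = int(round((spec.contact_time - spec.peak_lead) / dt))
    t_star = times[i_star]

    exceed_mask = np.zeros(n, dtype=bool)
    exceed_mask[chosen] = True
    peaks = np.empty(n)
    margin = 0.1 * (spec.peak_strain - level)
    peaks[exceed_mask] = rng.uniform(level + margin, spec.peak_strain - margin / 2,
                                     size=exceed_mask.sum())
    peaks[~exceed_mask] = rng.uniform(0.2 * level, 0.9 * level,
                                      size=(~exceed_mask).sum())
    peak_times = np.clip(rng.uniform(t_star - 3.0, t_star + 1.0, size=n),
                         times[0] + 1.0, times[-1] - 1.0)
    widths = rng.uniform(2.0, 6.0, size=n)

    # one designated element carries the global maximum exactly at t_star
    star = int(chosen[0]) if len(chosen) else int(order[-1])
    peaks[star] = spec.peak_strain if len(chosen) else 0.95 * level
    peaks[np.arange(n) != star] = np.minimum(peaks[np.arange(n) != star],
                                             0.999 * peaks[star])
    peak_times[star] = t_star

    traces = _bump_traces(rng, times, peaks, peak_times, widths)
    fieldx = ElementFieldHistory(
        element_ids=np.arange(n), element_measure=volumes, times=times,
        traces=traces, quantity="principal_strain", measure_kind="volume_mm3")
    truth = StrainFieldTruth(
        exceeding_ids=np.sort(chosen), achieved_fraction=float(achieved),
        peak_time=float(t_star), peak_element=star)
    return fieldx, truth


def gen_skull_stress_field(areas: np.ndarray, supra_threshold_ids: np.ndarray,
                           threshold: float = 65.0, seed: int = 0,
                           duration: float = 30.0, sample_interval: float = 0.5,
                           ) -> ElementFieldHistory:
    """Von Mises stress histories on skull shells with a known supra-threshold
    patch: exactly the listed element subset ever exceeds ``threshold`` MPa."""
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("shell areas must be positive")
    n = areas.size
    ids = np.asarray(supra_threshold_ids, dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= n):
        raise ValueError(f"supra-threshold ids outside element range [0, {n})")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + sample_interval / 2, sample_interval)
    mask = np.zeros(n, dtype=bool)
    mask[ids] = True
    peaks = np.empty(n)
    peaks[mask] = rng.uniform(1.1 * threshold, 1.8 * threshold, size=mask.sum())
    peaks[~mask] = rng.uniform(0.3 * threshold, 0.9 * threshold, size=(~mask).sum())
    peak_times = rng.uniform(times[0] + 2.0, times[-1] - 2.0, size=n)
    widths = rng.uniform(1.5, 5.0, size=n)
    traces = _bump_traces(rng, times, peaks, peak_times, widths)
    return ElementFieldHistory(
        element_ids=np.arange(n), element_measure=areas, times=times,
        traces=traces, quantity="von_mises_stress_MPa", measure_kind="area_mm2")


# ---------------------------------------------------------------------------
# stylized humanoid surface

def gen_body_surface(stature: float, mass: float, seed: int = 0,
                     ring_points: int = 16, jitter_mm: float = 1.0,
                     ) -> tuple[Mesh, LandmarkSet]:
    """Stylized multi-segment humanoid surface with named landmarks.

    A loft of elliptical cross-sections (feet to crown) closed by apex caps.
    All dimensions scale linearly with stature from 50th-percentile male
    reference proportions; lateral girth additionally scales with the square
    root of mass relative to isometric mass. The mesh's vertical extent
    equals ``stature`` exactly; the seed only jitters local vertex positions
    laterally, never the global dimensions or the landmarks.
    """
    if stature <= 0:
        raise ValueError("stature must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    s = stature / REFERENCE_STATURE_MM
    girth = math.sqrt(mass / (REFERENCE_MASS_KG * s**3))
    p = REFERENCE_PROPORTIONS
    half_w_shoulder = 0.5 * p["shoulder_width"] * stature * girth
    half_d_thorax = 0.5 * p["thorax_width"] * stature * girth

    # (z fraction, half-depth x fraction, half-width y fraction) of stature
    profile = [
        (0.000, 0.080, 0.060),
        (p["tibial_height"], 0.060, 0.070),
        (p["perineal_height"], 0.070, 0.100),
        (0.600, 0.078, 0.110),
        (0.750, p["thorax_width"] / 2, 0.115),       # thorax level
        (p["shoulder_height"], 0.070, p["shoulder_width"] / 2),
        (0.870, 0.040, 0.035),                        # neck
        (p["eye_level"], 0.060, 0.055),
        (0.975, 0.045, 0.040),
    ]
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(ring_points) / ring_points
    rings = []
    for zf, hdf, hwf in profile:
        hd = hdf * stature * girth
        hw = hwf * stature * girth
        x = hd * np.cos(theta) + rng.normal(0, jitter_mm, ring_points)
        y = hw * np.sin(theta) + rng.normal(0, jitter_mm, ring_points)
        z = np.full(ring_points, zf * stature)
        rings.append(np.column_stack([x, y, z]))
    verts = np.vstack(rings)
    apex_top = np.array([[0.0, 0.0, stature]])
    apex_bot = np.array([[0.0, 0.0, 0.0]])
    verts = np.vstack([verts, apex_top, apex_bot])
    i_top, i_bot = len(verts) - 2, len(verts) - 1

    faces = []
    m = ring_points
    for r in range(len(profile) - 1):
        base, nxt = r * m, (r + 1) * m
        for j in range(m):
            a, b = base + j, base + (j + 1) % m
            c, d = nxt + j, nxt + (j + 1) % m
            faces.append([a, b, c])
            faces.append([b, d, c])
    last = (len(profile) - 1) * m
    for j in range(m):
        faces.append([last + j, last + (j + 1) % m, i_top])
        faces.append([(j + 1) % m, j, i_bot])
    mesh = Mesh(verts, np.array(faces, dtype=int))

    lm = LandmarkSet(
        ("vertex", "eye", "shoulder_l", "shoulder_r", "perineum", "tibia",
         "thorax_front", "thorax_back"),
        np.array([
            [0.0, 0.0, stature],
            [0.060 * stature * girth, 0.0, p["eye_level"] * stature],
            [0.0, +half_w_shoulder, p["shoulder_height"] * stature],
            [0.0, -half_w_shoulder, p["shoulder_height"] * stature],
            [0.0, 0.0, p["perineal_height"] * stature],
            [0.060 * stature * girth, 0.0, p["tibial_height"] * stature],
            [+half_d_thorax, 0.0, 0.750 * stature],
            [-half_d_thorax, 0.0, 0.750 * stature],
        ]))
    return mesh, lm


# ---------------------------------------------------------------------------
# cadaver response curves

def gen_cadaver_curves(n_subjects: int, mass_mean: float, mass_sd: float,
                       base_curve: ResponseCurve, seed: int = 0,
                       noise_sd: float = 0.0,
                       on_nonpositive_mass: str = "resample",
                       ) -> list[tuple[float, ResponseCurve]]:
    """Cadaver pool: the base curve perturbed by bounded additive noise, one
    subject mass per curve drawn about ``mass_mean``.

    Noise is Gaussian truncated at 4 SD (bounded); with ``mass_sd=0`` and
    ``noise_sd=0`` every curve equals the base exactly. Non-positive sampled
    masses are resampled or rejected per ``on_nonpositive_mass``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if on_nonpositive_mass not in ("resample", "reject"):
        raise ValueError("on_nonpositive_mass must be 'resample' or 'reject'")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        mass = mass_mean + mass_sd * rng.standard_normal() if mass_sd else mass_mean
        tries = 0
        while mass <= 0:
            if on_nonpositive_mass == "reject" or tries > 100:
                raise ValueError(f"sampled non-positive subject mass {mass:.2f} kg")
            mass = mass_mean + mass_sd * rng.standard_normal()
            tries += 1
        if noise_sd:
            noise = np.clip(rng.normal(0, noise_sd, size=len(base_curve.ordinate)),
                            -4 * noise_sd, 4 * noise_sd)
        else:
            noise = 0.0
        out.append((float(mass), replace(base_curve,
                                         ordinate=base_curve.ordinate + noise,
                                         subject_mass=float(mass))))
    return out


# ---------------------------------------------------------------------------
# pedestrian wrap trajectory

@dataclass(frozen=True)
class TrajectorySpec:
    """Planar (sagittal) wrap-trajectory targets for the rigid-link chain.

    The head travels at the chain tip (radius = sum of segment lengths) while
    the pivot is carried forward at a fraction of vehicle speed; the angular
    rate profile is solved so the head crosses ``contact_plane`` at
    ``target_contact_time`` with speed ``vehicle_speed`` and an intrusion
    angle of ``target_angle`` degrees.
    """

    segment_lengths: tuple[float, ...]          # mm
    vehicle_speed: float                        # km/h
    contact_plane: ContactPlane
    target_contact_time: float                  # ms
    target_angle: float                         # degrees from horizontal
    seed: int = 0
    sample_rate: float = 8.0                    # samples per ms

    def __post_init__(self) -> None:
        if not self.segment_lengths or any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if not 0.0 <= self.target_angle <= 90.0:
            raise ValueError("target_angle must be within [0, 90] degrees")
        if self.vehicle_speed <= 0:
            raise ValueError("vehicle_speed must be positive")
        if self.target_contact_time <= 0:
            raise ValueError("target_contact_time must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def default_segments(stature: float = REFERENCE_STATURE_MM) -> tuple[float, float, float]:
    """Tibia / femur / torso+head segment lengths (mm) for a given stature."""
    p = REFERENCE_PROPORTIONS
    tibia = p["tibial_height"] * stature
    femur = (p["perineal_height"] - p["tibial_height"]) * stature
    upper = (1.0 - p["perineal_height"]) * stature
    return (tibia, femur, upper)


@dataclass(frozen=True)
class Trajectory:
    """Generated head/chest traces plus machine-readable ground truth."""

    times: np.ndarray
    head: np.ndarray
    chest: np.ndarray
    truth: ContactEvent
    plane: ContactPlane
    head_radius: float


def gen_pedestrian_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Planar rigid-link wrap trajectory hitting the configured contact
    targets.

    The chain pivots about a moving ground-contact point translated at a
    seed-jittered fraction of vehicle speed; the chain angle from vertical
    follows a linear angular-rate profile solved in closed form so that at
    ``target_contact_time`` the head velocity has the target magnitude and
    intrusion angle. The whole scene is then translated so the head meets
    ``contact_plane`` exactly at that instant. Raises when the targets are
    unreachable for the chain geometry.
    """
    radius = float(sum(spec.segment_lengths))
    t_c = spec.target_contact_time
    speed = spec.vehicle_speed / KMH_PER_MM_MS          # mm/ms
    theta = math.radians(spec.target_angle)
    rng = np.random.default_rng(spec.seed)

    # pivot drift speed: a fraction of the horizontal head-velocity component
    u = rng.uniform(0.3, 0.7) * speed * math.cos(theta)
    vx, vz = speed * math.cos(theta) - u, speed * math.sin(theta)
    omega_c = math.hypot(vx, vz) / radius               # rad/ms at contact
    beta_c = math.atan2(vz, vx)                         # chain angle from vertical
    if beta_c <= 0 or omega_c <= 0:
        raise ValueError("target_angle unreachable for this chain geometry")
    # linear angular-rate profile: omega(t) = a + b t, beta(0) = 0
    a = 2.0 * beta_c / t_c - omega_c
    b = 2.0 * (omega_c - beta_c / t_c) / t_c
    if a < 0:
        raise ValueError(
            "unreachable targets: required terminal angular rate exceeds twice "
            "the mean rate for this chain geometry")

    dt = 1.0 / spec.sample_rate
    times = np.arange(0.0, t_c + 8.0 + dt / 2, dt)
    beta = a * times + 0.5 * b * times**2
    omega = a + b * times

    def chain_point(r: float) -> np.ndarray:
        x = u * times + r * np.sin(beta)
        z = r * np.cos(beta)
        return np.column_stack([x, np.zeros_like(x), z])

    head = chain_point(radius)
    chest = chain_point(0.55 * radius)

    # translate the scene so the head meets the plane exactly at t_c
    beta_tc = a * t_c + 0.5 * b * t_c**2
    head_tc = np.array([u * t_c + radius * math.sin(beta_tc), 0.0,
                        radius * math.cos(beta_tc)])
    offset = spec.contact_plane.point - head_tc
    head += offset
    chest += offset

    vel_tc = np.array([u + radius * omega_c * math.cos(beta_tc), 0.0,
                       -radius * omega_c * math.sin(beta_tc)])
    truth = ContactEvent(
        time_ms=float(t_c),
        location_mm=spec.contact_plane.point.copy(),
        velocity_mm_ms=vel_tc,
        intrusion_angle_deg=float(spec.target_angle),
    )
    return Trajectory(times=times, head=head, chest=chest, truth=truth,
                      plane=spec.contact_plane, head_radius=radius)
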