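"""Cadaver-response standardization and biofidelity corridors.

Cadaver tests are run on subjects whose mass differs from the reference body;
before curves can be pooled they are scaled to a standard subject via
mass-ratio cube-root factors (Mertz–Viano normalization): with
``lam = (standard_mass / subject_mass)**(1/3)``, forces scale by ``lam**2``
and deflections by ``lam`` (equal-density, equal-modulus assumption, so
impact energy scales by ``lam**3``). Pooled curves define a biofidelity
corridor (Lobdell-style reference band); a surrogate model passes when a
configured fraction of its response stays inside the band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CORRIDOR_GRID_POINTS = 200  # uniform resampling grid over the common abscissa


@dataclass(frozen=True)
class ResponseCurve:
    """A mechanical response curve, e.g. chest force vs deflection.

    ``abscissa`` is deflection (mm) or time (ms), non-decreasing;
    ``ordinate`` is force (kN) or moment (Nm). ``subject_mass`` (kg) is the
    cadaver mass the curve was measured on, required for scaling.
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    abscissa_units: str = "mm"
    ordinate_units: str = "kN"
    subject_mass: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.ordinate, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("abscissa and ordinate must be 1-D and equal length")
        if np.any(np.diff(x) < 0):
            raise ValueError("abscissa must be non-decreasing")
        if not self.abscissa_units or not self.ordinate_units:
            raise ValueError("units labels are required")
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "ordinate", y)

    def resample(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.abscissa, self.ordinate)

    def energy(self) -> float:
        """Integral of ordinate over abscissa (trapezoid)."""
        return float(np.trapezoid(self.ordinate, self.abscissa))


def mertz_viano_scale(curve: ResponseCurve, standard_mass: float,
                      force_exponent: float = 2.0,
                      deflection_exponent: float = 1.0) -> ResponseCurve:
    """Scale a cadaver curve to a standard subject mass.

    ``lam = (standard_mass / subject_mass)**(1/3)``; ordinate (force) is
    multiplied by ``lam**force_exponent`` and abscissa (deflection) by
    ``lam**deflection_exponent``. Alternative exponent sets may be supplied
    for other normalization conventions.
    """
    if curve.subject_mass is None or curve.subject_mass <= 0:
        raise ValueError("curve must carry a positive subject_mass to be scaled")
    if standard_mass <= 0:
        raise ValueError("standard_mass must be positive")
    lam = (standard_mass / curve.subject_mass) ** (1.0 / 3.0)
    return replace(
        curve,
        abscissa=curve.abscissa * lam**deflection_exponent,
        ordinate=curve.ordinate * lam**force_exponent,
        subject_mass=standard_mass,
    )


@dataclass(frozen=True)
class Corridor:
    """Reference curve with lower/upper bounds on a shared abscissa grid."""

    abscissa: np.ndarray
    reference: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    construction: str = "sd_band"

    def __post_init__(self) -> None:
        for arr in (self.reference, self.lower, self.upper):
            if np.asarray(arr).shape != np.asarray(self.abscissa).shape:
                raise ValueError("corridor arrays must share the abscissa grid")
        if np.any(self.lower > self.reference + 1e-12) or np.any(self.reference > self.upper + 1e-12):
            raise ValueError("corridor bounds must satisfy lower <= reference <= upper")


def build_corridor(curves: list[ResponseCurve], construction: str = "sd_band",
                   width: float = 1.0, n_grid: int = CORRIDOR_GRID_POINTS) -> Corridor:
    """Pool curves into a corridor: pointwise mean reference with either a
    mean +/- width*SD band or a min/max envelope."""
    if len(curves) < 2:
        raise ValueError("need at least two curves to build a corridor")
    if construction not in ("sd_band", "min_max_envelope"):
        raise ValueError(f"unknown construction {construction!r}")
    lo = max(float(c.abscissa.min()) for c in curves)
    hi = min(float(c.abscissa.max()) for c in curves)
    if hi <= lo:
        raise ValueError("curves have no overlapping abscissa range")
    grid = np.linspace(lo, hi, n_grid)
    samples = np.vstack([c.resample(grid) for c in curves])
    mean = samples.mean(axis=0)
    if construction == "sd_band":
        sd = samples.std(axis=0, ddof=1)
        lower, upper = mean - width * sd, mean + width * sd
    else:
        lower, upper = samples.min(axis=0), samples.max(axis=0)
    return Corridor(grid, mean, lower, upper, construction)


def corridor_check(curve: ResponseCurve, corridor: Corridor,
                   min_fraction: float = 0.9) -> tuple[float, bool]:
    """Fraction of the curve inside the corridor band, and pass/fail.

    The curve is resampled on the part of the corridor grid it covers;
    a point counts as inside when ``lower <= value <= upper`` (with a tiny
    numerical slack at the boundaries).
    """
    mask = (corridor.abscissa >= curve.abscissa.min() - 1e-12) & \
           (corridor.abscissa <= curve.abscissa.max() + 1e-12)
    if not mask.any():
        raise ValueError("curve does not overlap the corridor abscissa")
    grid = corridor.abscissa[mask]
    vals = curve.resample(grid)
    eps = 1e-9 * (1.0 + np.abs(corridor.upper[mask]) + np.abs(corridor.lower[mask]))
    inside = (vals >= corridor.lower[mask] - eps) & (vals <= corridor.upper[mask] + eps)
    frac = float(inside.mean())
    return frac, frac >= min_fraction


# ---------------------------------------------------------------------------
# validation scenario presets (lateral-impact component tests)

@dataclass(frozen=True)
class ScenarioPreset:
    """One component validation scenario: impactor setup + reference ranges."""

    name: str
    impactor_mass_kg: float | None = None
    impactor_radius_mm: float | None = None
    impactor_diameter_mm: float | None = None
    impact_speed_m_s: float | None = None
    impact_speed_km_h: float | None = None
    angular_acceleration_rad_s2: float | None = None
    preload_N: float | None = None
    reference_ranges: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioPreset":
        return cls(**d)


def scenario_presets() -> dict[str, ScenarioPreset]:
    """Catalog of the component validation scenarios.

    Head: rigid-ball crown impact; head rotation: applied side-direction
    angular acceleration; chest: lateral cylindrical pendulum; lower limb:
    knee shear and bending impacts with an axial standing preload.
    """
    return {
        "head_ball": ScenarioPreset(
            name="head_ball", impactor_mass_kg=1.213, impactor_radius_mm=48.0,
            impact_speed_m_s=8.0,
        ),
        "head_rotation": ScenarioPreset(
            name="head_rotation", angular_acceleration_rad_s2=7400.0,
        ),
        "chest_lateral": ScenarioPreset(
            name="chest_lateral", impactor_mass_kg=23.0,
            impactor_diameter_mm=152.0, impact_speed_m_s=2.76,
        ),
        "lower_limb_bending": ScenarioPreset(
            name="lower_limb_bending", impactor_mass_kg=6.25,
            impact_speed_km_h=40.0, preload_N=400.0,
            reference_ranges={
                "bending_moment_Nm": (369.0, 545.0),
                "shear_force_kN": (1.6, 2.3),
                "knee_bending_angle_deg": (1.7, 4.1),
                "knee_shear_displacement_mm": (13.0, 14.0),
            },
        ),
        "lower_limb_shear": ScenarioPreset(
            name="lower_limb_shear", impactor_mass_kg=6.25,
            impact_speed_km_h=40.0, preload_N=400.0,
            reference_ranges={
                "bending_moment_Nm": (367.0, 450.0),
                "shear_force_kN": (1.2, 1.4),
                "knee_bending_angle_deg": (10.0, 14.8),
                "knee_shear_displacement_mm": (13.0, 17.0),
            },
        ),
    }


def save_presets(path: str | Path, presets: dict[str, ScenarioPreset]) -> None:
    Path(path).write_text(json.dumps(
        {k: p.to_dict() for k, p in presets.items()}, indent=2))


def load_presets(path: str | Path) -> dict[str, ScenarioPreset]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for k, d in raw.items():
        d = dict(d)
        d["reference_ranges"] = {
            m: tuple(v) for m, v in d.get("reference_ranges", {}).items()}
        out[k] = ScenarioPreset.from_dict(d)
    return out
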