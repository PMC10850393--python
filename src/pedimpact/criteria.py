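"""Head injury criteria from kinematics and element-field histories.

Metrics computed here:

* **HIC15** — ``max over windows t2-t1 <= 15 ms of
  (t2-t1) * (mean resultant acceleration in g over the window)**2.5`` with the
  window length in seconds; the search is exact over all sample pairs.
* **BrIC** — root-sum-square of per-axis peak angular velocity magnitudes
  normalized by critical values (defaults from the published criterion:
  66.25, 56.45, 42.87 rad/s about x, y, z).
* **MPS** — the global maximum of the brain first-principal-strain field over
  elements and time.
* **CSDM** — the volume fraction of brain elements whose strain EVER exceeds
  a threshold (0.25 by default); cumulative, so a trace that rises above the
  threshold and falls back still counts.
* **Skull fracture area** — total shell area of elements whose von Mises
  stress ever exceeds the cortical-bone fracture threshold (65 MPa), each
  element counted once.

Threshold flags follow the published injury references: HIC above 700,
any skull stress exceedance, brain tissue damage above 0.30 strain, and a
diffuse-axonal-injury flag at CSDM >= 0.49.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .fields import ElementFieldHistory
from .signals import TimeSeriesChannel, cfc_filter, resultant

DEFAULT_BRIC_CRITICAL = (66.25, 56.45, 42.87)  # rad/s about x, y, z
DEFAULT_HIC_WINDOW_MS = 15.0
DEFAULT_STRESS_THRESHOLD_MPA = 65.0
DEFAULT_CSDM_STRAIN_THRESHOLD = 0.25
DEFAULT_TISSUE_STRAIN_THRESHOLD = 0.30
DEFAULT_CSDM_DAI_FLAG = 0.49
DEFAULT_HIC_REFERENCE = 700.0


def hic(accel: TimeSeriesChannel, max_window: float = DEFAULT_HIC_WINDOW_MS,
        ) -> tuple[float, float, float]:
    """Head Injury Criterion of a resultant acceleration channel in g.

    Exact search over all sample-pair windows no longer than ``max_window``
    ms; ties broken toward the earliest window start. Returns
    ``(value, t1, t2)`` with times in ms. The mean over a window uses the
    trapezoid cumulative integral, and the duration factor is in seconds.
    """
    if accel.units != "g":
        raise ValueError(f"HIC expects acceleration in g, got units {accel.units!r}")
    a = accel.values
    if np.any(a < 0):
        raise ValueError("HIC expects a non-negative resultant acceleration")
    t = accel.times
    n = len(a)
    if n < 2:
        raise ValueError("HIC needs at least two samples")
    dt = accel.dt
    cum = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) * 0.5 * dt)])
    max_steps = max(1, int(np.floor(max_window / dt + 1e-9)))
    max_steps = min(max_steps, n - 1)

    best, best_t1, best_t2 = 0.0, t[0], t[0]
    for w in range(1, max_steps + 1):
        span = t[w:] - t[:-w]
        mean = (cum[w:] - cum[:-w]) / span
        vals = (span / 1000.0) * mean**2.5
        i = int(np.argmax(vals))
        v = float(vals[i])
        if v > best or (v == best and float(t[i]) < best_t1):
            best, best_t1, best_t2 = v, float(t[i]), float(t[i + w])
    return best, best_t1, best_t2


def bric(omega_x: TimeSeriesChannel, omega_y: TimeSeriesChannel,
         omega_z: TimeSeriesChannel,
         critical: tuple[float, float, float] = DEFAULT_BRIC_CRITICAL) -> float:
    """Brain Injury Criterion from tri-axial angular velocity in rad/s."""
    if any(c <= 0 for c in critical):
        raise ValueError("critical angular velocities must be positive")
    total = 0.0
    for ch, crit in zip((omega_x, omega_y, omega_z), critical):
        if ch.units != "rad/s":
            raise ValueError(f"BrIC expects rad/s channels, got {ch.units!r}")
        total += (float(np.max(np.abs(ch.values))) / crit) ** 2
    return float(np.sqrt(total))


def mps(field_history: ElementFieldHistory) -> tuple[float, int, float]:
    """Maximum principal strain: global max over elements and time.

    Returns ``(value, element_id, time_ms)`` at the argmax.
    """
    if field_history.quantity != "principal_strain":
        raise ValueError("MPS requires a principal_strain field")
    if field_history.n_elements == 0:
        raise ValueError("empty strain field")
    flat = int(np.argmax(field_history.traces))
    ei, ti = np.unravel_index(flat, field_history.traces.shape)
    return (float(field_history.traces[ei, ti]),
            int(field_history.element_ids[ei]),
            float(field_history.times[ti]))


def csdm(field_history: ElementFieldHistory,
         strain_threshold: float = DEFAULT_CSDM_STRAIN_THRESHOLD) -> float:
    """Cumulative strain damage measure: volume fraction of elements whose
    strain ever strictly exceeds ``strain_threshold``."""
    if field_history.quantity != "principal_strain":
        raise ValueError("CSDM requires a principal_strain field")
    if field_history.measure_kind != "volume_mm3":
        raise ValueError("CSDM requires element volumes (solid mesh)")
    total = field_history.total_measure
    if total <= 0:
        raise ValueError("zero total brain volume")
    mask = field_history.exceedance_mask(strain_threshold)
    return float(field_history.element_measure[mask].sum() / total)


def fracture_area(field_history: ElementFieldHistory,
                  stress_threshold: float = DEFAULT_STRESS_THRESHOLD_MPA) -> float:
    """Skull fracture area (mm^2): summed shell area of elements whose von
    Mises stress ever strictly exceeds ``stress_threshold`` MPa, each counted
    once regardless of how often or when it exceeds."""
    if field_history.quantity != "von_mises_stress_MPa":
        raise ValueError("fracture area requires a von Mises stress field")
    if field_history.measure_kind != "area_mm2":
        raise ValueError("fracture area requires shell areas, not volumes")
    mask = field_history.exceedance_mask(stress_threshold)
    return float(field_history.element_measure[mask].sum())


@dataclass(frozen=True)
class Thresholds:
    """Injury reference thresholds applied when assembling a report."""

    hic_reference: float = DEFAULT_HIC_REFERENCE
    stress_threshold: float = DEFAULT_STRESS_THRESHOLD_MPA
    csdm_strain_threshold: float = DEFAULT_CSDM_STRAIN_THRESHOLD
    tissue_strain_threshold: float = DEFAULT_TISSUE_STRAIN_THRESHOLD
    csdm_dai_flag: float = DEFAULT_CSDM_DAI_FLAG
    bric_critical: tuple[float, float, float] = DEFAULT_BRIC_CRITICAL
    hic_window_ms: float = DEFAULT_HIC_WINDOW_MS
    cfc_class: str | None = "CFC1000"


@dataclass
class InjuryReport:
    """Consolidated head-injury metrics with threshold flags and risks.

    Metrics are ``None`` when their input was not supplied. ``flags`` mark
    threshold exceedances; ``risks`` (AIS4+ probabilities) are attached by
    the risk layer.
    """

    peak_acceleration_g: float | None = None
    hic15: float | None = None
    hic_window: tuple[float, float] | None = None
    bric: float | None = None
    mps: float | None = None
    mps_element: int | None = None
    mps_time: float | None = None
    csdm: float | None = None
    fracture_area_mm2: float | None = None
    max_skull_stress_mpa: float | None = None
    flags: dict = field(default_factory=dict)
    risks: dict = field(default_factory=dict)
    risk_parameters: dict = field(default_factory=dict)

    METRIC_FIELDS = ("peak_acceleration_g", "hic15", "bric",
                     "max_skull_stress_mpa", "mps", "csdm", "fracture_area_mm2")

    def metrics(self) -> dict:
        return {k: getattr(self, k) for k in self.METRIC_FIELDS
                if getattr(self, k) is not None}

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "peak_acceleration_g", "hic15", "hic_window", "bric", "mps",
            "mps_element", "mps_time", "csdm", "fracture_area_mm2",
            "max_skull_stress_mpa")}
        d["flags"] = dict(self.flags)
        d["risks"] = dict(self.risks)
        d["risk_parameters"] = dict(self.risk_parameters)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "InjuryReport":
        d = dict(d)
        if d.get("hic_window") is not None:
            d["hic_window"] = tuple(d["hic_window"])
        return cls(**d)


def apply_flags(report: InjuryReport, thresholds: Thresholds) -> InjuryReport:
    """Set the threshold-exceedance flags on a report (idempotent).

    Strict ``>`` for the stress/strain/HIC references ("exceeds"), ``>=`` for
    the CSDM diffuse-axonal-injury flag ("occurs in 49%").
    """
    flags = {}
    if report.hic15 is not None:
        flags["hic_above_reference"] = report.hic15 > thresholds.hic_reference
    if report.fracture_area_mm2 is not None:
        flags["skull_fracture"] = report.fracture_area_mm2 > 0
    elif report.max_skull_stress_mpa is not None:
        flags["skull_fracture"] = report.max_skull_stress_mpa > thresholds.stress_threshold
    if report.mps is not None:
        flags["brain_tissue_damage"] = report.mps > thresholds.tissue_strain_threshold
    if report.csdm is not None:
        flags["dai"] = report.csdm >= thresholds.csdm_dai_flag
    report.flags = flags
    return report


def build_report(kinematics: dict | None = None,
                 skull_field: ElementFieldHistory | None = None,
                 brain_field: ElementFieldHistory | None = None,
                 thresholds: Thresholds = Thresholds()) -> InjuryReport:
    """Compute every metric its inputs allow and assemble the report.

    ``kinematics`` maps ``"linear"`` to an (x, y, z) triple of acceleration
    channels in g and/or ``"angular"`` to an (x, y, z) triple of angular
    velocity channels in rad/s. Linear acceleration is CFC-filtered (class
    from ``thresholds.cfc_class``, disabled with None) before the resultant
    and HIC. Missing inputs leave their metrics absent; they are never an
    error.
    """
    report = InjuryReport()
    kinematics = kinematics or {}
    if "linear" in kinematics:
        x, y, z = kinematics["linear"]
        if thresholds.cfc_class is not None:
            x, y, z = (cfc_filter(c, thresholds.cfc_class) for c in (x, y, z))
        res = resultant(x, y, z)
        res = replace(res, values=np.abs(res.values))  # guard filter undershoot
        report.peak_acceleration_g = float(np.max(res.values))
        value, t1, t2 = hic(res, thresholds.hic_window_ms)
        report.hic15 = value
        report.hic_window = (t1, t2)
    if "angular" in kinematics:
        wx, wy, wz = kinematics["angular"]
        report.bric = bric(wx, wy, wz, thresholds.bric_critical)
    if brain_field is not None:
        value, element, time = mps(brain_field)
        report.mps, report.mps_element, report.mps_time = value, element, time
        report.csdm = csdm(brain_field, thresholds.csdm_strain_threshold)
    if skull_field is not None:
        report.fracture_area_mm2 = fracture_area(skull_field,
                                                 thresholds.stress_threshold)
        report.max_skull_stress_mpa = float(skull_field.traces.max())
    return apply_flags(report, thresholds)


#: row labels of the printed head-injury comparison, keyed by metric field
TABLE_ROW_LABELS = {
    "peak_acceleration_g": "Head integrated acceleration (g)",
    "hic15": "HIC_15",
    "bric": "BRIC",
    "max_skull_stress_mpa": "Maximum equivalent stress on the skull (Mpa)",
    "mps": "Brain tissue MPS",
    "csdm": "Brain tissue CSDM",
}


def format_report_table(report: InjuryReport, label: str = "model") -> str:
    """Human-readable text table mirroring the printed comparison layout."""
    width = max(len(v) for v in TABLE_ROW_LABELS.values()) + 2
    lines = [f"{'Metric':<{width}}{label}"]
    for key, row in TABLE_ROW_LABELS.items():
        value = getattr(report, key)
        shown = "-" if value is None else f"{value:.4g}"
        lines.append(f"{row:<{width}}{shown}")
    if report.fracture_area_mm2 is not None:
        lines.append(f"{'Skull fracture area (mm2)':<{width}}"
                     f"{report.fracture_area_mm2:.4g}")
    for name, val in report.flags.items():
        lines.append(f"{'flag: ' + name:<{width}}{val}")
    for name, val in report.risks.items():
        lines.append(f"{'risk: ' + name:<{width}}{val:.3f}")
    return "\n".join(lines)
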