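"""Run configuration: sectioned flat key-value files with fail-loud parsing.

Every threshold and generator parameter has a default; unknown sections or
keys are errors. A config round-trips through serialization unchanged.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: default run configuration; values are flat scalars inside named sections
DEFAULTS: dict[str, dict] = {
    "run": {
        "seed": 0,
        "scenario": "sedan",  # sedan | suv | mpv | custom
    },
    "pulse": {
        "peak_g": 180.0,
        "duration_ms": 20.0,
        "shape": "haversine",
        "sample_rate_per_ms": 10.0,
    },
    "angular": {
        "peak_x_rad_s": 30.0,
        "peak_y_rad_s": 50.0,
        "peak_z_rad_s": 20.0,
        "duration_ms": 40.0,
    },
    "brain": {
        "n_elements": 500,
        "exceed_fraction": 0.49,
        "peak_strain": 0.86,
        "contact_time_ms": 118.0,
        "peak_lead_ms": 3.0,
        "volume_model": "equal",
        "strain_scale": 1.0,
    },
    "skull": {
        "n_elements": 200,
        "fracture_fraction": 0.10,
        "mean_shell_area_mm2": 110.0,
        "stress_scale": 1.0,
    },
    "trajectory": {
        "stature_mm": 1690.0,
        "vehicle_speed_km_h": 40.4,
        "contact_time_ms": 118.0,
        "angle_deg": 81.0,
        "sample_rate_per_ms": 8.0,
    },
    "thresholds": {
        "hic_reference": 700.0,
        "hic_window_ms": 15.0,
        "stress_threshold_mpa": 65.0,
        "csdm_strain_threshold": 0.25,
        "tissue_strain_threshold": 0.30,
        "csdm_dai_flag": 0.49,
        "cfc_class": "CFC1000",
        "bric_critical_x": 66.25,
        "bric_critical_y": 56.45,
        "bric_critical_z": 42.87,
    },
    "risk": {
        "bric_anchor1_value": 1.0,
        "bric_anchor1_prob": 0.5,
        "bric_anchor2_value": 1.5,
        "bric_anchor2_prob": 0.8,
        "mps_anchor_value": 0.89,
        "mps_anchor_prob": 0.5,
    },
}

#: named collision scenarios: head contact targets of the 40 km/h wrap cases
SCENARIOS = {
    "sedan": {"contact_time_ms": 118.0, "angle_deg": 81.0, "vehicle_speed_km_h": 40.4},
    "suv": {"contact_time_ms": 94.0, "angle_deg": 87.0, "vehicle_speed_km_h": 40.8},
    "mpv": {"contact_time_ms": 90.0, "angle_deg": 51.0, "vehicle_speed_km_h": 23.4},
}


class RunConfig(dict):
    """Validated sectioned configuration (a dict of section dicts)."""

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(copy.deepcopy(DEFAULTS))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        cfg = cls.default()
        for section, values in (mapping or {}).items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r} "
                                 f"(known: {sorted(cfg)})")
            if not isinstance(values, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            for key, value in values.items():
                if key not in cfg[section]:
                    raise ValueError(
                        f"unknown key {key!r} in section {section!r} "
                        f"(known: {sorted(cfg[section])})")
                cfg[section][key] = value
        scenario = cfg["run"]["scenario"]
        if scenario != "custom":
            if scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario {scenario!r} "
                                 f"(known: {sorted(SCENARIOS)} or 'custom')")
            cfg["trajectory"].update(SCENARIOS[scenario])
            cfg["brain"]["contact_time_ms"] = SCENARIOS[scenario]["contact_time_ms"]
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def to_yaml(self) -> str:
        return yaml.safe_dump(dict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(text) or {})
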