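"""Per-element scalar field histories on toy meshes.

Houses the post-processing inputs of strain/stress bookkeeping: each element
carries a measure (shell area in mm^2 or solid volume in mm^3) and a scalar
trace (von Mises stress in MPa or first principal strain) on a shared uniform
time base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

QUANTITIES = ("von_mises_stress_MPa", "principal_strain")
MEASURE_KINDS = ("area_mm2", "volume_mm3")


@dataclass(frozen=True)
class ElementFieldHistory:
    """Scalar time histories on a set of elements.

    ``traces`` is (n_elements, n_times); ``element_measure`` is the shell area
    (mm^2) or solid volume (mm^3) per element, declared by ``measure_kind``.
    """

    element_ids: np.ndarray
    element_measure: np.ndarray
    times: np.ndarray
    traces: np.ndarray
    quantity: str
    measure_kind: str

    def __post_init__(self) -> None:
        ids = np.asarray(self.element_ids, dtype=int)
        meas = np.asarray(self.element_measure, dtype=float)
        t = np.asarray(self.times, dtype=float)
        tr = np.asarray(self.traces, dtype=float)
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}, got {self.quantity!r}")
        if self.measure_kind not in MEASURE_KINDS:
            raise ValueError(f"measure_kind must be one of {MEASURE_KINDS}")
        if ids.size != meas.size:
            raise ValueError("element_ids and element_measure length mismatch")
        if tr.shape != (ids.size, t.size):
            raise ValueError(f"traces shape {tr.shape} != (n_elements={ids.size}, n_times={t.size})")
        if np.any(meas <= 0):
            raise ValueError("element measures must be positive")
        if ids.size != np.unique(ids).size:
            raise ValueError("element ids must be unique")
        object.__setattr__(self, "element_ids", ids)
        object.__setattr__(self, "element_measure", meas)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "traces", tr)

    @property
    def n_elements(self) -> int:
        return int(self.element_ids.size)

    @property
    def total_measure(self) -> float:
        return float(self.element_measure.sum())

    def exceedance_mask(self, level: float) -> np.ndarray:
        """Boolean per element: trace EVER strictly exceeds ``level``."""
        return np.any(self.traces > level, axis=1)


# ---------------------------------------------------------------------------
# I/O: HDF5 single-file container and a CSV trace-table fallback

def write_field_h5(path: str | Path, field: ElementFieldHistory) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["quantity"] = field.quantity
        f.attrs["measure_kind"] = field.measure_kind
        f.create_dataset("element_ids", data=field.element_ids)
        f.create_dataset("element_measure", data=field.element_measure)
        f.create_dataset("times_ms", data=field.times)
        f.create_dataset("traces", data=field.traces)


def read_field_h5(path: str | Path) -> ElementFieldHistory:
    with h5py.File(path, "r") as f:
        return ElementFieldHistory(
            element_ids=f["element_ids"][...],
            element_measure=f["element_measure"][...],
            times=f["times_ms"][...],
            traces=f["traces"][...],
            quantity=str(f.attrs["quantity"]),
            measure_kind=str(f.attrs["measure_kind"]),
        )


def write_field_csv(path: str | Path, field: ElementFieldHistory) -> None:
    """Trace table: one row per element, columns id, measure, then one per time."""
    cols = {"element_id": field.element_ids, "measure": field.element_measure}
    for j, t in enumerate(field.times):
        cols[f"t={t:.6g}"] = field.traces[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# quantity: {field.quantity}; measure_kind: {field.measure_kind}\n")
        df.to_csv(fh, index=False)


def read_field_csv(path: str | Path) -> ElementFieldHistory:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError("missing metadata header line")
    parts = dict(p.split(":", 1) for p in header.lstrip("# ").split(";"))
    parts = {k.strip(): v.strip() for k, v in parts.items()}
    df = pd.read_csv(path, comment="#")
    tcols = [c for c in df.columns if c.startswith("t=")]
    times = np.array([float(c[2:]) for c in tcols])
    return ElementFieldHistory(
        element_ids=df["element_id"].to_numpy(int),
        element_measure=df["measure"].to_numpy(float),
        times=times,
        traces=df[tcols].to_numpy(float),
        quantity=parts["quantity"],
        measure_kind=parts["measure_kind"],
    )
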