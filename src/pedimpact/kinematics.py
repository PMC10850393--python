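"""Head-impact kinematics extraction.

Given a time-stamped head trajectory and a vehicle contact surface, this
module recovers the descriptors a pedestrian-impact study reports: the first
contact time, the head velocity at contact (intrusion speed, km/h), the
intrusion angle (angle between the velocity vector and the horizontal plane,
degrees, 0-90), and the rotation radius of the path segment preceding
contact. Positions are mm, times ms; a velocity in mm/ms is numerically equal
to m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

KMH_PER_MM_MS = 3.6  # 1 mm/ms = 1 m/s = 3.6 km/h
INFINITE_RADIUS = math.inf
DEFAULT_CONTACT_TOLERANCE_MM = 5.0


@dataclass(frozen=True)
class ContactPlane:
    """Infinite plane: a point on it and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass(frozen=True)
class TrianglePatch:
    """Triangulated vehicle surface patch (vertices mm, triangle indices)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def distance(self, point: np.ndarray) -> float:
        return min(_point_triangle_distance(np.asarray(point, float),
                                            self.vertices[tri])
                   for tri in self.triangles)


@dataclass(frozen=True)
class ContactEvent:
    """First head-to-vehicle contact: when, where, how fast, at what angle."""

    time_ms: float
    location_mm: np.ndarray
    velocity_mm_ms: np.ndarray
    intrusion_angle_deg: float

    @property
    def speed_km_h(self) -> float:
        return float(np.linalg.norm(self.velocity_mm_ms) * KMH_PER_MM_MS)


def impact_angle(velocity: np.ndarray, surface_normal: np.ndarray | None = None) -> float:
    """Angle of a velocity vector, in degrees in [0, 90].

    Default convention: angle between the velocity and the horizontal (XY)
    plane, matching the regulatory headform-angle definition. If
    ``surface_normal`` is given, the surface-relative variant is returned
    instead: the angle between the velocity and the surface plane.
    """
    v = np.asarray(velocity, dtype=float).reshape(3)
    speed = np.linalg.norm(v)
    if speed == 0:
        raise ValueError("impact angle undefined for a zero velocity vector")
    if surface_normal is None:
        out_of_plane = abs(v[2])
    else:
        n = np.asarray(surface_normal, dtype=float).reshape(3)
        out_of_plane = abs(v @ (n / np.linalg.norm(n)))
    return math.degrees(math.asin(min(1.0, out_of_plane / speed)))


def impact_speed(velocity: np.ndarray) -> float:
    """Euclidean speed in km/h of a velocity given in mm/ms (= m/s)."""
    return float(np.linalg.norm(np.asarray(velocity, dtype=float)) * KMH_PER_MM_MS)


def _finite_difference_velocity(times: np.ndarray, path: np.ndarray, i: int) -> np.ndarray:
    """Central difference at sample i; one-sided at the endpoints. mm/ms."""
    n = len(times)
    if n < 2:
        raise ValueError("need at least two samples to estimate velocity")
    if 0 < i < n - 1:
        return (path[i + 1] - path[i - 1]) / (times[i + 1] - times[i - 1])
    if i == 0:
        return (path[1] - path[0]) / (times[1] - times[0])
    return (path[-1] - path[-2]) / (times[-1] - times[-2])


def detect_contact(times: np.ndarray, path: np.ndarray,
                   surface: ContactPlane | TrianglePatch,
                   tolerance: float = DEFAULT_CONTACT_TOLERANCE_MM,
                   ) -> ContactEvent | None:
    """First time the head point reaches within ``tolerance`` of the surface.

    For a plane, a sign change of the signed distance between consecutive
    samples also counts as contact (attributed to the nearer sample). Returns
    ``None`` when the path never reaches the surface — absence of contact is
    a result, not an error.
    """
    times = np.asarray(times, dtype=float)
    path = np.asarray(path, dtype=float).reshape(-1, 3)
    if len(times) != len(path):
        raise ValueError("times and path length mismatch")

    hit: int | None = None
    if isinstance(surface, ContactPlane):
        d = surface.signed_distance(path)
        within = np.abs(d) <= tolerance
        s = np.sign(d)
        touches = np.nonzero(s == 0)[0]                    # exactly on the plane
        changes = np.nonzero(s[:-1] * s[1:] < 0)[0]        # strict sign change
        first_within = int(np.argmax(within)) if within.any() else None
        cross_hit = None
        if touches.size and (not changes.size or touches[0] <= changes[0]):
            cross_hit = int(touches[0])
        elif changes.size:
            k = int(changes[0])
            cross_hit = k if abs(d[k]) <= abs(d[k + 1]) else k + 1
        if cross_hit is not None and (
                first_within is None
                or within[first_within:cross_hit + 1].all()):
            # the approach that first comes within tolerance carries through
            # the surface: attribute contact to the sample nearest the
            # geometric crossing
            hit = cross_hit
        else:
            # grazing pass (or no crossing at all): first within tolerance
            hit = first_within
    else:
        for i, p in enumerate(path):
            if surface.distance(p) <= tolerance:
                hit = i
                break
    if hit is None:
        return None
    vel = _finite_difference_velocity(times, path, hit)
    return ContactEvent(
        time_ms=float(times[hit]),
        location_mm=path[hit].copy(),
        velocity_mm_ms=vel,
        intrusion_angle_deg=impact_angle(vel),
    )


def rotation_radius(path: np.ndarray, collinear_tol: float = 1e-9) -> float:
    """Radius (mm) of the least-squares circle through a path segment.

    The points are projected onto their best-fit plane (SVD) and an algebraic
    (Kasa) circle fit is solved there; exact for points on a true circle.
    Collinear segments return an infinite-radius sentinel.
    """
    pts = np.asarray(path, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least three points to fit a circle")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = svals[0]
    if scale == 0 or svals[1] <= collinear_tol * scale:
        return INFINITE_RADIUS
    uv = centered @ vt[:2].T  # in-plane 2-D coordinates
    # Kasa fit: minimize ||x^2+y^2 - 2ax - 2by - c||
    A = np.column_stack([2 * uv, np.ones(len(uv))])
    rhs = (uv**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    a, b, c = sol
    r2 = c + a * a + b * b
    return float(np.sqrt(r2)) if r2 > 0 else INFINITE_RADIUS


def rotation_radius_before(times: np.ndarray, path: np.ndarray,
                           t_contact: float, window_ms: float) -> float:
    """Rotation radius of the path over the ``window_ms`` preceding contact."""
    times = np.asarray(times, dtype=float)
    mask = (times >= t_contact - window_ms) & (times <= t_contact)
    if mask.sum() < 3:
        raise ValueError("fewer than three samples in the pre-contact window")
    return rotation_radius(np.asarray(path, float)[mask])


@dataclass(frozen=True)
class HeadformPreset:
    """Regulatory adult headform impact test configuration."""

    speed_km_h: float
    angle_deg: float
    surface: str


def cncap_preset() -> HeadformPreset:
    """Adult headform preset of the pedestrian protection test procedure:
    40 km/h impact speed at 60 degrees onto the windshield area."""
    return HeadformPreset(speed_km_h=40.0, angle_deg=60.0, surface="windshield")


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    """Euclidean distance from a point to a 3-D triangle."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + t * ab)))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + t * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + t * (c - b))))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))
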