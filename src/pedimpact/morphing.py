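"""Landmark-driven Kriging mesh morphing and anthropometry.

A target-percentile body model is built from a baseline mesh in three steps:
vertex-corresponding surface meshes are averaged arithmetically; a Kriging
(dual radial-basis) transform with linear polynomial drift is fitted from the
baseline landmark set to the target landmark set; and the transform is
applied to every mesh node, leaving connectivity untouched. The transform is
an exact interpolator at the control points, and — because the drift is a
full linear polynomial — reproduces any affine landmark correspondence
globally. Anthropometric dimensions are then measured off the morphed mesh.

For each output coordinate the mapping is
``f(x) = c0 + C x + sum_i w_i k(|x - p_i|)`` with kernel ``k`` one of
``|r|``, ``|r|^3`` (default) or the thin-plate ``r^2 log r``; the weights
satisfy the orthogonality side conditions that make the drift absorb the
polynomial part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _la

from .meshes import LandmarkSet, Mesh

KERNELS = ("linear", "cubic", "thin_plate")
LANDMARK_TOL_MM = 1e-6


def _kernel_eval(r: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "linear":
        return r
    if kernel == "cubic":
        return r**3
    if kernel == "thin_plate":
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


@dataclass(frozen=True)
class KrigingTransform:
    """Fitted drift + covariance coefficients mapping source to target space.

    ``drift_coefficients`` is (4, 3): rows constant, x, y, z; columns the
    output coordinates. ``covariance_weights`` is (n_control, 3). Control
    points are stored normalized (centered, isotropically scaled) for
    conditioning; ``shift``/``scale`` undo the normalization.
    """

    control_points: LandmarkSet
    drift_coefficients: np.ndarray
    covariance_weights: np.ndarray
    kernel: str
    shift: np.ndarray
    scale: float

    def __call__(self, nodes: np.ndarray) -> np.ndarray:
        return apply_transform(self, nodes)


def fit_kriging(source: LandmarkSet, target: LandmarkSet,
                kernel: str = "cubic") -> KrigingTransform:
    """Fit the Kriging transform taking source landmarks to target landmarks.

    Requires identical label sets and at least 4 non-coplanar control points
    (the linear drift needs a full-rank polynomial basis). Exact interpolation
    at the landmarks is guaranteed to solver tolerance.
    """
    if set(source.names) != set(target.names):
        missing = set(source.names) ^ set(target.names)
        raise ValueError(f"source/target label sets differ: {sorted(missing)}")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
    # align target rows to source label order
    tgt = np.array([target[name] for name in source.names])
    src = source.coordinates
    n = len(source)
    if n < 4:
        raise ValueError("need at least 4 control points for a 3-D linear drift")

    dup = _duplicate_pairs(src, source.names)
    if dup:
        raise ValueError(f"duplicate control points: {dup}")

    shift = src.mean(axis=0)
    scale = float(np.abs(src - shift).max()) or 1.0
    p = (src - shift) / scale

    poly = np.column_stack([np.ones(n), p])             # (n, 4)
    if np.linalg.matrix_rank(poly, tol=1e-9) < 4:
        raise ValueError(
            "control points are coplanar; the linear drift is singular "
            f"(points: {list(source.names)})")

    r = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    K = _kernel_eval(r, kernel)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = poly
    A[n:, :n] = poly.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = _la.solve(A, rhs)
    except _la.LinAlgError as exc:
        raise ValueError(
            f"singular Kriging system for points {list(source.names)}: {exc}"
        ) from exc
    transform = KrigingTransform(
        control_points=source,
        covariance_weights=sol[:n],
        drift_coefficients=sol[n:],
        kernel=kernel, shift=shift, scale=scale,
    )
    check = apply_transform(transform, src)
    err = np.abs(check - tgt).max()
    if err > LANDMARK_TOL_MM:
        raise ValueError(
            f"Kriging fit failed landmark exactness: max error {err:.2e} mm "
            f"(ill-conditioned control points {list(source.names)})")
    return transform


def apply_transform(transform: KrigingTransform, nodes: np.ndarray,
                    chunk_size: int = 50_000) -> np.ndarray:
    """Map a node set through a fitted transform (positions only).

    Evaluated in chunks; chunking never changes the result (each node's image
    depends only on that node and the fitted coefficients).
    """
    nodes = np.asarray(nodes, dtype=float).reshape(-1, 3)
    if nodes.size == 0:
        return nodes.copy()
    ctrl = (transform.control_points.coordinates - transform.shift) / transform.scale
    out = np.empty_like(nodes)
    for start in range(0, len(nodes), chunk_size):
        block = (nodes[start:start + chunk_size] - transform.shift) / transform.scale
        r = np.linalg.norm(block[:, None, :] - ctrl[None, :, :], axis=2)
        K = _kernel_eval(r, transform.kernel)
        poly = np.column_stack([np.ones(len(block)), block])
        out[start:start + chunk_size] = (K @ transform.covariance_weights
                                         + poly @ transform.drift_coefficients)
    return out


def morph_mesh(mesh: Mesh, transform: KrigingTransform) -> Mesh:
    """Apply the transform to every mesh node; connectivity is preserved."""
    return mesh.with_vertices(apply_transform(transform, mesh.vertices))


def average_surfaces(meshes: list[Mesh]) -> Mesh:
    """Arithmetic mean of vertex-corresponding surfaces (template-registered).

    Output vertex ``i`` is the mean of the input vertices ``i``; connectivity
    is taken from the first mesh and must match across all inputs.
    """
    if not meshes:
        raise ValueError("need at least one mesh")
    first = meshes[0]
    for j, m in enumerate(meshes[1:], start=1):
        if not first.same_connectivity(m):
            raise ValueError(
                f"mesh 0 and mesh {j} differ: "
                f"{first.n_vertices} vs {m.n_vertices} vertices, "
                f"{len(first.faces)} vs {len(m.faces)} faces")
    mean_verts = np.mean([m.vertices for m in meshes], axis=0)
    return first.with_vertices(mean_verts)


@dataclass(frozen=True)
class AnthropometryTable:
    """Body-dimension summary of a (possibly morphed) surface model, mm/kg."""

    height: float
    eye_level: float
    shoulder_height: float
    perineal_height: float
    tibial_height: float
    shoulder_width: float
    thorax_width: float
    weight: float | None = None  # enclosed-volume estimate, approximate

    def __post_init__(self) -> None:
        lengths = (self.height, self.eye_level, self.shoulder_height,
                   self.perineal_height, self.tibial_height,
                   self.shoulder_width, self.thorax_width)
        if any(v <= 0 for v in lengths):
            raise ValueError("all dimensions must be positive")
        if self.eye_level >= self.height or self.shoulder_height >= self.height:
            raise ValueError("eye level and shoulder height must be below height")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if d["weight"] is None:
            d.pop("weight")
        return d


#: uniform soft-tissue density used for the approximate weight estimate
BODY_DENSITY_KG_MM3 = 1000.0 * 1e-9


def measure_anthropometry(mesh: Mesh, landmarks: LandmarkSet,
                          estimate_weight: bool = False) -> AnthropometryTable:
    """Measure body dimensions from a surface mesh and its landmarks.

    Height is the mesh's vertical extent; levels are the Z of the named
    landmarks; widths are landmark separations (shoulder left-right along Y,
    thorax front-back along X). The optional weight is enclosed volume times
    a uniform density and is approximate by construction.
    """
    required = ("eye", "shoulder_l", "shoulder_r", "perineum", "tibia",
                "thorax_front", "thorax_back")
    for name in required:
        if name not in landmarks:
            raise KeyError(f"landmark {name!r} missing from the landmark set")
    z0 = mesh.vertices[:, 2].min()
    weight = None
    if estimate_weight:
        weight = mesh.enclosed_volume() * BODY_DENSITY_KG_MM3
    return AnthropometryTable(
        height=mesh.vertical_extent(),
        eye_level=float(landmarks["eye"][2] - z0),
        shoulder_height=float(
            (landmarks["shoulder_l"][2] + landmarks["shoulder_r"][2]) / 2 - z0),
        perineal_height=float(landmarks["perineum"][2] - z0),
        tibial_height=float(landmarks["tibia"][2] - z0),
        shoulder_width=float(abs(landmarks["shoulder_l"][1]
                                 - landmarks["shoulder_r"][1])),
        thorax_width=float(abs(landmarks["thorax_front"][0]
                               - landmarks["thorax_back"][0])),
        weight=weight,
    )


def _duplicate_pairs(points: np.ndarray, names: tuple[str, ...],
                     tol: float = 1e-9) -> list[tuple[str, str]]:
    dupes = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.linalg.norm(points[i] - points[j]) <= tol:
                dupes.append((names[i], names[j]))
    return dupes
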