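"""Surface meshes, anatomical landmark sets, and solver-keyword text I/O.

Coordinates are mm in a right-handed frame: X along vehicle travel, Z vertical.
The interchange formats are deliberately minimal: a *NODE/*ELEMENT_SHELL/
*ELEMENT_SOLID keyword subset of the common explicit-solver deck syntax, a
generic OFF triangle-mesh format, and label,x,y,z CSV for landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Mesh:
    """Triangle surface mesh (vertices mm, faces as vertex indices).

    ``solids`` optionally carries 8-node (or 4-node) volume element
    connectivity for decks that mix shells and solids.
    """

    vertices: np.ndarray
    faces: np.ndarray
    solids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.size and (f.ndim != 2 or f.shape[1] != 3):
            raise ValueError("faces must be (m, 3) triangles")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of vertex range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f.reshape(-1, 3) if f.size else f.reshape(0, 3))

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def vertical_extent(self) -> float:
        """Height of the mesh bounding box along Z, in mm."""
        z = self.vertices[:, 2]
        return float(z.max() - z.min())

    def same_connectivity(self, other: "Mesh") -> bool:
        return (self.n_vertices == other.n_vertices
                and np.array_equal(self.faces, other.faces))

    def with_vertices(self, vertices: np.ndarray) -> "Mesh":
        return Mesh(vertices, self.faces, self.solids)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem, mm^3 (closed mesh assumed)."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points (mm). Names unique, one coordinate each."""

    names: tuple[str, ...]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.names)
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate landmark names: {dupes}")
        if coords.shape[0] != len(names):
            raise ValueError("coordinate count must equal name count")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.coordinates[self.names.index(name)]
        except ValueError:
            raise KeyError(f"landmark {name!r} not present (have {list(self.names)})") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: list[str]) -> "LandmarkSet":
        return LandmarkSet(tuple(names), np.array([self[n] for n in names]))


# ---------------------------------------------------------------------------
# solver-keyword deck subset

def write_keyword(path: str | Path, mesh: Mesh) -> None:
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i:8d}{x:16.6f}{y:16.6f}{z:16.6f}\n")
        if mesh.faces.size:
            fh.write("*ELEMENT_SHELL\n")
            for eid, (a, b, c) in enumerate(mesh.faces + 1, start=1):
                # degenerate 4th node repeats the 3rd (triangle-as-quad convention)
                fh.write(f"{eid:8d}{1:8d}{a:8d}{b:8d}{c:8d}{c:8d}\n")
        if mesh.solids is not None and len(mesh.solids):
            fh.write("*ELEMENT_SOLID\n")
            for eid, nodes in enumerate(np.asarray(mesh.solids) + 1, start=1):
                fh.write(f"{eid:8d}{1:8d}" + "".join(f"{n:8d}" for n in nodes) + "\n")
        fh.write("*END\n")


def read_keyword(path: str | Path) -> Mesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    solids: list[list[int]] = []
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("$"):
            continue
        if line.startswith("*"):
            section = line.upper()
            continue
        parts = line.split()
        if section == "*NODE":
            verts.append([float(p) for p in parts[1:4]])
        elif section == "*ELEMENT_SHELL":
            nodes = [int(p) - 1 for p in parts[2:6]]
            tri = nodes[:3] if len(nodes) < 4 or nodes[3] == nodes[2] else None
            if tri is None:
                raise ValueError("only triangular (degenerate-quad) shells supported")
            faces.append(tri)
        elif section == "*ELEMENT_SOLID":
            solids.append([int(p) - 1 for p in parts[2:]])
    return Mesh(np.array(verts).reshape(-1, 3),
                np.array(faces, dtype=int).reshape(-1, 3),
                np.array(solids, dtype=int) if solids else None)


# ---------------------------------------------------------------------------
# generic triangle-mesh text format (OFF) and landmark CSV

def write_off(path: str | Path, mesh: Mesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def read_off(path: str | Path) -> Mesh:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if lines[0].strip() != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2:2 + nv]])
    faces = np.array([[int(x) for x in ln.split()[1:4]] for ln in lines[2 + nv:2 + nv + nf]],
                     dtype=int).reshape(-1, 3)
    return Mesh(verts, faces)


def write_landmarks_csv(path: str | Path, lm: LandmarkSet) -> None:
    df = pd.DataFrame(lm.coordinates, columns=["x", "y", "z"])
    df.insert(0, "label", lm.names)
    df.to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(tuple(df["label"]), df[["x", "y", "z"]].to_numpy(float))
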