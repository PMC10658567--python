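"""Triangulated epicardial shells and discrete Gaussian curvature.

Curvature is computed by the angle-deficit (discrete Gauss–Bonnet)
formula: at an interior vertex v,

    K_v = (2*pi - sum of incident face angles at v) / A_v

with A_v the barycentric vertex area (one third of the incident face
areas).  Boundary vertices use ``pi`` in place of ``2*pi`` and are flagged.
Summed over a closed mesh the products K_v * A_v recover 2*pi*chi exactly
(Descartes' theorem), which makes the discretization self-checking.
Positive K marks locally spherical (elliptic) regions of a shell, negative
K saddle-like (hyperbolic) regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import InvalidArgumentError, MeshParseError

__all__ = [
    "TriangleMesh",
    "CurvatureMap",
    "load_mesh",
    "gaussian_curvature",
    "total_curvature",
]

log = logging.getLogger(__name__)

_AREA_EPS = 1e-12  # mm^2; faces below this are degenerate


@dataclass(frozen=True)
class TriangleMesh:
    """Vertices (mm) and triangular faces of a surface mesh."""

    vertices: np.ndarray  # (nv, 3) float, mm
    faces: np.ndarray     # (nf, 3) int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3 or not np.all(np.isfinite(v)):
            raise InvalidArgumentError("vertices must be finite (nv, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidArgumentError("faces must be (nf, 3)")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise InvalidArgumentError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open boundary (edges used once)."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[uniq[counts == 1].ravel()] = True
        return mask

    def euler_characteristic(self) -> int:
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        n_edges = np.unique(edges, axis=0).shape[0]
        return self.n_vertices - n_edges + self.n_faces


@dataclass(frozen=True)
class CurvatureMap:
    """Per-vertex Gaussian curvature K (1/mm^2) with area weights (mm^2)."""

    K: np.ndarray
    area: np.ndarray
    boundary: np.ndarray  # flagged: angle deficit taken against pi, not 2*pi
    valid: np.ndarray     # False where the area weight vanished

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": np.arange(self.K.size),
                "K_per_mm2": self.K,
                "area_mm2": self.area,
                "boundary_flag": self.boundary.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_mesh(path, file_format: str | None = None) -> TriangleMesh:
    """Read an STL/OBJ/PLY surface mesh into a :class:`TriangleMesh`.

    Vertex coordinates are taken verbatim from the file (no merging or
    re-ordering).  Zero-area faces are dropped with a logged count.
    """
    path = Path(path)
    fmt = file_format or path.suffix.lstrip(".").lower()
    try:
        loaded = trimesh.load(
            str(path), file_type=fmt, process=False, force="mesh"
        )
        vertices = np.asarray(loaded.vertices, dtype=float)
        faces = np.asarray(loaded.faces, dtype=int)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise MeshParseError(f"could not parse {path.name!r} as {fmt}: {exc}") from exc
    if vertices.size == 0 or faces.size == 0:
        raise MeshParseError(f"{path.name!r}: no triangles found ({fmt})")
    mesh = TriangleMesh(vertices=vertices, faces=faces)
    areas = mesh.face_areas()
    bad = areas <= _AREA_EPS
    if np.any(bad):
        log.warning("%s: dropped %d degenerate faces", path.name, int(bad.sum()))
        mesh = TriangleMesh(vertices=vertices, faces=faces[~bad])
    return mesh


def _corner_angles(mesh: TriangleMesh) -> np.ndarray:
    """(nf, 3) interior angle at each face corner, radians."""
    v = mesh.vertices
    f = mesh.faces
    angles = np.empty((mesh.n_faces, 3), dtype=float)
    for corner in range(3):
        a = v[f[:, (corner + 1) % 3]] - v[f[:, corner]]
        b = v[f[:, (corner + 2) % 3]] - v[f[:, corner]]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, _AREA_EPS)
        angles[:, corner] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return angles


def gaussian_curvature(mesh: TriangleMesh) -> CurvatureMap:
    """Angle-deficit Gaussian curvature with barycentric area weights."""
    if mesh.n_faces == 0:
        raise InvalidArgumentError("mesh has no faces")
    angles = _corner_angles(mesh)
    areas = mesh.face_areas()

    angle_sum = np.zeros(mesh.n_vertices)
    vertex_area = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(angle_sum, mesh.faces[:, corner], angles[:, corner])
        np.add.at(vertex_area, mesh.faces[:, corner], areas / 3.0)

    boundary = mesh.boundary_vertices()
    full_angle = np.where(boundary, np.pi, 2.0 * np.pi)
    valid = vertex_area > _AREA_EPS
    K = np.zeros(mesh.n_vertices)
    K[valid] = (full_angle[valid] - angle_sum[valid]) / vertex_area[valid]
    K[~valid] = np.nan
    return CurvatureMap(K=K, area=vertex_area, boundary=boundary, valid=valid)


def total_curvature(curv: CurvatureMap) -> float:
    """Integrated curvature  sum K_v * A_v  over a closed mesh.

    Equals ``2*pi*chi`` (4*pi for a genus-0 shell, 0 for a torus).  Refuses
    open meshes, where the boundary geodesic-curvature term is missing.
    """
    if np.any(curv.boundary):
        raise InvalidArgumentError(
            "total curvature is only defined for closed meshes; "
            "this map has boundary vertices (Gauss-Bonnet needs the boundary term)"
        )
    v = curv.valid
    return float(np.sum(curv.K[v] * curv.area[v]))
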