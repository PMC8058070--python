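"""Mesh and landmark data model, file I/O and exact surface-geometry queries.

All coordinates are millimetres. Vertex indices are 0-based internally; OBJ's
1-based indexing is converted at the I/O boundary. Meshes are not required to
be watertight or manifold — segmented anatomical surfaces often are not — only
the invariants below are enforced:

* every face index in ``[0, n_vertices)``,
* no face with a repeated vertex or (near-)zero area,
* all coordinates finite.

Closest-point queries are contractually exact: a KD-tree prefilter over face
centroids only discards faces that provably cannot hold the global minimum,
and ties between faces are broken by the lowest face index.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from ._geometry import SurfaceQuery, face_normals, vertex_normals
from .errors import (
    DegenerateGeometryError,
    InvalidMeshError,
    MeshFormatError,
    MissingLandmarkError,
)

MESH_FORMATS = ("obj", "ply", "stl")
_AREA_TOL = 1e-12  # mm^2

#: The 26 anatomical landmarks of the study protocol, in report order
#: (right side, midline, left side).
CANONICAL_LANDMARKS_26 = (
    "right condylar superior pole",
    "right condylar medial pole",
    "right condylar lateral pole",
    "right condylar posterior point",
    "right fovea pterygoidea",
    "right incisura lowest point",
    "right coronoid process tip",
    "right lingula",
    "right gonion",
    "right antegonial notch",
    "right mental foramen",
    "right tuberculum mentale",
    "protuberans mentale",
    "spina mentalis",
    "left tuberculum mentale",
    "left mental foramen",
    "left antegonial notch",
    "left gonion",
    "left lingula",
    "left coronoid process tip",
    "left incisura lowest point",
    "left fovea pterygoidea",
    "left condylar posterior point",
    "left condylar lateral pole",
    "left condylar medial pole",
    "left condylar superior pole",
)

#: The five crudely indicated positioning landmarks that initialize mapping.
CANONICAL_INIT_5 = (
    "left condylar lateral pole",
    "right condylar lateral pole",
    "left gonion",
    "right gonion",
    "protuberans mentale",
)


def _validate_mesh(vertices: np.ndarray, faces: np.ndarray) -> None:
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise InvalidMeshError(f"vertices must be (n, 3), got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise InvalidMeshError(f"faces must be (m, 3), got {faces.shape}")
    if len(vertices) == 0 or len(faces) == 0:
        raise InvalidMeshError("empty mesh (no vertices or no faces)")
    if not np.all(np.isfinite(vertices)):
        bad = int(np.nonzero(~np.isfinite(vertices).all(axis=1))[0][0])
        raise InvalidMeshError(f"non-finite coordinates at vertex {bad}")
    n = len(vertices)
    out = (faces < 0) | (faces >= n)
    if out.any():
        bad = int(np.nonzero(out.any(axis=1))[0][0])
        raise InvalidMeshError(
            f"face {bad} has vertex index out of range [0, {n}): {faces[bad].tolist()}"
        )
    rep = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if rep.any():
        bad = int(np.nonzero(rep)[0][0])
        raise InvalidMeshError(f"face {bad} repeats a vertex index: {faces[bad].tolist()}")
    tri = vertices[faces]
    area2 = np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    tiny = area2 / 2.0 <= _AREA_TOL
    if tiny.any():
        bad = int(np.nonzero(tiny)[0][0])
        raise InvalidMeshError(f"face {bad} has (near-)zero area")


class SurfaceMesh:
    """Immutable triangle surface mesh (coordinates in mm)."""

    __slots__ = ("vertices", "faces", "_query", "_vnormals", "_fnormals")

    def __init__(self, vertices, faces, validate: bool = True):
        v = np.array(vertices, dtype=float, copy=True)
        f = np.array(faces, dtype=np.int64, copy=True)
        if validate:
            _validate_mesh(v, f)
        v.setflags(write=False)
        f.setflags(write=False)
        self.vertices = v
        self.faces = f
        self._query = None
        self._vnormals = None
        self._fnormals = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def query(self) -> SurfaceQuery:
        if self._query is None:
            self._query = SurfaceQuery(self.vertices, self.faces)
        return self._query

    @property
    def vertex_normals(self) -> np.ndarray:
        if self._vnormals is None:
            self._vnormals = vertex_normals(self.vertices, self.faces)
        return self._vnormals

    @property
    def face_normals(self) -> np.ndarray:
        if self._fnormals is None:
            self._fnormals = face_normals(self.vertices, self.faces)
        return self._fnormals

    def with_vertices(self, vertices, validate: bool = False) -> "SurfaceMesh":
        """Same topology with new vertex positions."""
        m = SurfaceMesh(vertices, self.faces, validate=validate)
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurfaceMesh({self.n_vertices} vertices, {self.n_faces} faces)"


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Ordered, named sparse landmark set (mm)."""

    names: tuple
    points: np.ndarray

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        pts = np.array(self.points, dtype=float, copy=True)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if len(names) != len(pts):
            raise ValueError(f"{len(names)} names but {len(pts)} points")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate landmark names: {dup}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite landmark coordinates")
        pts.setflags(write=False)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise MissingLandmarkError(f"landmark {name!r} not in configuration") from None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.index(name)]

    def subset(self, names) -> "LandmarkConfiguration":
        idx = [self.index(n) for n in names]
        return LandmarkConfiguration(tuple(names), self.points[idx])

    def transformed(self, fn) -> "LandmarkConfiguration":
        """Apply a transform (object with .apply or a callable) to all points."""
        apply = fn.apply if hasattr(fn, "apply") else fn
        return LandmarkConfiguration(self.names, apply(self.points))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["x", "y", "z"], index=list(self.names))


@dataclass(frozen=True)
class BarycentricPoint:
    """A surface location: face index plus convex weights over its 3 vertices."""

    face_index: int
    weights: np.ndarray

    def __post_init__(self):
        w = np.array(self.weights, dtype=float, copy=True)
        if w.shape != (3,):
            raise ValueError(f"weights must have shape (3,), got {w.shape}")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"barycentric weights sum to {w.sum()!r}, not 1")
        if np.any(w < -1e-9) or np.any(w > 1.0 + 1e-9):
            raise ValueError(f"barycentric weights outside [0, 1]: {w.tolist()}")
        w = np.clip(w, 0.0, 1.0)
        w /= w.sum()
        w.setflags(write=False)
        object.__setattr__(self, "face_index", int(self.face_index))
        object.__setattr__(self, "weights", w)


# ---------------------------------------------------------------------------
# file I/O


def _infer_format(path, fmt=None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = str(fmt).lower()
    if fmt not in MESH_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {MESH_FORMATS}")
    return fmt


def read_mesh(path, fmt=None) -> SurfaceMesh:
    """Read OBJ / PLY / STL into a :class:`SurfaceMesh`, preserving vertex order.

    STL is a triangle soup: shared-vertex topology is not recoverable and the
    vertex/face layout follows the file's triangle order.
    """
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshFormatError(f"{path} does not contain a single triangle mesh")
    try:
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    except InvalidMeshError as exc:
        raise MeshFormatError(f"{path}: {exc}") from exc


def _export_ply_double(mesh: SurfaceMesh) -> bytes:
    # trimesh's PLY writer stores float32 coordinates, which loses ~2e-6 mm at
    # anatomical scale; write double-precision ASCII PLY instead (readable by
    # any PLY parser, including trimesh's).
    buf = io.StringIO()
    buf.write("ply\nformat ascii 1.0\n")
    buf.write(f"element vertex {mesh.n_vertices}\n")
    buf.write("property double x\nproperty double y\nproperty double z\n")
    buf.write(f"element face {mesh.n_faces}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    for x, y, z in mesh.vertices:
        buf.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    for a, b, c in mesh.faces:
        buf.write(f"3 {a} {b} {c}\n")
    return buf.getvalue().encode()


def write_mesh(mesh: SurfaceMesh, path, fmt=None) -> Path:
    """Write a mesh; OBJ and PLY round-trip vertices to better than 1e-6 mm.

    STL (binary) is contractually lossy: the format stores independent float32
    triangles, so shared-vertex topology and full double precision are lost.
    """
    fmt = _infer_format(path, fmt)
    path = Path(path)
    try:
        if fmt == "ply":
            path.write_bytes(_export_ply_double(mesh))
        else:
            tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
            tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise MeshFormatError(f"cannot write {path}: {exc}") from exc
    return path


def read_landmarks(path) -> LandmarkConfiguration:
    """Read a ``name,x,y,z`` CSV (mm) into a landmark configuration."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise MeshFormatError(
            f"{path}: landmark CSV must have columns name,x,y,z (got {list(df.columns)})"
        )
    return LandmarkConfiguration(
        tuple(df["name"].astype(str)), df[["x", "y", "z"]].to_numpy(dtype=float)
    )


def write_landmarks(config: LandmarkConfiguration, path) -> Path:
    df = config.as_frame().reset_index(names="name")
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# surface queries


def closest_point_on_surface(point, mesh: SurfaceMesh):
    """Globally closest surface point to ``point``.

    Returns ``(point_on_surface, BarycentricPoint, distance_mm)``.
    """
    pts, fi, bary, dist = mesh.query.closest(np.asarray(point, dtype=float)[None, :])
    return pts[0], BarycentricPoint(int(fi[0]), bary[0]), float(dist[0])


def closest_points_on_surface(points, mesh: SurfaceMesh):
    """Batch closest-point query: ``(points, face_indices, barycentric, distances)``."""
    return mesh.query.closest(np.asarray(points, dtype=float))


def barycentric_to_cartesian(bc: BarycentricPoint, mesh) -> np.ndarray:
    """Evaluate a barycentric surface address on a mesh (or anything with
    ``vertices``/``faces`` arrays sharing the binding topology)."""
    faces = np.asarray(mesh.faces)
    if not 0 <= bc.face_index < len(faces):
        raise InvalidMeshError(
            f"face index {bc.face_index} invalid for mesh with {len(faces)} faces"
        )
    verts = np.asarray(mesh.vertices)[faces[bc.face_index]]
    return bc.weights @ verts


def centroid_size(config) -> float:
    """Square root of the summed squared distances of landmarks to their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got {pts.shape}")
    if len(pts) < 2:
        raise DegenerateGeometryError("centroid size needs at least 2 landmarks")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))
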