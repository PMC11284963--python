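"""Surface-mesh data model and geometric primitives for long-bone analysis.

All coordinates are millimetres. A bone scan is a triangulated surface
(:class:`SurfaceMesh`). Scans are related by similarity transforms
(:class:`SimilarityTransform`: uniform scale, proper rotation, translation),
and each bone carries an anatomical coordinate frame (:class:`BoneFrame`)
derived from the principal axes of its vertex cloud: the dominant axis is
the diaphyseal (long) axis, the remaining two span the transverse plane.
Axial positions along the bone are expressed as fractions of bone length
(0 = distal tip, 1 = proximal tip), which parameterizes both the sectioning
used by the rotation-change pipeline and the virtual-twist simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "MeshError",
    "MeshFormatError",
    "MeshValidationError",
    "DegenerateGeometryError",
    "SectioningError",
    "SurfaceMesh",
    "SimilarityTransform",
    "BoneFrame",
    "RotationTriple",
    "EULER_XYZ",
    "ROTVEC",
    "load_mesh",
    "save_mesh",
    "apply_similarity",
    "principal_frame",
    "axial_fraction",
    "extract_section",
    "rotation_to_components",
    "components_to_rotation",
]

#: Euler decomposition about fixed (extrinsic) axes: R = Rz(c) @ Ry(b) @ Rx(a).
EULER_XYZ = "euler-xyz-extrinsic"
#: Axis-angle vector (matrix logarithm) scaled to degrees.
ROTVEC = "rotation-vector"

_SUPPORTED_SUFFIXES = {".stl", ".ply", ".obj"}


class MeshError(Exception):
    """Base class for mesh-layer errors."""


class MeshFormatError(MeshError):
    """File missing, unreadable, or in an unsupported format."""


class MeshValidationError(MeshError):
    """Mesh violates the surface-mesh invariants."""


class DegenerateGeometryError(MeshError):
    """Vertex cloud has no well-defined 3D principal frame."""


class SectioningError(MeshError):
    """Requested axial section contains no complete triangle."""


@dataclass
class SurfaceMesh:
    """Triangulated bone surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex indices per triangle, counter-clockwise when viewed from
        outside (outward normals).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.vertices.shape[0] < 4:
            raise MeshValidationError("a surface mesh needs at least 4 vertices")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("vertex coordinates must be finite")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if self.faces.shape[0] == 0:
            raise MeshValidationError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= self.vertices.shape[0]:
            raise MeshValidationError("face index out of range")
        f = self.faces
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise MeshValidationError("face with repeated vertex")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        """Unprocessed trimesh view (no welding, no reordering)."""
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def transformed(self, t: "SimilarityTransform") -> "SurfaceMesh":
        return SurfaceMesh(t.apply(self.vertices), self.faces.copy())


def _check_rotation(rotation: np.ndarray, tol: float = 1e-9) -> None:
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=tol):
        raise ValueError("rotation matrix must be proper (det +1)")


@dataclass(frozen=True)
class SimilarityTransform:
    """``p -> scale * rotation @ p + translation`` with proper rotation."""

    scale: float = 1.0
    rotation: np.ndarray = None  # type: ignore[assignment]
    translation: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rot = np.eye(3) if self.rotation is None else np.asarray(self.rotation, dtype=np.float64)
        tra = np.zeros(3) if self.translation is None else np.asarray(self.translation, dtype=np.float64)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra.reshape(3))
        object.__setattr__(self, "scale", float(self.scale))
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        _check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``inner`` first, then ``self``."""
        return SimilarityTransform(
            self.scale * inner.scale,
            self.rotation @ inner.rotation,
            self.scale * self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        inv_s = 1.0 / self.scale
        inv_r = self.rotation.T
        return SimilarityTransform(inv_s, inv_r, -inv_s * inv_r @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


def apply_similarity(mesh: SurfaceMesh, t: SimilarityTransform) -> SurfaceMesh:
    """Map every vertex through ``t``; connectivity is unchanged."""
    return mesh.transformed(t)


@dataclass(frozen=True)
class BoneFrame:
    """Anatomical frame of a long bone.

    ``axis_long`` is the diaphyseal axis, ``axis_2``/``axis_3`` span the
    transverse plane; ``(axis_2, axis_3, axis_long)`` is a right-handed
    orthonormal triple so :attr:`basis` maps bone coordinates (x, y, z)
    with z along the shaft. ``origin`` sits on the axis at the distal
    tip; ``proximal_sign`` says which direction along ``axis_long`` is
    proximal (frames built by :func:`principal_frame` always use +1 and
    orient ``axis_long`` itself proximally).
    """

    origin: np.ndarray
    axis_long: np.ndarray
    axis_2: np.ndarray
    axis_3: np.ndarray
    length: float
    proximal_sign: int = 1

    def __post_init__(self) -> None:
        for name in ("origin", "axis_long", "axis_2", "axis_3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3))
        object.__setattr__(self, "length", float(self.length))
        object.__setattr__(self, "proximal_sign", int(self.proximal_sign))
        if not self.length > 0:
            raise ValueError("length must be positive")
        if self.proximal_sign not in (-1, 1):
            raise ValueError("proximal_sign must be +1 or -1")
        basis = np.column_stack([self.axis_2, self.axis_3, self.axis_long])
        if not np.allclose(basis.T @ basis, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if not np.isclose(np.linalg.det(basis), 1.0, atol=1e-9):
            raise ValueError("frame axes must be right-handed")

    @property
    def proximal_direction(self) -> np.ndarray:
        return self.proximal_sign * self.axis_long

    @property
    def basis(self) -> np.ndarray:
        """Columns (axis_2, axis_3, axis_long): bone -> world rotation."""
        return np.column_stack([self.axis_2, self.axis_3, self.axis_long])

    def axis_point(self, fraction: float) -> np.ndarray:
        """Point on the long axis at the given axial fraction."""
        return self.origin + fraction * self.length * self.proximal_direction


def principal_frame(mesh: SurfaceMesh, proximal_hint: np.ndarray | None = None) -> BoneFrame:
    """Anatomical frame from the principal axes of the vertex cloud.

    The long axis is the dominant eigenvector of the vertex covariance.
    Its proximal orientation comes from ``proximal_hint`` (a rough world
    direction toward the proximal end) when given; otherwise from the
    heuristic that the proximal extremity is the one whose outermost slab
    of vertices has the larger transverse centroid offset from the axis:
    the head and neck shift the proximal end off-axis, while the paired
    condyles straddle the axis. Transverse-axis signs are fixed
    deterministically from the third moment of the projections so that
    repeated calls on the same geometry give the same frame.

    Raises
    ------
    DegenerateGeometryError
        If the vertex covariance is rank-deficient (flat or linear cloud).
    """
    v = mesh.vertices
    centroid = v.mean(axis=0)
    x = v - centroid
    cov = x.T @ x / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-10 * evals[2]:
        raise DegenerateGeometryError("vertex covariance is rank-deficient")

    axis_long = evecs[:, 2]
    t = x @ axis_long
    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=np.float64)
        if float(hint @ axis_long) < 0:
            axis_long = -axis_long
            t = -t
    else:
        transverse = x - np.outer(t, axis_long)
        span = t.max() - t.min()
        hi = t >= t.max() - 0.10 * span
        lo = t <= t.min() + 0.10 * span
        off_hi = np.linalg.norm(transverse[hi].mean(axis=0))
        off_lo = np.linalg.norm(transverse[lo].mean(axis=0))
        if off_hi < off_lo:
            axis_long = -axis_long
            t = -t

    axis_2 = evecs[:, 1]
    proj2 = x @ axis_2
    skew = float((proj2**3).mean())
    spread = float(proj2.std())
    if abs(skew) > 1e-9 * max(spread**3, 1e-30):
        if skew < 0:
            axis_2 = -axis_2
    else:
        # symmetric section: fall back to a fixed world-space sign rule
        k = int(np.argmax(np.abs(axis_2)))
        if axis_2[k] < 0:
            axis_2 = -axis_2
    axis_3 = np.cross(axis_long, axis_2)

    length = float(t.max() - t.min())
    origin = centroid + t.min() * axis_long
    return BoneFrame(origin, axis_long, axis_2, axis_3, length, proximal_sign=1)


def axial_fraction(frame: BoneFrame, point: np.ndarray) -> np.ndarray | float:
    """Axial position as a fraction of bone length (0 distal, 1 proximal).

    Accepts a single point or an (n, 3) array; values outside [0, 1] mean
    the point lies beyond the bone's axial extent.
    """
    pts = np.asarray(point, dtype=np.float64)
    u = (pts - frame.origin) @ frame.proximal_direction / frame.length
    return float(u) if pts.ndim == 1 else u


def extract_section(
    mesh: SurfaceMesh, frame: BoneFrame, end: str, fraction: float
) -> SurfaceMesh:
    """Axial section of the mesh: the distal or proximal ``fraction`` of length.

    A face is kept only when all three of its vertices pass the axial test
    (no face splitting), and vertex indices are re-compacted.
    """
    if end not in ("proximal", "distal"):
        raise ValueError("end must be 'proximal' or 'distal'")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    u = axial_fraction(frame, mesh.vertices)
    vmask = u >= 1.0 - fraction if end == "proximal" else u <= fraction
    fmask = vmask[mesh.faces].all(axis=1)
    if not fmask.any():
        raise SectioningError(f"{end} section at fraction {fraction} is empty")
    faces = mesh.faces[fmask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return SurfaceMesh(mesh.vertices[used], remap[faces])


@dataclass(frozen=True)
class RotationTriple:
    """Three rotation components in degrees, tagged with their convention."""

    angle_x: float
    angle_y: float
    angle_z: float
    convention: str = EULER_XYZ
    gimbal_lock: bool = False

    def __post_init__(self) -> None:
        for name in ("angle_x", "angle_y", "angle_z"):
            val = float(getattr(self, name))
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, val)
        if self.convention not in (EULER_XYZ, ROTVEC):
            raise ValueError(f"unknown convention {self.convention!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.angle_x, self.angle_y, self.angle_z])


def rotation_to_components(R: np.ndarray, convention: str = EULER_XYZ) -> RotationTriple:
    """Decompose a proper rotation into a degree triple.

    ``euler-xyz-extrinsic`` returns (a, b, c) with ``R = Rz(c) Ry(b) Rx(a)``
    about fixed axes; ``rotation-vector`` returns the matrix logarithm
    (axis times angle) in degrees. Both round-trip through
    :func:`components_to_rotation`. Near the Euler singularity
    (|b| within ~1e-6 deg of 90) the x/z split is not unique; the result
    is flagged via ``gimbal_lock`` with the conventional tie-break of the
    underlying decomposition.
    """
    R = np.asarray(R, dtype=np.float64)
    _check_rotation(R, tol=1e-8)
    rot = Rotation.from_matrix(R)
    if convention == EULER_XYZ:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, c = rot.as_euler("xyz", degrees=True)
        lock = abs(abs(b) - 90.0) < 1e-6
        return RotationTriple(a, b, c, EULER_XYZ, gimbal_lock=lock)
    if convention == ROTVEC:
        vx, vy, vz = rot.as_rotvec(degrees=True)
        return RotationTriple(vx, vy, vz, ROTVEC)
    raise ValueError(f"unknown convention {convention!r}")


def components_to_rotation(triple: RotationTriple) -> np.ndarray:
    """Inverse of :func:`rotation_to_components`."""
    if triple.convention == EULER_XYZ:
        return Rotation.from_euler("xyz", triple.as_array(), degrees=True).as_matrix()
    if triple.convention == ROTVEC:
        return Rotation.from_rotvec(triple.as_array(), degrees=True).as_matrix()
    raise ValueError(f"unknown convention {triple.convention!r}")


def load_mesh(path: str | Path) -> SurfaceMesh:
    """Read an STL/PLY/OBJ surface, welding duplicate vertices. Units: mm."""
    p = Path(path)
    if p.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format: {p.suffix!r}")
    if not p.exists():
        raise MeshFormatError(f"no such file: {p}")
    try:
        tm = trimesh.load(str(p), force="mesh", process=True)
    except Exception as exc:  # trimesh raises a zoo of loader errors
        raise MeshFormatError(f"could not read {p}: {exc}") from exc
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise MeshValidationError(f"{p} contains no triangles")
    return SurfaceMesh(verts, faces)


def save_mesh(mesh: SurfaceMesh, path: str | Path, stl_ascii: bool = False) -> None:
    """Write STL (binary by default, ASCII on request), PLY or OBJ."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix not in _SUPPORTED_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format: {suffix!r}")
    tm = mesh.to_trimesh()
    if suffix == ".stl" and stl_ascii:
        p.write_text(tm.export(file_type="stl_ascii"))
    else:
        tm.export(str(p))
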