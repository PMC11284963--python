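"""Seeded generator of immature-femur-like surface meshes and their grown
counterparts.

The generator emulates the longitudinal study design this package is built
for: a cohort of growing femurs, each scanned twice ~12 weeks apart, where
the later bone is substantially larger (body weight roughly doubles over
the interval, so volume roughly doubles too), slightly different in shape,
naturally somewhat more or less twisted, and meshed independently of the
first scan. Each bone is an implicit union of simple solids — a bowed
shaft tube, an offset head sphere on an angled, anteverted neck, a greater-
trochanter bump, and two unequal condylar lobes — polygonized on a uniform
grid. The head offset and the bicondylar distal end make the shape
rotationally asymmetric about the long axis, which is what makes torsion
observable at all.

Everything is deterministic per seed, down to the grid placement, so tests
and experiments are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh
from skimage import measure

from .mesh_core import BoneFrame, RotationTriple, SurfaceMesh
from .twist import TwistSpec, apply_virtual_twist

__all__ = [
    "GenerationError",
    "BoneParams",
    "GrowthParams",
    "Subject",
    "generate_femur",
    "grow_femur",
    "generate_cohort",
]


class GenerationError(Exception):
    """Mesh resolution too low to resolve the bone's features."""


@dataclass(frozen=True)
class BoneParams:
    """Dimensions of one synthetic immature femur (mm, degrees).

    Defaults describe a juvenile porcine-scale femur: 140 mm shaft with a
    6 mm sagittal bow, a 14 mm head offset on an 18 mm neck at 135 deg
    with 20 deg anteversion, an 8 mm greater-trochanter bump, and two
    ~13 mm condyles 22 mm apart. ``mesh_resolution`` is the target vertex
    count of the polygonized surface; ``noise_sd`` is Gaussian surface
    noise along vertex normals (0.1 mm, sub-voxel for 0.8 mm CT slices).
    """

    shaft_length: float = 140.0
    shaft_radius: float = 12.0
    curvature: float = 6.0
    head_radius: float = 14.0
    neck_length: float = 18.0
    neck_angle: float = 135.0
    anteversion: float = 20.0
    condyle_radius: float = 13.0
    condyle_separation: float = 22.0
    trochanter_bump: float = 8.0
    mesh_resolution: int = 4000
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shaft_length", "shaft_radius", "curvature", "head_radius",
            "neck_length", "condyle_radius", "condyle_separation", "trochanter_bump",
        ):
            if not float(getattr(self, name)) >= 0 or (
                name not in ("curvature",) and not float(getattr(self, name)) > 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.mesh_resolution < 500:
            raise ValueError("mesh_resolution must be >= 500")

    def replace(self, **kwargs) -> "BoneParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GrowthParams:
    """What happens to a femur over the 12-week interval.

    ``scale`` 1.35 with an extra 1.08 axial stretch gives a volume ratio
    of ~2.7, matching a rough doubling of body weight. ``natural_torsion``
    is the distal-vs-proximal rotation change that occurs without any
    intervention; ``None`` draws it per subject from N(3, 2) degrees.
    ``shape_jitter`` perturbs radii relatively (shape drift);
    ``remesh=True`` rebuilds the surface with an independent vertex
    layout, mirroring two independent CT segmentations.
    """

    scale: float = 1.35
    elongation_extra: float = 1.08
    natural_torsion: float | None = None
    shape_jitter: float = 0.03
    remesh: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scale >= 1.0:
            raise ValueError("growth scale must be >= 1")
        if not self.elongation_extra > 0:
            raise ValueError("elongation_extra must be positive")
        if self.shape_jitter < 0:
            raise ValueError("shape_jitter must be >= 0")

    def replace(self, **kwargs) -> "GrowthParams":
        return replace(self, **kwargs)


@dataclass
class Subject:
    """One cohort member: both scans plus the generator's ground truths."""

    subject_id: str
    w0: SurfaceMesh
    w0_frame: BoneFrame
    w12: SurfaceMesh
    w12_frame: BoneFrame
    natural_torsion: RotationTriple
    bone_params: BoneParams
    growth_params: GrowthParams


def _geometry(p: BoneParams) -> dict:
    """Analytic solids making up the bone, in its canonical pose.

    Long axis = +z with the distal end near z = 0; the head points toward
    +x (rotated by the anteversion about z), the trochanter toward -x,
    and the condyles sit at +/- y with unequal radii and a small
    posterior (-x) offset. All offsets scale with the driving dimension
    so grown bones keep their proportions.
    """
    length = p.shaft_length
    alpha = np.radians(180.0 - p.neck_angle)
    antev = np.radians(p.anteversion)
    neck_dir = np.array(
        [np.sin(alpha) * np.cos(antev), np.sin(alpha) * np.sin(antev), np.cos(alpha)]
    )
    neck_start = np.array([0.0, 0.0, length - 0.5 * p.shaft_radius])
    head_center = neck_start + p.neck_length * neck_dir

    troch_r = 0.7 * p.shaft_radius
    troch_center = np.array(
        [-(p.shaft_radius + p.trochanter_bump - troch_r), 0.0, length - 1.5 * troch_r]
    )

    half_sep = 0.5 * p.condyle_separation
    rc = p.condyle_radius
    cz = 0.55 * rc
    # condyles: the medial one distinctly larger and more posterior, as
    # in real femora; the asymmetry is what makes long-axis rotation of
    # the distal block observable, so it is deliberately pronounced
    condyle_a = (np.array([-0.35 * rc, +half_sep, cz]), 1.10 * rc)
    condyle_b = (np.array([+0.05 * rc, -half_sep, cz]), 0.92 * rc)
    # epicondylar bumps: lateral prominences that, with the trochlear
    # groove, give the distal block the surface relief that pins its
    # pose in registration (two bare spheres are rotationally slippery
    # for point-to-point correspondences)
    epi_a = (np.array([0.1 * rc, +(half_sep + 0.80 * rc), 1.0 * rc]), 0.55 * rc)
    epi_b = (np.array([0.1 * rc, -(half_sep + 0.70 * rc), 0.8 * rc]), 0.45 * rc)
    groove = (np.array([0.95 * rc, 0.0, 0.95 * rc]), 0.65 * rc)

    # linea aspera: longitudinal ridge along the posterior shaft; anchors
    # torsion (rotation about the long axis) over the whole shaft, which
    # an axisymmetric tube would leave unconstrained. It runs distally
    # into the supracondylar region (as the real ridge does) so the
    # distal section also carries an azimuthal anchor.
    ridge = {
        "radius": 0.30 * p.shaft_radius,
        "offset": 0.95 * p.shaft_radius,
        "z_lo": 0.05 * length,
        "z_hi": 0.88 * length,
    }

    return {
        "length": length,
        "neck": (neck_start, head_center, 0.55 * p.head_radius),
        "head": (head_center, p.head_radius),
        "trochanter": (troch_center, troch_r),
        "condyles": (condyle_a, condyle_b),
        "epicondyles": (epi_a, epi_b),
        "groove": groove,
        "ridge": ridge,
    }


def _sdf(points: np.ndarray, p: BoneParams, geo: dict) -> np.ndarray:
    """Signed distance (negative inside) of the union of solids."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    length = geo["length"]

    zc = np.clip(z, 0.0, length)
    bow = p.curvature * np.sin(np.pi * zc / length)
    d = np.sqrt((x - bow) ** 2 + y**2 + (z - zc) ** 2) - p.shaft_radius

    def sphere(center, radius):
        return np.linalg.norm(points - center, axis=1) - radius

    def capsule(a, b, radius):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        return np.linalg.norm(points - (a + t[:, None] * ab), axis=1) - radius

    a, b, neck_r = geo["neck"]
    d = np.minimum(d, capsule(a, b, neck_r))
    d = np.minimum(d, sphere(*geo["head"]))
    d = np.minimum(d, sphere(*geo["trochanter"]))
    for center, radius in geo["condyles"] + geo["epicondyles"]:
        d = np.minimum(d, sphere(center, radius))
    ridge = geo["ridge"]
    zr = np.clip(z, ridge["z_lo"], ridge["z_hi"])
    bow_r = p.curvature * np.sin(np.pi * zr / length)
    d_ridge = (
        np.sqrt((x - (bow_r - ridge["offset"])) ** 2 + y**2 + (z - zr) ** 2)
        - ridge["radius"]
    )
    d = np.minimum(d, d_ridge)
    # trochlear groove: carved (CSG difference), not unioned
    d = np.maximum(d, -sphere(*geo["groove"]))
    return d


def _bounds(p: BoneParams, geo: dict) -> tuple[np.ndarray, np.ndarray]:
    pts = []
    for z in np.linspace(0.0, geo["length"], 24):
        c = np.array([p.curvature * np.sin(np.pi * z / geo["length"]), 0.0, z])
        pts.append((c, p.shaft_radius))
    a, b, neck_r = geo["neck"]
    pts += [(a, neck_r), (b, neck_r), (geo["head"]), (geo["trochanter"])]
    pts += list(geo["condyles"]) + list(geo["epicondyles"])
    ridge = geo["ridge"]
    for z in (ridge["z_lo"], ridge["z_hi"]):
        c = np.array([p.curvature * np.sin(np.pi * z / geo["length"]) - ridge["offset"], 0.0, z])
        pts.append((c, ridge["radius"]))
    lo = np.min([c - r for c, r in pts], axis=0)
    hi = np.max([c + r for c, r in pts], axis=0)
    return lo, hi


def _polygonize(p: BoneParams, geo: dict, pitch: float, origin_shift: np.ndarray) -> trimesh.Trimesh:
    lo, hi = _bounds(p, geo)
    margin = 3.0 * pitch
    origin = lo - margin + origin_shift * pitch
    shape = np.ceil((hi + margin - origin) / pitch).astype(int) + 1
    axes = [origin[i] + pitch * np.arange(shape[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vol = _sdf(grid_pts, p, geo).reshape(shape)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts + origin
    tm = trimesh.Trimesh(verts, faces, process=True)
    # vertex welding can collapse slivers into faces with repeated indices
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if tm.volume < 0:
        tm.invert()
    return tm


def generate_femur(params: BoneParams) -> tuple[SurfaceMesh, BoneFrame]:
    """Build one watertight femur surface and its ground-truth frame.

    The grid pitch is calibrated in two passes (vertex count scales as
    pitch^-2) so the polygonized surface lands near ``mesh_resolution``
    vertices; Gaussian noise is then applied along vertex normals.
    Deterministic per ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    geo = _geometry(params)
    origin_shift = rng.uniform(0.0, 1.0, size=3)  # sub-cell grid placement

    pitch = 2.5 * (params.shaft_length / 140.0)
    tm = _polygonize(params, geo, pitch, origin_shift)
    pitch = pitch * np.sqrt(len(tm.vertices) / params.mesh_resolution)
    min_feature = min(params.shaft_radius, 0.55 * params.head_radius, params.condyle_radius)
    if pitch > 0.9 * min_feature:
        raise GenerationError(
            f"grid pitch {pitch:.2f} mm cannot resolve the thinnest feature "
            f"({min_feature:.2f} mm); raise mesh_resolution"
        )
    tm = _polygonize(params, geo, pitch, origin_shift)

    verts = np.asarray(tm.vertices, dtype=np.float64)
    if params.noise_sd > 0:
        normals = np.asarray(tm.vertex_normals, dtype=np.float64)
        verts = verts + rng.normal(0.0, params.noise_sd, size=len(verts))[:, None] * normals
    mesh = SurfaceMesh(verts, np.asarray(tm.faces, dtype=np.int64))

    z = verts[:, 2]
    frame = BoneFrame(
        origin=np.array([0.0, 0.0, float(z.min())]),
        axis_long=np.array([0.0, 0.0, 1.0]),
        axis_2=np.array([1.0, 0.0, 0.0]),
        axis_3=np.array([0.0, 1.0, 0.0]),
        length=float(z.max() - z.min()),
        proximal_sign=1,
    )
    return mesh, frame


def grow_femur(
    params: BoneParams, growth: GrowthParams
) -> tuple[SurfaceMesh, BoneFrame, RotationTriple]:
    """The same bone 12 weeks later: larger, drifted, re-meshed, twisted.

    Returns the grown mesh, its ground-truth frame, and the natural
    torsion actually applied (degrees about the bone frame, z = long
    axis) so experiments can use it as ground truth.
    """
    rng = np.random.default_rng(growth.seed)
    if growth.natural_torsion is None:
        torsion = float(rng.normal(3.0, 2.0))
    else:
        torsion = float(growth.natural_torsion)

    def jittered(value: float) -> float:
        if growth.shape_jitter > 0:
            return value * growth.scale * (1.0 + rng.normal(0.0, growth.shape_jitter))
        return value * growth.scale

    mesh_seed = int(np.random.SeedSequence([growth.seed, params.seed]).generate_state(1)[0] % 2**31)

    if growth.remesh:
        grown = params.replace(
            shaft_length=params.shaft_length * growth.scale * growth.elongation_extra,
            shaft_radius=jittered(params.shaft_radius),
            curvature=params.curvature * growth.scale,
            head_radius=jittered(params.head_radius),
            neck_length=jittered(params.neck_length),
            condyle_radius=jittered(params.condyle_radius),
            condyle_separation=jittered(params.condyle_separation),
            trochanter_bump=jittered(params.trochanter_bump),
            seed=mesh_seed,
        )
        w12, frame12 = generate_femur(grown)
    else:
        # direct similarity (+ axial stretch) of the W0 mesh: preserves vertex
        # correspondence, used for null-growth checks
        w0, frame0 = generate_femur(params)
        ez = frame0.proximal_direction
        verts = frame0.origin + growth.scale * (w0.vertices - frame0.origin)
        axial = (verts - frame0.origin) @ ez
        verts = verts + (growth.elongation_extra - 1.0) * axial[:, None] * ez[None, :]
        w12 = SurfaceMesh(verts, w0.faces.copy())
        frame12 = BoneFrame(
            origin=frame0.origin,
            axis_long=frame0.axis_long,
            axis_2=frame0.axis_2,
            axis_3=frame0.axis_3,
            length=frame0.length * growth.scale * growth.elongation_extra,
            proximal_sign=frame0.proximal_sign,
        )

    if torsion != 0.0:
        w12 = apply_virtual_twist(w12, frame12, TwistSpec(angles=(0.0, 0.0, torsion)))
    return w12, frame12, RotationTriple(0.0, 0.0, torsion)


def generate_cohort(
    n: int,
    master_seed: int,
    params: BoneParams | None = None,
    growth: GrowthParams | None = None,
) -> list[Subject]:
    """A cohort of ``n`` subjects with per-subject shape jitter (+/-10% on
    radii and lengths, +/-3% on angles) and per-subject seeds derived from
    ``master_seed``. Fully deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base_p = params or BoneParams()
    base_g = growth or GrowthParams()
    subjects: list[Subject] = []
    for i, child in enumerate(np.random.SeedSequence(master_seed).spawn(n)):
        s_jit, s_bone, s_growth = (int(s % 2**31) for s in child.generate_state(3))
        rng = np.random.default_rng(s_jit)

        def j10(value: float) -> float:
            return value * rng.uniform(0.9, 1.1)

        p = base_p.replace(
            shaft_length=j10(base_p.shaft_length),
            shaft_radius=j10(base_p.shaft_radius),
            curvature=j10(base_p.curvature),
            head_radius=j10(base_p.head_radius),
            neck_length=j10(base_p.neck_length),
            neck_angle=base_p.neck_angle * rng.uniform(0.97, 1.03),
            anteversion=base_p.anteversion * rng.uniform(0.97, 1.03),
            condyle_radius=j10(base_p.condyle_radius),
            condyle_separation=j10(base_p.condyle_separation),
            trochanter_bump=j10(base_p.trochanter_bump),
            seed=s_bone,
        )
        g = base_g.replace(seed=s_growth)
        w0, f0 = generate_femur(p)
        w12, f12, torsion = grow_femur(p, g)
        subjects.append(Subject(f"S{i:02d}", w0, f0, w12, f12, torsion, p, g))
    return subjects
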