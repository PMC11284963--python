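"""Principal-axis prealignment and iterative-closest-point registration.

Registration maps a source surface onto a target surface with a similarity
transform (optionally rigid). The inner least-squares step is the closed-form
similarity fit on paired points; the outer loop is classic point-to-point ICP
with nearest-vertex correspondences, an optional worst-pair trim, and a
seeded uniform vertex subsample of the source for bounded, deterministic
runtime. A prealignment stage matches the principal inertial axes of the two
bones (trying the four right-handed axis sign assignments) so that ICP starts
inside its convergence basin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import SimilarityTransform, SurfaceMesh, principal_frame

__all__ = [
    "DegenerateFitError",
    "IcpParams",
    "RegistrationResult",
    "closed_form_fit",
    "symmetric_nn_rms",
    "prealign",
    "icp",
]

# right-handed sign assignments of one orthonormal triple onto another
_FLIPS = ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))


class DegenerateFitError(Exception):
    """Point pairs are collinear/degenerate; no unique transform exists."""


@dataclass(frozen=True)
class IcpParams:
    """Free parameters of the ICP loop.

    ``rms_tolerance`` is the relative change of RMS between successive
    iterations below which the loop stops (absolute RMS is mesh-scale
    dependent). ``trim_fraction`` discards that fraction of the worst
    correspondences each iteration (0 = none). ``seed`` fixes the source
    vertex subsample, making results bit-reproducible. ``scale_band``
    bounds the estimated scale to within that relative band of the
    initial transform's scale: with unconstrained scale, similarity ICP
    on poorly overlapping poses can collapse the cloud toward the target
    centroid instead of rotating, and the size ratio of two scans of the
    same bone is always known to prealignment accuracy. ``scale_anchor``
    pins the band to a fixed value instead of the initial transform's
    scale — used when one registration is restarted from earlier results
    (cascades, probes) so the band cannot ratchet.
    """

    max_iterations: int = 100
    rms_tolerance: float = 1e-7
    sample_size: int = 2000
    with_scale: bool = False
    trim_fraction: float = 0.0
    seed: int = 0
    scale_band: float = 0.05
    scale_anchor: float | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.sample_size < 3:
            raise ValueError("sample_size must be >= 3")
        if not self.rms_tolerance > 0:
            raise ValueError("rms_tolerance must be positive")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if not 0.0 <= self.scale_band < 1.0:
            raise ValueError("scale_band must be in [0, 1)")

    def replace(self, **kwargs) -> "IcpParams":
        return replace(self, **kwargs)


@dataclass
class RegistrationResult:
    transform: SimilarityTransform
    rms: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def closed_form_fit(
    source_points: np.ndarray, target_points: np.ndarray, with_scale: bool = False
) -> SimilarityTransform:
    """Least-squares similarity (or rigid) transform for paired points.

    Minimizes ``sum || s R p + t - q ||^2`` over proper rotations R,
    translation t and (optionally) uniform scale s, via the SVD of the
    cross-covariance with the determinant-sign correction that keeps R
    proper even for reflected configurations.
    """
    p = np.asarray(source_points, dtype=np.float64)
    q = np.asarray(target_points, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = p.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 point pairs")
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    xp = p - mu_p
    xq = q - mu_q
    cov = xq.T @ xp / n
    u, d, vt = np.linalg.svd(cov)
    if d[1] <= 1e-12 * max(d[0], 1e-300):
        raise DegenerateFitError("point pairs are (near-)collinear")
    s_diag = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s_diag[2] = -1.0
    rot = u @ np.diag(s_diag) @ vt
    if with_scale:
        var_p = float((xp**2).sum()) / n
        scale = float((d * s_diag).sum()) / var_p
        if not scale > 0:
            raise DegenerateFitError("non-positive scale in similarity fit")
    else:
        scale = 1.0
    t = mu_q - scale * rot @ mu_p
    return SimilarityTransform(scale, rot, t)


def symmetric_nn_rms(
    a: np.ndarray,
    b: np.ndarray,
    sample_size: int = 1000,
    seed: int = 0,
) -> float:
    """Symmetric nearest-neighbour RMS distance between two point clouds.

    Both directions (a→b and b→a) are measured on seeded subsamples; used
    as the prealignment candidate score and as a shape-identifiability
    diagnostic.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ia = rng.choice(a.shape[0], size=min(sample_size, a.shape[0]), replace=False)
    ib = rng.choice(b.shape[0], size=min(sample_size, b.shape[0]), replace=False)
    d_ab = cKDTree(b).query(a[ia])[0]
    d_ba = cKDTree(a).query(b[ib])[0]
    return float(np.sqrt(np.mean(np.concatenate([d_ab**2, d_ba**2]))))


def _surface_area(mesh: SurfaceMesh) -> float:
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def prealign_candidates(
    source: SurfaceMesh,
    target: SurfaceMesh,
    sample_size: int = 1000,
    seed: int = 0,
) -> list[RegistrationResult]:
    """Coarse alignments by principal inertial axes, best first.

    The four right-handed sign assignments of the source principal axes
    onto the target axes are each completed with a scale from the
    surface-area ratio (area is nearly invariant under the bending and
    twisting deformities being measured, unlike axial extent) and a
    centroid-matching translation, then ranked by symmetric
    nearest-neighbour RMS. Deliberately crude — a candidate only needs
    to land inside the ICP convergence basin.
    """
    fs = principal_frame(source)
    ft = principal_frame(target)
    cs = source.vertices.mean(axis=0)
    ct = target.vertices.mean(axis=0)
    scale = np.sqrt(_surface_area(target) / _surface_area(source))

    rng = np.random.default_rng(seed)
    si = rng.choice(source.n_vertices, size=min(sample_size, source.n_vertices), replace=False)
    ti = rng.choice(target.n_vertices, size=min(sample_size, target.n_vertices), replace=False)
    target_tree = cKDTree(target.vertices)
    target_sample = target.vertices[ti]

    ranked: list[RegistrationResult] = []
    for flip in _FLIPS:
        rot = ft.basis @ np.diag(flip).astype(np.float64) @ fs.basis.T
        t = ct - scale * rot @ cs
        cand = SimilarityTransform(scale, rot, t)
        moved = cand.apply(source.vertices)
        d_st = target_tree.query(moved[si])[0]
        d_ts = cKDTree(moved).query(target_sample)[0]
        rms = float(np.sqrt(np.mean(np.concatenate([d_st**2, d_ts**2]))))
        ranked.append(RegistrationResult(cand, rms, iterations=0, converged=True))
    ranked.sort(key=lambda r: r.rms)
    return ranked


def prealign(
    source: SurfaceMesh,
    target: SurfaceMesh,
    sample_size: int = 1000,
    seed: int = 0,
) -> RegistrationResult:
    """Best coarse alignment by principal inertial axes (see
    :func:`prealign_candidates`)."""
    return prealign_candidates(source, target, sample_size, seed)[0]


def icp(
    source: SurfaceMesh,
    target: SurfaceMesh,
    params: IcpParams | None = None,
    initial: SimilarityTransform | None = None,
) -> RegistrationResult:
    """Point-to-point ICP of ``source`` onto ``target``.

    Each iteration matches a fixed seeded subsample of source vertices to
    their nearest target vertices, optionally trims the worst pairs, and
    refits the full source→target transform in closed form. The loop stops
    when the relative RMS change drops below ``params.rms_tolerance`` or
    after ``params.max_iterations``; non-convergence is reported via the
    ``converged`` flag, not an exception. With ``trim_fraction == 0`` the
    post-fit RMS is non-increasing across iterations.

    ``initial`` seeds the first correspondence search (use
    :func:`prealign`); note that with ``with_scale=False`` any scale in
    ``initial`` only guides correspondences and the returned transform is
    rigid.
    """
    params = params or IcpParams()
    rng = np.random.default_rng(params.seed)
    n = source.n_vertices
    k = min(params.sample_size, n)
    idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
    p = source.vertices[idx]
    tree = cKDTree(target.vertices)

    transform = initial if initial is not None else SimilarityTransform.identity()
    s_base = params.scale_anchor if params.scale_anchor is not None else transform.scale
    s_lo = s_base * (1.0 - params.scale_band)
    s_hi = s_base * (1.0 + params.scale_band)
    n_keep = max(3, k - int(np.floor(params.trim_fraction * k)))
    prev_rms = np.inf
    rms = np.inf
    converged = False
    history: list[float] = []
    iterations = 0

    for iterations in range(1, params.max_iterations + 1):
        moved = transform.apply(p)
        dist, nn = tree.query(moved)
        if n_keep < k:
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        src = p[keep]
        dst = target.vertices[nn[keep]]
        transform = closed_form_fit(src, dst, with_scale=params.with_scale)
        if params.with_scale and not s_lo <= transform.scale <= s_hi:
            s_c = float(np.clip(transform.scale, s_lo, s_hi))
            t_c = dst.mean(axis=0) - s_c * transform.rotation @ src.mean(axis=0)
            transform = SimilarityTransform(s_c, transform.rotation, t_c)
        resid = transform.apply(src) - dst
        rms = float(np.sqrt(np.mean((resid**2).sum(axis=1))))
        history.append(rms)
        if rms < 1e-12:
            converged = True
            break
        if np.isfinite(prev_rms) and abs(prev_rms - rms) <= params.rms_tolerance * prev_rms:
            converged = True
            break
        prev_rms = rms

    return RegistrationResult(transform, rms, iterations, converged, history)
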