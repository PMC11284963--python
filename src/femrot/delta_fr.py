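"""The rotation-change pipeline: whole-bone alignment, sectioning, per-section
registration, and extraction of the 3D femoral rotation change.

Given two scans of the same bone — an earlier scan ``w0`` and a later scan
``w12`` — the pipeline first registers ``w0`` onto ``w12`` with a similarity
transform (scale absorbs growth), producing the size-matched ``w0t``. The
proximal and distal sections of ``w0t`` (by default 40% and 15% of bone
length) are then each registered rigidly to the full ``w12``. If the distal
end rotated relative to the proximal end between the two scans, the two
section registrations disagree by exactly that rotation: the rotation change
is the relative rotation ``R_D @ R_P^-1``, expressed in the anatomical frame
of the later scan so its components map to anatomical axes (z = torsion
about the long axis). A result of (0, 0, 0) degrees means no rotational
change.

Cross-subject comparisons (validation against growth) additionally need a
growth baseline: the rotation change measured on the untwisted pair is
removed from the one measured on the twisted pair (`growth_correct`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.spatial.transform import Rotation

from .mesh_core import (
    EULER_XYZ,
    ROTVEC,
    BoneFrame,
    RotationTriple,
    SimilarityTransform,
    SurfaceMesh,
    components_to_rotation,
    extract_section,
    principal_frame,
    rotation_to_components,
)
from .registration import IcpParams, RegistrationResult, icp, prealign_candidates

__all__ = ["DeltaFR", "initial_align", "assess_delta_fr", "growth_correct"]

#: Relative spread of the two transverse covariance eigenvalues below which
#: a section is flagged as near-axisymmetric (long-axis rotation of such a
#: section is ill-conditioned).
TRANSVERSE_CONDITION_TOL = 0.05


@dataclass
class DeltaFR:
    """3D rotation of the distal section relative to the proximal section.

    ``rotation_matrix`` is expressed in the target-scan bone frame;
    components are reported both as extrinsic XYZ Euler angles and as a
    rotation vector (degrees). Registration diagnostics for the initial
    alignment and both sections are attached.
    """

    rotation_matrix: np.ndarray
    components_euler: RotationTriple
    components_rotvec: RotationTriple
    initial_result: RegistrationResult
    proximal_result: RegistrationResult
    distal_result: RegistrationResult
    reference_frame: BoneFrame | None = None
    warnings: list[str] = field(default_factory=list)


def initial_align(
    w0: SurfaceMesh,
    w12: SurfaceMesh,
    params: IcpParams | None = None,
    initial: SimilarityTransform | None = None,
) -> tuple[SurfaceMesh, RegistrationResult]:
    """Whole-bone similarity registration of ``w0`` onto ``w12``.

    Principal-axis prealignment followed by ICP with uniform scale (scale
    compensates interval growth; the shape of ``w0`` is preserved).

    Among the four sign-assignment prealignment candidates, the one with
    the smallest rotation is refined. This encodes the assumption that
    the two scans arrive in grossly consistent orientation (CT scans
    share the scanner/patient frame, so the true relative rotation is
    far below 90 degrees). A femur is coarsely two-fold symmetric about
    its shaft — the head can masquerade as the trochanter — so with
    inter-subject shape differences no surface-distance score reliably
    separates the correct alignment from the 180-degree flip; gross
    input orientation is the honest disambiguator, and
    :func:`femrot.registration.prealign` remains available for fully
    pose-free same-bone alignment.

    An explicit ``initial`` transform (e.g. the result of aligning the
    same source onto a closely related target) replaces the prealignment
    stage entirely.

    Returns the transformed mesh ``w0t`` and the cumulative transform.
    """
    params = params or IcpParams()
    if initial is not None:
        start = initial
    else:
        candidates = prealign_candidates(w0, w12, seed=params.seed)

        def rotation_angle(result: RegistrationResult) -> float:
            rotvec = Rotation.from_matrix(result.transform.rotation).as_rotvec()
            return float(np.linalg.norm(rotvec))

        start = min(candidates, key=rotation_angle).transform
    icp_params = params.replace(with_scale=True, scale_anchor=start.scale)
    res = icp(w0, w12, icp_params, initial=start)
    return w0.transformed(res.transform), res


#: Long-axis nudges (degrees) probed around the converged section pose.
_LONG_AXIS_PROBES = (-9.0, -6.0, -3.0, 3.0, 6.0, 9.0)


def _cascade_fractions(end: str, fraction: float) -> list[float]:
    """Section-size schedule for coarse-to-fine registration."""
    if end == "distal":
        levels = [min(0.45, 3.0 * fraction), min(0.30, 2.0 * fraction), fraction]
    else:
        levels = [min(0.60, fraction + 0.20), fraction]
    out: list[float] = []
    for f in levels:
        if f >= fraction and (not out or f < out[-1]):
            out.append(f)
    if out[-1] != fraction:
        out.append(fraction)
    return out


def _register_section(
    w0t: SurfaceMesh,
    frame0: BoneFrame,
    target: SurfaceMesh,
    params: IcpParams,
    end: str,
    fraction: float,
    start: SimilarityTransform | None = None,
) -> RegistrationResult:
    """Register one section of the aligned bone onto the full target mesh.

    Runs a coarse-to-fine cascade over section sizes (e.g. distal 45% ->
    30% -> 15%): each stage's ICP result initializes the next, smaller
    section. A large relative rotation (a 20 deg tri-axial twist is a
    ~34 deg net rotation of the distal block) lies outside the
    convergence basin of a single ICP started at the identity, which
    stalls in a shallow minimum with the section cradled ~1-2 mm off the
    surface; the larger sections overlap the deformation ramp, so their
    registrations land at intermediate rotations that walk the start
    point into the final section's basin. An explicit ``start`` (from a
    warm-started assessment) seeds the first cascade level. The returned
    result is always the registration of the section at the requested
    fraction.
    """
    result: RegistrationResult | None = None
    initial = start
    section: SurfaceMesh | None = None
    for f in _cascade_fractions(end, fraction):
        section = extract_section(w0t, frame0, end, f)
        result = icp(section, target, params, initial=initial)
        initial = result.transform
    assert result is not None and section is not None

    # Long-axis rotation is the ill-conditioned direction of a bone
    # section (near-axisymmetry): on independently meshed scans the final
    # ICP can settle a few degrees off about the shaft. Probe small
    # long-axis rotations around the converged pose and keep the best.
    centroid = section.vertices.mean(axis=0)
    axis = frame0.axis_long
    for deg in _LONG_AXIS_PROBES:
        rot = Rotation.from_rotvec(np.radians(deg) * axis).as_matrix()
        nudge = SimilarityTransform(1.0, rot, centroid - rot @ centroid)
        probe = icp(section, target, params, initial=result.transform.compose(nudge))
        if probe.rms < result.rms:
            result = probe
    return result


def _subdivide_once(mesh: SurfaceMesh) -> SurfaceMesh:
    """Midpoint-subdivide a mesh (4x faces), halving the vertex spacing.

    Section registrations match source vertices to target *vertices*;
    on meshes with ~2 mm spacing that quantization alone can bias the
    fitted section pose by more than a degree. One subdivision of the
    registration target is a cheap stand-in for true point-to-surface
    correspondence and removes most of that bias. Original vertices are
    preserved, so exact-overlap registrations stay exact.
    """
    tm = mesh.to_trimesh().subdivide()
    return SurfaceMesh(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces, dtype=np.int64))


def _transverse_condition(mesh: SurfaceMesh, axis: np.ndarray) -> float:
    """Relative gap of the two transverse covariance eigenvalues."""
    x = mesh.vertices - mesh.vertices.mean(axis=0)
    x = x - np.outer(x @ axis, axis)
    evals = np.linalg.eigvalsh(x.T @ x / x.shape[0])
    lo, hi = evals[1], evals[2]  # evals[0] ~ 0 along the removed axis
    return float((hi - lo) / max(hi, 1e-300))


def assess_delta_fr(
    w0: SurfaceMesh,
    w12: SurfaceMesh,
    proximal_fraction: float = 0.40,
    distal_fraction: float = 0.15,
    params: IcpParams | None = None,
    reference_frame: BoneFrame | None = None,
    section_with_scale: bool = True,
    warm_start: "DeltaFR | None" = None,
) -> DeltaFR:
    """Measure the 3D rotation change between two scans of one bone.

    Parameters
    ----------
    proximal_fraction, distal_fraction
        Axial extent of the two sections as fractions of bone length
        (defaults: proximal 40% including head/neck/trochanters, distal
        15% including the condyles); must sum to at most 1.
    params
        ICP settings shared by all three registrations. The initial
        whole-bone stage always estimates scale. The section stages also
        estimate scale by default, tightly banded around 1: the initial
        alignment is a compromise whose scale can be off by a few
        percent when the bone deformed between scans, and rigid section
        registration would turn that size mismatch into a rotation bias.
        ``section_with_scale=False`` makes them strictly rigid.
    reference_frame
        Anatomical frame in which components are reported. Defaults to
        the principal frame of ``w12``. Harnesses that compare against a
        twist ground truth should pass the frame the twist was defined
        in, so that frame estimation does not leak into the comparison.
    warm_start
        A previous assessment of the *same source bone* against a
        closely related target (e.g. the untwisted counterpart of
        ``w12``). Its initial alignment is reused verbatim and its
        section transforms seed this run's section cascades, so the two
        measurements share one convergence context and their
        shape-mismatch biases correlate — which is exactly what lets a
        growth baseline cancel in :func:`growth_correct`. The section
        registrations still converge fully on the actual target.

    Notes
    -----
    Sections are registered to the *full* later-scan mesh; nearest-
    neighbour correspondences land on the matching anatomy without
    requiring a consistent sectioning of the later scan. The proximal
    registration is not assumed to be the identity: using the relative
    rotation ``R_D @ R_P^-1`` makes the measure independent of how the
    initial alignment distributed its residual error.
    """
    if not 0 < proximal_fraction < 1 or not 0 < distal_fraction < 1:
        raise ValueError("section fractions must lie in (0, 1)")
    if proximal_fraction + distal_fraction > 1:
        raise ValueError("sections overlap: fractions must sum to <= 1")
    params = params or IcpParams()

    frame12 = reference_frame if reference_frame is not None else principal_frame(w12)
    if warm_start is not None:
        # Reuse the warm-start alignment verbatim: both assessments then
        # section the *same* w0t, the proximal registration repeats
        # exactly (its target region is unchanged), and section starts
        # are flip-consistent with the earlier run.
        init_res = warm_start.initial_result
        w0t = w0.transformed(init_res.transform)
    else:
        w0t, init_res = initial_align(w0, w12, params)
    frame0 = principal_frame(w0t, proximal_hint=frame12.proximal_direction)

    proximal = extract_section(w0t, frame0, "proximal", proximal_fraction)
    distal = extract_section(w0t, frame0, "distal", distal_fraction)

    notes: list[str] = []
    for name, section in (("proximal", proximal), ("distal", distal)):
        gap = _transverse_condition(section, frame0.axis_long)
        if gap < TRANSVERSE_CONDITION_TOL:
            notes.append(
                f"{name} section is near-axisymmetric (transverse eigenvalue "
                f"gap {gap:.3f}); long-axis rotation may be ill-conditioned"
            )

    sp = params.replace(with_scale=section_with_scale, scale_anchor=1.0)
    start_p = warm_start.proximal_result.transform if warm_start is not None else None
    start_d = warm_start.distal_result.transform if warm_start is not None else None
    target_fine = _subdivide_once(w12)
    res_p = _register_section(w0t, frame0, target_fine, sp, "proximal", proximal_fraction, start=start_p)
    res_d = _register_section(w0t, frame0, target_fine, sp, "distal", distal_fraction, start=start_d)

    r_rel = res_d.transform.rotation @ res_p.transform.rotation.T
    basis = frame12.basis
    r_bone = basis.T @ r_rel @ basis
    return DeltaFR(
        rotation_matrix=r_bone,
        components_euler=rotation_to_components(r_bone, EULER_XYZ),
        components_rotvec=rotation_to_components(r_bone, ROTVEC),
        initial_result=init_res,
        proximal_result=res_p,
        distal_result=res_d,
        reference_frame=frame12,
        warnings=notes,
    )


def growth_correct(
    delta_twisted: DeltaFR, delta_baseline: DeltaFR, mode: str = "compose"
) -> RotationTriple:
    """Remove the growth baseline from a measured rotation change.

    ``compose`` (default) removes the baseline as a rotation:
    ``decompose(R_twisted @ R_baseline^-1)`` — exact for same-axis
    rotations and correct to first order otherwise. ``subtract`` is
    literal component-wise angle subtraction; the two differ only at
    second order for small non-commuting angles. Both inputs must be
    expressed in the same target bone frame by the caller.
    """
    if delta_twisted.components_euler.convention != delta_baseline.components_euler.convention:
        raise ValueError("rotation-change inputs use different conventions")
    if mode == "compose":
        r = delta_twisted.rotation_matrix @ delta_baseline.rotation_matrix.T
        return rotation_to_components(r, EULER_XYZ)
    if mode == "subtract":
        a = delta_twisted.components_euler.as_array() - delta_baseline.components_euler.as_array()
        return RotationTriple(a[0], a[1], a[2], EULER_XYZ)
    raise ValueError("mode must be 'compose' or 'subtract'")


def _roundtrip_check(delta: DeltaFR, tol: float = 1e-9) -> bool:
    """Components must reproduce the rotation matrix (internal invariant)."""
    r1 = components_to_rotation(delta.components_euler)
    r2 = components_to_rotation(delta.components_rotvec)
    return bool(
        np.allclose(r1, delta.rotation_matrix, atol=tol)
        and np.allclose(r2, delta.rotation_matrix, atol=tol)
    )
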