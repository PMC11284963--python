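"""Virtual twist: a rotational-osteotomy simulator with known ground truth.

The twist rotates the distal part of a bone about its anatomical axes by
prescribed angles, ramping smoothly from zero at ``ramp_start_fraction`` of
the bone length (measured from the distal end) to the full angle at
``ramp_full_fraction``, so the distal block below the ramp is rotated as a
rigid body by exactly the nominal angles. That rigid block is what makes
the simulated deformity a usable ground truth: any assessment that sections
the bone below ``ramp_full_fraction`` should read back the nominal angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_core import BoneFrame, RotationTriple, SurfaceMesh, axial_fraction

__all__ = ["TwistSpec", "ramp_weight", "apply_virtual_twist"]


@dataclass(frozen=True)
class TwistSpec:
    """Twist magnitude and ramp geometry.

    ``angles`` are degrees about the bone-frame X, Y, Z axes (Z = long
    axis, so the Z component is the torsional one). The default ramp runs
    from 40% of bone length down to 20%, leaving the distal 20% — and in
    particular the distal 15% section used for assessment — rigidly
    rotated. ``pivot`` defaults to the long-axis point at the ramp start;
    a single fixed pivot keeps the fully twisted zone a rigid body.
    """

    angles: tuple[float, float, float] | RotationTriple
    ramp_start_fraction: float = 0.40
    ramp_full_fraction: float = 0.20
    profile: str = "cosine"
    pivot: np.ndarray | None = None

    def __post_init__(self) -> None:
        ang = self.angles
        if isinstance(ang, RotationTriple):
            ang = (ang.angle_x, ang.angle_y, ang.angle_z)
        ang = tuple(float(a) for a in ang)
        if len(ang) != 3 or not all(np.isfinite(ang)):
            raise ValueError("angles must be three finite degrees")
        object.__setattr__(self, "angles", ang)
        if not 0.0 <= self.ramp_full_fraction < self.ramp_start_fraction <= 1.0:
            raise ValueError("need 0 <= ramp_full_fraction < ramp_start_fraction <= 1")
        if self.profile not in ("cosine", "linear"):
            raise ValueError("profile must be 'cosine' or 'linear'")
        if self.pivot is not None:
            object.__setattr__(self, "pivot", np.asarray(self.pivot, dtype=np.float64).reshape(3))


def ramp_weight(u: np.ndarray | float, spec: TwistSpec) -> np.ndarray | float:
    """Twist weight at axial fraction ``u``: 1 distal of the ramp, 0 proximal.

    The cosine profile is C1-continuous (zero slope at both ends); the
    linear profile is provided for comparison. Monotone non-increasing in u.
    """
    scalar = np.isscalar(u)
    u = np.atleast_1d(np.asarray(u, dtype=np.float64))
    lo, hi = spec.ramp_full_fraction, spec.ramp_start_fraction
    s = np.clip((u - lo) / (hi - lo), 0.0, 1.0)
    if spec.profile == "cosine":
        w = 0.5 * (1.0 + np.cos(np.pi * s))
    else:
        w = 1.0 - s
    w = np.where(u >= hi, 0.0, np.where(u <= lo, 1.0, w))
    return float(w[0]) if scalar else w


def apply_virtual_twist(mesh: SurfaceMesh, frame: BoneFrame, spec: TwistSpec) -> SurfaceMesh:
    """Rotate the distal bone by the ramped twist; faces are unchanged.

    Each vertex at pre-twist axial fraction ``u`` is rotated about the
    pivot by ``Rz(w*az) Ry(w*ay) Rx(w*ax)`` in bone-frame axes with
    ``w = ramp_weight(u)``. Vertices proximal of the ramp start are left
    bit-identical; vertices distal of the ramp end share one common rigid
    rotation by exactly the nominal angles.
    """
    if not any(spec.angles):
        return mesh.copy()
    u = axial_fraction(frame, mesh.vertices)
    w = ramp_weight(u, spec)
    pivot = spec.pivot if spec.pivot is not None else frame.axis_point(spec.ramp_start_fraction)

    out = mesh.vertices.copy()
    mask = w > 0.0
    if mask.any():
        basis = frame.basis
        local = (mesh.vertices[mask] - pivot) @ basis  # bone-frame coords
        angles = w[mask, None] * np.asarray(spec.angles)[None, :]
        rots = Rotation.from_euler("xyz", angles, degrees=True)
        out[mask] = rots.apply(local) @ basis.T + pivot
    return SurfaceMesh(out, mesh.faces.copy())
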