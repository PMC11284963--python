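"""Shared fixtures: small synthetic bones kept session-scoped because
polygonization and registration dominate test runtime."""

import numpy as np
import pytest

from femrot import BoneParams, SurfaceMesh, generate_femur


@pytest.fixture(scope="session")
def femur_small():
    """A coarse femur (≈1500 vertices) plus its ground-truth frame."""
    return generate_femur(BoneParams(mesh_resolution=1500, seed=11))


@pytest.fixture(scope="session")
def femur_mesh(femur_small):
    return femur_small[0]


@pytest.fixture(scope="session")
def femur_truth_frame(femur_small):
    return femur_small[1]


def make_cube(edge: float = 1.0) -> SurfaceMesh:
    """Unit cube as 12 triangles over 8 vertices, outward CCW winding."""
    v = edge * np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2],          # bottom (z=0, normal -z)
         [4, 5, 6], [4, 6, 7],          # top
         [0, 1, 5], [0, 5, 4],          # y=0
         [2, 3, 7], [2, 7, 6],          # y=1
         [1, 2, 6], [1, 6, 5],          # x=1
         [3, 0, 4], [3, 4, 7]]          # x=0
    )
    return SurfaceMesh(v, f)


def make_tube(n_rings: int = 100, n_around: int = 24, length: float = 100.0,
              radius: float = 10.0) -> SurfaceMesh:
    """Open cylindrical tube of evenly spaced vertex rings along +z."""
    z = np.linspace(0.0, length, n_rings)
    theta = np.linspace(0.0, 2 * np.pi, n_around, endpoint=False)
    verts = np.array(
        [[radius * np.cos(t), radius * np.sin(t), zz] for zz in z for t in theta]
    )
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_around):
            a = i * n_around + j
            b = i * n_around + (j + 1) % n_around
            c = a + n_around
            d = b + n_around
            faces.append([a, b, d])
            faces.append([a, d, c])
    return SurfaceMesh(verts, np.array(faces))
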