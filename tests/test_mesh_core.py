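"""Mesh data model, I/O, frames, sectioning and rotation conventions."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import logm
from scipy.spatial.transform import Rotation

from femrot.mesh_core import (
    EULER_XYZ,
    ROTVEC,
    BoneFrame,
    DegenerateGeometryError,
    MeshFormatError,
    MeshValidationError,
    RotationTriple,
    SectioningError,
    SimilarityTransform,
    SurfaceMesh,
    apply_similarity,
    axial_fraction,
    components_to_rotation,
    extract_section,
    load_mesh,
    principal_frame,
    rotation_to_components,
    save_mesh,
)

from conftest import make_cube, make_tube


def _sorted_rows(a):
    a = np.asarray(a)
    return a[np.lexsort(a.T[::-1])]


class TestSurfaceMesh:
    def test_invariants_enforced(self):
        good = make_cube()
        with pytest.raises(MeshValidationError):
            SurfaceMesh(good.vertices[:3], np.array([[0, 1, 2]]))
        with pytest.raises(MeshValidationError):
            SurfaceMesh(good.vertices, np.array([[0, 1, 99]]))
        with pytest.raises(MeshValidationError):
            SurfaceMesh(good.vertices, np.array([[0, 1, 1]]))
        bad = good.vertices.copy()
        bad[0, 0] = np.nan
        with pytest.raises(MeshValidationError):
            SurfaceMesh(bad, good.faces)


class TestMeshIO:
    def test_stl_cube_welds_to_eight_vertices(self, tmp_path):
        cube = make_cube()
        path = tmp_path / "cube.stl"
        save_mesh(cube, path)  # STL stores per-facet vertices (duplicated)
        loaded = load_mesh(path)
        assert loaded.n_vertices == 8
        assert loaded.n_faces == 12
        assert np.allclose(_sorted_rows(loaded.vertices), _sorted_rows(cube.vertices))

    def test_binary_and_ascii_stl_agree(self, tmp_path):
        """ASCII dialect written by hand (independent writer) must load to
        the same welded vertex set as the binary written by the package."""
        cube = make_cube()
        bin_path = tmp_path / "bin.stl"
        save_mesh(cube, bin_path)

        lines = ["solid cube"]
        for tri in cube.faces:
            a, b, c = cube.vertices[tri]
            n = np.cross(b - a, c - a)
            n = n / np.linalg.norm(n)
            lines.append(f"facet normal {n[0]} {n[1]} {n[2]}")
            lines.append("outer loop")
            for v in (a, b, c):
                lines.append(f"vertex {v[0]} {v[1]} {v[2]}")
            lines.append("endloop")
            lines.append("endfacet")
        lines.append("endsolid cube")
        ascii_path = tmp_path / "ascii.stl"
        ascii_path.write_text("\n".join(lines))

        from_bin = load_mesh(bin_path)
        from_ascii = load_mesh(ascii_path)
        assert np.allclose(
            _sorted_rows(from_bin.vertices), _sorted_rows(from_ascii.vertices), atol=1e-6
        )

    @pytest.mark.parametrize("suffix", ["stl", "ply", "obj"])
    def test_roundtrip_preserves_vertices(self, tmp_path, femur_mesh, suffix):
        path = tmp_path / f"bone.{suffix}"
        save_mesh(femur_mesh, path)
        loaded = load_mesh(path)
        assert np.allclose(
            _sorted_rows(loaded.vertices), _sorted_rows(femur_mesh.vertices), atol=1e-6
        )

    def test_errors(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "missing.stl")
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "file.xyz")
        with pytest.raises(MeshFormatError):
            save_mesh(make_cube(), tmp_path / "file.vtk")


class TestSimilarityTransform:
    def test_identity_is_bitwise(self, femur_mesh):
        out = apply_similarity(femur_mesh, SimilarityTransform.identity())
        assert np.array_equal(out.vertices, femur_mesh.vertices)

    def test_scale_doubles_bbox_diagonal(self):
        cube = make_cube()
        out = apply_similarity(cube, SimilarityTransform(scale=2.0))
        diag = out.vertices.max(0) - out.vertices.min(0)
        assert np.allclose(diag, 2.0 * (cube.vertices.max(0) - cube.vertices.min(0)))

    def test_compose_equals_sequential_application(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3))
        t1 = SimilarityTransform(1.3, Rotation.random(random_state=1).as_matrix(), [1, -2, 3])
        t2 = SimilarityTransform(0.7, Rotation.random(random_state=2).as_matrix(), [-4, 0, 5])
        assert np.allclose(t2.compose(t1).apply(pts), t2.apply(t1.apply(pts)), atol=1e-9)

    def test_inverse(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3))
        t = SimilarityTransform(1.5, Rotation.random(random_state=5).as_matrix(), [3, 4, 5])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(rotation=np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(ValueError):
            SimilarityTransform(scale=-1.0)


class TestPrincipalFrame:
    def _box(self, extents=(100.0, 20.0, 20.0)):
        tm = trimesh.creation.box(extents=extents)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))

    def test_box_long_axis_and_length(self):
        frame = principal_frame(self._box())
        assert abs(abs(frame.axis_long[0]) - 1.0) < 1e-6
        assert abs(frame.length - 100.0) < 1e-6

    def test_equivariance_under_rotation(self):
        box = self._box()
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        moved = apply_similarity(box, SimilarityTransform(rotation=rot))
        a0 = principal_frame(box).axis_long
        a1 = principal_frame(moved).axis_long
        assert min(np.linalg.norm(a1 - rot @ a0), np.linalg.norm(a1 + rot @ a0)) < 1e-6

    def test_proximal_heuristic_points_to_head(self, femur_mesh, femur_truth_frame):
        frame = principal_frame(femur_mesh)
        assert float(frame.proximal_direction @ femur_truth_frame.proximal_direction) > 0.9

    def test_proximal_hint_overrides(self, femur_mesh, femur_truth_frame):
        flipped = principal_frame(femur_mesh, proximal_hint=-femur_truth_frame.proximal_direction)
        assert float(flipped.proximal_direction @ femur_truth_frame.proximal_direction) < -0.9

    def test_degenerate_geometry_raises(self):
        # flat sheet: covariance rank 2
        g = np.mgrid[0:5, 0:5].reshape(2, -1).T.astype(float)
        verts = np.column_stack([g, np.zeros(len(g))])
        faces = [[i * 5 + j, i * 5 + j + 1, (i + 1) * 5 + j] for i in range(4) for j in range(4)]
        with pytest.raises(DegenerateGeometryError):
            principal_frame(SurfaceMesh(verts, np.array(faces)))

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            BoneFrame(np.zeros(3), [0, 0, 1], [1, 0, 0], [0, -1, 0], 100.0)  # left-handed


class TestAxialFractionAndSectioning:
    @pytest.fixture()
    def frame(self):
        return BoneFrame(
            origin=np.zeros(3),
            axis_long=np.array([0.0, 0.0, 1.0]),
            axis_2=np.array([1.0, 0.0, 0.0]),
            axis_3=np.array([0.0, 1.0, 0.0]),
            length=100.0,
        )

    def test_axial_fraction_linear(self, frame):
        assert axial_fraction(frame, np.array([5.0, -3.0, 0.0])) == pytest.approx(0.0)
        assert axial_fraction(frame, np.array([0.0, 0.0, 100.0])) == pytest.approx(1.0)
        assert axial_fraction(frame, np.array([0.0, 0.0, 15.0])) == pytest.approx(0.15)
        u = axial_fraction(frame, np.array([[0, 0, -10.0], [0, 0, 110.0]]))
        assert u[0] < 0 < 1 < u[1]

    def test_whole_mesh_at_fraction_one(self, frame):
        tube = make_tube()
        assert extract_section(tube, frame, "distal", 1.0).n_faces == tube.n_faces

    def test_distal_section_matches_bruteforce_filter(self, frame):
        tube = make_tube(n_rings=100, n_around=24)
        section = extract_section(tube, frame, "distal", 0.15)
        u = tube.vertices[:, 2] / 100.0
        keep = u <= 0.15
        expected_faces = keep[tube.faces].all(axis=1).sum()
        assert section.n_faces == expected_faces
        assert section.n_vertices == np.unique(tube.faces[keep[tube.faces].all(axis=1)]).size

    def test_default_fractions_disjoint(self, frame):
        tube = make_tube()
        prox = extract_section(tube, frame, "proximal", 0.40)
        dist = extract_section(tube, frame, "distal", 0.15)
        prox_set = {tuple(v) for v in prox.vertices}
        dist_set = {tuple(v) for v in dist.vertices}
        assert not prox_set & dist_set

    def test_empty_section_raises(self, frame):
        tube = make_tube(n_rings=10)
        with pytest.raises(SectioningError):
            extract_section(tube, frame, "distal", 1e-6)
        with pytest.raises(ValueError):
            extract_section(tube, frame, "distal", 0.0)
        with pytest.raises(ValueError):
            extract_section(tube, frame, "middle", 0.5)


class TestRotationComponents:
    @pytest.mark.parametrize("convention", [EULER_XYZ, ROTVEC])
    def test_identity(self, convention):
        triple = rotation_to_components(np.eye(3), convention)
        assert np.allclose(triple.as_array(), 0.0)

    @pytest.mark.parametrize("convention", [EULER_XYZ, ROTVEC])
    def test_single_axis(self, convention):
        rz = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        triple = rotation_to_components(rz, convention)
        assert np.allclose(triple.as_array(), [0, 0, 10], atol=1e-9)

    def test_compound_euler_recovery_and_rotvec_oracle(self):
        r = (
            Rotation.from_euler("z", 5, degrees=True)
            * Rotation.from_euler("y", 5, degrees=True)
            * Rotation.from_euler("x", 5, degrees=True)
        ).as_matrix()
        euler = rotation_to_components(r, EULER_XYZ)
        assert np.allclose(euler.as_array(), [5, 5, 5], atol=1e-9)

        rotvec = rotation_to_components(r, ROTVEC)
        # independent oracle: matrix logarithm
        w = logm(r)
        expected = np.degrees([w[2, 1], w[0, 2], w[1, 0]])
        assert np.allclose(rotvec.as_array(), expected, atol=1e-6)
        # the rotation vector is close to, but distinct from, the euler triple
        assert np.abs(rotvec.as_array() - 5.0).max() <= 0.5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ax=st.floats(-89, 89),
        ay=st.floats(-89, 89),
        az=st.floats(-89, 89),
        convention=st.sampled_from([EULER_XYZ, ROTVEC]),
    )
    def test_roundtrip(self, ax, ay, az, convention):
        triple = RotationTriple(ax, ay, az, convention)
        back = rotation_to_components(components_to_rotation(triple), convention)
        assert np.allclose(components_to_rotation(back), components_to_rotation(triple), atol=1e-9)

    def test_gimbal_lock_flagged(self):
        r = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        assert rotation_to_components(r, EULER_XYZ).gimbal_lock
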