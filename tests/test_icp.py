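import numpy as np
import pytest

from facesup import GrowthParams, apply_growth, run_icp
from facesup.geometry import MeshQuery
from facesup.icp import (
    Correspondences,
    DegenerateGeometryWarning,
    ICPSettings,
    correspondences,
    solve_point_to_plane_step,
)
from facesup.regions import build_reference_area
from facesup.transforms import RigidTransform

from conftest import MISALIGNMENT


def test_source_equals_target_gives_identity(face):
    mesh, lms, _ = face
    mask = build_reference_area(mesh, lms, "area4")
    result = run_icp(mesh, mask, mesh)
    assert np.abs(result.transform.rotation - np.eye(3)).max() < 1e-9
    assert np.abs(result.transform.translation).max() < 1e-9
    assert result.runs_used <= 3
    assert result.converged


def test_recovers_known_rigid_motion(face):
    """Noise-free displaced copy: composed transform is identity to < 1e-3 mm."""
    mesh, lms, _ = face
    motion = RigidTransform.from_axis_angle([0, 1, 0], 5.0, [2.0, -1.0, 3.0])
    moving = mesh.transformed(motion)
    mask = build_reference_area(moving, lms.transformed(motion), "area4")
    result = run_icp(moving, mask, mesh)
    composed = result.transform.compose(motion)
    assert composed.max_displacement(mesh.vertices) < 1e-3


def test_contaminated_mask_recovers_worse_than_stable_mask(clean_subject):
    """Growth inside the reference area biases the fit (the study's key point)."""
    s = clean_subject
    errors = {}
    for area in ("area4", "area1"):
        mask = build_reference_area(s.t1_mesh, s.landmarks_t1, area)
        result = run_icp(s.t1_mesh, mask, s.t0_mesh)
        composed = result.transform.compose(s.true_transform.inverse())
        errors[area] = composed.mean_displacement(s.t0_mesh.vertices)
    assert errors["area4"] < 1e-3  # noise-free, deformation outside the mask
    assert errors["area1"] > 10 * errors["area4"]


def test_residual_trace_non_increasing(noisy_subject):
    s = noisy_subject
    mask = build_reference_area(s.t1_mesh, s.landmarks_t1, "area3")
    result = run_icp(s.t1_mesh, mask, s.t0_mesh)
    trace = np.array(result.per_run_residual)
    assert (np.diff(trace) <= 1e-9).all()
    assert result.converged


def test_equivariance_under_joint_rigid_motion(face):
    """Pre-moving both meshes conjugates the recovered transform."""
    mesh, lms, _ = face
    motion = RigidTransform.from_axis_angle([0, 0, 1], 3.0, [1.0, 0.0, -2.0])
    moving = mesh.transformed(motion)
    mask = build_reference_area(moving, lms.transformed(motion), "area4")
    base = run_icp(moving, mask, mesh).transform

    g = RigidTransform.from_axis_angle([1, 1, 0], 11.0, [5.0, 5.0, -5.0])
    conj = run_icp(
        moving.transformed(g), mask, mesh.transformed(g)
    ).transform
    expected = g.compose(base).compose(g.inverse())
    assert np.abs(conj.matrix() - expected.matrix()).max() < 1e-6


def test_noise_scaling_monotone(face):
    """Recovered-transform error grows with the acquisition noise level."""
    mesh, lms, idx = face
    errors = []
    for sigma in (0.0, 0.05, 0.1, 0.2):
        growth = GrowthParams(
            lower_face_protrusion=0.0,
            noise_sigma=sigma,
            misalignment=MISALIGNMENT,
            seed=3,
        )
        s = apply_growth(mesh, lms, growth, landmark_indices=idx)
        mask = build_reference_area(s.t1_mesh, s.landmarks_t1, "area4")
        result = run_icp(s.t1_mesh, mask, s.t0_mesh)
        composed = result.transform.compose(s.true_transform.inverse())
        errors.append(composed.mean_displacement(s.t0_mesh.vertices))
    assert errors[0] < 1e-6
    assert errors[0] < errors[1] < errors[3]
    assert errors[1] < errors[2] * 2  # roughly linear growth, not explosive


class TestCorrespondences:
    def test_boundary_hits_rejected(self, flat_patch):
        pts = np.array([[0.0, 0.0, 1.0], [15.0, 0.0, 1.0]])
        corr = correspondences(pts, flat_patch, exclude_overhangs=True)
        assert len(corr) == 1
        np.testing.assert_allclose(corr.closest[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_all_rejected_raises(self, flat_patch):
        pts = np.array([[50.0, 50.0, 1.0]])
        with pytest.raises(ValueError, match="overlap"):
            correspondences(pts, flat_patch, exclude_overhangs=True)

    def test_exhaustive_agreement_under_exclusion_off(self, face):
        import trimesh.proximity

        mesh, _, _ = face
        rng = np.random.default_rng(5)
        pts = mesh.vertices[rng.choice(mesh.n_vertices, 20)] + rng.normal(
            scale=2.0, size=(20, 3)
        )
        corr = correspondences(pts, mesh, exclude_overhangs=False)
        _, d_oracle, _ = trimesh.proximity.closest_point_naive(mesh.to_trimesh(), pts)
        np.testing.assert_allclose(corr.point_distances, d_oracle, atol=1e-10)


class TestPointToPlaneSolver:
    def test_zero_residual_gives_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        normals = rng.normal(size=(20, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        corr = Correspondences(source=pts, closest=pts.copy(), normals=normals)
        step = solve_point_to_plane_step(corr)
        assert np.abs(step.matrix() - np.eye(4)).max() < 1e-12

    def test_pure_translation_recovered(self, face):
        mesh, _, _ = face
        query = MeshQuery(mesh)
        rng = np.random.default_rng(1)
        pts = mesh.vertices[rng.choice(mesh.n_vertices, 200, replace=False)]
        offset = np.array([0.0, 0.0, 0.5])
        corr = correspondences(pts + offset, query, exclude_overhangs=True)
        step = solve_point_to_plane_step(corr)
        # one linearised step on a curved target recovers the translation well
        assert np.linalg.norm(step.translation + offset) < 0.05
        # and full ICP drives it to numerical zero
        moved = pts + offset
        pose = RigidTransform.identity()
        for _ in range(20):
            c = correspondences(pose.apply(moved), query, exclude_overhangs=True)
            pose = solve_point_to_plane_step(c).compose(pose)
        assert np.linalg.norm(pose.translation + offset) < 1e-6

    def test_planar_correspondences_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(-5, 5, size=(30, 2))
        src = np.column_stack([xy, np.full(30, 0.7)])
        # lateral offset between source and closest: unconstrained in-plane
        closest = np.column_stack([xy + [2.0, 0.0], np.zeros(30)])
        normals = np.tile([0.0, 0.0, 1.0], (30, 1))
        corr = Correspondences(source=src, closest=closest, normals=normals)
        with pytest.warns(DegenerateGeometryWarning):
            step = solve_point_to_plane_step(corr)
        np.testing.assert_allclose(step.translation[:2], 0.0, atol=1e-9)
        np.testing.assert_allclose(step.translation[2], -0.7, atol=1e-9)

    def test_too_few_correspondences(self):
        corr = Correspondences(
            source=np.zeros((3, 3)), closest=np.zeros((3, 3)), normals=np.zeros((3, 3))
        )
        with pytest.raises(ValueError, match="6"):
            solve_point_to_plane_step(corr)


def test_settings_validation():
    with pytest.raises(ValueError):
        ICPSettings(overlap_fraction=0.0)
    with pytest.raises(ValueError):
        ICPSettings(max_iterations=0)
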