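import numpy as np
import pytest

from facesup import (
    DistanceMap,
    build_measurement_patch,
    build_reference_area,
    export_colormap,
    patch_mad,
    read_mesh,
    reference_congruence,
    reproducibility_difference,
    run_icp,
    signed_distance_map,
    t1_method_difference,
)
from facesup import GrowthParams, apply_growth
from facesup.distance import MadReport
from facesup.regions import PATCH_LABELS, RegionMask
from facesup.transforms import RigidTransform

from conftest import MISALIGNMENT


def test_self_distance_is_zero(face):
    mesh, _, _ = face
    dmap = signed_distance_map(mesh, mesh)
    assert np.abs(dmap.values).max() == 0.0


def test_normal_offset_reads_positive_one(flat_patch):
    comparison = flat_patch.with_vertices(flat_patch.vertices + [0.0, 0.0, 1.0])
    dmap = signed_distance_map(flat_patch, comparison)
    np.testing.assert_allclose(dmap.values, 1.0, atol=1e-6)


def test_posterior_offset_reads_negative(flat_patch):
    comparison = flat_patch.with_vertices(flat_patch.vertices - [0.0, 0.0, 0.8])
    dmap = signed_distance_map(flat_patch, comparison)
    interior = np.abs(flat_patch.vertices[:, :2]).max(axis=1) < 8
    np.testing.assert_allclose(dmap.values[interior], -0.8, atol=1e-6)


def test_magnitude_matches_exhaustive_oracle(face):
    import trimesh.proximity

    mesh, _, _ = face
    moved = mesh.transformed(RigidTransform.from_axis_angle([1, 0, 0], 1.0, [0.3, 0.1, -0.4]))
    dmap = signed_distance_map(mesh, moved)
    sub = np.arange(0, mesh.n_vertices, 37)  # spot-check against the O(n·m) oracle
    _, d_oracle, _ = trimesh.proximity.closest_point_naive(
        moved.to_trimesh(), mesh.vertices[sub]
    )
    np.testing.assert_allclose(np.abs(dmap.values[sub]), d_oracle, atol=1e-10)


def test_joint_rigid_motion_invariance(face):
    mesh, _, _ = face
    moved = mesh.transformed(RigidTransform.from_axis_angle([0, 1, 0], 2.0, [1, 0, 0]))
    base = signed_distance_map(mesh, moved)
    g = RigidTransform.from_axis_angle([1, 1, 1], 20.0, [7.0, -3.0, 2.0])
    conj = signed_distance_map(mesh.transformed(g), moved.transformed(g))
    np.testing.assert_allclose(conj.values, base.values, atol=1e-9)


class TestPatchMad:
    def test_zero_map(self):
        dmap = DistanceMap("m", np.zeros(200))
        patch = RegionMask("m", np.arange(100), "meas_N")
        assert patch_mad(dmap, patch) == 0.0

    def test_absolute_value_contract(self):
        dmap = DistanceMap("m", np.array([1.0, -1.0, 1.0, -1.0]))
        patch = RegionMask("m", np.arange(4), "meas_N")
        assert patch_mad(dmap, patch) == 1.0

    def test_closed_form_mean(self):
        dmap = DistanceMap("m", np.arange(1, 101) / 100.0)
        patch = RegionMask("m", np.arange(100), "meas_N")
        assert abs(patch_mad(dmap, patch) - 0.505) < 1e-12

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=300)
        patch = RegionMask("m", np.arange(100), "meas_N")
        perm = rng.permutation(300)
        base = patch_mad(DistanceMap("m", values), patch)
        inflated = patch_mad(DistanceMap("m", values * 1.5), patch)
        assert inflated > base
        # permuting values *within* the patch leaves the mean unchanged
        shuffled = values.copy()
        shuffled[:100] = values[rng.permutation(100)]
        assert abs(patch_mad(DistanceMap("m", shuffled), patch) - base) < 1e-12

    def test_out_of_range_patch_rejected(self):
        dmap = DistanceMap("m", np.zeros(50))
        patch = RegionMask("m", np.arange(100), "meas_N")
        with pytest.raises(ValueError):
            patch_mad(dmap, patch)


class TestT1MethodDifference:
    def test_identical_placements_zero(self, face):
        mesh, lms, _ = face
        patches = [build_measurement_patch(mesh, lms, l) for l in PATCH_LABELS]
        report, dmap = t1_method_difference(mesh, mesh, patches)
        assert all(v == 0.0 for v in report.per_patch.values())
        assert np.abs(dmap.values).max() == 0.0

    def test_half_millimetre_offset_on_facing_patch(self, flat_patch):
        moved = flat_patch.with_vertices(flat_patch.vertices + [0.0, 0.0, 0.5])
        patch = RegionMask("flat", np.arange(100), "meas_N")
        report, _ = t1_method_difference(flat_patch, moved, [patch])
        assert abs(report.per_patch["meas_N"] - 0.5) < 1e-6

    def test_small_translation_bounded_by_displacement(self, face):
        mesh, lms, _ = face
        offset = RigidTransform(translation=[0.0, 0.0, 0.3])
        moved = mesh.transformed(offset)
        patches = [build_measurement_patch(mesh, lms, l) for l in PATCH_LABELS]
        report, _ = t1_method_difference(mesh, moved, patches)
        for label, value in report.per_patch.items():
            assert 0.2 <= value <= 0.3 + 1e-9, label

    def test_different_models_rejected(self, face, flat_patch):
        mesh, lms, _ = face
        with pytest.raises(ValueError, match="same T1 model"):
            t1_method_difference(mesh, flat_patch, [])


class TestReferenceCongruence:
    def test_identical_models(self, face):
        mesh, lms, _ = face
        mask = build_reference_area(mesh, lms, "area4")
        assert reference_congruence(mesh, mesh, mask) == 0.0

    def test_noise_free_after_icp(self, clean_subject):
        s = clean_subject
        mask = build_reference_area(s.t1_mesh, s.landmarks_t1, "area4")
        result = run_icp(s.t1_mesh, mask, s.t0_mesh)
        method_t1 = s.t1_mesh.transformed(result.transform)
        assert reference_congruence(s.t0_mesh, method_t1, mask) < 1e-3

    def test_noisy_congruence_band(self, face):
        mesh, lms, idx = face
        growth = GrowthParams(
            lower_face_protrusion=2.0, noise_sigma=0.2, misalignment=MISALIGNMENT, seed=9
        )
        s = apply_growth(mesh, lms, growth, landmark_indices=idx)
        mask = build_reference_area(s.t1_mesh, s.landmarks_t1, "area4")
        result = run_icp(s.t1_mesh, mask, s.t0_mesh)
        method_t1 = s.t1_mesh.transformed(result.transform)
        assert 0.1 <= reference_congruence(s.t0_mesh, method_t1, mask) <= 0.5


class TestReproducibilityDifference:
    def test_identical_runs(self):
        r = MadReport(per_patch={"meas_N": 0.4, "meas_A": 0.2}, patch_sizes={"meas_N": 100, "meas_A": 100})
        diffs = reproducibility_difference(r, r)
        assert all(v == 0.0 for v in diffs.values())

    def test_sign_preserved(self):
        a = MadReport(per_patch={"meas_N": 0.5}, patch_sizes={"meas_N": 100})
        b = MadReport(per_patch={"meas_N": 0.8}, patch_sizes={"meas_N": 100})
        assert reproducibility_difference(a, b)["meas_N"] == pytest.approx(-0.3)

    def test_mismatched_labels_rejected(self):
        a = MadReport(per_patch={"meas_N": 0.5}, patch_sizes={"meas_N": 100})
        b = MadReport(per_patch={"meas_A": 0.5}, patch_sizes={"meas_A": 100})
        with pytest.raises(ValueError, match="mismatched"):
            reproducibility_difference(a, b)


class TestColormapExport:
    def test_zero_map_uniform_midpoint(self, flat_patch, tmp_path):
        import trimesh

        dmap = DistanceMap("flat", np.zeros(flat_patch.n_vertices))
        path = tmp_path / "zero.ply"
        export_colormap(dmap, flat_patch, path, scale=(-2.0, 2.0))
        colors = np.asarray(trimesh.load(path, process=False).visual.vertex_colors)[:, :3]
        assert (colors == colors[0]).all()

    def test_clamping_at_scale(self, flat_patch, tmp_path):
        import trimesh

        n = flat_patch.n_vertices
        at_max = DistanceMap("flat", np.full(n, 2.0))
        beyond = DistanceMap("flat", np.full(n, 4.0))
        p1, p2 = tmp_path / "a.ply", tmp_path / "b.ply"
        export_colormap(at_max, flat_patch, p1, scale=(-2.0, 2.0))
        export_colormap(beyond, flat_patch, p2, scale=(-2.0, 2.0))
        c1 = np.asarray(trimesh.load(p1, process=False).visual.vertex_colors)
        c2 = np.asarray(trimesh.load(p2, process=False).visual.vertex_colors)
        np.testing.assert_array_equal(c1, c2)

    def test_scale_recorded_and_readable(self, flat_patch, tmp_path):
        dmap = DistanceMap("flat", np.zeros(flat_patch.n_vertices))
        path = tmp_path / "m.ply"
        export_colormap(dmap, flat_patch, path, scale=(-1.5, 1.5))
        assert "scale_mm -1.5 1.5" in path.read_text()[:300]
        back = read_mesh(path)
        assert back.n_vertices == flat_patch.n_vertices

    def test_invalid_scale_rejected(self, flat_patch):
        dmap = DistanceMap("flat", np.zeros(flat_patch.n_vertices))
        with pytest.raises(ValueError, match="scale"):
            export_colormap(dmap, flat_patch, "x.ply", scale=(2.0, -2.0))
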