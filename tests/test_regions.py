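import numpy as np
import pytest

from facesup import (
    LandmarkSet,
    SurfaceMesh,
    build_measurement_patch,
    build_reference_area,
    transfer_mask,
)
from facesup.mesh_io import REQUIRED_LANDMARKS, face_frame
from facesup.regions import (
    AREA_LABELS,
    DEFAULT_AREA_CONFIG,
    PATCH_LABELS,
    PATCH_SEEDS,
    load_mask,
    save_mask,
)
from facesup.transforms import RigidTransform

MOTION = RigidTransform.from_axis_angle([1.0, 0.2, -0.4], 17.0, [10.0, -4.0, 6.0])


def test_area5_is_area4_minus_forehead_rectangle(face):
    mesh, lms, _ = face
    a4 = set(build_reference_area(mesh, lms, "area4").vertex_indices)
    a5 = set(build_reference_area(mesh, lms, "area5").vertex_indices)
    # independent scan: which area4 vertices sit in the forehead rectangle?
    p = face_frame(lms).apply(mesh.vertices)
    half_x, y0, y1 = DEFAULT_AREA_CONFIG.forehead_rect
    in_rect = {
        i
        for i in a4
        if abs(p[i, 0]) <= half_x and y0 <= p[i, 1] <= y1
    }
    assert a5 == a4 - in_rect
    assert a5 < a4


@pytest.mark.parametrize("label", ["area1", "area3"])
def test_nose_tip_exclusion(face, label):
    mesh, lms, _ = face
    mask = build_reference_area(mesh, lms, label)
    d = np.linalg.norm(mesh.vertices[mask.vertex_indices] - lms["pronasale"], axis=1)
    assert d.min() > DEFAULT_AREA_CONFIG.nose_tip_radius


def test_area3_upper_half_bound(face):
    mesh, lms, _ = face
    mask = build_reference_area(mesh, lms, "area3")
    y = face_frame(lms).apply(mesh.vertices[mask.vertex_indices])[:, 1]
    assert y.min() >= DEFAULT_AREA_CONFIG.upper_face_y_min


def test_area2_avoids_mouth(face):
    mesh, lms, _ = face
    mask = build_reference_area(mesh, lms, "area2")
    mouth = 0.5 * (lms["cheilion_R"] + lms["cheilion_L"])
    d = np.linalg.norm(mesh.vertices[mask.vertex_indices] - mouth, axis=1)
    assert d.min() > 10.0


def test_area4_has_both_components(face):
    mesh, lms, _ = face
    mask = build_reference_area(mesh, lms, "area4")
    p = face_frame(lms).apply(mesh.vertices[mask.vertex_indices])
    half_x, y0, y1 = DEFAULT_AREA_CONFIG.forehead_rect
    in_rect = (np.abs(p[:, 0]) <= half_x) & (p[:, 1] >= y0) & (p[:, 1] <= y1)
    assert in_rect.any() and (~in_rect).any()


def test_all_areas_rigid_invariant(face):
    mesh, lms, _ = face
    moved_mesh = mesh.transformed(MOTION)
    moved_lms = lms.transformed(MOTION)
    for label in AREA_LABELS:
        a = build_reference_area(mesh, lms, label)
        b = build_reference_area(moved_mesh, moved_lms, label)
        np.testing.assert_array_equal(a.vertex_indices, b.vertex_indices)


class TestMeasurementPatches:
    def test_matches_brute_force_sort(self, face):
        mesh, lms, _ = face
        for label in PATCH_LABELS:
            patch = build_measurement_patch(mesh, lms, label)
            d = np.round(np.linalg.norm(mesh.vertices - lms[PATCH_SEEDS[label]], axis=1), 9)
            oracle = set(np.lexsort((np.arange(len(d)), d))[:100])
            assert set(patch.vertex_indices) == oracle
            assert len(patch) == 100

    def test_pairwise_disjoint(self, face):
        mesh, lms, _ = face
        sets = [
            set(build_measurement_patch(mesh, lms, l).vertex_indices)
            for l in PATCH_LABELS
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_rigid_invariance(self, face):
        mesh, lms, _ = face
        a = build_measurement_patch(mesh, lms, "meas_Pog")
        b = build_measurement_patch(mesh.transformed(MOTION), lms.transformed(MOTION), "meas_Pog")
        np.testing.assert_array_equal(a.vertex_indices, b.vertex_indices)

    def test_mesh_with_exactly_100_vertices(self):
        g = np.linspace(0, 9, 10)
        xx, yy = np.meshgrid(g, g)
        v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(100)])
        faces = [(i, i + 1, i + 10) for i in range(89) if (i + 1) % 10]
        mesh = SurfaceMesh(v, np.array(faces))
        lms = LandmarkSet({n: (4.0, 4.0, 0.0) for n in REQUIRED_LANDMARKS})
        patch = build_measurement_patch(mesh, lms, "meas_N")
        assert set(patch.vertex_indices) == set(range(100))

    def test_too_few_vertices_rejected(self):
        v = np.column_stack([np.arange(50.0), np.zeros(50), np.zeros(50)])
        mesh = SurfaceMesh(v, np.array([[0, 1, 2]]))
        lms = LandmarkSet({n: (0.0, 0.0, 0.0) for n in REQUIRED_LANDMARKS})
        with pytest.raises(ValueError, match="100"):
            build_measurement_patch(mesh, lms, "meas_N")


class TestTransferMask:
    def test_identity_target(self, face):
        mesh, lms, _ = face
        patch = build_measurement_patch(mesh, lms, "meas_N")
        out = transfer_mask(patch, mesh, mesh)
        np.testing.assert_array_equal(out.vertex_indices, patch.vertex_indices)
        assert out.original_size == 100

    def test_permuted_target_maps_to_same_points(self, face):
        mesh, lms, _ = face
        rng = np.random.default_rng(3)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mesh.n_vertices)
        permuted = SurfaceMesh(mesh.vertices[perm], inv[mesh.faces], mesh_id="perm")
        patch = build_measurement_patch(mesh, lms, "meas_A")
        out = transfer_mask(patch, mesh, permuted)
        a = mesh.vertices[patch.vertex_indices]
        b = permuted.vertices[out.vertex_indices]
        assert {tuple(p) for p in np.round(a, 9)} == {tuple(p) for p in np.round(b, 9)}

    def test_decimated_target_stays_within_patch_extent(self, face):
        mesh, lms, _ = face
        keep = np.zeros(mesh.n_vertices, dtype=bool)
        keep[::2] = True
        half = mesh.submesh(keep, mesh_id="half")
        patch = build_measurement_patch(mesh, lms, "meas_Pog")
        out = transfer_mask(patch, mesh, half)
        src = mesh.vertices[patch.vertex_indices]
        center = src.mean(axis=0)
        radius = np.linalg.norm(src - center, axis=1).max()
        edge = np.linalg.norm(
            mesh.vertices[mesh.faces[:, 0]] - mesh.vertices[mesh.faces[:, 1]], axis=1
        ).mean()
        d = np.linalg.norm(half.vertices[out.vertex_indices] - center, axis=1)
        assert d.max() <= radius + 2 * edge
        assert len(out) <= 100 and out.original_size == 100


def test_mask_file_round_trip(face, tmp_path):
    mesh, lms, _ = face
    patch = build_measurement_patch(mesh, lms, "meas_GoR")
    path = tmp_path / "mask.txt"
    save_mask(patch, path)
    back = load_mask(path)
    assert back.label == patch.label
    np.testing.assert_array_equal(back.vertex_indices, patch.vertex_indices)
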