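"""Superimposition reference areas and measurement patches.

Five candidate reference areas are defined parametrically in the
face-aligned frame (mm), combining boxes, ellipsoids, spheres and
half-spaces, with exclusion zones over the eyes, the mouth and the nose
tip:

* area1 — whole facial surface minus eyes, mouth and nose tip;
* area2 — forehead/glabella plus the base of the nose;
* area3 — upper half of the face minus eyes and nose tip;
* area4 — a small forehead rectangle plus the mid-nose strip and the two
  infraorbital patches;
* area5 — area4 without the forehead rectangle.

The seven measurement patches are the 100 mesh vertices nearest
(Euclidean) to their seed landmark, ties broken toward the lower vertex
index, so the selection is deterministic and rigid-motion invariant.
Every geometric constant lives in :class:`AreaConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import LandmarkSet, SurfaceMesh, face_frame

__all__ = [
    "RegionMask",
    "AreaConfig",
    "DEFAULT_AREA_CONFIG",
    "AREA_LABELS",
    "PATCH_LABELS",
    "PATCH_SEEDS",
    "build_reference_area",
    "build_measurement_patch",
    "transfer_mask",
    "save_mask",
    "load_mask",
]

AREA_LABELS = ("area1", "area2", "area3", "area4", "area5")

#: measurement patch -> seed landmark
PATCH_SEEDS = {
    "meas_N": "soft_nasion",
    "meas_A": "soft_A_point",
    "meas_Pog": "soft_pogonion",
    "meas_ZygR": "zygion_R",
    "meas_ZygL": "zygion_L",
    "meas_GoR": "gonion_R",
    "meas_GoL": "gonion_L",
}
PATCH_LABELS = tuple(PATCH_SEEDS)

PATCH_SIZE = 100


@dataclass(frozen=True)
class RegionMask:
    """A set of vertex indices on a specific mesh."""

    mesh_id: str
    vertex_indices: np.ndarray  # sorted unique 0-based indices
    label: str
    original_size: int | None = None  # pre-collapse size after transfer

    def __post_init__(self):
        idx = np.unique(np.asarray(self.vertex_indices, dtype=np.int64))
        if idx.size == 0:
            raise ValueError(f"empty region mask {self.label!r}")
        if idx.min() < 0:
            raise ValueError("negative vertex index in mask")
        object.__setattr__(self, "vertex_indices", idx)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def validate_on(self, mesh: SurfaceMesh) -> None:
        if self.vertex_indices.max() >= mesh.n_vertices:
            raise ValueError(
                f"mask {self.label!r} indexes past the end of mesh {mesh.mesh_id!r}"
            )


@dataclass(frozen=True)
class AreaConfig:
    """Every constant of the parametric area definitions (face frame, mm)."""

    # exclusion zones
    eye_semi_axes: tuple = (22.0, 14.0, 15.0)
    eye_posterior_offset: float = 2.0
    pupil_x_fraction: float = 0.55  # pupil x as a fraction of exocanthion x
    mouth_semi_axes: tuple = (30.0, 18.0, 15.0)
    nose_tip_radius: float = 10.0
    # area2
    forehead_box: tuple = (30.0, 5.0, 45.0, -5.0)  # |x|<=, y in [., .], z >=
    nasal_base_box: tuple = (12.0, -8.0, 8.0)  # |x|<=, y in [., .] about nasion
    # area3
    upper_face_y_min: float = -15.0
    # area4 / area5
    forehead_rect: tuple = (15.0, 18.0, 38.0)  # |x|<=, y in [., .]
    mid_nose_strip: tuple = (10.0, -25.0, 0.0)  # |x|<=, y in [., .]
    infraorbital_radius: float = 12.0


DEFAULT_AREA_CONFIG = AreaConfig()


def _frame_coords(mesh: SurfaceMesh, landmarks: LandmarkSet):
    frame = face_frame(landmarks)
    return frame.apply(mesh.vertices), frame


def _ellipsoid_mask(p, center, semi_axes):
    q = (p - center) / np.asarray(semi_axes)
    return np.einsum("ij,ij->i", q, q) <= 1.0


def _exclusions(p, landmarks, frame, cfg: AreaConfig):
    """Boolean mask of vertices inside any eye/mouth/nose-tip exclusion."""
    return (
        _eye_masks(p, landmarks, frame, cfg)
        | _mouth_only(p, landmarks, frame, cfg)
        | _nose_tip(p, landmarks, frame, cfg)
    )


def _nose_tip(p, landmarks, frame, cfg: AreaConfig):
    prn = frame.apply(landmarks["pronasale"])
    return np.linalg.norm(p - prn, axis=1) <= cfg.nose_tip_radius


def _forehead_rect_mask(p, cfg: AreaConfig):
    half_x, y0, y1 = cfg.forehead_rect
    return (np.abs(p[:, 0]) <= half_x) & (p[:, 1] >= y0) & (p[:, 1] <= y1)


def _area_select(p, landmarks, frame, label: str, cfg: AreaConfig):
    x, y = p[:, 0], p[:, 1]
    if label == "area1":
        return ~_exclusions(p, landmarks, frame, cfg)
    if label == "area2":
        half_x, y0, y1, z_min = cfg.forehead_box
        forehead = (np.abs(x) <= half_x) & (y >= y0) & (y <= y1) & (p[:, 2] >= z_min)
        nb_half_x, nb_y0, nb_y1 = cfg.nasal_base_box
        nasion_y = frame.apply(landmarks["soft_nasion"])[1]
        nasal = (np.abs(x) <= nb_half_x) & (y >= nasion_y + nb_y0) & (y <= nasion_y + nb_y1)
        return forehead | nasal
    if label == "area3":
        upper = y >= cfg.upper_face_y_min
        return upper & ~_eye_masks(p, landmarks, frame, cfg) & ~_nose_tip(p, landmarks, frame, cfg)
    if label in ("area4", "area5"):
        sel = _mid_nose_and_orbits(p, landmarks, frame, cfg)
        if label == "area4":
            sel = sel | _forehead_rect_mask(p, cfg)
        return sel
    raise ValueError(f"unknown reference area label {label!r}")


def _eye_masks(p, landmarks, frame, cfg):
    out = np.zeros(len(p), dtype=bool)
    for side in ("R", "L"):
        exo = frame.apply(landmarks[f"exocanthion_{side}"])
        pupil = exo.copy()
        pupil[0] *= cfg.pupil_x_fraction
        center = 0.5 * (exo + pupil)
        center[2] -= cfg.eye_posterior_offset
        out |= _ellipsoid_mask(p, center, cfg.eye_semi_axes)
    return out


def _mouth_only(p, landmarks, frame, cfg):
    mouth_center = 0.5 * (
        frame.apply(landmarks["cheilion_R"]) + frame.apply(landmarks["cheilion_L"])
    )
    return _ellipsoid_mask(p, mouth_center, cfg.mouth_semi_axes)


def _mid_nose_and_orbits(p, landmarks, frame, cfg):
    half_x, y0, y1 = cfg.mid_nose_strip
    strip = (
        (np.abs(p[:, 0]) <= half_x)
        & (p[:, 1] >= y0)
        & (p[:, 1] <= y1)
        & ~_nose_tip(p, landmarks, frame, cfg)
    )
    orbits = np.zeros(len(p), dtype=bool)
    for side in ("R", "L"):
        orb = frame.apply(landmarks[f"orbitale_{side}"])
        orbits |= np.linalg.norm(p - orb, axis=1) <= cfg.infraorbital_radius
    return strip | orbits


def build_reference_area(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    label: str,
    config: AreaConfig = DEFAULT_AREA_CONFIG,
) -> RegionMask:
    """Select the vertices of one of the five reference areas."""
    if label not in AREA_LABELS:
        raise ValueError(f"unknown reference area label {label!r}")
    if landmarks.max_distance_to(mesh) > 2.0:
        raise ValueError("landmarks do not lie on this mesh (surface distance > 2 mm)")
    p, frame = _frame_coords(mesh, landmarks)
    sel = _area_select(p, landmarks, frame, label, config)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"reference area {label!r} selected no vertices")
    return RegionMask(mesh_id=mesh.mesh_id, vertex_indices=idx, label=label)


def build_measurement_patch(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    label: str,
    size: int = PATCH_SIZE,
) -> RegionMask:
    """The *size* vertices nearest (Euclidean) to the patch's seed landmark."""
    if label not in PATCH_SEEDS:
        raise ValueError(f"unknown measurement patch label {label!r}")
    if mesh.n_vertices < size:
        raise ValueError(
            f"mesh has {mesh.n_vertices} vertices; patch needs at least {size}"
        )
    seed = landmarks[PATCH_SEEDS[label]]
    # distances rounded to 1e-9 mm so grid-symmetric ties resolve identically
    # after any rigid motion; ties then break toward the lower index
    d = np.round(np.linalg.norm(mesh.vertices - seed, axis=1), 9)
    order = np.lexsort((np.arange(mesh.n_vertices), d))
    return RegionMask(mesh_id=mesh.mesh_id, vertex_indices=order[:size], label=label)


def transfer_mask(
    mask: RegionMask, source_mesh: SurfaceMesh, target_mesh: SurfaceMesh
) -> RegionMask:
    """Duplicate a mask onto another mesh by nearest-vertex mapping.

    Both meshes must already be in a common frame (post-superimposition).
    Duplicate targets collapse; the original size is recorded.
    """
    mask.validate_on(source_mesh)
    src = source_mesh.vertices[mask.vertex_indices]
    _, nearest = cKDTree(target_mesh.vertices).query(src)
    return RegionMask(
        mesh_id=target_mesh.mesh_id,
        vertex_indices=np.unique(nearest),
        label=mask.label,
        original_size=len(mask),
    )


def save_mask(mask: RegionMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {mask.label} {mask.mesh_id} {len(mask)}\n")
        for i in mask.vertex_indices:
            fh.write(f"{int(i)}\n")


def load_mask(path) -> RegionMask:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# label mesh_id count' header")
        parts = header[1:].split()
        label, mesh_id = parts[0], parts[1] if len(parts) > 1 else ""
        idx = [int(line) for line in fh if line.strip()]
    return RegionMask(mesh_id=mesh_id, vertex_indices=np.array(idx), label=label)
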