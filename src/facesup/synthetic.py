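"""Synthetic longitudinal facial surfaces with known ground truth.

Real serial CBCT/stereophotogrammetry data are not redistributable, so the
pipeline is validated on a parametric stand-in: a smooth face-like height
field over a half-ellipsoid dome with Gaussian-bump features (forehead and
brow, nasal bridge and tip, orbital sockets, cheeks, lips, chin). Because
the surface and its 16 soft-tissue landmarks have closed forms, a subject
carries exact ground truth:

* ``true_transform`` — the inverse of the rigid misalignment imposed
  between the scans: the synthetic analogue of the gold-standard
  (cranial-base) registration frame;
* ``true_displacement_field`` — the growth deformation in that stable
  frame.

The growth model follows what serial facial surfaces of adolescents show:
a protrusion of the middle/lower face (smoothly weighted below the
subnasale level), optional nasal growth decaying radially from the nose
tip, an optional global anterior drift of the whole face, optional signed
adiposity change weighted on the cheeks, plus scanner-like Gaussian noise
along vertex normals. All randomness flows from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_io import LandmarkSet, SurfaceMesh, face_frame, write_landmarks, write_mesh
from .transforms import RigidTransform

__all__ = [
    "FaceParams",
    "GrowthParams",
    "SyntheticSubject",
    "generate_face",
    "apply_growth",
    "generate_cohort",
    "random_misalignment",
    "SCENARIOS",
]

#: nominal landmark positions in the generator frame (x lateral, y vertical,
#: mm; origin at soft nasion). Landmarks snap to the nearest grid vertex so
#: they lie exactly on the triangulated surface.
LANDMARK_XY = {
    "glabella": (0.0, 12.0),
    "soft_nasion": (0.0, 0.0),
    "pronasale": (0.0, -28.0),
    "subnasale": (0.0, -38.0),
    "orbitale_R": (18.0, -8.0),
    "orbitale_L": (-18.0, -8.0),
    "exocanthion_R": (42.0, 2.0),
    "exocanthion_L": (-42.0, 2.0),
    "cheilion_R": (22.0, -58.0),
    "cheilion_L": (-22.0, -58.0),
    "soft_A_point": (0.0, -45.0),
    "soft_pogonion": (0.0, -78.0),
    "zygion_R": (55.0, -10.0),
    "zygion_L": (-55.0, -10.0),
    "gonion_R": (48.0, -55.0),
    "gonion_L": (-48.0, -55.0),
}

# half-extent of the generated patch and the dome ellipse (mm)
_X_EXTENT = (-70.0, 70.0)
_Y_EXTENT = (-88.0, 42.0)
_DOME_MARGIN = 0.15  # drop the steep dome rim: keeps the surface smooth & open


@dataclass(frozen=True)
class FaceParams:
    """Shape parameters of one synthetic face."""

    size: float = 1.0  # global isotropic scale (1.0 ≈ adolescent face, 140 mm wide)
    nose_amplitude: float = 12.0  # nose tip height, mm
    bridge_amplitude: float = 5.0  # nasal bridge height, mm
    brow_amplitude: float = 3.0  # brow ridge, mm
    chin_amplitude: float = 6.0  # chin prominence, mm
    cheek_amplitude: float = 4.0  # cheek fullness, mm
    orbital_rim_amplitude: float = 2.5  # infraorbital/orbital rim ridge, mm
    glabella_amplitude: float = 2.0  # central glabellar prominence, mm
    resolution: int = 3000  # vertex count target
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 2000:
            raise ValueError(
                "resolution must be >= 2000 vertices so 100-vertex patches stay local"
            )


@dataclass(frozen=True)
class GrowthParams:
    """T0 → T1 deformation over roughly 1–3 years of growth."""

    global_forward_drift: float = 0.0  # mm, whole-face anterior translation
    lower_face_protrusion: float = 2.0  # mm at full weight (chin level)
    nasal_growth: float = 0.0  # mm at pronasale, radial Gaussian decay
    adiposity_change: float = 0.0  # mm, signed, along normals on the cheeks
    noise_sigma: float = 0.05  # mm, Gaussian noise along vertex normals
    noise_correlation: float = 3.0  # mm, spatial correlation length of the noise
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0
    # weight-field constants (face frame, mm)
    protrusion_y_start: float = -32.0  # weight 0 at/above this height
    protrusion_y_full: float = -55.0  # weight 1 at/below this height
    nasal_sigma: float = 10.0
    cheek_centers: tuple = ((45.0, -35.0), (-45.0, -35.0))
    cheek_sigma: float = 16.0


@dataclass
class SyntheticSubject:
    """Ground-truth bundle for one simulated individual."""

    subject_id: str
    t0_mesh: SurfaceMesh
    t1_mesh: SurfaceMesh
    landmarks_t0: LandmarkSet
    landmarks_t1: LandmarkSet
    true_transform: RigidTransform  # T1 -> T0 stable frame (gold-standard analogue)
    true_displacement_field: np.ndarray  # (n, 3) growth in the stable frame, mm
    face_params: FaceParams
    growth_params: GrowthParams


def _height_field(x, y, fp: FaceParams):
    """Closed-form facial height (anterior coordinate) over the (x, y) plane."""
    s = fp.size
    x = x / s
    y = y / s
    dome = 55.0 * np.sqrt(np.clip(1.0 - (x / 85.0) ** 2 - ((y + 35.0) / 105.0) ** 2, 0.0, None))
    nose = fp.nose_amplitude * np.exp(-((x / 7.0) ** 2) - (((y + 28.0) / 11.0) ** 2))
    bridge = fp.bridge_amplitude * np.exp(-((x / 6.0) ** 2) - (((y + 12.0) / 12.0) ** 2))
    brow = fp.brow_amplitude * np.exp(-(((y - 14.0) / 7.0) ** 2)) * np.exp(-((x / 30.0) ** 2))
    sockets = -3.0 * (
        np.exp(-(((x - 30.0) / 12.0) ** 2) - (((y - 4.0) / 7.0) ** 2))
        + np.exp(-(((x + 30.0) / 12.0) ** 2) - (((y - 4.0) / 7.0) ** 2))
    )
    # bony orbital margin: a ridge ringing each socket (the lower arc is the
    # infraorbital rim the registration areas anchor on)
    r_orbit_r = np.sqrt((x - 30.0) ** 2 + (y - 4.0) ** 2)
    r_orbit_l = np.sqrt((x + 30.0) ** 2 + (y - 4.0) ** 2)
    rims = fp.orbital_rim_amplitude * (
        np.exp(-(((r_orbit_r - 14.0) / 4.5) ** 2))
        + np.exp(-(((r_orbit_l - 14.0) / 4.5) ** 2))
    )
    glab = fp.glabella_amplitude * np.exp(-((x / 12.0) ** 2) - (((y - 8.0) / 9.0) ** 2))
    chin = fp.chin_amplitude * np.exp(-((x / 16.0) ** 2) - (((y + 78.0) / 12.0) ** 2))
    cheeks = fp.cheek_amplitude * (
        np.exp(-(((x - 45.0) / 18.0) ** 2) - (((y + 35.0) / 16.0) ** 2))
        + np.exp(-(((x + 45.0) / 18.0) ** 2) - (((y + 35.0) / 16.0) ** 2))
    )
    lips = 2.0 * np.exp(-((x / 20.0) ** 2) - (((y + 58.0) / 6.0) ** 2))
    return s * (dome + nose + bridge + brow + sockets + rims + glab + chin + cheeks + lips)


def generate_face(params: FaceParams = FaceParams()):
    """Generate one open face-like surface and its 16 landmarks.

    Returns ``(mesh, landmarks, landmark_vertex_indices)``; the indices let
    the growth model displace landmarks exactly with their vertices.
    Deterministic given the parameters (the seed participates only through
    the cohort generator's parameter draws; the surface itself is analytic).
    """
    s = params.size
    # grid sized so that, after trimming the dome rim, roughly `resolution`
    # vertices survive (the elliptical trim keeps ~95% of the bounding box)
    target = params.resolution / 0.95
    span_x = _X_EXTENT[1] - _X_EXTENT[0]
    span_y = _Y_EXTENT[1] - _Y_EXTENT[0]
    nx = int(round(np.sqrt(target * span_x / span_y)))
    if nx % 2 == 0:
        nx += 1  # odd count keeps the grid (and landmark snapping) symmetric in x
    ny = int(np.ceil(target / nx))
    gx = np.linspace(_X_EXTENT[0] * s, _X_EXTENT[1] * s, nx)
    gy = np.linspace(_Y_EXTENT[0] * s, _Y_EXTENT[1] * s, ny)
    xx, yy = np.meshgrid(gx, gy, indexing="xy")
    inside = (
        (xx / s / 85.0) ** 2 + ((yy / s + 35.0) / 105.0) ** 2 <= 1.0 - _DOME_MARGIN
    )
    zz = _height_field(xx, yy, params)

    index_grid = -np.ones(xx.shape, dtype=np.int64)
    index_grid[inside] = np.arange(int(inside.sum()))
    vertices = np.column_stack([xx[inside], yy[inside], zz[inside]])

    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            q = (
                index_grid[j, i],
                index_grid[j, i + 1],
                index_grid[j + 1, i + 1],
                index_grid[j + 1, i],
            )
            if q[0] >= 0 and q[1] >= 0 and q[2] >= 0:
                faces.append((q[0], q[1], q[2]))
            if q[0] >= 0 and q[2] >= 0 and q[3] >= 0:
                faces.append((q[0], q[2], q[3]))
    mesh = SurfaceMesh(vertices, np.array(faces, dtype=np.int64), mesh_id="synthetic-face")
    if mesh.n_vertices < 2000:
        raise ValueError("generated mesh fell below the 2000-vertex minimum")

    landmark_indices = {}
    points = {}
    for name, (lx, ly) in LANDMARK_XY.items():
        d2 = (vertices[:, 0] - lx * s) ** 2 + (vertices[:, 1] - ly * s) ** 2
        if name == "pronasale":
            # the nose tip is the most anterior vertex of the tip region,
            # not merely the vertex nearest the nominal coordinate
            near = d2 <= (6.0 * s) ** 2
            candidates = np.flatnonzero(near)
            idx = int(candidates[np.argmax(vertices[candidates, 2])])
        else:
            idx = int(np.argmin(d2))
        landmark_indices[name] = idx
        points[name] = vertices[idx]
    return mesh, LandmarkSet(points), landmark_indices


def _noise_field(vertices, rng, sigma, correlation_length):
    """Scanner-like acquisition noise: per-vertex Gaussian with N(0, σ)
    marginals and smooth spatial correlation.

    Real surface-scan noise is wavy, not independent per vertex: an i.i.d.
    field at sub-millimetre mesh spacing would make the two surfaces jagged
    at a scale no scanner produces. A white field is therefore convolved
    with a Gaussian kernel of the given correlation length; normalising
    each row by its l2 weight norm keeps the per-vertex marginal exactly
    N(0, σ). ``correlation_length <= 0`` falls back to white noise.
    """
    n = len(vertices)
    white = rng.normal(size=n)
    if sigma == 0.0:
        return np.zeros(n)
    if correlation_length <= 0:
        return sigma * white
    from scipy.spatial import cKDTree

    tree = cKDTree(vertices)
    pairs = tree.sparse_distance_matrix(
        tree, 2.5 * correlation_length, output_type="coo_matrix"
    )
    weights = np.exp(-((pairs.data / correlation_length) ** 2))
    smooth = np.zeros(n)
    norm2 = np.zeros(n)
    np.add.at(smooth, pairs.row, weights * white[pairs.col])
    np.add.at(norm2, pairs.row, weights**2)
    return sigma * smooth / np.sqrt(norm2)


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def growth_weights(frame_coords: np.ndarray, growth: GrowthParams, landmarks_frame: dict):
    """Spatial weight fields (each in [0, 1]) evaluated at face-frame points."""
    y = frame_coords[:, 1]
    w_lower = _smoothstep(
        (growth.protrusion_y_start - y)
        / (growth.protrusion_y_start - growth.protrusion_y_full)
    )
    prn = landmarks_frame["pronasale"]
    r_nose = np.linalg.norm(frame_coords - prn, axis=1)
    w_nasal = np.exp(-((r_nose / growth.nasal_sigma) ** 2))
    w_cheek = np.zeros(len(frame_coords))
    for cx, cy in growth.cheek_centers:
        d2 = (frame_coords[:, 0] - cx) ** 2 + (y - cy) ** 2
        w_cheek = np.maximum(w_cheek, np.exp(-d2 / growth.cheek_sigma**2))
    return {"lower_face": w_lower, "nasal": w_nasal, "cheek": w_cheek}


def apply_growth(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    growth: GrowthParams,
    face_params: FaceParams = FaceParams(),
    landmark_indices: dict | None = None,
    subject_id: str = "subject",
) -> SyntheticSubject:
    """Produce the T0/T1 pair with recorded ground truth.

    T1 = misalignment ∘ (T0_clean + displacement field + noise along
    normals); T0 receives independent noise of the same σ. The recorded
    ``true_displacement_field`` is the noise-free deformation in the stable
    (T0) frame.
    """
    if landmark_indices is None:
        landmark_indices = {
            name: int(np.argmin(np.linalg.norm(mesh.vertices - landmarks[name], axis=1)))
            for name in landmarks.names()
        }
    frame = face_frame(landmarks)
    p = frame.apply(mesh.vertices)
    lm_frame = {n: frame.apply(landmarks[n]) for n in landmarks.names()}
    weights = growth_weights(p, growth, lm_frame)

    anterior = frame.rotation[2]  # world-space unit vector of face-frame +z
    normals = mesh.vertex_normals
    disp = (
        growth.global_forward_drift
        + growth.lower_face_protrusion * weights["lower_face"]
        + growth.nasal_growth * weights["nasal"]
    )[:, None] * anterior
    disp = disp + growth.adiposity_change * weights["cheek"][:, None] * normals

    rng = np.random.default_rng(growth.seed)
    noise0 = _noise_field(mesh.vertices, rng, growth.noise_sigma, growth.noise_correlation)
    noise1 = _noise_field(mesh.vertices, rng, growth.noise_sigma, growth.noise_correlation)

    t0_vertices = mesh.vertices + noise0[:, None] * normals
    t1_stable = mesh.vertices + disp + noise1[:, None] * normals
    t1_vertices = growth.misalignment.apply(t1_stable)

    t0_mesh = SurfaceMesh(t0_vertices, mesh.faces, mesh_id=f"{subject_id}-t0")
    t1_mesh = SurfaceMesh(t1_vertices, mesh.faces, mesh_id=f"{subject_id}-t1")
    idx = np.array([landmark_indices[n] for n in landmarks.names()])
    names = landmarks.names()
    landmarks_t0 = LandmarkSet({n: t0_vertices[i] for n, i in zip(names, idx)})
    landmarks_t1 = LandmarkSet({n: t1_vertices[i] for n, i in zip(names, idx)})
    return SyntheticSubject(
        subject_id=subject_id,
        t0_mesh=t0_mesh,
        t1_mesh=t1_mesh,
        landmarks_t0=landmarks_t0,
        landmarks_t1=landmarks_t1,
        true_transform=growth.misalignment.inverse(),
        true_displacement_field=disp,
        face_params=face_params,
        growth_params=growth,
    )


def random_misalignment(rng: np.random.Generator, max_angle_deg=5.0, max_translation=5.0):
    """Arbitrary moderate pose difference between the two acquisitions."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(1.0, max_angle_deg)
    translation = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform.from_axis_angle(axis, angle, translation)


#: named study scenarios: parameter ranges for the cohort draws
SCENARIOS = {
    # growth confined to the middle/lower face, outside every area4 primitive
    "stable": dict(
        lower_face_protrusion=(1.0, 3.0),
        global_forward_drift=(0.0, 0.0),
        nasal_growth=(0.0, 0.0),
        adiposity_change=(0.0, 0.0),
    ),
    # adds a whole-face anterior drift (and cheek adiposity change): growth
    # contaminates every surface reference area
    "contaminated": dict(
        lower_face_protrusion=(1.0, 3.0),
        global_forward_drift=(0.3, 0.8),
        nasal_growth=(0.0, 0.0),
        adiposity_change=(-0.5, 0.5),
    ),
    # nasal growth with no forehead anchor changes: exposes the rotation
    # artifact of the small, forehead-less reference area
    "rotation": dict(
        lower_face_protrusion=(1.0, 3.0),
        global_forward_drift=(0.0, 0.0),
        nasal_growth=(1.0, 2.0),
        adiposity_change=(0.0, 0.0),
    ),
}


def generate_cohort(
    n_subjects: int,
    scenario: str = "stable",
    seed: int = 0,
    resolution: int = 3000,
    noise_sigma: float = 0.05,
):
    """Simulate a cohort of longitudinal subjects.

    Per-subject seeds derive from the master seed; the returned manifest
    records every parameter draw.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    ranges = SCENARIOS[scenario]
    master = np.random.SeedSequence(seed)
    subjects = []
    rows = []
    for k, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        fp = FaceParams(
            nose_amplitude=rng.uniform(10.0, 14.0),
            bridge_amplitude=rng.uniform(4.0, 6.0),
            brow_amplitude=rng.uniform(2.0, 4.0),
            chin_amplitude=rng.uniform(4.5, 7.5),
            cheek_amplitude=rng.uniform(3.0, 5.0),
            resolution=resolution,
            seed=sub_seed,
        )
        gp = GrowthParams(
            lower_face_protrusion=rng.uniform(*ranges["lower_face_protrusion"]),
            global_forward_drift=rng.uniform(*ranges["global_forward_drift"]),
            nasal_growth=rng.uniform(*ranges["nasal_growth"]),
            adiposity_change=rng.uniform(*ranges["adiposity_change"]),
            noise_sigma=noise_sigma,
            misalignment=random_misalignment(rng),
            seed=sub_seed,
        )
        mesh, lms, lm_idx = generate_face(fp)
        subject = apply_growth(
            mesh, lms, gp, face_params=fp, landmark_indices=lm_idx,
            subject_id=f"S{k + 1:02d}",
        )
        subjects.append(subject)
        rows.append(
            {
                "subject": subject.subject_id,
                "seed": sub_seed,
                "scenario": scenario,
                "n_vertices": mesh.n_vertices,
                "lower_face_protrusion_mm": gp.lower_face_protrusion,
                "global_forward_drift_mm": gp.global_forward_drift,
                "nasal_growth_mm": gp.nasal_growth,
                "adiposity_change_mm": gp.adiposity_change,
                "noise_sigma_mm": gp.noise_sigma,
                "misalignment_angle_deg": gp.misalignment.rotation_angle_deg(),
                "misalignment_translation_mm": float(
                    np.linalg.norm(gp.misalignment.translation)
                ),
            }
        )
    return subjects, pd.DataFrame(rows)


def save_subject(subject: SyntheticSubject, outdir) -> None:
    """Write one subject as STL meshes + landmark CSVs + ground-truth files."""
    out = Path(outdir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    write_mesh(subject.t0_mesh, out / "t0.stl")
    write_mesh(subject.t1_mesh, out / "t1.stl")
    write_landmarks(subject.landmarks_t0, out / "landmarks_t0.csv")
    write_landmarks(subject.landmarks_t1, out / "landmarks_t1.csv")
    subject.true_transform.save(out / "true_transform.txt", comment="T1 -> T0 stable frame")
    meta = {
        "subject_id": subject.subject_id,
        "face_params": asdict(subject.face_params),
        "growth_params": {
            k: v
            for k, v in asdict(subject.growth_params).items()
            if not isinstance(v, dict)
        },
    }
    meta["growth_params"]["misalignment"] = subject.growth_params.misalignment.matrix().tolist()
    (out / "params.json").write_text(json.dumps(meta, indent=2, default=float))
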