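"""Surface meshes, landmark tables, and the face-aligned coordinate frame.

All coordinates are millimetres. STL files carry no unit information; this
package assumes mm throughout, which is what CBCT- and
stereophotogrammetry-derived facial surfaces conventionally use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .transforms import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "REQUIRED_LANDMARKS",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "face_frame",
    "crop_to_face",
    "CROP_BOUNDS",
]

#: merge tolerance for duplicate vertices (STL stores per-facet vertices)
MERGE_TOL = 1e-6

#: soft-tissue landmark names every LandmarkSet must provide
REQUIRED_LANDMARKS = (
    "glabella",
    "soft_nasion",
    "pronasale",
    "subnasale",
    "orbitale_R",
    "orbitale_L",
    "exocanthion_R",
    "exocanthion_L",
    "cheilion_R",
    "cheilion_L",
    "soft_A_point",
    "soft_pogonion",
    "zygion_R",
    "zygion_L",
    "gonion_R",
    "gonion_L",
)

#: face-frame crop box, mm: (xmin, xmax, ymin, ymax, zmin). Wide enough to
#: keep forehead-to-chin, ear-to-ear coverage; anything deeper than 20 mm
#: behind the nasion plane (ears, neck, scan border) is discarded.
CROP_BOUNDS = (-75.0, 75.0, -90.0, 45.0, -20.0)


class MeshFormatError(ValueError):
    """Raised when a mesh or landmark file cannot be parsed."""


class SurfaceMesh:
    """Triangulated facial surface in mm.

    Vertices are merged (tolerance 1e-6 mm) so shared edges are
    topologically connected; vertex normals are area-weighted averages of
    incident face normals; boundary vertices are those incident to an edge
    used by fewer than two faces.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, mesh_id: str = ""):
        vertices = np.ascontiguousarray(vertices, dtype=float)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.isfinite(vertices).all():
            raise ValueError("mesh contains non-finite coordinates")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face index out of range")
        degenerate = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 2] == faces[:, 0])
        )
        if degenerate.any():
            logger.info("dropping %d degenerate faces", int(degenerate.sum()))
            faces = faces[~degenerate]
        self.vertices = vertices
        self.faces = faces
        self.mesh_id = mesh_id
        self._cache: dict = {}

    # -- derived geometry (cached; invalidated by with_vertices etc.) --

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _cached(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def face_normals(self) -> np.ndarray:
        def compute():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            norms = np.linalg.norm(n, axis=1)
            norms[norms == 0] = 1.0
            return n / norms[:, None]

        return self._cached("face_normals", compute)

    @property
    def face_areas(self) -> np.ndarray:
        def compute():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            return 0.5 * np.linalg.norm(n, axis=1)

        return self._cached("face_areas", compute)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""

        def compute():
            v = self.vertices
            f = self.faces
            fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            vn = np.zeros_like(v)
            for k in range(3):
                np.add.at(vn, f[:, k], fn)
            norms = np.linalg.norm(vn, axis=1)
            norms[norms == 0] = 1.0
            return vn / norms[:, None]

        return self._cached("vertex_normals", compute)

    @property
    def edges_unique(self):
        """(sorted unique edges (e, 2), per-edge face count, face->edge map (m, 3))."""

        def compute():
            f = self.faces
            e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            uniq, inverse, counts = np.unique(
                e, axis=0, return_inverse=True, return_counts=True
            )
            face_edge = inverse.reshape(3, -1).T  # column k = edge (k, k+1)
            return uniq, counts, face_edge

        return self._cached("edges_unique", compute)

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted indices of vertices on an open (border) edge."""

        def compute():
            uniq, counts, _ = self.edges_unique
            border = uniq[counts < 2]
            return np.unique(border)

        return self._cached("boundary_vertices", compute)

    @property
    def is_boundary_vertex(self) -> np.ndarray:
        def compute():
            flags = np.zeros(self.n_vertices, dtype=bool)
            flags[self.boundary_vertices] = True
            return flags

        return self._cached("is_boundary_vertex", compute)

    # -- manipulation --------------------------------------------------

    def with_vertices(self, vertices: np.ndarray, mesh_id: str | None = None) -> "SurfaceMesh":
        """Same topology, new vertex positions (normals recomputed)."""
        return SurfaceMesh(vertices, self.faces, mesh_id=mesh_id or self.mesh_id)

    def transformed(self, transform: RigidTransform, mesh_id: str | None = None) -> "SurfaceMesh":
        return self.with_vertices(transform.apply(self.vertices), mesh_id=mesh_id)

    def submesh(self, keep_vertices: np.ndarray, mesh_id: str | None = None) -> "SurfaceMesh":
        """Keep the flagged vertices and every face whose vertices all survive."""
        keep = np.asarray(keep_vertices)
        if keep.dtype != bool:
            mask = np.zeros(self.n_vertices, dtype=bool)
            mask[keep] = True
            keep = mask
        new_index = -np.ones(self.n_vertices, dtype=np.int64)
        new_index[keep] = np.arange(int(keep.sum()))
        face_ok = keep[self.faces].all(axis=1)
        return SurfaceMesh(
            self.vertices[keep], new_index[self.faces[face_ok]], mesh_id=mesh_id or self.mesh_id
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class LandmarkSet:
    """Named facial soft-tissue landmarks (mm) on a given mesh."""

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            pts[name] = p
        missing = [n for n in REQUIRED_LANDMARKS if n not in pts]
        if missing:
            raise ValueError(f"missing required landmarks: {', '.join(missing)}")
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return list(self.points)

    def array(self, names=None) -> np.ndarray:
        names = names or list(self.points)
        return np.stack([self.points[n] for n in names])

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: transform.apply(p) for n, p in self.points.items()})

    def max_distance_to(self, mesh: SurfaceMesh) -> float:
        """Largest landmark-to-surface distance (mm) — should stay under 2 mm."""
        from .geometry import MeshQuery

        res = MeshQuery(mesh).closest(self.array())
        return float(res.distances.max())


# ----------------------------------------------------------------------
# File IO
# ----------------------------------------------------------------------


def _merge_duplicate_vertices(vertices, faces, tol=MERGE_TOL):
    """Merge duplicates within *tol*, preserving first-appearance order."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # appearance order of the unique vertices
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][faces]


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read an STL (binary or ASCII, auto-detected) or PLY surface.

    Duplicate vertices within 1e-6 mm are merged so the triangulation is
    topologically connected; degenerate faces are dropped with a logged count.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types on bad bytes
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: no triangulated surface found")
    vertices, faces = _merge_duplicate_vertices(
        np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)
    )
    name = path.rsplit("/", 1)[-1]
    return SurfaceMesh(vertices, faces, mesh_id=name)


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None, vertex_colors=None) -> None:
    """Write STL or PLY; per-vertex RGB colors are PLY-only."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    if vertex_colors is not None and fmt == "stl":
        raise ValueError("STL carries no vertex color channel; use PLY")
    tm = mesh.to_trimesh()
    if vertex_colors is not None:
        colors = np.asarray(vertex_colors)
        if colors.shape != (mesh.n_vertices, 3):
            raise ValueError("vertex_colors must be one RGB triple per vertex")
        tm.visual.vertex_colors = colors.astype(np.uint8)
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        tm.export(path, file_type="stl")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark table: one ``name, x, y, z`` row per landmark.

    Tab- or comma-separated; an optional header row is skipped. Missing
    required names and duplicates are errors.
    """
    points = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
            if lineno == 1 and len(parts) >= 4:
                try:
                    [float(x) for x in parts[1:4]]
                except ValueError:
                    continue  # header row
            if len(parts) < 4:
                raise MeshFormatError(f"{path}:{lineno}: expected 'name,x,y,z', got {line!r}")
            name = parts[0]
            try:
                xyz = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if name in points:
                raise MeshFormatError(f"{path}:{lineno}: duplicate landmark {name!r}")
            points[name] = xyz
    missing = [n for n in REQUIRED_LANDMARKS if n not in points]
    if missing:
        raise MeshFormatError(f"{path}: missing required landmarks: {', '.join(missing)}")
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("name,x,y,z\n")
        for name, p in landmarks.points.items():
            fh.write(f"{name},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}\n")


# ----------------------------------------------------------------------
# Face-aligned frame and cropping
# ----------------------------------------------------------------------


def face_frame(landmarks: LandmarkSet) -> RigidTransform:
    """World -> face-frame transform.

    Origin at soft nasion; +x from left toward right exocanthion (subject's
    right), +y from soft pogonion toward glabella (up), +z anterior,
    orthonormalized Gram–Schmidt in the order x then y (right-handed).
    """
    origin = landmarks["soft_nasion"]
    x = landmarks["exocanthion_R"] - landmarks["exocanthion_L"]
    x = x / np.linalg.norm(x)
    y = landmarks["glabella"] - landmarks["soft_pogonion"]
    y = y - (y @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    rot = np.stack([x, y, z])  # rows: frame axes => R @ p gives frame coords
    return RigidTransform(rotation=rot, translation=-rot @ origin)


def crop_to_face(
    mesh: SurfaceMesh, landmarks: LandmarkSet, bounds=CROP_BOUNDS
) -> SurfaceMesh:
    """Crop to the facial region of interest (forehead to below the chin,
    ear to ear, front of the head) in the face-aligned frame. Idempotent."""
    xmin, xmax, ymin, ymax, zmin = bounds
    p = face_frame(landmarks).apply(mesh.vertices)
    keep = (
        (p[:, 0] >= xmin)
        & (p[:, 0] <= xmax)
        & (p[:, 1] >= ymin)
        & (p[:, 1] <= ymax)
        & (p[:, 2] >= zmin)
    )
    if keep.sum() < 0.05 * mesh.n_vertices:
        raise ValueError(
            "crop removed more than 95% of vertices; landmarks are "
            "inconsistent with the mesh"
        )
    if keep.all():
        return mesh
    return mesh.submesh(keep, mesh_id=mesh.mesh_id + "|cropped" if mesh.mesh_id else "cropped")
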