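"""Signed distance maps, per-patch MAD, and method-comparison summaries.

Distances are exact point-to-surface closest distances evaluated at the
reference mesh's vertices. The sign convention: positive where the
comparison surface lies along the reference vertex's outward normal, so
anterior movement of a growing face (measured from T0) reads positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MeshQuery
from .mesh_io import SurfaceMesh
from .regions import RegionMask

__all__ = [
    "DistanceMap",
    "MadReport",
    "signed_distance_map",
    "patch_mad",
    "mad_report",
    "t1_method_difference",
    "reference_congruence",
    "reproducibility_difference",
    "export_colormap",
]


@dataclass
class DistanceMap:
    """Per-vertex signed distances (mm) from a reference mesh to a surface."""

    reference_mesh_id: str
    values: np.ndarray  # (n,) signed distances, mm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    def __len__(self):
        return len(self.values)


@dataclass
class MadReport:
    """Mean absolute distance per measurement patch, mm."""

    per_patch: dict = field(default_factory=dict)  # label -> MAD, mm
    patch_sizes: dict = field(default_factory=dict)  # label -> vertex count used
    overall: float = float("nan")  # pooled mean |distance| over all patch vertices

    def labels(self):
        return list(self.per_patch)

    def values(self, labels=None) -> np.ndarray:
        labels = labels or self.labels()
        return np.array([self.per_patch[p] for p in labels])

    def to_frame(self, subject: str = "", method: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": subject,
                "method": method,
                "patch": list(self.per_patch),
                "mad_mm": list(self.per_patch.values()),
                "n_vertices": [self.patch_sizes[p] for p in self.per_patch],
            }
        )


def signed_distance_map(reference: SurfaceMesh, comparison: SurfaceMesh) -> DistanceMap:
    """Signed exact closest distance from every reference vertex to *comparison*.

    Sign = sign of the dot product between (closest point − vertex) and the
    reference vertex's outward normal; exact-zero distances are signed 0.
    """
    if comparison.n_faces == 0:
        raise ValueError("comparison mesh is empty")
    hits = MeshQuery(comparison).closest(reference.vertices)
    offset = hits.points - reference.vertices
    dots = np.einsum("ij,ij->i", offset, reference.vertex_normals)
    signed = hits.distances * np.sign(dots)
    signed[hits.distances == 0.0] = 0.0
    return DistanceMap(reference_mesh_id=reference.mesh_id, values=signed)


def patch_mad(dist_map: DistanceMap, patch: RegionMask) -> float:
    """Arithmetic mean of |signed distance| over the patch's vertices."""
    if len(patch) == 0:
        raise ValueError("empty measurement patch")
    idx = patch.vertex_indices
    if idx.max() >= len(dist_map):
        raise ValueError(
            f"patch {patch.label!r} does not fit distance map of "
            f"{dist_map.reference_mesh_id!r}"
        )
    return float(np.mean(np.abs(dist_map.values[idx])))


def mad_report(dist_map: DistanceMap, patches) -> MadReport:
    """MAD for each of the measurement patches plus the pooled value."""
    report = MadReport()
    pooled = []
    for patch in patches:
        report.per_patch[patch.label] = patch_mad(dist_map, patch)
        report.patch_sizes[patch.label] = len(patch)
        pooled.append(np.abs(dist_map.values[patch.vertex_indices]))
    report.overall = float(np.mean(np.concatenate(pooled)))
    return report


def t1_method_difference(
    t1_gold: SurfaceMesh, t1_method: SurfaceMesh, patches
) -> tuple[MadReport, DistanceMap]:
    """Difference between two placements of the *same* T1 model.

    ``t1_gold`` (the gold-standard placement) is the reference; patches must
    refer to it. Per-patch MADs between the placements summarise how far
    each surface-based superimposition strays from the gold standard.
    """
    if t1_gold.n_vertices != t1_method.n_vertices:
        raise ValueError(
            "gold and method placements must be the same T1 model "
            f"({t1_gold.n_vertices} vs {t1_method.n_vertices} vertices)"
        )
    dist_map = signed_distance_map(t1_gold, t1_method)
    return mad_report(dist_map, patches), dist_map


def reference_congruence(
    t0: SurfaceMesh, t1_superimposed: SurfaceMesh, reference_mask: RegionMask
) -> float:
    """T0–T1 MAD restricted to the superimposition reference area itself.

    The mask refers to the (superimposed) T1 model, on which reference
    areas are selected; distances run from its masked vertices to the T0
    surface.
    """
    reference_mask.validate_on(t1_superimposed)
    pts = t1_superimposed.vertices[reference_mask.vertex_indices]
    hits = MeshQuery(t0).closest(pts)
    return float(np.mean(hits.distances))


def reproducibility_difference(mad_run1: MadReport, mad_run2: MadReport) -> dict:
    """Signed per-patch differences run1 − run2 (mm), sign preserved."""
    if set(mad_run1.per_patch) != set(mad_run2.per_patch):
        raise ValueError(
            "mismatched patch labels: "
            f"{sorted(mad_run1.per_patch)} vs {sorted(mad_run2.per_patch)}"
        )
    return {
        label: mad_run1.per_patch[label] - mad_run2.per_patch[label]
        for label in mad_run1.per_patch
    }


def export_colormap(
    dist_map: DistanceMap,
    mesh: SurfaceMesh,
    path,
    scale: tuple = (-2.0, 2.0),
) -> None:
    """Write the reference mesh as an ASCII PLY colored by signed distance.

    A symmetric diverging ramp (blue = negative/posterior, red =
    positive/anterior), hard-clamped at the scale limits; the scale is
    recorded in a PLY header comment.
    """
    lo, hi = float(scale[0]), float(scale[1])
    if lo >= hi:
        raise ValueError(f"invalid colormap scale ({lo}, {hi})")
    if len(dist_map) != mesh.n_vertices:
        raise ValueError("distance map does not match mesh vertex count")
    from matplotlib import colormaps

    normalized = np.clip((dist_map.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = colormaps["RdBu_r"](normalized)
    colors = (rgba[:, :3] * 255).round().astype(np.uint8)
    _write_ply_with_comment(
        mesh, colors, path, f"signed distance colormap, scale_mm {lo} {hi}"
    )


def _write_ply_with_comment(mesh: SurfaceMesh, colors, path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {comment}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, c in zip(mesh.vertices, colors):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {c[0]} {c[1]} {c[2]}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
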