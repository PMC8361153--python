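"""Region-constrained rigid point-to-plane ICP superimposition.

T0 is the fixed reference; the moving T1 model is relocated so that its
masked reference-area vertices best fit the T0 surface. The registration
uses the classical point-to-plane objective

    E(R, t) = Σ_i [ n_i · (R s_i + t − c_i) ]²

where s_i are masked source vertices, c_i their exact closest points on
the target surface and n_i the supporting-surface normals there. Each
iteration solves the small-angle linearisation in closed form (6×6 normal
equations) and projects the update back onto SO(3), so the pose stays
exactly rigid.

Settings mirror common surface-registration software for serial facial
scans: 100% overlap, 100% point sampling (no trimming), exact nearest
neighbours, overhang (mesh-border) exclusion, up to 50 inner iterations.
The whole inner loop is re-run from the converged pose ("usually 4–5
times") until the mean absolute correspondence distance stops improving.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import MeshQuery
from .mesh_io import SurfaceMesh
from .regions import RegionMask
from .transforms import RigidTransform, nearest_rotation

logger = logging.getLogger(__name__)

__all__ = [
    "ICPSettings",
    "SuperimpositionResult",
    "Correspondences",
    "correspondences",
    "solve_point_to_plane_step",
    "run_icp",
    "DegenerateGeometryWarning",
]


class DegenerateGeometryWarning(UserWarning):
    """Normal distribution too poor to constrain all six rigid parameters."""


@dataclass(frozen=True)
class ICPSettings:
    """Registration settings (defaults = the serial-face protocol)."""

    overlap_fraction: float = 1.0
    sampling_fraction: float = 1.0
    metric: str = "point_to_plane"
    exact_nn: bool = True
    exclude_overhangs: bool = True
    max_iterations: int = 50
    inner_tolerance: float = 1e-6  # mm, residual improvement
    outer_max_runs: int = 10
    outer_tolerance: float = 1e-4  # mm, mean |distance| improvement

    def __post_init__(self):
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.max_iterations < 1 or self.outer_max_runs < 1:
            raise ValueError("iteration counts must be >= 1")

    def fingerprint(self) -> str:
        return (
            f"metric={self.metric} overlap={self.overlap_fraction} "
            f"sampling={self.sampling_fraction} exclude_overhangs={self.exclude_overhangs} "
            f"max_iter={self.max_iterations} inner_tol={self.inner_tolerance} "
            f"outer_runs={self.outer_max_runs} outer_tol={self.outer_tolerance}"
        )


@dataclass
class Correspondences:
    """Masked source points paired with exact target surface hits."""

    source: np.ndarray  # (n, 3)
    closest: np.ndarray  # (n, 3)
    normals: np.ndarray  # (n, 3)

    def __len__(self):
        return len(self.source)

    @property
    def plane_residuals(self) -> np.ndarray:
        return np.einsum("ij,ij->i", self.normals, self.source - self.closest)

    @property
    def point_distances(self) -> np.ndarray:
        return np.linalg.norm(self.source - self.closest, axis=1)


@dataclass
class SuperimpositionResult:
    """Composite T1→T0 transform plus the residual trace of the outer runs."""

    transform: RigidTransform
    runs_used: int
    per_run_residual: list = field(default_factory=list)  # mean |point-to-plane|, mm
    per_run_distance: list = field(default_factory=list)  # mean |point-to-point|, mm
    converged: bool = False


def correspondences(
    source_points: np.ndarray,
    target: SurfaceMesh | MeshQuery,
    exclude_overhangs: bool = True,
) -> Correspondences:
    """Exact closest target-surface point (and its normal) per source point.

    With overhang exclusion, hits landing on a border edge or border vertex
    of the open target surface are discarded: such correspondences do not
    constrain the fit and drag the solution toward the mesh rim.
    """
    query = target if isinstance(target, MeshQuery) else MeshQuery(target)
    pts = np.atleast_2d(np.asarray(source_points, dtype=float))
    hits = query.closest(pts)
    keep = ~hits.on_boundary if exclude_overhangs else np.ones(len(pts), dtype=bool)
    if not keep.any():
        raise ValueError("no overlap under overhang exclusion")
    return Correspondences(
        source=pts[keep], closest=hits.points[keep], normals=hits.normals[keep]
    )


def solve_point_to_plane_step(corr: Correspondences) -> RigidTransform:
    """One closed-form point-to-plane update.

    Solves the linearised 6×6 system for (ω, t) and projects I + [ω]× onto
    the nearest rotation. If the normal distribution leaves the system
    rank-deficient (e.g. every correspondence on one plane, which allows
    in-plane sliding), the minimum-norm solution is taken — unconstrained
    components, such as in-plane translation, come out exactly zero — and a
    :class:`DegenerateGeometryWarning` is emitted.
    """
    if len(corr) < 6:
        raise ValueError(f"need at least 6 correspondences, got {len(corr)}")
    s, n = corr.source, corr.normals
    a = np.hstack([np.cross(s, n), n])  # rows: [ (s × n)ᵀ, nᵀ ]
    b = -corr.plane_residuals
    u, sv, vt = np.linalg.svd(a, full_matrices=False)
    rank = int((sv > 1e-9 * sv[0]).sum())
    if rank < 6:
        warnings.warn(
            "point-to-plane system is rank-deficient "
            f"(rank {rank}); unconstrained motion components set to zero",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        inv = np.where(sv > 1e-9 * sv[0], 1.0 / np.where(sv > 0, sv, 1.0), 0.0)
    x = vt.T @ (inv * (u.T @ b))
    omega, t = x[:3], x[3:]
    skew = np.array(
        [
            [0.0, -omega[2], omega[1]],
            [omega[2], 0.0, -omega[0]],
            [-omega[1], omega[0], 0.0],
        ]
    )
    return RigidTransform(rotation=nearest_rotation(np.eye(3) + skew), translation=t)


def run_icp(
    source: SurfaceMesh,
    source_mask: RegionMask,
    target: SurfaceMesh,
    settings: ICPSettings = ICPSettings(),
    initial: RigidTransform | None = None,
) -> SuperimpositionResult:
    """Superimpose the moving *source* (T1) onto the fixed *target* (T0).

    Inner loop: up to ``max_iterations`` of correspond → solve → apply,
    stopping early once the mean absolute point-to-plane residual stops
    improving by ``inner_tolerance`` (an iteration that would increase it
    is rolled back). Outer loop: the inner loop is restarted from the
    current pose until the mean absolute correspondence distance improves
    by less than ``outer_tolerance``, capped at ``outer_max_runs``.
    """
    source_mask.validate_on(source)
    masked = source.vertices[source_mask.vertex_indices]
    query = MeshQuery(target)
    pose = initial if initial is not None else RigidTransform.identity()

    result = SuperimpositionResult(transform=pose, runs_used=0)
    prev_run_distance = np.inf
    for run in range(settings.outer_max_runs):
        pose, run_residual, run_distance = _inner_loop(masked, query, pose, settings)
        result.runs_used = run + 1
        result.per_run_residual.append(run_residual)
        result.per_run_distance.append(run_distance)
        logger.info(
            "ICP run %d: mean |plane residual| %.6g mm, mean distance %.6g mm",
            run + 1,
            run_residual,
            run_distance,
        )
        if not np.isfinite(run_residual):
            raise ArithmeticError(
                f"non-finite ICP residual in run {run + 1}; "
                f"pose so far: {pose.matrix()!r}"
            )
        if prev_run_distance - run_distance < settings.outer_tolerance:
            result.converged = True
            break
        prev_run_distance = run_distance
    result.transform = pose
    return result


def _inner_loop(masked, query, pose, settings):
    corr = correspondences(pose.apply(masked), query, settings.exclude_overhangs)
    residual = float(np.mean(np.abs(corr.plane_residuals)))
    for _ in range(settings.max_iterations):
        step = solve_point_to_plane_step(corr)
        candidate = step.compose(pose)
        cand_corr = correspondences(
            candidate.apply(masked), query, settings.exclude_overhangs
        )
        cand_residual = float(np.mean(np.abs(cand_corr.plane_residuals)))
        if cand_residual > residual + 1e-9:
            break  # linearised step overshot: keep the previous pose
        improvement = residual - cand_residual
        pose, corr, residual = candidate, cand_corr, cand_residual
        if improvement < settings.inner_tolerance:
            break
    return pose, residual, float(np.mean(corr.point_distances))
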