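"""Rigid (rotation + translation) transforms in millimetre space.

Both time points of a subject are calibrated scans of the same person, so
every relocation in this package is strictly rigid: no scale, no shear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "nearest_rotation", "kabsch"]

_ORTHO_TOL = 1e-9


def nearest_rotation(matrix: np.ndarray) -> np.ndarray:
    """Project a near-rotation 3x3 matrix onto SO(3) (polar decomposition)."""
    u, _, vt = np.linalg.svd(np.asarray(matrix, dtype=float))
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R p + t``.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Orthonormal with determinant +1.
    translation : (3,) ndarray
        Offset in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(r).all() and np.isfinite(t).all()):
            raise ValueError("non-finite rigid transform")
        r = nearest_rotation(r)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rotation is not orthonormal with det +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        translation: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
        return cls(rotation=rot.as_matrix(), translation=np.asarray(translation, float))

    # -- algebra ------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    # -- diagnostics ---------------------------------------------------

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation component, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def max_displacement(self, points: np.ndarray) -> float:
        """Largest vertex displacement this transform induces on *points*."""
        p = np.asarray(points, dtype=float)
        return float(np.max(np.linalg.norm(self.apply(p) - p, axis=1), initial=0.0))

    def mean_displacement(self, points: np.ndarray) -> float:
        """Mean vertex displacement this transform induces on *points*."""
        p = np.asarray(points, dtype=float)
        return float(np.mean(np.linalg.norm(self.apply(p) - p, axis=1)))

    # -- persistence (row-major 4x4 plain text) ------------------------

    def save(self, path, comment: str = "") -> None:
        header = "rigid transform, homogeneous 4x4, row-major, mm"
        if comment:
            header += "\n" + comment
        np.savetxt(path, self.matrix(), fmt="%.17g", header=header)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of paired points (no scaling).

    Returns the transform T minimising ``Σ ||T(source_i) − target_i||²``.
    Used to pre-align T1 onto T0 from shared landmark names before ICP.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 3:
        raise ValueError("kabsch needs matching (n>=3, 3) point arrays")
    sc = s - s.mean(axis=0)
    tc = t - t.mean(axis=0)
    r = nearest_rotation(tc.T @ sc)
    return RigidTransform(rotation=r, translation=t.mean(axis=0) - r @ s.mean(axis=0))
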