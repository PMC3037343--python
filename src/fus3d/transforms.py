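"""Rigid 3D transforms used for probe poses and inter-view registration.

Points map as ``x' = R @ x + t`` with ``R`` a proper rotation
(``det R = +1``).  Composition is written ``A.compose(B)`` and means
"apply B first, then A", i.e. ``(A∘B)(x) = A(B(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det < 0): not a rigid transform")
        # canonicalize to remove round-off drift from repeated composition
        R = Rotation.from_matrix(R).as_matrix()
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0), seq: str = "zyx") -> "RigidTransform":
        R = Rotation.from_euler(seq, angles_deg, degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(Rotation.from_rotvec(rotvec).as_matrix(), np.asarray(translation, float))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_quat_wxyz(cls, quat, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        w, x, y, z = quat
        R = Rotation.from_quat([x, y, z, w]).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def rotation_about_point(cls, rotation: np.ndarray, pivot) -> "RigidTransform":
        """Rotation about an arbitrary pivot point (in mm)."""
        pivot = np.asarray(pivot, dtype=float)
        return cls(rotation, pivot - rotation @ pivot)

    # -- accessors -------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def quat_wxyz(self) -> np.ndarray:
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        return np.array([w, x, y, z])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    # -- algebra ---------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """(self ∘ other): apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __eq__(self, other) -> bool:  # exact, used for identity checks in configs
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return np.array_equal(self.rotation, other.rotation) and np.array_equal(
            self.translation, other.translation)

    def is_close(self, other: "RigidTransform", rot_tol_deg: float = 1e-6, trans_tol: float = 1e-6) -> bool:
        delta = self.compose(other.inverse())
        return delta.rotation_angle_deg() <= rot_tol_deg and np.linalg.norm(delta.translation) <= trans_tol
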