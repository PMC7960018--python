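"""Rigid-body transforms for slice and volume geometry.

A rigid transform is parameterized by three Euler angles (radians) and a
3-vector translation (mm), and realized as a 4x4 homogeneous matrix acting on
homogeneous column vectors ``[x, y, z, 1]^T``.

Convention: intrinsic Z-Y-X Euler angles, ``R = Rz(a) @ Ry(b) @ Rx(c)`` with
``rotation = (a, b, c)``.  Any fixed convention would do; this one is used
consistently throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform"]


def _rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid body map: 3 Euler angles (rad) and a translation (mm)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        rot = tuple(float(v) for v in self.rotation)
        tra = tuple(float(v) for v in self.translation)
        if len(rot) != 3 or len(tra) != 3:
            raise ValueError("rotation and translation must each have 3 components")
        if not all(np.isfinite(rot)) or not all(np.isfinite(tra)):
            raise ValueError("rigid transform parameters must be finite")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (rotation block orthonormal, det +1)."""
        a, b, c = self.rotation
        m = np.eye(4)
        m[:3, :3] = _rot_z(a) @ _rot_y(b) @ _rot_x(c)
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_parameters(cls, params: np.ndarray) -> "RigidTransform":
        """Build from a flat 6-vector ``[a, b, c, tx, ty, tz]``."""
        p = np.asarray(params, dtype=float)
        if p.shape != (6,):
            raise ValueError("expected 6 rigid parameters")
        return cls(rotation=tuple(p[:3]), translation=tuple(p[3:]))

    @property
    def parameters(self) -> np.ndarray:
        """Flat 6-vector ``[a, b, c, tx, ty, tz]``."""
        return np.array([*self.rotation, *self.translation])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, *, tol: float = 1e-6) -> "RigidTransform":
        """Recover Euler angles and translation from a 4x4 rigid matrix.

        Inverts the intrinsic Z-Y-X composition.  For the middle angle at
        +-pi/2 the decomposition is gimbal-degenerate; the returned angles
        still reproduce the matrix.
        """
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("matrix rotation block is not a proper rotation")
        # R = Rz(a) Ry(b) Rx(c):  r[2,0] = -sin b
        b = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
        if abs(np.cos(b)) > tol:
            a = np.arctan2(r[1, 0], r[0, 0])
            c = np.arctan2(r[2, 1], r[2, 2])
        else:  # gimbal lock: fold c into a
            a = np.arctan2(-r[0, 1], r[1, 1])
            c = 0.0
        return cls(rotation=(a, b, c), translation=tuple(m[:3, 3]))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self applied after ``other`` (matrix product self @ other)."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        m = self.matrix
        inv = np.eye(4)
        inv[:3, :3] = m[:3, :3].T
        inv[:3, 3] = -m[:3, :3].T @ m[:3, 3]
        return RigidTransform.from_matrix(inv)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points (mm)."""
        p = np.asarray(points, dtype=float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
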