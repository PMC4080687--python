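"""Rigid transforms (rotation + translation) between scanner and laboratory frames.

A :class:`RigidTransform` maps points from a source frame (a tilted scan) to
the target/laboratory frame: ``y = R @ x + t`` with world coordinates ordered
``(z, y, x)`` in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "rotation_about_axis"]

_AXES = {"z": 0, "y": 1, "x": 2}


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about a coordinate axis ('z'|'y'|'x' or index).

    Acts on (z, y, x)-ordered vectors.  A rotation about z by +theta maps
    (y, x) -> (y cos - x sin, y sin + x cos).
    """
    if isinstance(axis, str):
        axis = _AXES[axis.lower()]
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    others = [i for i in range(3) if i != axis]
    R = np.eye(3)
    R[others[0], others[0]] = c
    R[others[0], others[1]] = -s
    R[others[1], others[0]] = s
    R[others[1], others[1]] = c
    return R


@dataclass
class RigidTransform:
    """y = rotation @ x + translation, coordinates (z, y, x) in cm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.validate()

    def validate(self):
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1 (no reflections)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_axis(cls, axis, angle_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(rotation_about_axis(axis, angle_deg), np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points, shape (..., 3) or (3, N)."""
        pts = np.asarray(points, dtype=np.float64)
        if pts.shape[0] == 3 and pts.ndim == 2:
            return self.rotation @ pts + self.translation[:, None]
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply `other`, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    # -- plain-text persistence (one transform per scan) --------------------

    def to_text(self) -> str:
        rows = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in self.rotation)
        t = " ".join(f"{v:.17g}" for v in self.translation)
        return f"# rigid transform: rotation rows (z,y,x), then translation (cm)\n{rows}\n{t}\n"

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform":
        rows = [
            [float(v) for v in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        if len(rows) != 4:
            raise ValueError("transform file must have 3 rotation rows + 1 translation row")
        return cls(np.array(rows[:3]), np.array(rows[3]))

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_text(fh.read())
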