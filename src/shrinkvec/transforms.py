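"""Rigid-body transforms in world (micrometre) coordinates.

A :class:`RigidTransform` maps a point ``p`` (μm) to ``R (p - c) + c + t``
where ``R`` is a rotation given by intrinsic z-y-x Euler angles in degrees,
``c`` the rotation centre and ``t`` a translation, all in μm.  This is the
pose applied to the post-polymerization scene relative to the
pre-polymerization scan, and the transform recovered by rigid registration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p -> R (p - center) + center + translation``.

    Parameters
    ----------
    angles_zyx
        Intrinsic z-y-x Euler angles ``(rz, ry, rx)`` in degrees: the scene
        is rotated about z first, then the new y, then the new x axis.
    translation
        Translation ``(tx, ty, tz)`` in μm.
    center
        Rotation centre in μm.
    """

    angles_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("angles_zyx", "translation", "center"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be 3 finite numbers, got {v!r}")
            object.__setattr__(self, name, tuple(float(x) for x in v))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYX", self.angles_zyx, degrees=True)

    def matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(A, b)`` with the transform written as ``p -> A p + b``."""
        A = self.rotation.as_matrix()
        c = np.asarray(self.center)
        b = c + np.asarray(self.translation) - A @ c
        return A, b

    def apply(self, points: Iterable[float] | np.ndarray) -> np.ndarray:
        """Map one ``(3,)`` point or an ``(N, 3)`` array of points (μm)."""
        p = np.asarray(points, dtype=float)
        A, b = self.matrix_offset()
        return p @ A.T + b

    def is_identity(self, tol: float = 0.0) -> bool:
        A, b = self.matrix_offset()
        return bool(
            np.all(np.abs(A - np.eye(3)) <= tol) and np.all(np.abs(b) <= tol)
        )

    def to_dict(self) -> dict:
        return {
            "angles_zyx_deg": list(self.angles_zyx),
            "translation_um": list(self.translation),
            "center_um": list(self.center),
            "euler_convention": "intrinsic z-y-x",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            angles_zyx=tuple(d["angles_zyx_deg"]),
            translation=tuple(d["translation_um"]),
            center=tuple(d.get("center_um", (0.0, 0.0, 0.0))),
        )


def identity() -> RigidTransform:
    return RigidTransform()


def _from_matrix_offset(A: np.ndarray, b: np.ndarray) -> RigidTransform:
    angles = Rotation.from_matrix(A).as_euler("ZYX", degrees=True)
    return RigidTransform(
        angles_zyx=tuple(angles), translation=tuple(b), center=(0.0, 0.0, 0.0)
    )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` first, then ``a``: ``compose(a, b)(p) = a(b(p))``."""
    Aa, ba = a.matrix_offset()
    Ab, bb = b.matrix_offset()
    return _from_matrix_offset(Aa @ Ab, Aa @ bb + ba)


def invert(a: RigidTransform) -> RigidTransform:
    """Inverse transform: ``invert(a)(a(p)) == p``."""
    A, b = a.matrix_offset()
    return _from_matrix_offset(A.T, -A.T @ b)


def rotation_angle_between(a: RigidTransform, b: RigidTransform) -> float:
    """Geodesic angle (degrees) between the rotation parts of two transforms."""
    r = a.rotation * b.rotation.inv()
    return float(np.degrees(r.magnitude()))
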