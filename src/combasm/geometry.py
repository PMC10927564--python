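"""Rigid-body transforms and least-squares superposition.

A :class:`RigidTransform` is a proper rotation plus a translation acting on
column stacks of 3-D points, ``x -> R @ x + t``.  These are the currency of
the whole assembly engine: every placed subunit copy is its representative
structure under one accumulated transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "superpose", "rmsd", "random_rotation"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion of 3-D space (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-5:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("improper rotation (reflection) not allowed")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def _trusted(cls, rotation: np.ndarray, translation: np.ndarray):
        """Construct without validation (products of validated transforms)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "rotation", rotation)
        object.__setattr__(obj, "translation", translation)
        return obj

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform._trusted(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = np.ascontiguousarray(self.rotation.T)
        return RigidTransform._trusted(rt, -rt @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-6) -> bool:
        return (
            np.linalg.norm(self.rotation - other.rotation) <= tol
            and np.linalg.norm(self.translation - other.translation) <= tol
        )

    def to_json(self) -> dict:
        return {
            "rotation": [list(map(float, row)) for row in self.rotation],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RigidTransform":
        return cls(np.array(obj["rotation"]), np.array(obj["translation"]))


def superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares (Kabsch) superposition of *mobile* onto *target*.

    Returns the rigid transform ``T`` minimising ``||T(mobile) - target||``
    over all proper rotations and translations.  Both inputs are (N, 3)
    arrays with N >= 3 points in correspondence.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("superpose expects matching (N, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    mob_c = mob.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    h = (mob - mob_c).T @ (tgt - tgt_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, tgt_c - rot @ mob_c)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two (N, 3) point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly from SO(3) via unit quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
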