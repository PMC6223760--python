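"""Rigid-body geometry shared by every lapnav module.

Conventions
-----------
* Points and translations are millimetres, stored as length-3 float arrays.
* Rotations are stored as 3x3 proper orthonormal matrices; unit quaternions
  in scalar-first ``(w, x, y, z)`` order appear only at I/O boundaries,
  matching optical-tracker file formats.
* Anatomical frame convention used throughout: column 1 of a rotation is the
  patient longitudinal axis (cranial->caudal), column 3 the anterior "up"
  direction, column 2 the left-right axis completing a right-handed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateAxesError, EmptyInputError

__all__ = [
    "as_vector3",
    "RigidTransform",
    "Pose",
    "rotation_from_axes",
    "mean_rotation",
    "quaternion_to_matrix",
    "matrix_to_quaternion",
    "rotation_about_axis",
]

#: orthonormality drift beyond which matrices are re-orthonormalized
_ORTHO_DRIFT = 1e-12
#: orthonormality tolerance for invariant validation
_ORTHO_TOL = 1e-9


def as_vector3(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Coerce ``p`` to a finite float array of shape (3,)."""
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a length-3 vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("vector components must be finite")
    return v


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (Frobenius norm) via SVD."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    drift = np.abs(R.T @ R - np.eye(3)).max()
    if drift > _ORTHO_DRIFT:
        R = _orthonormalize(R)
        drift = np.abs(R.T @ R - np.eye(3)).max()
    if drift > tol or abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("matrix is not a proper rotation")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rotation plus translation; maps points of one frame into another.

    ``apply`` computes ``R @ p + t``.  Instances are immutable; composition
    and inversion return new transforms.  Orthonormality is validated on
    construction (tolerance 1e-9) and silently repaired by SVD projection
    when the drift is tiny (>1e-12) — e.g. after long composition chains.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(self, "translation", as_vector3(self.translation))

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major, mm)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a homogeneous matrix must be 0 0 0 1")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_quaternion(
        cls, q_wxyz: Sequence[float], translation: Sequence[float]
    ) -> "RigidTransform":
        return cls(quaternion_to_matrix(q_wxyz), translation)

    # -- representations --------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def as_quaternion(self) -> np.ndarray:
        """Unit quaternion, scalar-first ``(w, x, y, z)``."""
        return matrix_to_quaternion(self.rotation)

    # -- algebra ----------------------------------------------------------
    def apply(self, p: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map a point: ``R @ p + t``.  Also accepts an (n, 3) array."""
        p = np.asarray(p, dtype=float)
        if p.ndim == 2:
            return p @ self.rotation.T + self.translation
        return self.rotation @ as_vector3(p) + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``inner`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class Pose:
    """A timestamped rigid transform of a tracked tool.

    ``transform`` maps the tool's local frame into the tracking reference
    frame (the rigid body fixed to the operating table).
    """

    timestamp: float
    tool_id: str
    transform: RigidTransform


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Functional alias for :meth:`RigidTransform.compose`."""
    return outer.compose(inner)


def apply(transform: RigidTransform, p: Sequence[float]) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return transform.apply(p)


def rotation_from_axes(
    longitudinal: Sequence[float], up: Sequence[float]
) -> np.ndarray:
    """Right-handed frame from a longitudinal axis and an approximate up.

    Column 1 is the normalized longitudinal direction; column 3 is the
    component of ``up`` orthogonal to it (Gram-Schmidt), normalized;
    column 2 is the cross product completing a right-handed, proper
    rotation.

    Raises
    ------
    DegenerateAxesError
        If either vector is (near-)zero or the two are (anti)parallel.
    """
    lo = np.asarray(longitudinal, dtype=float)
    u = np.asarray(up, dtype=float)
    n_lo, n_u = np.linalg.norm(lo), np.linalg.norm(u)
    if n_lo < 1e-12 or n_u < 1e-12:
        raise DegenerateAxesError("axis vectors must have norm > 1e-12")
    c1 = lo / n_lo
    u_orth = u - (u @ c1) * c1
    # sin(angle between up and longitudinal); reject below ~1e-6 rad
    if np.linalg.norm(u_orth) / n_u < 1e-6:
        raise DegenerateAxesError("longitudinal and up axes are (anti)parallel")
    c3 = u_orth / np.linalg.norm(u_orth)
    c2 = np.cross(c3, c1)  # so that c1 x c2 = c3 (right-handed)
    return np.column_stack([c1, c2, c3])


def rotation_about_axis(axis: Sequence[float], angle_rad: float) -> np.ndarray:
    """Rotation matrix by ``angle_rad`` about ``axis`` (need not be unit)."""
    a = as_vector3(axis)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise DegenerateAxesError("rotation axis must be nonzero")
    return Rotation.from_rotvec(a / n * angle_rad).as_matrix()


def quaternion_to_matrix(q_wxyz: Sequence[float]) -> np.ndarray:
    """Rotation matrix from a scalar-first quaternion (normalized first)."""
    q = np.asarray(q_wxyz, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have 4 components, got {q.shape}")
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise ValueError("quaternion norm too small")
    return Rotation.from_quat(q / n, scalar_first=True).as_matrix()


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion from a rotation matrix (w >= 0)."""
    q = Rotation.from_matrix(np.asarray(R, dtype=float)).as_quat(scalar_first=True)
    return q if q[0] >= 0 else -q


def mean_rotation(samples: Iterable[Sequence[float]]) -> np.ndarray:
    """Chordal mean of unit quaternions (scalar-first).

    Signs are aligned to the first sample (q and -q encode the same
    rotation), components averaged, and the result normalized.  Adequate
    for tightly clustered samples such as repeated orientation
    acquisitions of a held tool; not a Karcher mean for widely spread
    inputs.

    Raises
    ------
    EmptyInputError
        If ``samples`` is empty.
    """
    qs = np.asarray([np.asarray(q, dtype=float) for q in samples])
    if qs.size == 0:
        raise EmptyInputError("mean_rotation needs at least one sample")
    if qs.ndim != 2 or qs.shape[1] != 4:
        raise ValueError("samples must be quaternions of 4 components")
    qs = qs / np.linalg.norm(qs, axis=1, keepdims=True)
    signs = np.where(qs @ qs[0] < 0.0, -1.0, 1.0)
    m = (qs * signs[:, None]).mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-12:
        raise ValueError("samples cancel; chordal mean undefined")
    m = m / n
    # canonical sign: first component of largest magnitude positive, so the
    # result is invariant to flipping the sign of any input sample
    k = int(np.argmax(np.abs(m)))
    return m if m[k] > 0 else -m
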