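"""Image-to-patient registration: single-landmark (SLRM) and fiducial (FLRM).

SLRM aligns a preoperative image volume to the tracked patient frame from a
single anatomical landmark plus the orientation of a tracked tool laid along
the patient's longitudinal axis, parallel to the coronal plane.  Later
re-registrations (e.g. at a lesion clicked in a tracked ultrasound image)
update only the translation offset, keeping the orientation fixed, so the
model matches exactly at the newly registered point.

FLRM is the classical least-squares rigid match of >=3 corresponding
fiducials (centroid subtraction + SVD of the cross-covariance, reflection
corrected), reporting the fiducial registration error (FRE) as the RMS
residual.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    InsufficientPointsError,
    MethodMismatchError,
)
from .geometry import (
    Pose,
    RigidTransform,
    as_vector3,
    mean_rotation,
    matrix_to_quaternion,
    quaternion_to_matrix,
    rotation_about_axis,
)

__all__ = [
    "LandmarkPair",
    "PatientOrientation",
    "RegistrationResult",
    "slrm_initialize",
    "slrm_reregister",
    "flrm_register",
    "fiducial_residuals",
]

#: singular-value ratio below which the fiducial set is treated as collinear
_COLLINEAR_TOL = 1e-6


@dataclass(frozen=True)
class LandmarkPair:
    """One landmark marked in both the image volume and the patient frame."""

    label: str
    p_image: np.ndarray
    p_patient: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_image", as_vector3(self.p_image))
        object.__setattr__(self, "p_patient", as_vector3(self.p_patient))


class PatientOrientation(str, enum.Enum):
    """Whether the patient lies supine or prone on the table.

    In the prone position the tracked tool is still held facing upwards
    (so its reflective markers stay visible); the registration compensates
    by flipping the acquired orientation 180 degrees about the longitudinal
    axis.
    """

    SUPINE = "supine"
    PRONE = "prone"


class Method(str, enum.Enum):
    SLRM = "SLRM"
    FLRM = "FLRM"


@dataclass(frozen=True)
class RegistrationResult:
    """Output of either registration method.

    ``fre`` (fiducial registration error, RMS residual over the fitting
    fiducials, mm) is reported for FLRM only; the single-landmark method
    has zero residual at its one point by construction.
    """

    transform: RigidTransform
    method: Method
    n_points: int
    fre: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fre is not None and self.fre < 0:
            raise ValueError("fre must be >= 0")


# 180 degree flip about the image longitudinal axis (x), used for prone
_PRONE_FLIP = rotation_about_axis([1.0, 0.0, 0.0], np.pi)


def _tool_rotation(tool_pose: Pose | Sequence[Pose], mode: str) -> np.ndarray:
    """Rotation from one tool pose or several orientation samples.

    The tool's local axes are read under the package convention: local x is
    laid along the patient longitudinal axis and local z points anteriorly
    ("up"), so the tool rotation directly gives the patient anatomical frame
    in tracker coordinates.
    """
    if isinstance(tool_pose, Pose):
        return tool_pose.transform.rotation
    poses = list(tool_pose)
    if not poses:
        raise ValueError("at least one tool pose is required")
    if mode == "last":
        return poses[-1].transform.rotation
    if mode != "average":
        raise ValueError(f"unknown orientation mode: {mode!r}")
    q = mean_rotation([matrix_to_quaternion(p.transform.rotation) for p in poses])
    return quaternion_to_matrix(q)


def slrm_initialize(
    tool_pose: Pose | Sequence[Pose],
    orientation: PatientOrientation | str,
    ref: LandmarkPair,
    *,
    orientation_mode: str = "average",
) -> RegistrationResult:
    """Initial single-landmark registration.

    The rotation is taken from the tracked tool's measured orientation
    (several samples may be given; by default their chordal mean is used,
    ``orientation_mode="last"`` keeps only the final sample).  For a prone
    patient a 180-degree rotation about the longitudinal image axis is
    pre-composed, since the tool is held facing upwards in both positions.
    The translation is chosen so the reference landmark maps exactly:
    ``t = p_patient - R @ p_image``.
    """
    orientation = PatientOrientation(orientation)
    R = _tool_rotation(tool_pose, orientation_mode)
    if orientation is PatientOrientation.PRONE:
        R = R @ _PRONE_FLIP
    t = ref.p_patient - R @ ref.p_image
    return RegistrationResult(
        transform=RigidTransform(R, t), method=Method.SLRM, n_points=1
    )


def slrm_reregister(
    current: RegistrationResult, new_pair: LandmarkPair
) -> RegistrationResult:
    """Update the translation offset so ``new_pair`` maps exactly.

    The rotation is carried over unchanged (bitwise); only the offset
    moves.  Re-registration keeps no history: the newest point wins.
    """
    if current.method is not Method.SLRM:
        raise MethodMismatchError(
            f"re-registration applies to SLRM results, got {current.method.value}"
        )
    R = current.transform.rotation
    t = new_pair.p_patient - R @ new_pair.p_image
    return RegistrationResult(
        transform=RigidTransform(R, t), method=Method.SLRM, n_points=1
    )


def flrm_register(pairs: Sequence[LandmarkPair]) -> RegistrationResult:
    """Least-squares rigid registration of corresponding fiducials.

    Centroid-subtracted cross-covariance SVD; a reflection in the optimal
    orthogonal matrix is corrected by flipping the sign of the last
    singular direction.  FRE is the root-mean-square fiducial residual.

    Raises
    ------
    InsufficientPointsError
        Fewer than 3 pairs.
    DegenerateConfigurationError
        Image-side fiducials (near-)collinear: the ratio of the
        second-largest to largest singular value of the centered point
        matrix is below 1e-6.
    """
    if len(pairs) < 3:
        raise InsufficientPointsError(
            f"fiducial registration needs >=3 pairs, got {len(pairs)}"
        )
    P = np.array([p.p_image for p in pairs])
    Q = np.array([p.p_patient for p in pairs])
    p_bar, q_bar = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p_bar, Q - q_bar

    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] / sv[0] < _COLLINEAR_TOL:
        raise DegenerateConfigurationError(
            "fiducials are (near-)collinear; rotation is unidentifiable"
        )

    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = q_bar - R @ p_bar

    transform = RigidTransform(R, t)
    residuals = np.linalg.norm(transform.apply(P) - Q, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(
        transform=transform, method=Method.FLRM, n_points=len(pairs), fre=fre
    )


def fiducial_residuals(
    result: RegistrationResult, pairs: Sequence[LandmarkPair]
) -> np.ndarray:
    """Per-pair Euclidean residuals (mm) of a registration on ``pairs``.

    For the pairs a FLRM result was fitted on, the RMS of these residuals
    equals ``result.fre``.
    """
    P = np.array([p.p_image for p in pairs])
    Q = np.array([p.p_patient for p in pairs])
    return np.linalg.norm(result.transform.apply(P) - Q, axis=1)
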