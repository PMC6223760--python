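"""Pivot calibration of a tracked pointed tool.

Pivoting the tool about a fixed physical point while tracking it yields,
for each pose ``(R_i, t_i)``, the constraint ``R_i @ p_tip + t_i = p_pivot``
with the tip offset ``p_tip`` expressed in the tool frame and the pivot
point ``p_pivot`` in the reference frame.  Stacking all poses gives a
linear least-squares system in the six unknowns, exact in the noiseless
case.  No vendor-style sample-validity filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientMotionError
from .geometry import Pose

__all__ = ["PivotSolution", "pivot_calibrate"]

#: smallest singular value of the stacked system below which the pose set
#: is treated as rotationally degenerate
_RANK_TOL = 1e-8


@dataclass(frozen=True)
class PivotSolution:
    """Tip offset (tool frame), pivot point (reference frame), fit quality."""

    tip_offset: np.ndarray
    pivot_point: np.ndarray
    rms_residual: float
    n_poses: int

    def __post_init__(self) -> None:
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        if self.n_poses < 3:
            raise ValueError("n_poses must be >= 3")


def pivot_calibrate(poses: Sequence[Pose]) -> PivotSolution:
    """Solve the stacked system ``R_i @ p_tip - p_pivot = -t_i``.

    Raises
    ------
    InsufficientMotionError
        Fewer than 3 poses, or the poses share (nearly) one orientation so
        the 3n x 6 system is rank-deficient (smallest singular value below
        1e-8).
    """
    n = len(poses)
    if n < 3:
        raise InsufficientMotionError(f"pivot calibration needs >=3 poses, got {n}")

    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, pose in enumerate(poses):
        A[3 * i : 3 * i + 3, :3] = pose.transform.rotation
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -pose.transform.translation

    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < _RANK_TOL:
        raise InsufficientMotionError(
            "poses share (nearly) one orientation; tip and pivot are not "
            "separable"
        )

    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    tip, pivot = x[:3], x[3:]
    res = np.array(
        [
            np.linalg.norm(p.transform.rotation @ tip + p.transform.translation - pivot)
            for p in poses
        ]
    )
    rms = float(np.sqrt(np.mean(res**2)))
    return PivotSolution(
        tip_offset=tip, pivot_point=pivot, rms_residual=rms, n_poses=n
    )
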