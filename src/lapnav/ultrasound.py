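"""Tracked-ultrasound point localization.

Maps a user click on a live 2-D ultrasound slice to a 3-D point in the
tracking reference frame through the calibrated transform chain

    pixel -> image-plane mm -> probe sensor frame -> reference frame.

Pixel convention: 0-based, ``u`` indexes columns (lateral), ``v`` indexes
rows (axial depth); a point sits at the pixel center and fractional
coordinates are allowed — zooming the displayed slice only refines the
click to sub-pixel precision, it never changes the mapping.  The geometry
assumes a linear transducer (no scan conversion); any vendor axis
convention is absorbed by the probe calibration transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import OutOfBoundsError
from .geometry import Pose, RigidTransform

__all__ = ["UsImageGeometry", "UsClick", "pixel_to_image_mm", "click_to_reference"]


@dataclass(frozen=True)
class UsImageGeometry:
    """Pixel grid, physical spacing and probe calibration of a US image.

    ``calibration`` maps the image-plane frame (u*spacing_u, v*spacing_v, 0)
    into the probe's tracking-sensor frame.
    """

    rows: int
    cols: int
    spacing_u: float
    spacing_v: float
    calibration: RigidTransform

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if self.spacing_u <= 0 or self.spacing_v <= 0:
            raise ValueError("pixel spacings must be > 0")


@dataclass(frozen=True)
class UsClick:
    """A click on the live slice, with the probe pose at click time."""

    u: float
    v: float
    probe_pose: Pose


def pixel_to_image_mm(click: UsClick, geom: UsImageGeometry) -> np.ndarray:
    """Click pixel to millimetres in the image-plane frame (z identically 0).

    Raises
    ------
    OutOfBoundsError
        If the (possibly fractional) coordinates fall outside
        ``[0, cols-1] x [0, rows-1]``.
    """
    if not (0.0 <= click.u <= geom.cols - 1 and 0.0 <= click.v <= geom.rows - 1):
        raise OutOfBoundsError(
            f"click ({click.u}, {click.v}) outside "
            f"[0, {geom.cols - 1}] x [0, {geom.rows - 1}]"
        )
    return np.array([click.u * geom.spacing_u, click.v * geom.spacing_v, 0.0])


def click_to_reference(click: UsClick, geom: UsImageGeometry) -> np.ndarray:
    """3-D reference-frame point of a click: pose . calibration . pixel_mm."""
    p_plane = pixel_to_image_mm(click, geom)
    return click.probe_pose.transform.apply(geom.calibration.apply(p_plane))
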