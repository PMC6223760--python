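"""Plain-text file formats: transforms, pose streams, landmark tables,
ultrasound geometry and experiment configurations.

Formats
-------
transform   4 rows x 4 whitespace-separated floats (row-major homogeneous
            matrix, mm).
poses       CSV with header ``timestamp,tool_id,qw,qx,qy,qz,tx,ty,tz``
            (unit quaternion scalar-first, translation in mm).
landmarks   CSV ``label,frame,x,y,z`` with ``frame`` in {image, patient};
            pairs are joined on label.
us geometry YAML with ``rows, cols, spacing_u, spacing_v, calibration``
            (4x4 nested list).
experiment  YAML mirroring ExperimentConfig / NoiseModel fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import Pose, RigidTransform
from .phantom import ExperimentConfig, NoiseModel, TrialRecord
from .registration import LandmarkPair
from .ultrasound import UsImageGeometry

__all__ = [
    "read_transform",
    "write_transform",
    "read_poses",
    "write_poses",
    "read_landmark_pairs",
    "write_landmark_pairs",
    "read_us_geometry",
    "write_us_geometry",
    "read_experiment_config",
    "write_experiment_config",
    "trials_to_frame",
    "write_trials",
    "read_trials_frame",
]

POSE_COLUMNS = ["timestamp", "tool_id", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]


def read_transform(path: str | Path) -> RigidTransform:
    m = np.loadtxt(path)
    return RigidTransform.from_matrix(m)


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    np.savetxt(path, transform.as_matrix(), fmt="%.12g")


def read_poses(path: str | Path) -> list[Pose]:
    frame = pd.read_csv(path)
    missing = set(POSE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pose file missing columns: {sorted(missing)}")
    poses = []
    for row in frame.itertuples(index=False):
        transform = RigidTransform.from_quaternion(
            [row.qw, row.qx, row.qy, row.qz], [row.tx, row.ty, row.tz]
        )
        poses.append(Pose(float(row.timestamp), str(row.tool_id), transform))
    return poses


def write_poses(poses: Sequence[Pose], path: str | Path) -> None:
    rows = []
    for p in poses:
        q = p.transform.as_quaternion()
        t = p.transform.translation
        rows.append([p.timestamp, p.tool_id, *q, *t])
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)


def read_landmark_pairs(path: str | Path) -> list[LandmarkPair]:
    """Join image- and patient-frame rows on label; order follows the
    image-frame rows."""
    frame = pd.read_csv(path)
    required = {"label", "frame", "x", "y", "z"}
    if not required <= set(frame.columns):
        raise ValueError(f"landmark file needs columns {sorted(required)}")
    bad = set(frame["frame"]) - {"image", "patient"}
    if bad:
        raise ValueError(f"unknown frame values: {sorted(bad)}")
    by_frame = {
        name: grp.set_index("label")[["x", "y", "z"]]
        for name, grp in frame.groupby("frame")
    }
    if "image" not in by_frame or "patient" not in by_frame:
        raise ValueError("file must contain both image and patient rows")
    pairs = []
    for label, img_row in by_frame["image"].iterrows():
        if label not in by_frame["patient"].index:
            raise ValueError(f"label {label!r} has no patient-frame row")
        pat_row = by_frame["patient"].loc[label]
        pairs.append(
            LandmarkPair(str(label), img_row.to_numpy(float), pat_row.to_numpy(float))
        )
    return pairs


def write_landmark_pairs(pairs: Sequence[LandmarkPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append([p.label, "image", *p.p_image])
        rows.append([p.label, "patient", *p.p_patient])
    pd.DataFrame(rows, columns=["label", "frame", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_us_geometry(path: str | Path) -> UsImageGeometry:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    calibration = RigidTransform.from_matrix(np.array(cfg["calibration"], dtype=float))
    return UsImageGeometry(
        rows=int(cfg["rows"]),
        cols=int(cfg["cols"]),
        spacing_u=float(cfg["spacing_u"]),
        spacing_v=float(cfg["spacing_v"]),
        calibration=calibration,
    )


def write_us_geometry(geom: UsImageGeometry, path: str | Path) -> None:
    cfg = {
        "rows": geom.rows,
        "cols": geom.cols,
        "spacing_u": geom.spacing_u,
        "spacing_v": geom.spacing_v,
        "calibration": geom.calibration.as_matrix().tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    noise = NoiseModel(**cfg.pop("noise", {}))
    known = {"displacements", "axes", "repetitions", "methods", "phantom_seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}
    return ExperimentConfig(noise=noise, **kwargs)


def write_experiment_config(config: ExperimentConfig, path: str | Path) -> None:
    cfg = {
        "displacements": list(config.displacements),
        "axes": list(config.axes),
        "repetitions": config.repetitions,
        "methods": list(config.methods),
        "phantom_seed": config.phantom_seed,
        "noise": {
            "sigma_tool_pos": config.noise.sigma_tool_pos,
            "sigma_tool_angle": config.noise.sigma_tool_angle,
            "sigma_click": config.noise.sigma_click,
            "rng_seed": config.noise.rng_seed,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [t.method for t in trials],
            "axis": [t.axis for t in trials],
            "displacement_mm": [t.displacement_mm for t in trials],
            "rep": [t.repetition for t in trials],
            "tre_mm": [t.tre_mm for t in trials],
        }
    )


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"method", "axis", "displacement_mm", "rep", "tre_mm"}
    if not required <= set(frame.columns):
        raise ValueError(f"trials file needs columns {sorted(required)}")
    return frame
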