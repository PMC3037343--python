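"""File formats tying the pipeline together.

Frames are numbered 8-bit PNGs with a CSV pose sidecar (translation mm,
quaternion w,x,y,z, pixel spacing); contours are per-frame CSVs of
(x_px, y_px); volumes are NIfTI with affine diag(spacing)+origin;
transforms are 4×4 row-major text files; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .contours import Contour
from .phantom import ImageFrame
from .reconstruction import VolumeGrid, WallSurfaceSet
from .transforms import RigidTransform

POSE_COLUMNS = ["frame_index", "t_x", "t_y", "t_z", "q_w", "q_x", "q_y", "q_z",
                "pixel_spacing_x", "pixel_spacing_y"]


def write_frames(directory, frames: list[ImageFrame]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in frames:
        iio.imwrite(directory / f"frame_{f.frame_index:04d}.png", f.pixels)
        q = f.pose.quat_wxyz()
        t = f.pose.translation
        rows.append([f.frame_index, t[0], t[1], t[2], q[0], q[1], q[2], q[3],
                     f.pixel_spacing[0], f.pixel_spacing[1]])
        if f.truth_contour is not None:
            write_contour(directory / f"truth_{f.frame_index:04d}.csv", f.truth_contour)
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(directory / "poses.csv", index=False)


def read_frames(directory) -> list[ImageFrame]:
    directory = Path(directory)
    poses = pd.read_csv(directory / "poses.csv")
    frames = []
    for _, row in poses.iterrows():
        i = int(row.frame_index)
        pixels = iio.imread(directory / f"frame_{i:04d}.png")
        pose = RigidTransform.from_quat_wxyz(
            [row.q_w, row.q_x, row.q_y, row.q_z], [row.t_x, row.t_y, row.t_z])
        truth_path = directory / f"truth_{i:04d}.csv"
        truth = read_contour(truth_path, i) if truth_path.exists() else None
        frames.append(ImageFrame(pixels, pose, (row.pixel_spacing_x, row.pixel_spacing_y),
                                 i, truth))
    return frames


def write_contour(path, contour: Contour) -> None:
    pd.DataFrame(contour.points, columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_contour(path, frame_index: int = 0) -> Contour:
    df = pd.read_csv(path)
    return Contour(df[["x_px", "y_px"]].to_numpy(), frame_index)


def write_contours(directory, contours) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, c in enumerate(contours):
        if c is not None:
            write_contour(directory / f"contour_{i:04d}.csv", c)


def write_transform(path, t: RigidTransform) -> None:
    np.savetxt(path, t.as_matrix(), fmt="%.12g")


def read_transform(path) -> RigidTransform:
    return RigidTransform.from_matrix(np.loadtxt(path))


def write_volume(path, vol: VolumeGrid) -> None:
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.affine
    return VolumeGrid(values=np.asarray(img.dataobj, dtype=float),
                      origin=affine[:3, 3], spacing=float(affine[0, 0]))


def write_points(path, points: WallSurfaceSet) -> None:
    pd.DataFrame(points.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def read_points(path, source_view: str = "") -> WallSurfaceSet:
    df = pd.read_csv(path)
    return WallSurfaceSet(df[["x_mm", "y_mm", "z_mm"]].to_numpy(), source_view)


def write_yaml(path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
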