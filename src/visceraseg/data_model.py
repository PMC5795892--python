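"""Core types and I/O for registered RGB-D viscera images.

The raw input record is a registered pair of an 8-bit RGB image and a
16-bit depth image (stored in millimetres; 0 marks a missing depth
measurement) plus pinhole camera intrinsics.  Ground truth is a per-pixel
label image over four foreground organ classes (miscellaneous tissue,
heart, liver, lung), a background class, and an ignore code covering the
ambiguous boundary band between organs and pixels without depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

# Label codes
BACKGROUND = 0
MISC = 1
HEART = 2
LIVER = 3
LUNG = 4
IGNORE = 255

FOREGROUND_CLASSES = (MISC, HEART, LIVER, LUNG)
CLASS_NAMES = {
    BACKGROUND: "background",
    MISC: "miscellaneous",
    HEART: "heart",
    LIVER: "liver",
    LUNG: "lung",
    IGNORE: "ignore",
}

VIEW_TAGS = ("center-front", "right-front", "center-back", "right-back")


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels.

    ``depth_scale`` converts stored integer depth units to metres
    (default 0.001 for millimetre-coded 16-bit depth PNGs).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")


@dataclass
class RGBDImage:
    """Registered color + depth grids.

    ``depth`` is in metres after scaling; 0 marks missing measurements.
    ``id`` combines the viscera set identity with the view tag.
    """

    rgb: np.ndarray          # H x W x 3, uint8
    depth: np.ndarray        # H x W, float, metres, 0 = missing
    intrinsics: CameraIntrinsics
    id: str = ""
    set_id: Optional[int] = None
    view_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.depth.shape:
            raise ValueError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape} "
                "dimensions differ"
            )
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class LabelImage:
    """Per-pixel class codes (background / 4 organ classes / ignore)."""

    labels: np.ndarray       # H x W, uint8

    VALID_CODES = frozenset({BACKGROUND, MISC, HEART, LIVER, LUNG, IGNORE})

    def __post_init__(self) -> None:
        codes = set(np.unique(self.labels).tolist())
        if not codes <= self.VALID_CODES:
            raise ValueError(f"unknown label codes: {sorted(codes - self.VALID_CODES)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "LabelImage":
        return LabelImage(self.labels.copy())


@dataclass
class PointCloud:
    """One point per valid-depth pixel, in the camera frame.

    x right, y down, z forward (metres).  ``pixel_index`` holds the
    (row, col) source pixel of each point, preserving the bijection with
    valid-depth pixels.  ``normals``, when present, are unit vectors.
    """

    xyz: np.ndarray            # N x 3, metres
    color: np.ndarray          # N x 3, uint8
    pixel_index: np.ndarray    # N x 2, (row, col)
    shape: tuple[int, int] = (0, 0)   # source image H, W
    normals: Optional[np.ndarray] = None   # N x 3, unit vectors

    def __len__(self) -> int:
        return len(self.xyz)


def read_rgbd_pair(rgb_path, depth_path, intrinsics: CameraIntrinsics,
                   id: str = "") -> RGBDImage:
    """Read a registered RGB PNG + 16-bit depth PNG pair.

    Depth is converted to metres via ``intrinsics.depth_scale``; stored
    zeros stay zero (missing).
    """
    rgb = np.asarray(Image.open(rgb_path).convert("RGB"), dtype=np.uint8)
    depth_raw = np.asarray(Image.open(depth_path))
    if depth_raw.ndim != 2:
        raise ValueError(f"depth image {depth_path} is not single-channel")
    if rgb.shape[:2] != depth_raw.shape:
        raise ValueError(
            f"dimension mismatch: rgb {rgb.shape[:2]} vs depth {depth_raw.shape}"
        )
    depth = depth_raw.astype(np.float64) * intrinsics.depth_scale
    return RGBDImage(rgb=rgb, depth=depth, intrinsics=intrinsics, id=id)


def write_rgbd_pair(image: RGBDImage, rgb_path, depth_path) -> None:
    """Write an RGBDImage as an 8-bit RGB PNG and a 16-bit depth PNG."""
    Image.fromarray(image.rgb).save(rgb_path)
    stored = np.round(image.depth / image.intrinsics.depth_scale)
    stored = np.clip(stored, 0, 65535).astype(np.uint16)
    Image.fromarray(stored).save(depth_path)


def read_label_image(path) -> LabelImage:
    return LabelImage(np.asarray(Image.open(path)).astype(np.uint8))


def write_label_image(labels: LabelImage, path) -> None:
    Image.fromarray(labels.labels.astype(np.uint8)).save(path)


def backproject(image: RGBDImage) -> PointCloud:
    """Backproject valid-depth pixels through the pinhole model.

    For pixel (r, c) with depth d > 0:
        x = (c - cx) * d / fx,  y = (r - cy) * d / fy,  z = d.
    """
    k = image.intrinsics
    rows, cols = np.nonzero(image.depth > 0)
    d = image.depth[rows, cols]
    x = (cols - k.cx) * d / k.fx
    y = (rows - k.cy) * d / k.fy
    xyz = np.column_stack([x, y, d])
    color = image.rgb[rows, cols]
    pixel_index = np.column_stack([rows, cols])
    return PointCloud(xyz=xyz, color=color, pixel_index=pixel_index,
                      shape=image.shape)


def forward_project(xyz: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points to (row, col) pixel coordinates."""
    xyz = np.atleast_2d(xyz)
    z = xyz[:, 2]
    col = xyz[:, 0] * intrinsics.fx / z + intrinsics.cx
    row = xyz[:, 1] * intrinsics.fy / z + intrinsics.cy
    return np.column_stack([row, col])


def make_ignore_boundary(labels: LabelImage, width: int,
                         depth: Optional[np.ndarray] = None) -> LabelImage:
    """Recode ambiguous boundary pixels and depth holes to the ignore class.

    A non-background pixel within Chebyshev distance <= ``width`` of a pixel
    holding a *different* non-background class becomes ignore, yielding a
    symmetric band of ``width`` pixels on each side of every inter-class
    border.  Borders against background do not create a band.  Any pixel
    with a missing depth measurement also becomes ignore.
    """
    if width < 0:
        raise ValueError("width must be non-negative")
    lab = labels.labels
    out = lab.copy()
    if width > 0:
        # Chebyshev ball = square structuring element of side 2*width+1
        selem = np.ones((2 * width + 1, 2 * width + 1), dtype=bool)
        fg = lab != BACKGROUND
        for cls in FOREGROUND_CLASSES:
            mask = lab == cls
            if not mask.any():
                continue
            other = fg & ~mask & (lab != IGNORE)
            if not other.any():
                continue
            near_other = ndimage.binary_dilation(other, structure=selem)
            out[mask & near_other] = IGNORE
    if depth is not None:
        if depth.shape != lab.shape:
            raise ValueError("depth and labels resolutions differ")
        out[depth == 0] = IGNORE
    return LabelImage(out)


def write_ply(cloud: PointCloud, path) -> None:
    """Export a point cloud as ASCII PLY (x y z r g b [nx ny nz])."""
    path = Path(path)
    has_n = cloud.normals is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        if has_n:
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        fh.write("end_header\n")
        for i in range(len(cloud)):
            x, y, z = cloud.xyz[i]
            r, g, b = cloud.color[i]
            line = f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}"
            if has_n:
                nx, ny, nz = cloud.normals[i]
                line += f" {nx:.6f} {ny:.6f} {nz:.6f}"
            fh.write(line + "\n")
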