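"""Per-superpixel feature pooling: unary vectors for the classifier and
pairwise vectors for the CRF edges.

Feature responses are mean-pooled over the member pixels of each
superpixel.  Three feature modes exist:

====== ===================================== ==========================
mode    unary features (dim)                  edge features (dim)
====== ===================================== ==========================
2D      LAB 3 + centroid (row,col)/(H,W) (5)  |dLAB| 3 + |dcentroid| 2
3D      LAB 3 + centroid xyz metres (6)       |dLAB| 3 + |dxyz| 3 + |dn| 3
3D+CNN  3D unary + mean CNN activations       same as 3D (9)
====== ===================================== ==========================

Edge features are absolute per-component differences of pooled
statistics, hence symmetric in the edge's endpoints and zero iff the two
superpixels' pooled statistics coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import RGBDImage
from .feature_maps import CnnProvider, compute_lab, iter_cnn_maps
from .overseg import Oversegmentation

FEATURE_MODES = ("2D", "3D", "3D+CNN")


@dataclass
class UnaryFeatureMatrix:
    """S x D_u matrix, row order = superpixel id."""

    values: np.ndarray
    names: list

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("unary features contain non-finite entries")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column registry does not match matrix width")


@dataclass
class EdgeFeatureMatrix:
    """E x D_e matrix aligned with the adjacency edge list."""

    values: np.ndarray
    names: list

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge features contain non-finite entries")


def _check_mode(mode: str) -> None:
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}; "
                         f"expected one of {FEATURE_MODES}")


def pool_map(overseg: Oversegmentation, m: np.ndarray) -> np.ndarray:
    """Mean of one H x W map over each superpixel's members."""
    if m.shape != overseg.ids.shape:
        raise ValueError("map and oversegmentation resolutions differ")
    valid = overseg.ids >= 0
    ids = overseg.ids[valid]
    sums = np.bincount(ids, weights=m[valid], minlength=overseg.n_segments)
    counts = np.bincount(ids, minlength=overseg.n_segments)
    return sums / counts


def pool_unary(overseg: Oversegmentation, image: RGBDImage, mode: str,
               provider: Optional[CnnProvider] = None) -> UnaryFeatureMatrix:
    """Per-superpixel unary feature vectors for the given mode.

    CNN activations (3D+CNN mode) are pooled map-by-map as the provider
    yields them, so the full activation stack is never materialized.
    """
    _check_mode(mode)
    if overseg.ids.shape != image.shape:
        raise ValueError("oversegmentation and image resolutions differ")
    lab = compute_lab(image.rgb)
    cols = [pool_map(overseg, lab[..., d]) for d in range(3)]
    names = ["lab_l", "lab_a", "lab_b"]
    H, W = image.shape
    if mode == "2D":
        cols.append(overseg.centroid_px[:, 0] / H)
        cols.append(overseg.centroid_px[:, 1] / W)
        names += ["center_row", "center_col"]
    else:
        if overseg.centroid_xyz is None:
            raise ValueError(f"{mode} mode requires a 3D oversegmentation")
        for d, nm in enumerate(("center_x", "center_y", "center_z")):
            cols.append(overseg.centroid_xyz[:, d])
            names.append(nm)
    if mode == "3D+CNN":
        if provider is None:
            raise ValueError("3D+CNN mode requires a CnnProvider")
        for i, m in enumerate(iter_cnn_maps(image.rgb, provider)):
            cols.append(pool_map(overseg, m))
            names.append(f"cnn_{i:04d}")
    return UnaryFeatureMatrix(values=np.column_stack(cols), names=names)


def compute_edge_features(overseg: Oversegmentation,
                          edges: Optional[np.ndarray] = None,
                          mode: str = "3D",
                          image_shape: Optional[tuple] = None,
                          include_bias: bool = False) -> EdgeFeatureMatrix:
    """Pairwise feature vectors for adjacency edges.

    Componentwise absolute differences of the superpixels' pooled LAB,
    centroid and (3D modes) mean normal.  An optional constant bias
    column can be appended for the CRF learner; it is off by default so
    dimensionalities match the feature-mode table.
    """
    _check_mode(mode)
    if edges is None:
        edges = overseg.edges
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size and edges.max() >= overseg.n_segments:
        raise ValueError("edge references an unknown superpixel id")
    a, b = edges[:, 0], edges[:, 1]
    feats = [np.abs(overseg.mean_lab[a] - overseg.mean_lab[b])]
    names = ["d_lab_l", "d_lab_a", "d_lab_b"]
    if mode == "2D":
        shape = image_shape or overseg.ids.shape
        cen = overseg.centroid_px / np.asarray(shape, dtype=float)
        feats.append(np.abs(cen[a] - cen[b]))
        names += ["d_center_row", "d_center_col"]
    else:
        if overseg.centroid_xyz is None:
            raise ValueError(f"{mode} mode requires a 3D oversegmentation")
        feats.append(np.abs(overseg.centroid_xyz[a] - overseg.centroid_xyz[b]))
        names += ["d_center_x", "d_center_y", "d_center_z"]
        nrm = (overseg.mean_normal if overseg.mean_normal is not None
               else np.zeros((overseg.n_segments, 3)))
        feats.append(np.abs(nrm[a] - nrm[b]))
        names += ["d_normal_x", "d_normal_y", "d_normal_z"]
    if include_bias:
        feats.append(np.ones((len(edges), 1)))
        names.append("bias")
    values = (np.column_stack([f.reshape(len(edges), -1) for f in feats])
              if len(edges) else np.zeros((0, len(names))))
    return EdgeFeatureMatrix(values=values, names=names)


def unary_dim(mode: str, provider: Optional[CnnProvider] = None) -> int:
    _check_mode(mode)
    base = 5 if mode == "2D" else 6
    if mode == "3D+CNN":
        if provider is None:
            raise ValueError("3D+CNN dimensionality needs the provider")
        base += provider.count_maps()
    return base


def edge_dim(mode: str) -> int:
    _check_mode(mode)
    return 5 if mode == "2D" else 9
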