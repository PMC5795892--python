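"""Per-pixel feature maps: LAB color, depth, surface-normal components,
and CNN activation maps resized to the input resolution.

The CNN channel follows the hypercolumn idea: every filter of every
convolutional layer of a VGG-16-shaped network contributes one activation
map, bilinearly upsampled back to input resolution (4224 maps in total
for VGG-16).  Two providers implement the contract: a real VGG-16 with
ImageNet weights (optional, needs torchvision and a weight download) and
a deterministic seeded random-convolution bank with an identical
layer/filter layout, which keeps the full numerical path testable
offline.  Swapping providers changes feature values only, never shapes
or orderings.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import rgb2lab
from skimage.transform import resize

from .data_model import PointCloud

#: filters per conv layer of VGG-16; the per-block structure is
#: (2, 2, 3, 3, 3) conv layers with 2x2 max-pooling between blocks
VGG16_CONV_FILTERS = (64, 64, 128, 128, 256, 256, 256,
                      512, 512, 512, 512, 512, 512)
VGG16_POOL_AFTER = (1, 3, 6, 9, 12)     # layer indices followed by a pool


@dataclass
class FeatureMapStack:
    """Named list of full-resolution real-valued maps."""

    names: list
    maps: list                       # of H x W arrays
    provenance: list                 # per map: color | depth | normal | cnn

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("map names must be unique")
        shapes = {m.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError(f"maps disagree on resolution: {shapes}")

    def __len__(self) -> int:
        return len(self.maps)


class CnnProvider(ABC):
    """Contract for a bank of convolutional activation maps.

    ``architecture`` lists filter counts per conv layer in order;
    ``produce`` yields one activation map per filter, ordered by
    (layer index, filter index), at the layer's native resolution.
    """

    architecture: tuple

    def count_maps(self) -> int:
        return int(sum(self.architecture))

    @abstractmethod
    def produce(self, rgb: np.ndarray) -> Iterator[np.ndarray]:
        ...


class RandomConvProvider(CnnProvider):
    """Seeded random-convolution bank mimicking a CNN's layer layout.

    3x3 filters drawn once from a seeded generator, ReLU after each
    layer, 2x2 max-pooling at the configured block boundaries.  Fully
    deterministic; intended as the default offline feature provider and
    as a test fixture.
    """

    def __init__(self, architecture: Sequence[int] = VGG16_CONV_FILTERS,
                 pool_after: Sequence[int] = VGG16_POOL_AFTER,
                 seed: int = 0):
        self.architecture = tuple(int(a) for a in architecture)
        self.pool_after = frozenset(pool_after)
        self.seed = seed

    def produce(self, rgb: np.ndarray) -> Iterator[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        x = rgb.astype(np.float64) / 255.0 - 0.5     # C-last
        x = np.moveaxis(x, -1, 0)                    # C x H x W
        for li, n_out in enumerate(self.architecture):
            n_in = x.shape[0]
            w = rng.normal(0.0, 1.0 / np.sqrt(9 * n_in),
                           size=(n_out, n_in, 3, 3))
            y = _conv3x3(x, w)
            y = np.maximum(y, 0.0)                   # post-ReLU activations
            for f in range(n_out):
                yield y[f]
            x = y
            if li in self.pool_after:
                x = _maxpool2(x)


def _conv3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution, channels-first."""
    n_out, n_in, _, _ = w.shape
    H, W = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    # im2col over the 9 taps
    cols = np.stack([xp[:, i:i + H, j:j + W]
                     for i in range(3) for j in range(3)], axis=1)
    cols = cols.reshape(n_in * 9, H * W)     # (in, tap) raveled as in*9
    wm = w.reshape(n_out, n_in * 9)          # cross-correlation convention
    return (wm @ cols).reshape(n_out, H, W)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    if H2 == 0 or W2 == 0:
        return x
    t = x[:, :H2 * 2, :W2 * 2].reshape(C, H2, 2, W2, 2)
    return t.max(axis=(2, 4))


class VGG16Provider(CnnProvider):
    """Real VGG-16 (ImageNet weights, used without fine-tuning).

    Requires torch + torchvision and a weight download; import and
    instantiation are lazy so the rest of the package works offline.
    Input preprocessing: mean-subtracted RGB, shorter side resized to
    ``input_size`` before extraction; activations are taken after each
    conv layer's ReLU.
    """

    architecture = VGG16_CONV_FILTERS

    def __init__(self, input_size: int = 224, pre_relu: bool = False):
        try:
            import torch                      # noqa: F401
            import torchvision                # noqa: F401
        except ImportError as exc:            # pragma: no cover
            raise ImportError(
                "VGG16Provider requires the optional 'vgg' extra "
                "(torch + torchvision)") from exc
        self.input_size = input_size
        self.pre_relu = pre_relu
        import torchvision.models as models
        self._net = models.vgg16(weights="IMAGENET1K_V1").features.eval()

    def produce(self, rgb: np.ndarray):        # pragma: no cover
        import torch
        import torch.nn as nn
        x = rgb.astype(np.float32)
        x -= np.array([123.68, 116.779, 103.939], dtype=np.float32)
        h, w = x.shape[:2]
        scale = self.input_size / min(h, w)
        x = resize(x, (round(h * scale), round(w * scale)),
                   order=1, preserve_range=True, anti_aliasing=False)
        t = torch.from_numpy(np.moveaxis(x, -1, 0)[None])
        with torch.no_grad():
            for layer in self._net:
                if isinstance(layer, nn.Conv2d):
                    t = layer(t)
                    out = t if self.pre_relu else torch.relu(t)
                    for f in range(out.shape[1]):
                        yield out[0, f].numpy()
                elif isinstance(layer, nn.ReLU):
                    t = torch.relu(t)
                else:
                    t = layer(t)


def compute_lab(rgb: np.ndarray) -> np.ndarray:
    """CIE L*a*b* (D65, sRGB input), shape H x W x 3, L in [0, 100]."""
    return rgb2lab(rgb)


def estimate_normals(cloud: PointCloud, k_neighbors: int = 12) -> np.ndarray:
    """Per-point unit surface normals from local plane fits.

    The normal is the smallest principal axis of the k-nearest-neighbor
    covariance, sign-flipped toward the camera (n_z <= 0).  Degenerate
    neighborhoods (fewer than 3 points) yield a zero vector.
    """
    pts = cloud.xyz
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to estimate normals")
    k = min(k_neighbors, n)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    idx = idx.reshape(n, k)
    nb = pts[idx]                             # n x k x 3
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb) / k
    # smallest-eigenvalue eigenvector of each 3x3 covariance
    wvals, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    flip = normals[:, 2] > 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    normals[ok] /= norms[ok, None]
    normals[~ok] = 0.0
    return normals


def compute_normals(cloud: PointCloud, k_neighbors: int = 12) -> np.ndarray:
    """Normal-component maps (3 x H x W); 0 at pixels without depth."""
    if cloud.shape == (0, 0):
        raise ValueError("point cloud lacks source image shape")
    normals = estimate_normals(cloud, k_neighbors)
    maps = np.zeros((3,) + cloud.shape)
    r, c = cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]
    for d in range(3):
        maps[d, r, c] = normals[:, d]
    return maps


def resize_map(m: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``shape``; identity when already that shape."""
    if m.shape == tuple(shape):
        return m
    return resize(m, shape, order=1, preserve_range=True,
                  anti_aliasing=False)


def cnn_activation_stack(rgb: np.ndarray,
                         provider: CnnProvider) -> FeatureMapStack:
    """Materialize every provider activation map at input resolution.

    Maps are ordered by (layer, filter).  For the full VGG-16 layout
    this is memory-heavy; prefer :func:`iter_cnn_maps` for on-the-fly
    per-superpixel pooling.
    """
    shape = rgb.shape[:2]
    maps, names = [], []
    try:
        for i, m in enumerate(provider.produce(rgb)):
            maps.append(resize_map(np.asarray(m, dtype=float), shape))
            names.append(f"cnn_{i:04d}")
    except Exception as exc:
        raise RuntimeError(f"CNN provider failed: {exc}") from exc
    if len(maps) != provider.count_maps():
        raise RuntimeError(
            f"provider yielded {len(maps)} maps, expected "
            f"{provider.count_maps()}")
    return FeatureMapStack(names=names, maps=maps,
                           provenance=["cnn"] * len(maps))


def iter_cnn_maps(rgb: np.ndarray, provider: CnnProvider):
    """Yield provider activation maps one at a time, resized to input
    resolution (constant-memory alternative to cnn_activation_stack)."""
    shape = rgb.shape[:2]
    for m in provider.produce(rgb):
        yield resize_map(np.asarray(m, dtype=float), shape)
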