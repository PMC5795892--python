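"""Synthetic RGB-D viscera scene generator.

Emulates the statistical structure of a poultry-viscera RGB-D dataset:
each viscera *set* is imaged from four perspectives; the foreground
occupies a roughly 150x350-px hanging region inside a 480x640 frame; the
pixel count over the four organ classes is heavily skewed (about 70%
miscellaneous tissue, 20% liver, 5% heart, 5% lung); heart and lungs sit
near the top of the viscera while the liver occupies the centre; depth
maps have missing-measurement holes and a 2-px ignore band separates
adjacent organ classes.

Organ shapes are smoothed-noise blobs rather than anatomical meshes —
the objects being emulated are non-rigid bodies without straight lines
or sharp edges, and thresholded smooth noise reproduces that character.
Organ geometry is generated once per set; each view applies a small
in-plane translation plus a depth-dependent parallax shift.

Two deliberate difficulty features mirror the real data: heart and
miscellaneous tissue overlap in color (the heart is partly covered by
fat), while organs protrude toward the camera by class-specific amounts,
so depth carries class information that color alone does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .data_model import (
    BACKGROUND, HEART, LIVER, LUNG, MISC, VIEW_TAGS,
    CameraIntrinsics, LabelImage, RGBDImage, make_ignore_boundary,
)

_CLASS_ORDER = (HEART, LUNG, LIVER)   # assigned in this order; misc = remainder


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution.

    Sizes are in pixels; fractions are relative to the frame so the same
    configuration scales across working resolutions.  Depth quantities
    are metres.
    """

    height: int = 480
    width: int = 640
    # foreground bounding box as frame fractions (~350x150 px at 480x640)
    fg_height_frac: float = 0.73
    fg_width_frac: float = 0.23
    fg_fill: float = 0.72            # blob area / bounding-box area
    # target pixel shares among non-ignore foreground pixels
    class_shares: dict = field(default_factory=lambda: {
        MISC: 0.70, LIVER: 0.20, HEART: 0.05, LUNG: 0.05})
    # per-class mean RGB; heart deliberately overlaps miscellaneous
    class_colors: dict = field(default_factory=lambda: {
        MISC: (205.0, 145.0, 120.0),
        HEART: (190.0, 135.0, 112.0),
        LIVER: (122.0, 62.0, 55.0),
        LUNG: (235.0, 162.0, 160.0)})
    color_jitter: float = 10.0       # per-set mean-color jitter (RGB units)
    color_noise: float = 9.0         # per-pixel noise std
    color_field_noise: float = 10.0  # smooth within-organ variation amplitude
    background_color: tuple = (92.0, 92.0, 96.0)
    # vertical layout priors: band centre as fraction of foreground height
    layout_centers: dict = field(default_factory=lambda: {
        HEART: 0.22, LUNG: 0.12, LIVER: 0.55})
    layout_strength: float = 2.2     # weight of layout prior vs shape noise
    # depth model
    base_depth: float = 0.35         # camera-to-viscera distance
    background_depth: float = 0.55
    relief_amplitude: float = 0.018  # smooth surface relief
    class_protrusion: dict = field(default_factory=lambda: {
        MISC: 0.0, LIVER: 0.012, LUNG: 0.022, HEART: 0.032})
    depth_noise: float = 0.0012
    hole_rate: float = 0.02
    # annotation convention
    ignore_width: int = 2
    # view model: translation (frame fraction) + parallax gain (px at W=160)
    view_shift_frac: float = 0.035
    parallax_gain_frac: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        shares = self.class_shares
        if any(s < 0 for s in shares.values()):
            raise ValueError("class shares must be non-negative")
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("class shares must sum to 1")
        if not 0 <= self.hole_rate < 1:
            raise ValueError("hole rate must lie in [0, 1)")

    def intrinsics(self) -> CameraIntrinsics:
        f = 0.96 * self.width
        return CameraIntrinsics(fx=f, fy=f, cx=(self.width - 1) / 2,
                                cy=(self.height - 1) / 2)


@dataclass
class SyntheticDataset:
    """A list of (RGBDImage, LabelImage) items grouped by viscera set."""

    items: list            # of (RGBDImage, LabelImage)
    set_ids: np.ndarray    # per-item set id
    view_tags: list        # per-item view tag

    def __len__(self) -> int:
        return len(self.items)

    @property
    def unique_sets(self) -> np.ndarray:
        return np.unique(self.set_ids)

    def subset(self, keep_sets) -> "SyntheticDataset":
        keep = np.isin(self.set_ids, list(keep_sets))
        idx = np.nonzero(keep)[0]
        return SyntheticDataset(
            items=[self.items[i] for i in idx],
            set_ids=self.set_ids[idx],
            view_tags=[self.view_tags[i] for i in idx])


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed at scale sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _view_index(view_tag: str) -> int:
    if view_tag in VIEW_TAGS:
        return VIEW_TAGS.index(view_tag)
    if view_tag.startswith("view-"):
        return int(view_tag.split("-", 1)[1])
    raise ValueError(f"unknown view tag {view_tag!r}")


def view_tag_for(index: int) -> str:
    return VIEW_TAGS[index] if index < len(VIEW_TAGS) else f"view-{index}"


def _class_score_fields(rng, shape, cfg: SceneConfig) -> dict:
    """One smooth score field per organ class: shape noise plus a
    vertical layout prior (heart/lung near the top, liver central)."""
    H_box, W_box = shape
    rows = np.arange(H_box, dtype=float)[:, None] / max(H_box - 1, 1)
    sigma = max(min(H_box, W_box) / 7.0, 1.5)
    fields = {}
    for cls in _CLASS_ORDER:
        noise = _smooth_noise(rng, shape, sigma)
        band = np.exp(-0.5 * ((rows - cfg.layout_centers[cls]) / 0.16) ** 2)
        fields[cls] = noise + cfg.layout_strength * np.broadcast_to(band, shape)
    return fields


def _assign_classes(score_fields: dict, fg_mask, targets: dict) -> np.ndarray:
    """Carve organ blobs out of the foreground by quantile-thresholding
    the per-class score fields; remaining foreground is miscellaneous.

    ``targets`` maps class code -> desired pixel count.
    """
    labels = np.where(fg_mask, MISC, BACKGROUND).astype(np.uint8)
    available = fg_mask.copy()
    for cls in _CLASS_ORDER:
        want = int(targets.get(cls, 0))
        if want <= 0:
            continue
        score = score_fields[cls]
        vals = score[available]
        if len(vals) <= want:
            labels[available] = cls
            available[:] = False
            continue
        thresh = np.partition(vals, len(vals) - want)[len(vals) - want]
        take = available & (score >= thresh)
        # quantile ties can overshoot by a few pixels; trim deterministically
        extra = take.sum() - want
        if extra > 0:
            rr, cc = np.nonzero(take & (score == thresh))
            take[rr[:extra], cc[:extra]] = False
        labels[take] = cls
        available &= ~take
    return labels


_GEOMETRY_CACHE: dict = {}


def _canonical_geometry_cached(cfg: SceneConfig, set_seed: int):
    key = (repr(cfg), set_seed)
    if key not in _GEOMETRY_CACHE:
        if len(_GEOMETRY_CACHE) > 4:
            _GEOMETRY_CACHE.clear()
        _GEOMETRY_CACHE[key] = _canonical_geometry(cfg, set_seed)
    return _GEOMETRY_CACHE[key]


def _canonical_geometry(cfg: SceneConfig, set_seed: int):
    """Per-set label and depth maps, identical across the set's views."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, set_seed]))
    H, W = cfg.height, cfg.width
    H_box = max(int(round(cfg.fg_height_frac * H)), 8)
    W_box = max(int(round(cfg.fg_width_frac * W)), 8)
    r0 = (H - H_box) // 2
    c0 = (W - W_box) // 2

    # foreground blob: radial profile + smooth noise, thresholded at the
    # quantile that yields the configured fill fraction
    rr = (np.arange(H_box)[:, None] - (H_box - 1) / 2) / (H_box / 2)
    cc = (np.arange(W_box)[None, :] - (W_box - 1) / 2) / (W_box / 2)
    radial = 1.0 - (rr ** 2 + cc ** 2)
    shape_noise = _smooth_noise(rng, (H_box, W_box),
                                max(min(H_box, W_box) / 6.0, 1.5))
    fg_field = radial + 0.45 * shape_noise
    thresh = np.quantile(fg_field, 1.0 - cfg.fg_fill)
    fg_mask = fg_field > thresh

    # carve organ blobs, then calibrate: the ignore band removes a 2-px
    # rim from both sides of every organ border, which depletes the small
    # classes and inflates the majority class in the *measured* (band-
    # excluded) shares.  Fixed-point-iterate the organ pixel targets
    # against the measured post-band shares on frozen score fields so
    # the kept-pixel shares match the configured skew.
    n_fg = int(fg_mask.sum())
    fields = _class_score_fields(rng, (H_box, W_box), cfg)
    targets = {cls: cfg.class_shares.get(cls, 0.0) * n_fg
               for cls in _CLASS_ORDER}
    box_labels = _assign_classes(fields, fg_mask, targets)
    for _ in range(6):
        band = make_ignore_boundary(
            LabelImage(box_labels), cfg.ignore_width).labels
        kept = np.isin(band, (MISC, HEART, LIVER, LUNG))
        n_kept = max(int(kept.sum()), 1)
        converged = True
        for cls in _CLASS_ORDER:
            want = cfg.class_shares.get(cls, 0.0)
            achieved = np.count_nonzero(band[kept] == cls) / n_kept
            if want <= 0:
                continue
            if abs(achieved - want) > 0.1 * want:
                converged = False
            ratio = want / achieved if achieved > 0 else 1.6
            targets[cls] = min(targets[cls] * float(np.clip(ratio, 0.5, 2.0)),
                               4.0 * want * n_fg)
        if converged:
            break
        box_labels = _assign_classes(fields, fg_mask, targets)

    labels = np.full((H, W), BACKGROUND, dtype=np.uint8)
    labels[r0:r0 + H_box, c0:c0 + W_box] = box_labels

    # canonical depth: base distance minus class protrusion plus relief
    z = np.full((H, W), cfg.background_depth)
    protrusion = np.zeros((H, W))
    for cls, p in cfg.class_protrusion.items():
        protrusion[labels == cls] = p
    fg_full = labels != BACKGROUND
    relief = _smooth_noise(rng, (H, W), max(min(H, W) / 10.0, 2.0))
    z[fg_full] = cfg.base_depth - protrusion[fg_full] \
        + cfg.relief_amplitude * relief[fg_full]
    z = np.where(fg_full, ndimage.gaussian_filter(z, 1.0), z)

    # per-set appearance: jittered class color means
    color_means = {}
    for cls, mean in cfg.class_colors.items():
        jit = rng.normal(0.0, cfg.color_jitter, size=3)
        color_means[cls] = np.asarray(mean) + jit
    return labels, z, color_means


def generate_scene(config: SceneConfig, set_seed: int,
                   view_tag: str = "center-front") -> tuple[RGBDImage, LabelImage]:
    """Render one deterministic RGB-D scene plus ground truth.

    The output is bit-identical for a fixed (config.seed, set_seed,
    view_tag); views of the same set share organ geometry and differ by a
    small in-plane translation with depth-dependent parallax, lighting
    and noise.
    """
    cfg = config
    v = _view_index(view_tag)
    labels0, z0, color_means = _canonical_geometry_cached(cfg, set_seed)
    H, W = cfg.height, cfg.width
    vrng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, set_seed, 1000 + v]))

    # view transform: fixed per-view translation + small random jitter
    base = [(0.0, 0.0), (0.0, 1.0), (0.5, -0.5), (0.5, 0.7)]
    fy, fx = base[v % 4] if v < 4 else (vrng.uniform(-1, 1), vrng.uniform(-1, 1))
    dy = int(round(fy * cfg.view_shift_frac * H)) + int(vrng.integers(-1, 2))
    dx = int(round(fx * cfg.view_shift_frac * W)) + int(vrng.integers(-1, 2))

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    src_r = np.clip(rr - dy, 0, H - 1)
    src_c0 = np.clip(cc - dx, 0, W - 1)
    # parallax: pixels closer than the base distance shift further
    z_probe = z0[src_r, src_c0]
    par = cfg.parallax_gain_frac * W * (cfg.base_depth - z_probe) / cfg.base_depth
    src_c = np.clip(cc - dx - np.round(par).astype(int), 0, W - 1)
    oob = (rr - dy < 0) | (rr - dy >= H) | (cc - dx < 0) | (cc - dx >= W)

    labels = labels0[src_r, src_c]
    z = z0[src_r, src_c].copy()
    labels[oob] = BACKGROUND
    z[oob] = cfg.background_depth

    # render color
    rgb = np.empty((H, W, 3))
    rgb[:] = np.asarray(cfg.background_color)
    light = vrng.uniform(0.94, 1.06)
    for cls, mean in color_means.items():
        rgb[labels == cls] = mean * light
    for ch in range(3):
        rgb[..., ch] += cfg.color_field_noise * _smooth_noise(
            vrng, (H, W), max(min(H, W) / 20.0, 1.5))
    rgb += vrng.normal(0.0, cfg.color_noise, size=(H, W, 3))
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    # depth noise and missing-measurement holes
    z += vrng.normal(0.0, cfg.depth_noise, size=(H, W))
    z = np.clip(z, 0.01, None)
    if cfg.hole_rate > 0:
        holes = vrng.random((H, W)) < cfg.hole_rate
        z[holes] = 0.0

    image = RGBDImage(rgb=rgb, depth=z, intrinsics=cfg.intrinsics(),
                      id=f"set{set_seed:04d}-{view_tag}",
                      set_id=set_seed, view_tag=view_tag)
    gt = make_ignore_boundary(LabelImage(labels.astype(np.uint8)),
                              cfg.ignore_width, depth=z)
    return image, gt


def generate_dataset(config: SceneConfig, n_sets: int, n_views: int = 4,
                     seed: Optional[int] = None) -> SyntheticDataset:
    """Generate ``n_sets`` viscera sets imaged from ``n_views`` perspectives."""
    if n_sets < 1 or n_views < 1:
        raise ValueError("n_sets and n_views must be >= 1")
    cfg = config if seed is None else replace(config, seed=seed)
    items, set_ids, view_tags = [], [], []
    for s in range(n_sets):
        for v in range(n_views):
            tag = view_tag_for(v)
            items.append(generate_scene(cfg, s, tag))
            set_ids.append(s)
            view_tags.append(tag)
    return SyntheticDataset(items=items, set_ids=np.asarray(set_ids),
                            view_tags=view_tags)


def split_dataset(dataset: SyntheticDataset, sizes: Sequence[int],
                  seed: int = 0) -> tuple:
    """Group-aware split by viscera set id.

    ``sizes`` gives the number of *sets* per partition and must sum to
    the number of distinct set ids; all views of a set land in exactly
    one partition, so the same viscera never straddles training and test.
    """
    sets = dataset.unique_sets
    if sum(sizes) != len(sets):
        raise ValueError(
            f"split sizes {tuple(sizes)} do not sum to set count {len(sets)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sets)
    parts, start = [], 0
    for n in sizes:
        parts.append(dataset.subset(perm[start:start + n]))
        start += n
    return tuple(parts)
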