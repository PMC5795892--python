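"""Supervoxel / superpixel oversegmentation by seeded iterative clustering.

A VCCS-style scheme: seeds are placed on an even spatial grid of pitch
``rseed``, then alternating assign/update iterations cluster points (3D
mode) or pixels (2D mode) under the weighted dissimilarity

    D = sqrt(w_c * D_c^2  +  w_s * D_s^2 / (3 rseed)^2  +  w_g * D_g^2)

where D_c is Euclidean distance in CIE LAB, D_s is spatial distance
(metres in 3D, pixels in 2D) and D_g = 1 - |n_i . n_k| compares the
candidate's surface normal with the cluster's mean normal (identically 0
in 2D mode or when w_g = 0).  Assignment is restricted to a hard search
radius of 3 rseed around each cluster centroid; ties go to the lowest
cluster id.  The weight triple exposes the relative importance of color,
spatial and geometric similarity, which is what lets the 2D mode be
obtained from the 3D machinery by disabling the geometric channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import rgb2lab

from .data_model import PointCloud, RGBDImage


@dataclass(frozen=True)
class OversegParams:
    """Clustering resolution and distance weights.

    In 3D mode ``rseed``/``rvoxel`` are metres; in 2D mode ``rseed`` is
    pixels and ``rvoxel`` is unused.
    """

    mode: str = "3D"                  # "2D" | "3D"
    rseed: float = 0.012
    rvoxel: float = 0.002
    w_color: float = 0.004
    w_spatial: float = 1.0
    w_geometric: float = 0.5
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("2D", "3D"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "3D" and not self.rseed > self.rvoxel > 0:
            raise ValueError("3D mode requires rseed > rvoxel > 0")
        if self.mode == "2D" and self.rseed <= 0:
            raise ValueError("rseed must be positive")
        if min(self.w_color, self.w_spatial, self.w_geometric) < 0:
            raise ValueError("weights must be non-negative")
        if max(self.w_color, self.w_spatial, self.w_geometric) <= 0:
            raise ValueError("at least one weight must be positive")

    @staticmethod
    def defaults_2d(rseed: float = 15.0) -> "OversegParams":
        return OversegParams(mode="2D", rseed=rseed, w_color=0.004,
                             w_spatial=1.0, w_geometric=0.0)


@dataclass
class Oversegmentation:
    """Pixel -> superpixel map plus per-superpixel summary statistics.

    ``ids`` is -1 at pixels outside the clustered set (masked-out or
    no-depth).  Superpixel ids are compact, 0..n_segments-1.
    """

    ids: np.ndarray                     # H x W int32, -1 = unclustered
    n_segments: int
    centroid_px: np.ndarray             # S x 2, (row, col)
    mean_lab: np.ndarray                # S x 3
    centroid_xyz: Optional[np.ndarray] = None   # S x 3 (3D mode)
    mean_normal: Optional[np.ndarray] = None    # S x 3 (3D mode w/ normals)
    edges: Optional[np.ndarray] = None          # E x 2, a < b
    mode: str = "3D"
    rvoxel: float = 0.002
    point_xyz: Optional[np.ndarray] = None      # N x 3 (3D mode, for adjacency)
    point_pixel: Optional[np.ndarray] = None    # N x 2 matching point_xyz
    objective_history: list = field(default_factory=list)

    @property
    def member_counts(self) -> np.ndarray:
        valid = self.ids[self.ids >= 0]
        return np.bincount(valid, minlength=self.n_segments)

    def members(self, k: int) -> np.ndarray:
        """(row, col) members of superpixel k."""
        rr, cc = np.nonzero(self.ids == k)
        return np.column_stack([rr, cc])


def _grid_seeds_1d(lo: float, hi: float, pitch: float) -> np.ndarray:
    n = max(int(np.floor((hi - lo) / pitch)) + 1, 1)
    if n == 1:
        return np.array([(lo + hi) / 2])   # degenerate extent: centre node
    return lo + pitch / 2 + pitch * np.arange(n)


def _cluster(points: np.ndarray, lab: np.ndarray,
             normals: Optional[np.ndarray], params: OversegParams,
             spatial_dim: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                        Optional[np.ndarray], list]:
    """Core alternating clustering shared by the 2D and 3D modes.

    ``points`` are spatial coordinates (px or metres).  Returns
    (assignment, centroids, mean_lab, mean_normal, objective_history).
    """
    n = len(points)
    r3 = 3.0 * params.rseed
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    axes = [_grid_seeds_1d(lo[d], hi[d], params.rseed)
            for d in range(spatial_dim)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")],
                    axis=1)
    tree = cKDTree(points)
    # keep grid nodes with data nearby; initialize each seed at the
    # nearest data point
    dist, nearest = tree.query(grid, k=1)
    keep = dist <= params.rseed / 2
    if not keep.any():
        # degenerate extent: single seed at the first point
        seed_pts = np.array([0])
    else:
        seed_pts = np.unique(nearest[keep])
    centroids = points[seed_pts].astype(float)
    cen_lab = lab[seed_pts].astype(float)
    cen_nrm = normals[seed_pts].astype(float) if normals is not None else None

    use_geom = (params.w_geometric > 0 and normals is not None)
    assign = np.full(n, -1, dtype=np.int64)
    history: list = []
    n_cand = min(16, len(centroids))
    for _ in range(params.max_iterations):
        ctree = cKDTree(centroids)
        _, cand = ctree.query(points, k=n_cand)
        cand = cand.reshape(n, n_cand)
        # candidate columns sorted by cluster id so that argmin resolves
        # distance ties in favor of the lowest id
        cand = np.sort(cand, axis=1)
        ds2 = np.sum((points[:, None, :] - centroids[cand]) ** 2, axis=2)
        d2 = params.w_spatial * ds2 / r3 ** 2
        d2 += params.w_color * np.sum(
            (lab[:, None, :] - cen_lab[cand]) ** 2, axis=2)
        if use_geom:
            dg = 1.0 - np.abs(np.einsum("nd,nkd->nk", normals, cen_nrm[cand]))
            d2 += params.w_geometric * dg ** 2
        d2[ds2 > r3 ** 2] = np.inf      # hard 3*rseed assignment radius
        pick = np.argmin(d2, axis=1)
        best = d2[np.arange(n), pick]
        new_assign = cand[np.arange(n), pick]
        uncovered = ~np.isfinite(best)
        if uncovered.all():
            raise ValueError("all points farther than 3*rseed from every seed")
        if uncovered.any():
            # rare fallback: attach stragglers to the spatially nearest
            # centroid so every valid point receives an id
            _, near = ctree.query(points[uncovered], k=1)
            new_assign[uncovered] = np.atleast_1d(near)
        history.append(float(np.sum(best[np.isfinite(best)])))
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        # update step: per-cluster means
        counts = np.bincount(assign, minlength=len(centroids)).astype(float)
        nonzero = counts > 0
        for arr_src, arr_dst in ((points, centroids), (lab, cen_lab)):
            sums = np.zeros_like(arr_dst)
            for d in range(arr_src.shape[1]):
                sums[:, d] = np.bincount(assign, weights=arr_src[:, d],
                                         minlength=len(centroids))
            arr_dst[nonzero] = sums[nonzero] / counts[nonzero, None]
        if use_geom:
            sums = np.zeros_like(cen_nrm)
            for d in range(3):
                sums[:, d] = np.bincount(assign, weights=normals[:, d],
                                         minlength=len(centroids))
            norm = np.linalg.norm(sums, axis=1)
            ok = nonzero & (norm > 1e-12)
            cen_nrm[ok] = sums[ok] / norm[ok, None]

    # drop empty clusters, compact ids
    counts = np.bincount(assign, minlength=len(centroids))
    remap = -np.ones(len(centroids), dtype=np.int64)
    live = np.nonzero(counts > 0)[0]
    remap[live] = np.arange(len(live))
    assign = remap[assign]
    return (assign, centroids[live], cen_lab[live],
            cen_nrm[live] if cen_nrm is not None else None, history)


def oversegment(source, params: OversegParams,
                valid_mask: Optional[np.ndarray] = None) -> Oversegmentation:
    """Oversegment an RGBDImage (2D mode) or PointCloud (3D mode).

    2D mode clusters the pixel grid on LAB color + pixel position; 3D
    mode clusters the point cloud on LAB + metric position + normal
    alignment.  ``valid_mask`` optionally restricts 2D clustering to a
    pixel subset.  Adjacency edges are computed and stored.
    """
    if params.mode == "2D":
        if not isinstance(source, RGBDImage):
            raise TypeError("2D mode expects an RGBDImage")
        H, W = source.shape
        lab_img = rgb2lab(source.rgb)
        if valid_mask is None:
            valid_mask = np.ones((H, W), dtype=bool)
        rr, cc = np.nonzero(valid_mask)
        if len(rr) == 0:
            raise ValueError("empty input: no valid pixels")
        points = np.column_stack([rr, cc]).astype(float)
        lab = lab_img[rr, cc]
        assign, cen, cen_lab, _, hist = _cluster(points, lab, None, params, 2)
        ids = np.full((H, W), -1, dtype=np.int32)
        ids[rr, cc] = assign
        ids = _enforce_connectivity(ids)
        assign = ids[rr, cc].astype(np.int64)
        n_seg = int(assign.max()) + 1
        cen_px = _per_cluster_mean(assign, points, n_seg)
        mean_lab = _per_cluster_mean(assign, lab, n_seg)
        ov = Oversegmentation(ids=ids, n_segments=n_seg, centroid_px=cen_px,
                              mean_lab=mean_lab, mode="2D",
                              objective_history=hist)
    else:
        if not isinstance(source, PointCloud):
            raise TypeError("3D mode expects a PointCloud")
        cloud = source
        if len(cloud) == 0:
            raise ValueError("empty input: point cloud has no points")
        lab = rgb2lab(cloud.color.reshape(-1, 1, 3)).reshape(-1, 3)
        if valid_mask is not None:
            keep = valid_mask[cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]]
            if not keep.any():
                raise ValueError("empty input: no valid points")
        else:
            keep = np.ones(len(cloud), dtype=bool)
        pts = cloud.xyz[keep]
        labk = lab[keep]
        nrm = cloud.normals[keep] if cloud.normals is not None else None
        pix = cloud.pixel_index[keep]
        assign, cen, cen_lab, cen_nrm, hist = _cluster(
            pts, labk, nrm, params, 3)
        H, W = cloud.shape
        ids = np.full((H, W), -1, dtype=np.int32)
        ids[pix[:, 0], pix[:, 1]] = assign
        ids = _enforce_connectivity(ids)
        new_assign = ids[pix[:, 0], pix[:, 1]].astype(np.int64)
        if len(cen) == int(new_assign.max()) + 1:
            # orphan hand-off must respect the 3*rseed assignment radius;
            # violators (e.g. across a depth discontinuity) keep their
            # clustered id
            d = np.linalg.norm(pts - cen[new_assign], axis=1)
            revert = (d > 3 * params.rseed) & (new_assign != assign)
            new_assign[revert] = assign[revert]
            ids[pix[:, 0], pix[:, 1]] = new_assign
        assign = new_assign
        n_seg = int(assign.max()) + 1
        cen_px = _per_cluster_mean(assign, pix.astype(float), n_seg)
        mean_lab = _per_cluster_mean(assign, labk, n_seg)
        cen_xyz = _per_cluster_mean(assign, pts, n_seg)
        mean_normal = (_per_cluster_mean(assign, nrm, n_seg)
                       if nrm is not None else None)
        ov = Oversegmentation(ids=ids, n_segments=n_seg, centroid_px=cen_px,
                              mean_lab=mean_lab, centroid_xyz=cen_xyz,
                              mean_normal=mean_normal, mode="3D",
                              rvoxel=params.rvoxel, point_xyz=pts,
                              point_pixel=pix, objective_history=hist)
    ov.edges = build_adjacency(ov)
    return ov


def _enforce_connectivity(ids: np.ndarray) -> np.ndarray:
    """Keep each superpixel's largest 8-connected component and hand the
    orphaned fragment pixels to the nearest retained pixel's superpixel.

    Tiny fragments arise because per-pixel noise lets isolated pixels
    hop to a similar-colored cluster elsewhere in the search window; the
    cleanup restores (near-)contiguity, as is standard for SLIC-family
    methods.  Ids are compacted afterwards.
    """
    from scipy import ndimage
    from skimage.measure import label as cc_label

    valid = ids >= 0
    comp = cc_label(ids, background=-1, connectivity=2)
    comp_sizes = np.bincount(comp.ravel())
    # map each component to its superpixel id; find the largest per id
    flat_ids = ids.ravel()
    flat_comp = comp.ravel()
    n_comp = comp_sizes.size
    comp_to_id = np.full(n_comp, -1, dtype=np.int64)
    comp_to_id[flat_comp[flat_ids >= 0]] = flat_ids[flat_ids >= 0]
    keep_comp = np.zeros(n_comp, dtype=bool)
    for sp in np.unique(flat_ids[flat_ids >= 0]):
        comps = np.nonzero(comp_to_id == sp)[0]
        keep_comp[comps[np.argmax(comp_sizes[comps])]] = True
    kept = valid & keep_comp[comp]
    orphan = valid & ~kept
    if orphan.any():
        _, (ir, ic) = ndimage.distance_transform_edt(
            ~kept, return_indices=True)
        out = ids.copy()
        out[orphan] = ids[ir[orphan], ic[orphan]]
    else:
        out = ids
    # compact ids
    live = np.unique(out[out >= 0])
    remap = np.full(out.max() + 1 if out.max() >= 0 else 1, -1, dtype=np.int32)
    remap[live] = np.arange(len(live), dtype=np.int32)
    res = np.where(out >= 0, remap[np.clip(out, 0, None)], -1)
    return res.astype(np.int32)


def _per_cluster_mean(assign: np.ndarray, values: np.ndarray,
                      n_seg: int) -> np.ndarray:
    counts = np.bincount(assign, minlength=n_seg).astype(float)
    out = np.zeros((n_seg, values.shape[1]))
    for d in range(values.shape[1]):
        out[:, d] = np.bincount(assign, weights=values[:, d],
                                minlength=n_seg)
    return out / counts[:, None]


def build_adjacency(overseg: Oversegmentation) -> np.ndarray:
    """Adjacency edges between superpixels.

    2D mode: superpixels sharing an 8-connected pixel border.  3D mode:
    superpixels whose member points occupy the same or 26-connected
    voxels at resolution ``rvoxel``.  Returned as a sorted (E, 2) array
    of unordered pairs (a < b), no self-edges.
    """
    if overseg.mode == "2D" or overseg.point_xyz is None:
        return _adjacency_2d(overseg.ids)
    return _adjacency_voxel(overseg)


def _adjacency_2d(ids: np.ndarray) -> np.ndarray:
    H, W = ids.shape
    pairs = []
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:  # half the 8-neighborhood
        ra = slice(0, H - dr)
        rb = slice(dr, H)
        ca = slice(max(0, -dc), W - max(0, dc))
        cb = slice(max(0, dc), W - max(0, -dc))
        a = ids[ra, ca]
        b = ids[rb, cb]
        ok = (a >= 0) & (b >= 0) & (a != b)
        if ok.any():
            pairs.append(np.column_stack([a[ok], b[ok]]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    e = np.concatenate(pairs)
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _adjacency_voxel(overseg: Oversegmentation) -> np.ndarray:
    pts = overseg.point_xyz
    assign = overseg.ids[overseg.point_pixel[:, 0], overseg.point_pixel[:, 1]]
    vox = np.floor(pts / overseg.rvoxel).astype(np.int64)
    vox -= vox.min(axis=0)
    dims = vox.max(axis=0) + 3        # +1 slack each side for offsets
    key = (vox[:, 0] * dims[1] + vox[:, 1]) * dims[2] + vox[:, 2]
    occ = np.unique(np.column_stack([key, assign]), axis=0)
    okey, oseg = occ[:, 0], occ[:, 1]
    # okey is sorted; group boundaries give per-voxel seg lists
    starts = np.searchsorted(okey, okey, side="left")
    counts_at = np.searchsorted(okey, okey, side="right") - starts
    all_pairs = []
    # half-space of the 26-neighborhood plus the zero offset (co-occupancy)
    offsets = [(0, 0, 0)] + [o for o in [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
               if o > (0, 0, 0)]
    for off in offsets:
        dk = (off[0] * dims[1] + off[1]) * dims[2] + off[2]
        tkey = okey + dk
        pos = np.searchsorted(okey, tkey, side="left")
        pos_r = np.searchsorted(okey, tkey, side="right")
        m = pos_r > pos
        if not m.any():
            continue
        src = np.nonzero(m)[0]
        cnt = (pos_r - pos)[src]
        tot = int(cnt.sum())
        within = np.arange(tot) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        gather = np.repeat(pos[src], cnt) + within
        a = np.repeat(oseg[src], cnt)
        b = oseg[gather]
        keep = a != b
        if keep.any():
            all_pairs.append(np.column_stack([a[keep], b[keep]]))
    if not all_pairs:
        return np.empty((0, 2), dtype=np.int64)
    e = np.concatenate(all_pairs)
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)
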