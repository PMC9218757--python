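"""SLIC superpixel partition and per-block color features.

The RGB image is converted to CIE L*a*b* and partitioned into compact
blocks by localized k-means over the combined distance

    Dis = sqrt(dc^2 + (ds/S)^2 * m^2)

with ``dc`` the Lab color distance, ``ds`` the spatial distance, ``S`` the
seed grid step (S = round(sqrt(N/k))) and ``m`` the compactness weight in
Lab units.  Each block then contributes one feature point — its mean R-B
and mean G-B over the ORIGINAL RGB channels — which is what the clustering
stage consumes: the blue channel carries little fruit/foliage contrast, so
these two differences spread near-color green fruit away from the
background far better than raw RGB does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, measure

from .errors import InputError, InternalConsistencyError, ParameterError
from .rgbd_io import RgbImage


@dataclass(frozen=True)
class LabImage:
    l: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.l.shape


@dataclass
class SlicParams:
    """k: target block count; m: compactness (Lab units); max_iter cap."""

    k: int = 600
    m: float = 10.0
    max_iter: int = 10
    min_fragment_divisor: int = 16  # fragments below S^2/divisor get merged

    def __post_init__(self):
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.m <= 0:
            raise ParameterError("m must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")

    def grid_step(self, n_pixels: int) -> int:
        """S = round(sqrt(N / k))."""
        return max(1, int(round(np.sqrt(n_pixels / self.k))))


@dataclass(frozen=True)
class BlockSet:
    """A total partition of the image into labeled blocks.

    ``features`` holds per-block (mean R-B, mean G-B) in signed intensity
    units (None until :func:`block_features` fills it); centroids are
    (row, col); sizes are pixel counts.
    """

    labels: np.ndarray
    block_centroids: np.ndarray
    block_sizes: np.ndarray
    block_features: np.ndarray | None = None

    def __post_init__(self):
        if self.block_sizes.sum() != self.labels.size:
            raise InternalConsistencyError("block sizes do not tile the image")

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


def rgb_to_lab(rgb: RgbImage) -> LabImage:
    """sRGB -> CIE L*a*b* under D65."""
    lab = color.rgb2lab(rgb.array / 255.0)
    return LabImage(l=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def _seed_grid(h: int, w: int, step: int) -> np.ndarray:
    rows = np.arange(step // 2, h, step)
    cols = np.arange(step // 2, w, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.int64)


def _perturb_seeds(seeds: np.ndarray, grad_mag: np.ndarray) -> np.ndarray:
    """Move each seed to the lowest-gradient pixel of its 3x3 neighborhood."""
    h, w = grad_mag.shape
    out = seeds.copy()
    for i, (r, c) in enumerate(seeds):
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        win = grad_mag[r0:r1, c0:c1]
        dr, dc = np.unravel_index(np.argmin(win), win.shape)
        out[i] = (r0 + dr, c0 + dc)
    return out


def slic_segment(lab: LabImage, params: SlicParams, seed: int = 0) -> BlockSet:
    """Partition a Lab image into ~k compact blocks.

    Fully deterministic; the ``seed`` argument exists for interface
    symmetry with the stochastic stages and is unused.  Iteration stops
    after ``max_iter`` rounds or when no center moves by >= 0.5 px.
    Disconnected fragments smaller than S^2/16 are merged into an adjacent
    block so the partition is usable downstream.
    """
    h, w = lab.shape
    n = h * w
    if params.k > n // 4:
        raise ParameterError(f"k={params.k} too large for {n} pixels")
    step = params.grid_step(n)

    gy, gx = np.gradient(lab.l)
    grad_mag = np.hypot(gx, gy)
    seeds = _perturb_seeds(_seed_grid(h, w, step), grad_mag)

    feats = np.stack([lab.l, lab.a, lab.b], axis=-1)
    centers_color = feats[seeds[:, 0], seeds[:, 1]].astype(np.float64)
    centers_pos = seeds.astype(np.float64)
    n_centers = len(seeds)
    weight = (params.m / step) ** 2

    labels = np.full((h, w), -1, dtype=np.int64)
    rows = np.arange(h)
    cols = np.arange(w)

    for _ in range(params.max_iter):
        best = np.full((h, w), np.inf)
        labels.fill(-1)
        for ci in range(n_centers):
            cr, cc_ = centers_pos[ci]
            r0 = max(int(cr) - step, 0)
            r1 = min(int(cr) + step + 1, h)
            c0 = max(int(cc_) - step, 0)
            c1 = min(int(cc_) + step + 1, w)
            win = feats[r0:r1, c0:c1]
            dc2 = ((win - centers_color[ci]) ** 2).sum(axis=-1)
            ds2 = ((rows[r0:r1, None] - cr) ** 2
                   + (cols[None, c0:c1] - cc_) ** 2)
            dis2 = dc2 + ds2 * weight  # Dis^2; sqrt is monotonic
            sub_best = best[r0:r1, c0:c1]
            better = dis2 < sub_best
            sub_best[better] = dis2[better]
            labels[r0:r1, c0:c1][better] = ci

        orphan = labels < 0
        if orphan.any():
            orows, ocols = np.nonzero(orphan)
            d2 = ((orows[:, None] - centers_pos[None, :, 0]) ** 2
                  + (ocols[:, None] - centers_pos[None, :, 1]) ** 2)
            labels[orows, ocols] = d2.argmin(axis=1)

        counts = np.bincount(labels.ravel(), minlength=n_centers)
        occupied = counts > 0
        new_pos = centers_pos.copy()
        new_color = centers_color.copy()
        flat = labels.ravel()
        rr = np.repeat(rows, w)
        cc2 = np.tile(cols, h)
        new_pos[occupied, 0] = (np.bincount(flat, weights=rr,
                                            minlength=n_centers)[occupied]
                                / counts[occupied])
        new_pos[occupied, 1] = (np.bincount(flat, weights=cc2,
                                            minlength=n_centers)[occupied]
                                / counts[occupied])
        for ch in range(3):
            new_color[occupied, ch] = (
                np.bincount(flat, weights=feats[..., ch].ravel(),
                            minlength=n_centers)[occupied] / counts[occupied])
        movement = np.hypot(*(new_pos - centers_pos).T).max()
        centers_pos, centers_color = new_pos, new_color
        if movement < 0.5:
            break

    labels = _enforce_connectivity(
        labels, step * step // params.min_fragment_divisor)
    return _build_blockset(labels)


def _enforce_connectivity(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge small disconnected fragments into an adjacent block."""
    comps = measure.label(labels, connectivity=1, background=-2)
    n_comps = comps.max()
    sizes = np.bincount(comps.ravel(), minlength=n_comps + 1)
    comp_block = np.full(n_comps + 1, -1, dtype=np.int64)
    comp_block[comps.ravel()] = labels.ravel()
    # keep the largest component of each block untouched
    keep = np.zeros(n_comps + 1, dtype=bool)
    keep[0] = True
    for block in np.unique(labels):
        members = np.nonzero(comp_block == block)[0]
        if len(members):
            keep[members[np.argmax(sizes[members])]] = True
    keep |= sizes >= max(min_size, 1)

    out = labels.copy()
    objects = ndimage.find_objects(comps)
    h, w = labels.shape
    for comp_id in np.nonzero(~keep)[0]:
        sl = objects[comp_id - 1]
        if sl is None:
            continue
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, h)
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, w)
        sub = comps[r0:r1, c0:c1] == comp_id
        ring = ndimage.binary_dilation(
            sub, structure=np.ones((3, 3), dtype=bool)) & ~sub
        neighbor_labels = out[r0:r1, c0:c1][ring]
        neighbor_labels = neighbor_labels[neighbor_labels >= 0]
        if len(neighbor_labels) == 0:
            continue
        vals, cnts = np.unique(neighbor_labels, return_counts=True)
        out[r0:r1, c0:c1][sub] = vals[np.argmax(cnts)]
    return out


def _build_blockset(labels: np.ndarray) -> BlockSet:
    _, dense = np.unique(labels, return_inverse=True)
    dense = dense.reshape(labels.shape)
    nb = dense.max() + 1
    flat = dense.ravel()
    sizes = np.bincount(flat, minlength=nb)
    h, w = labels.shape
    rr = np.repeat(np.arange(h), w)
    cc = np.tile(np.arange(w), h)
    centroids = np.stack([
        np.bincount(flat, weights=rr, minlength=nb) / sizes,
        np.bincount(flat, weights=cc, minlength=nb) / sizes,
    ], axis=1)
    return BlockSet(labels=dense, block_centroids=centroids,
                    block_sizes=sizes)


def block_features(labels: np.ndarray, rgb: RgbImage) -> BlockSet:
    """Fill per-block (mean R-B, mean G-B) features from the raw RGB image.

    Signed values are retained (range -255..255).
    """
    if labels.shape != rgb.shape:
        raise InputError("labels and RGB image shapes differ")
    blocks = _build_blockset(labels)
    flat = blocks.labels.ravel()
    nb = blocks.n_blocks
    if np.any(blocks.block_sizes == 0):
        raise InternalConsistencyError("empty block id in partition")
    r = rgb.r.astype(np.float64).ravel()
    g = rgb.g.astype(np.float64).ravel()
    b = rgb.b.astype(np.float64).ravel()
    rb = np.bincount(flat, weights=r - b, minlength=nb) / blocks.block_sizes
    gb = np.bincount(flat, weights=g - b, minlength=nb) / blocks.block_sizes
    feats = np.stack([rb, gb], axis=1)
    return BlockSet(labels=blocks.labels,
                    block_centroids=blocks.block_centroids,
                    block_sizes=blocks.block_sizes,
                    block_features=feats)
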