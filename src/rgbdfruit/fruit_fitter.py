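"""Fuse depth-derived centers with the segmented cluster map into circles.

The connected component of the cluster map that contains a detected center
is taken as that fruit's region.  The radius comes from the center-to-
boundary distance profile: for an isolated fruit the profile maximum (the
unoccluded directions still reach the full rim); when several centers
share one component (overlapping fruit) the minimum over the profile's
local maxima, which picks each fruit's own rim rather than the partner's
far side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .center_locator import CenterSet
from .errors import InputError
from .rgbd_io import FruitDetection, PipelineConfig
from .superpixels import BlockSet


@dataclass(frozen=True)
class RegionMask:
    """One 8-connected component of the fruit-containing cluster."""

    mask: np.ndarray
    region_id: int

    def __post_init__(self):
        if not self.mask.any():
            raise InputError("region mask is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BoundaryProfile:
    """Distance from a center to the region boundary per sample angle."""

    angles: np.ndarray
    radii: np.ndarray


@dataclass(frozen=True)
class MatchedCenter:
    center: tuple
    region: RegionMask
    overlap_flag: bool
    omega_value: float = 0.0


@dataclass
class DetectionMetrics:
    n_truth: int
    n_detections: int
    n_matched: int
    recognition_rate: float
    per_category: dict
    mean_center_error_px: float
    mean_radius_error_rel: float
    matches: list = field(default_factory=list)


def match_centers_to_regions(centers: CenterSet, cluster_labels: np.ndarray,
                             blocks: BlockSet,
                             min_region_px: int = 150,
                             max_region_fraction: float = 0.30
                             ) -> list[MatchedCenter]:
    """Pair each detected center with the connected component of its
    cluster.

    The per-block cluster labels are painted onto pixels through the block
    label map, split into 8-connected components, and each center claims
    the component under its pixel.  Components that are implausible as
    fruit — larger than ``max_region_fraction`` of the image (a background
    cluster) or smaller than ``min_region_px`` — drop their centers.
    Multiple centers sharing one component are all flagged overlapping.
    """
    cluster_map = np.asarray(cluster_labels)[blocks.labels]
    comps = measure.label(cluster_map, connectivity=2, background=-1)
    n_px = cluster_map.size
    by_comp: dict[int, list] = {}
    for row, col, omega in centers.centers:
        comp_id = int(comps[row, col])
        if comp_id == 0:  # center on an unassigned pixel
            continue
        by_comp.setdefault(comp_id, []).append((row, col, omega))
    out: list[MatchedCenter] = []
    for comp_id, members in sorted(by_comp.items()):
        mask = comps == comp_id
        area = int(mask.sum())
        if area < min_region_px or area > max_region_fraction * n_px:
            continue
        region = RegionMask(mask=mask, region_id=comp_id)
        overlap = len(members) > 1
        for row, col, omega in members:
            out.append(MatchedCenter(center=(row, col), region=region,
                                     overlap_flag=overlap,
                                     omega_value=omega))
    return out


def boundary_profile(region: RegionMask, center: tuple,
                     n_angles: int = 360) -> BoundaryProfile:
    """Ray-march from the center along uniform angles; the radius at each
    angle is the distance at which the ray first leaves the mask."""
    row0, col0 = center
    mask = region.mask
    h, w = mask.shape
    r_i, c_i = int(round(row0)), int(round(col0))
    if not (0 <= r_i < h and 0 <= c_i < w) or not mask[r_i, c_i]:
        raise InputError("center lies outside the region mask")
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    max_r = float(np.hypot(h, w))
    steps = np.arange(0.0, max_r, 0.5)
    rr = row0 + np.outer(np.sin(angles), steps)
    cc = col0 + np.outer(np.cos(angles), steps)
    rri = np.clip(np.round(rr).astype(np.int64), 0, h - 1)
    cci = np.clip(np.round(cc).astype(np.int64), 0, w - 1)
    inside = mask[rri, cci]
    inside &= (rr >= -0.5) & (rr <= h - 0.5) & (cc >= -0.5) & (cc <= w - 0.5)
    first_out = np.argmin(inside, axis=1)
    # argmin returns 0 when the ray never leaves (all True): cap at max_r
    never_leaves = inside.all(axis=1)
    radii = steps[first_out]
    radii[never_leaves] = max_r
    return BoundaryProfile(angles=angles, radii=radii)


def radius_single(profile: BoundaryProfile) -> float:
    """Maximum-value rule for an isolated fruit: the profile maximum."""
    return float(profile.radii.max())


def radius_overlap(profile: BoundaryProfile,
                   min_separation: float = np.deg2rad(10.0)) -> float:
    """Minimum-of-maxima rule for overlapping fruit.

    The circular profile is smoothed with a moving average of half-width
    ``min_separation``; local maxima (plateau runs included) are found and
    the smallest maximum is returned.  A profile with no local structure
    (constant) falls back to the plain maximum rule.
    """
    radii = profile.radii
    n = len(radii)
    half = max(1, int(round(min_separation / (2.0 * np.pi) * n)))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    padded = np.concatenate([radii[-half:], radii, radii[:half]])
    smoothed = np.convolve(padded, kernel, mode="same")[half:half + n]

    ge_prev = smoothed >= np.roll(smoothed, 1)
    ge_next = smoothed >= np.roll(smoothed, -1)
    cand = ge_prev & ge_next
    if cand.all() or not cand.any():
        return radius_single(profile)
    # group circularly-contiguous candidate runs into single peaks
    start = int(np.argmin(cand))  # a non-candidate index to anchor runs
    rolled = np.roll(cand, -start)
    peak_values = []
    run_members: list[int] = []
    for offset in range(n):
        if rolled[offset]:
            run_members.append((start + offset) % n)
        elif run_members:
            peak_values.append(max(radii[i] for i in run_members))
            run_members = []
    if run_members:
        peak_values.append(max(radii[i] for i in run_members))
    if not peak_values:
        return radius_single(profile)
    return float(min(peak_values))


def fit_detections(matched: list[MatchedCenter], config: PipelineConfig,
                   image: str = "") -> list[FruitDetection]:
    """Emit a fitted circle per matched center, choosing the radius rule
    by the overlap flag."""
    detections = []
    min_sep = np.deg2rad(config.overlap_min_separation_deg)
    # circles smaller than the domain's smallest plausible fruit are stray
    # centers near a region edge, not fruit
    for m in matched:
        profile = boundary_profile(m.region, m.center, config.n_angles)
        if m.overlap_flag:
            radius = radius_overlap(profile, min_sep)
        else:
            radius = radius_single(profile)
        if radius < config.min_radius_px:
            continue
        detections.append(FruitDetection(
            center=(float(m.center[0]), float(m.center[1])),
            radius=radius, region_id=m.region.region_id,
            overlap_flag=m.overlap_flag, image=image))
    return detections


def circle_iou(c1: tuple, r1: float, c2: tuple, r2: float) -> float:
    """Exact intersection-over-union of two discs."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    a1, a2 = np.pi * r1 ** 2, np.pi * r2 ** 2
    if d >= r1 + r2:
        inter = 0.0
    elif d <= abs(r1 - r2):
        inter = min(a1, a2)
    else:
        alpha = np.arccos(np.clip((d ** 2 + r1 ** 2 - r2 ** 2)
                                  / (2 * d * r1), -1, 1))
        beta = np.arccos(np.clip((d ** 2 + r2 ** 2 - r1 ** 2)
                                 / (2 * d * r2), -1, 1))
        inter = (r1 ** 2 * (alpha - np.sin(2 * alpha) / 2)
                 + r2 ** 2 * (beta - np.sin(2 * beta) / 2))
    union = a1 + a2 - inter
    return float(inter / union) if union > 0 else 0.0


def draw_detections(rgb, detections: list[FruitDetection],
                    color=(255, 60, 40)) -> np.ndarray:
    """Overlay fitted circles and center marks on an RGB frame; returns a
    new (H, W, 3) uint8 array."""
    from skimage.draw import circle_perimeter, disk

    canvas = rgb.array.copy()
    shape = canvas.shape[:2]
    for det in detections:
        r, c = int(round(det.center[0])), int(round(det.center[1]))
        for thick in (0, 1):
            rr, cc = circle_perimeter(r, c, max(int(round(det.radius)) - thick,
                                                1), shape=shape)
            canvas[rr, cc] = color
        rr, cc = disk((r, c), 3, shape=shape)
        canvas[rr, cc] = color
    return canvas


def evaluate_detections(detections: list[FruitDetection], ground_truth: list,
                        iou_threshold: float = 0.5) -> DetectionMetrics:
    """Score detections against ground-truth circles.

    A detection matches a truth circle when the detected center lies
    inside the truth circle and the circle IoU is at least
    ``iou_threshold``; matching is greedy one-to-one by descending IoU.
    Ground-truth entries need ``center``, ``radius`` and (optionally)
    ``category`` attributes.  Reports the recognition rate overall and per
    category, plus mean center error (px) and mean relative radius error
    over the matched pairs.
    """
    pairs = []
    for di, det in enumerate(detections):
        for ti, truth in enumerate(ground_truth):
            dist = np.hypot(det.center[0] - truth.center[0],
                            det.center[1] - truth.center[1])
            if dist > truth.radius:
                continue
            iou = circle_iou(det.center, det.radius, truth.center,
                             truth.radius)
            if iou >= iou_threshold:
                pairs.append((iou, di, ti))
    pairs.sort(key=lambda t: -t[0])
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for iou, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((di, ti, iou))

    cats: dict[str, list[int]] = {}
    for ti, truth in enumerate(ground_truth):
        cats.setdefault(getattr(truth, "category", "all"), []).append(ti)
    per_category = {}
    for cat, tis in sorted(cats.items()):
        matched = sum(1 for _, ti, _ in matches if ti in tis)
        per_category[cat] = {"n_truth": len(tis), "n_matched": matched,
                             "rate": matched / len(tis)}

    if matches:
        center_errors = []
        radius_errors = []
        for di, ti, _ in matches:
            det, truth = detections[di], ground_truth[ti]
            center_errors.append(np.hypot(det.center[0] - truth.center[0],
                                          det.center[1] - truth.center[1]))
            radius_errors.append(abs(det.radius - truth.radius)
                                 / truth.radius)
        mean_center = float(np.mean(center_errors))
        mean_radius = float(np.mean(radius_errors))
    else:
        mean_center = float("nan")
        mean_radius = float("nan")

    n_truth = len(ground_truth)
    return DetectionMetrics(
        n_truth=n_truth,
        n_detections=len(detections),
        n_matched=len(matches),
        recognition_rate=len(matches) / n_truth if n_truth else float("nan"),
        per_category=per_category,
        mean_center_error_px=mean_center,
        mean_radius_error_rel=mean_radius,
        matches=matches,
    )


def evaluate_scenes(scene_pairs: list, iou_threshold: float = 0.5
                    ) -> DetectionMetrics:
    """Score many scenes: match within each scene, aggregate the counts.

    ``scene_pairs`` is a list of (detections, ground_truth) tuples, one per
    scene; matching never crosses scene boundaries.
    """
    per_scene = [evaluate_detections(dets, truths, iou_threshold)
                 for dets, truths in scene_pairs]
    n_truth = sum(m.n_truth for m in per_scene)
    n_matched = sum(m.n_matched for m in per_scene)
    per_category: dict[str, dict] = {}
    for m in per_scene:
        for cat, row in m.per_category.items():
            agg = per_category.setdefault(cat, {"n_truth": 0, "n_matched": 0})
            agg["n_truth"] += row["n_truth"]
            agg["n_matched"] += row["n_matched"]
    for row in per_category.values():
        row["rate"] = row["n_matched"] / row["n_truth"]
    center_errs = [m.mean_center_error_px * m.n_matched for m in per_scene
                   if m.n_matched]
    radius_errs = [m.mean_radius_error_rel * m.n_matched for m in per_scene
                   if m.n_matched]
    return DetectionMetrics(
        n_truth=n_truth,
        n_detections=sum(m.n_detections for m in per_scene),
        n_matched=n_matched,
        recognition_rate=n_matched / n_truth if n_truth else float("nan"),
        per_category=dict(sorted(per_category.items())),
        mean_center_error_px=(sum(center_errs) / n_matched
                              if n_matched else float("nan")),
        mean_radius_error_rel=(sum(radius_errs) / n_matched
                               if n_matched else float("nan")),
    )
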