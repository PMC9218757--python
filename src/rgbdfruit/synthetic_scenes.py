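"""Synthetic RGB-D orchard scenes with exact ground truth.

Emulates the acquisition conditions the pipeline is designed for: green
spherical fruit in front of a foliage background of nearly the same color,
viewed by a range camera (nearer surface = smaller depth value, in mm,
0 = hole).  Geometry is orthographic with a fixed mm-per-pixel scale — the
only depth property the algorithm exploits is that a fruit is a convex
bowl with its minimum at the center, which this projection preserves.

Every scene is deterministic in its seed and carries ground-truth circles
with a category per fruit: ``single`` (unobstructed), ``occluded``
(a branch/leaf primitive crosses the fruit), ``overlapping`` (fruit discs
intersect).  Categories are recomputable from the geometry alone.

Realism choices (see docs/methods.md for rationale): scenes are close-range
frames in which each fruit spans a large part of the image, as in
harvesting imagery; fruit gets mild Lambertian limb darkening plus skin
mottle; the canopy background is bimodal (sunlit leaf faces vs deep
interior shadow) with independent leaf-to-leaf hue and redness variation,
over a rippled depth plane so the background gradient field is irregular;
fruit, leaf and branch mean colors differ by at most 15 intensity units
per channel (the near-color condition that makes color-only segmentation
genuinely hard).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError
from .rgbd_io import DepthImage, RgbImage

CATEGORIES = ("single", "occluded", "overlapping")
DEFAULT_MIX = (0.55, 0.17, 0.28)

# mean colors (R, G, B): fruit differs from foliage and branch means by at
# most 15 intensity units per channel (near-color condition)
FRUIT_COLOR = (95.0, 130.0, 55.0)
FOLIAGE_COLOR = (82.0, 117.0, 68.0)
BRANCH_COLOR = (100.0, 118.0, 68.0)


@dataclass(frozen=True)
class FruitSpec:
    """One spherical fruit: image-plane center, radius (px), sphere-center
    depth (mm)."""

    row: float
    col: float
    radius_px: float
    depth_mm: float


@dataclass(frozen=True)
class OccluderSpec:
    """A branch/leaf primitive: a rotated rectangle ('branch') or ellipse
    ('leaf') lying between the fruit and the camera."""

    kind: str  # "branch" | "leaf"
    row: float
    col: float
    length: float   # half-length along the main axis (px)
    width: float    # half-width across it (px)
    angle: float    # radians
    depth_mm: float


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; rendering is a pure function
    of this object."""

    width: int = 512
    height: int = 424
    fruits: list = field(default_factory=list)
    occluders: list = field(default_factory=list)
    background_depth: float = 2600.0
    background_ripple_mm: float = 25.0
    mm_per_px: float = 2.0
    fruit_color_mean: tuple = FRUIT_COLOR
    background_color_mean: tuple = FOLIAGE_COLOR
    branch_color_mean: tuple = BRANCH_COLOR
    color_noise_sd: float = 7.0
    depth_noise_sd: float = 5.0
    hole_fraction: float = 0.05
    fruit_shade_floor: float = 0.88   # diffuse daylight: mild limb darkening
    fruit_texture_sd: float = 0.04    # skin mottle/lenticels (fractional)
    # canopy illumination is bimodal: sunlit leaf faces vs deep interior
    # shadow; brightness interpolates between the two through a sigmoid of a
    # smooth field, and an independent hue field shifts the green channel
    foliage_shadow_level: float = 0.35
    foliage_lit_level: float = 1.25
    foliage_bimodality: float = 2.0
    foliage_hue_sd: float = 8.0
    foliage_red_sd: float = 3.0   # leaf-to-leaf redness variation (intensity)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.hole_fraction <= 0.2):
            raise ParameterError("hole_fraction must be in [0, 0.2]")
        for f in self.fruits:
            if f.radius_px < 10:
                raise InputError("fruit radii must be >= 10 px")
            if not (0 <= f.row < self.height and 0 <= f.col < self.width):
                raise InputError(f"fruit center {(f.row, f.col)} out of bounds")
            if f.depth_mm >= self.background_depth:
                raise InputError("fruit must be nearer than the background")


@dataclass(frozen=True)
class GroundTruthFruit:
    center: tuple  # (row, col)
    radius: float
    category: str


@dataclass(frozen=True)
class SyntheticScene:
    rgb: RgbImage
    depth: DepthImage
    truth: list  # of GroundTruthFruit
    spec: SceneSpec

    def truth_dicts(self) -> list[dict]:
        return [
            {"center_y": t.center[0], "center_x": t.center[1],
             "radius_px": t.radius, "category": t.category}
            for t in self.truth
        ]


def categorize_fruits(spec: SceneSpec) -> list[str]:
    """Ground-truth category per fruit, from geometry alone.

    Intersecting fruit discs -> both ``overlapping`` (dominant); otherwise
    an occluder primitive crossing the disc -> ``occluded``; else
    ``single``.
    """
    cats = []
    for i, f in enumerate(spec.fruits):
        overlapping = any(
            np.hypot(f.row - g.row, f.col - g.col) < f.radius_px + g.radius_px
            for j, g in enumerate(spec.fruits) if j != i
        )
        if overlapping:
            cats.append("overlapping")
            continue
        occluded = any(_occluder_hits_fruit(o, f) for o in spec.occluders)
        cats.append("occluded" if occluded else "single")
    return cats


def _occluder_frame(o: OccluderSpec, rows: np.ndarray, cols: np.ndarray):
    dr = rows - o.row
    dc = cols - o.col
    ca, sa = np.cos(o.angle), np.sin(o.angle)
    along = dc * ca + dr * sa
    across = -dc * sa + dr * ca
    return along, across


def _occluder_mask(o: OccluderSpec, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    along, across = _occluder_frame(o, rr, cc)
    if o.kind == "branch":
        return (np.abs(along) <= o.length) & (np.abs(across) <= o.width)
    return (along / o.length) ** 2 + (across / o.width) ** 2 <= 1.0


def _occluder_hits_fruit(o: OccluderSpec, f: FruitSpec) -> bool:
    # sample the fruit disc on a coarse polar grid and test membership
    ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    rad = np.linspace(0, f.radius_px, 12)
    rr = f.row + np.outer(rad, np.sin(ang)).ravel()
    cc = f.col + np.outer(rad, np.cos(ang)).ravel()
    along, across = _occluder_frame(o, rr, cc)
    if o.kind == "branch":
        inside = (np.abs(along) <= o.length) & (np.abs(across) <= o.width)
    else:
        inside = (along / o.length) ** 2 + (across / o.width) ** 2 <= 1.0
    return bool(inside.any())


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance low-frequency noise field."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene spec to (rgb, depth, truth), deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")

    # --- depth buffer: background plane + ripple, then nearest surface wins
    ripple = _smooth_noise(rng, (h, w), 40.0) * spec.background_ripple_mm
    depth = spec.background_depth + ripple
    surface = np.zeros((h, w), dtype=np.int32)  # 0 bg, i+1 fruit i, -j-1 occluder j
    shade = np.ones((h, w))

    for i, f in enumerate(spec.fruits):
        d2 = (rr - f.row) ** 2 + (cc - f.col) ** 2
        inside = d2 < f.radius_px ** 2
        bulge = np.zeros_like(depth)
        bulge[inside] = np.sqrt(f.radius_px ** 2 - d2[inside])
        sphere = f.depth_mm - spec.mm_per_px * bulge
        nearer = inside & (sphere < depth)
        depth[nearer] = sphere[nearer]
        surface[nearer] = i + 1
        # Lambertian-ish shading: brightest where the surface faces the camera
        nz = bulge[nearer] / f.radius_px
        lo = spec.fruit_shade_floor
        shade[nearer] = lo + (1.0 - lo) * nz
    if spec.fruit_texture_sd > 0 and spec.fruits:
        # skin mottle: smooth multiplicative field over the fruit surface
        mottle = 1.0 + spec.fruit_texture_sd * _smooth_noise(rng, (h, w), 10.0)
        on_fruit = surface > 0
        shade[on_fruit] *= np.clip(mottle[on_fruit], 0.7, 1.3)

    for j, o in enumerate(spec.occluders):
        mask = _occluder_mask(o, (h, w)) & (o.depth_mm < depth)
        depth[mask] = o.depth_mm
        surface[mask] = -j - 1

    # --- RGB from the visibility buffer
    rgb = np.empty((h, w, 3))
    from scipy.special import expit
    lo, hi = spec.foliage_shadow_level, spec.foliage_lit_level
    brightness = lo + (hi - lo) * expit(
        spec.foliage_bimodality * _smooth_noise(rng, (h, w), 12.0))
    hue_shift = spec.foliage_hue_sd * _smooth_noise(rng, (h, w), 12.0)
    red_shift = spec.foliage_red_sd * _smooth_noise(rng, (h, w), 12.0)
    for ch in range(3):
        col = np.full((h, w), spec.background_color_mean[ch]) * brightness
        if ch == 1:
            col += hue_shift
        elif ch == 0:
            col += red_shift
        for i, f in enumerate(spec.fruits):
            sel = surface == i + 1
            col[sel] = spec.fruit_color_mean[ch] * shade[sel]
        for j, o in enumerate(spec.occluders):
            sel = surface == -j - 1
            base = spec.branch_color_mean[ch] * (
                1.0 + 0.4 * (brightness[sel] - 1.0))
            col[sel] = base + (hue_shift[sel] if ch == 1 else 0.0)
        rgb[..., ch] = col
    rgb += rng.normal(0.0, spec.color_noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    # --- sensor noise and holes
    if spec.depth_noise_sd > 0:
        depth = depth + rng.normal(0.0, spec.depth_noise_sd, size=depth.shape)
    depth = np.maximum(depth, 1.0)
    holes = rng.random(depth.shape) < spec.hole_fraction
    depth[holes] = 0.0

    cats = categorize_fruits(spec)
    truth = [GroundTruthFruit(center=(f.row, f.col), radius=f.radius_px,
                              category=cat)
             for f, cat in zip(spec.fruits, cats)]
    return SyntheticScene(rgb=RgbImage(rgb), depth=DepthImage.from_raw(depth),
                          truth=truth, spec=spec)


DEFAULT_RADIUS_FRACTIONS = (0.22, 0.27)  # of the frame's short side


def _random_fruit(rng: np.random.Generator, w: int, h: int,
                  background_depth: float,
                  radius_range=None) -> FruitSpec:
    if radius_range is None:
        m = min(w, h)
        radius_range = (DEFAULT_RADIUS_FRACTIONS[0] * m,
                        DEFAULT_RADIUS_FRACTIONS[1] * m)
    radius = rng.uniform(*radius_range)
    margin = radius + 15.0
    row = rng.uniform(margin, h - margin)
    col = rng.uniform(margin, w - margin)
    depth_mm = rng.uniform(0.5, 0.8) * background_depth
    return FruitSpec(row=row, col=col, radius_px=radius, depth_mm=depth_mm)


def make_scene_spec(category: str, seed: int, width: int = 512,
                    height: int = 424, **overrides) -> SceneSpec:
    """Randomized scene geometry for one ground-truth category."""
    if category not in CATEGORIES:
        raise ParameterError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    background_depth = rng.uniform(2300.0, 2900.0)
    fruits: list[FruitSpec] = []
    occluders: list[OccluderSpec] = []

    if category == "single":
        fruits.append(_random_fruit(rng, width, height, background_depth))
    elif category == "occluded":
        f = _random_fruit(rng, width, height, background_depth)
        fruits.append(f)
        # a branch crossing a chord of the fruit, away from its center so
        # the central vortex stays visible
        offset = rng.uniform(0.35, 0.75) * f.radius_px
        angle = rng.uniform(0, np.pi)
        occluders.append(OccluderSpec(
            kind="branch",
            row=f.row + offset * np.cos(angle),
            col=f.col - offset * np.sin(angle),
            length=f.radius_px * rng.uniform(1.5, 2.5),
            width=rng.uniform(5.0, 12.0),
            angle=angle,
            depth_mm=f.depth_mm - f.radius_px * 2.0 - rng.uniform(40.0, 120.0),
        ))
    else:  # overlapping
        f1 = _random_fruit(rng, width, height, background_depth)
        m = min(width, height)
        r2 = rng.uniform(DEFAULT_RADIUS_FRACTIONS[0] * m,
                         DEFAULT_RADIUS_FRACTIONS[1] * m)
        sep = rng.uniform(0.62, 0.92) * (f1.radius_px + r2)
        sep = max(sep, abs(f1.radius_px - r2) + 12.0)
        # place the partner at the drawn separation; rotate (and as a last
        # resort shrink sep slightly) until it fits the frame, so clipping
        # never collapses the pair into near-coincidence
        margin = r2 + 15.0
        row2 = col2 = None
        for _ in range(128):
            ang = rng.uniform(0, 2 * np.pi)
            cand_row = f1.row + sep * np.sin(ang)
            cand_col = f1.col + sep * np.cos(ang)
            if (margin <= cand_row <= height - margin
                    and margin <= cand_col <= width - margin):
                row2, col2 = float(cand_row), float(cand_col)
                break
            sep = max(sep * 0.99, 0.55 * (f1.radius_px + r2))
        if row2 is None:  # extremely cramped frame: place beside fruit 1
            row2 = float(np.clip(f1.row, margin, height - margin))
            col2 = float(np.clip(f1.col + sep, margin, width - margin))
        depth2 = f1.depth_mm + rng.uniform(-40.0, 40.0)
        fruits = [f1, FruitSpec(row=row2, col=col2, radius_px=r2,
                                depth_mm=depth2)]

    spec = SceneSpec(width=width, height=height, fruits=fruits,
                     occluders=occluders, background_depth=background_depth,
                     seed=int(rng.integers(0, 2 ** 31)))
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise ParameterError(f"unknown SceneSpec field {key!r}")
        setattr(spec, key, value)
    return spec


def benchmark_suite(n_scenes: int, mix: Sequence[float] = DEFAULT_MIX,
                    seed: int = 0, width: int = 512, height: int = 424,
                    **overrides) -> list[SyntheticScene]:
    """A reproducible list of scenes with the stated category mix.

    Categories are drawn per scene from ``mix`` (single, occluded,
    overlapping), so counts follow a multinomial around the proportions.
    """
    if n_scenes < 1:
        raise ParameterError("n_scenes must be >= 1")
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (3,) or mix.min() < 0 or mix.sum() <= 0:
        raise ParameterError("mix must be 3 non-negative proportions")
    mix = mix / mix.sum()
    root = np.random.default_rng(seed)
    scenes = []
    for k in range(n_scenes):
        cat = CATEGORIES[root.choice(3, p=mix)]
        sub_seed = int(root.integers(0, 2 ** 31))
        spec = make_scene_spec(cat, seed=sub_seed, width=width, height=height,
                               **overrides)
        scenes.append(render_scene(spec))
    return scenes
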