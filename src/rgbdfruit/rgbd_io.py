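"""Aligned RGB-depth pair I/O, detection result I/O, and run configuration.

Depth images follow the Kinect convention: range in millimetres stored as
non-negative integers, with ``0`` acting as the no-data sentinel.  The RGB
image of a pair is resampled to the depth grid when resolutions differ, so
every downstream stage works on one common pixel lattice.

Coordinates are 0-based ``(row, col)`` internally; files expose ``x = col``
and ``y = row``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize

from .errors import FormatError, InputError, ParameterError

DEPTH_SENTINEL = 0


@dataclass(frozen=True)
class DepthImage:
    """2-D grid of range values (mm) plus a validity mask.

    ``valid_mask`` is False exactly where the raw sensor reading was the
    no-data sentinel (0 mm); invalid pixels carry the value 0.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if values.ndim != 2:
            raise InputError(f"depth must be 2-D, got shape {values.shape}")
        if values.shape != mask.shape:
            raise InputError(
                f"depth values {values.shape} and mask {mask.shape} differ"
            )
        if np.any(values[mask] < 0):
            raise InputError("valid depth values must be non-negative")
        values = values.copy()
        values[~mask] = DEPTH_SENTINEL
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "DepthImage":
        """Build from a raw sensor frame; zeros become invalid pixels."""
        raw = np.asarray(raw, dtype=np.float64)
        return cls(values=raw, valid_mask=raw != DEPTH_SENTINEL)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RgbImage:
    """8-bit colour image stored as an (H, W, 3) array."""

    array: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.array)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"RGB image must be (H, W, 3), got {arr.shape}")
        object.__setattr__(self, "array", arr.astype(np.uint8, copy=False))

    @property
    def r(self) -> np.ndarray:
        return self.array[..., 0]

    @property
    def g(self) -> np.ndarray:
        return self.array[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.array[..., 2]

    @property
    def height(self) -> int:
        return self.array.shape[0]

    @property
    def width(self) -> int:
        return self.array.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape[:2]


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline with their defaults.

    Units: sigmas and distances in pixels unless noted; ``contour_interval``
    in millimetres; ``kde_sigma`` in feature (intensity-difference) units,
    ``None`` meaning Silverman's rule on the feature cloud.
    """

    smoothing_sigma: float = 4.0
    contour_interval: float = 25.0
    center_min_distance: int = 20
    vorticity_threshold: float = 0.3
    omega_smoothing_sigma: float = 8.0
    gradient_floor: float = 0.5
    gradient_ceiling: float = 3.0
    slic_k: int = 150
    slic_m: float = 10.0
    slic_max_iter: int = 10
    kde_sigma: float | None = 2.0
    n_density_top: int = 60
    n_delta_top: int = 4
    n_keep_clusters: int = 4
    min_region_px: int = 150
    min_radius_px: float = 10.0
    max_region_fraction: float = 0.45
    n_angles: int = 360
    overlap_min_separation_deg: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("center_min_distance", "slic_k", "slic_max_iter",
                     "n_density_top", "n_delta_top", "n_keep_clusters",
                     "n_angles", "min_region_px"):
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be a positive count")
        if not (0.0 < self.vorticity_threshold <= 1.0):
            raise ParameterError("vorticity_threshold must be in (0, 1]")
        if self.n_delta_top > self.n_density_top:
            raise ParameterError("n_delta_top must be <= n_density_top")
        if self.n_keep_clusters > self.n_delta_top:
            raise ParameterError("n_keep_clusters must be <= n_delta_top")
        if self.smoothing_sigma < 0:
            raise ParameterError("smoothing_sigma must be >= 0")
        if self.kde_sigma is not None and self.kde_sigma <= 0:
            raise ParameterError("kde_sigma must be positive or None")
        if self.gradient_floor <= 0:
            raise ParameterError("gradient_floor must be positive")
        if self.gradient_ceiling <= self.gradient_floor:
            raise ParameterError("gradient_ceiling must exceed gradient_floor")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FruitDetection:
    """A fitted circle: the pipeline's output unit."""

    center: tuple[float, float]  # (row, col)
    radius: float
    region_id: int = 0
    overlap_flag: bool = False
    image: str = ""


DETECTION_FIELDS = ("image", "region_id", "center_x", "center_y", "radius_px")


def read_rgbd_pair(rgb_path: str | Path, depth_path: str | Path
                   ) -> tuple[RgbImage, DepthImage]:
    """Read an aligned RGB/depth pair (PNG or BMP).

    The depth file must decode to a single-channel integer image; the RGB
    image is resampled to the depth grid when resolutions differ.  Zero
    depth readings become invalid pixels in the returned mask.
    """
    rgb_path, depth_path = Path(rgb_path), Path(depth_path)
    for p in (rgb_path, depth_path):
        if not p.exists():
            raise IOError(f"cannot read image file: {p}")
    rgb_raw = iio.imread(rgb_path)
    depth_raw = iio.imread(depth_path)

    if depth_raw.ndim == 3 and depth_raw.shape[2] == 1:
        depth_raw = depth_raw[..., 0]
    if depth_raw.ndim != 2:
        raise FormatError(
            f"depth file {depth_path} is not single-channel "
            f"(shape {depth_raw.shape})")
    if rgb_raw.ndim == 3 and rgb_raw.shape[2] == 4:  # drop alpha
        rgb_raw = rgb_raw[..., :3]
    if rgb_raw.ndim != 3 or rgb_raw.shape[2] < 3:
        raise FormatError(f"RGB file {rgb_path} has fewer than 3 channels")

    depth = DepthImage.from_raw(depth_raw)
    rgb = RgbImage(rgb_raw)
    if rgb.shape != depth.shape:
        rgb = resample_rgb(rgb, depth.shape)
    return rgb, depth


def resample_rgb(rgb: RgbImage, shape: tuple[int, int]) -> RgbImage:
    """Resample an RGB image to ``shape`` (no-op when already matching)."""
    if rgb.shape == tuple(shape):
        return rgb
    out = resize(rgb.array, shape, order=1, preserve_range=True,
                 anti_aliasing=True)
    return RgbImage(np.clip(np.round(out), 0, 255).astype(np.uint8))


def write_depth_png(depth: DepthImage, path: str | Path) -> None:
    """Write depth as 16-bit PNG (mm, 0 = invalid)."""
    values = np.round(depth.values).astype(np.uint16)
    values[~depth.valid_mask] = DEPTH_SENTINEL
    iio.imwrite(Path(path), values)


def write_rgb_png(rgb: RgbImage, path: str | Path) -> None:
    iio.imwrite(Path(path), rgb.array)


def write_detections(detections: Sequence[FruitDetection],
                     path: str | Path,
                     json_path: str | Path | None = None) -> None:
    """Write detections as CSV (header always present) + optional JSON."""
    path = Path(path)
    try:
        fh = open(path, "w", newline="")
    except OSError as exc:
        raise IOError(f"cannot write detections to {path}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_FIELDS)
        for det in detections:
            writer.writerow([
                det.image, det.region_id,
                f"{det.center[1]:.8g}", f"{det.center[0]:.8g}",
                f"{det.radius:.8g}",
            ])
    if json_path is not None:
        records = [
            {"image": d.image, "region_id": d.region_id,
             "center_x": d.center[1], "center_y": d.center[0],
             "radius_px": d.radius, "overlap": bool(d.overlap_flag)}
            for d in detections
        ]
        with open(json_path, "w") as jf:
            json.dump(records, jf, indent=2)


def read_detections(path: str | Path) -> list[FruitDetection]:
    """Read back a detections CSV written by :func:`write_detections`."""
    out: list[FruitDetection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != DETECTION_FIELDS:
            raise FormatError(f"{path} is not a detections CSV")
        for row in reader:
            out.append(FruitDetection(
                center=(float(row["center_y"]), float(row["center_x"])),
                radius=float(row["radius_px"]),
                region_id=int(row["region_id"]),
                image=row["image"],
            ))
    return out
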