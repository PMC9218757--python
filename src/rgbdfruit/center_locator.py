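"""Fruit-center location from the depth image's rotated gradient field.

The idea: a spherical fruit surface facing the camera is a convex depth
bowl, so its depth gradient points radially outward from the fruit center.
Rotating every gradient vector 90 degrees clockwise turns that diverging
field into a vortex circulating around the center.  The scalar vorticity
(curl) of the rotated field is therefore large and positive at fruit
centers, while cluttered background (foliage, branches) produces an
irregular field whose circulation averages out.

Two vorticity flavours are available:

* :func:`compute_vorticity` on the raw rotated gradient.  This equals the
  finite-difference Laplacian of depth exactly (curl of a 90-degree-rotated
  gradient = divergence of the gradient), which makes a clean test oracle —
  but its magnitude is dominated by the depth step at the fruit silhouette.
* the detection path first passes the rotated field through
  :func:`normalize_field` (direction only, unit speed).  The curl of a unit
  vortex grows like 1/r toward its center, so the response peaks at the
  fruit center itself rather than at the rim, and is insensitive to the
  size of the depth step.  This is the "angular velocity (direction only)"
  view of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import peak_local_max

from .errors import DegenerateInputError, ParameterError, InputError
from .rgbd_io import DepthImage, PipelineConfig

_FULL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class GradientField:
    """Per-pixel (u, v) = (dD/dx, dD/dy) vectors, x = col right, y = row down."""

    u: np.ndarray
    v: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class VorticityMap:
    """Signed scalar curl of a 2-D vector field."""

    omega: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class CenterSet:
    """Detected fruit centers, strongest first."""

    centers: list  # of (row, col, omega_value)
    detection_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.centers)

    def positions(self) -> np.ndarray:
        if not self.centers:
            return np.empty((0, 2))
        return np.array([(r, c) for r, c, _ in self.centers], dtype=float)


@dataclass(frozen=True)
class ContourMap:
    """Iso-depth polylines per level, for visual inspection only."""

    levels: list
    polylines: dict  # level -> list of (n, 2) float arrays in (row, col)


def _fill_invalid(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace invalid pixels with their nearest valid value."""
    if mask.all():
        return values
    if not mask.any():
        raise DegenerateInputError("depth image has no valid pixels")
    idx = ndimage.distance_transform_edt(~mask, return_distances=False,
                                         return_indices=True)
    return values[tuple(idx)]


def smooth_depth(depth: DepthImage, sigma: float) -> DepthImage:
    """Gaussian-smooth depth, excluding invalid pixels via masked weights.

    Weights of invalid pixels are zeroed and the convolution renormalized,
    so holes neither bleed zeros into their surroundings nor shift local
    means.  The validity mask is unchanged.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return DepthImage(depth.values.copy(), depth.valid_mask.copy())
    mask = depth.valid_mask
    weighted = ndimage.gaussian_filter(depth.values * mask, sigma)
    weight = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
    out = np.zeros_like(depth.values)
    nz = weight > 1e-12
    out[nz] = weighted[nz] / weight[nz]
    out[~mask] = 0.0
    return DepthImage(out, mask.copy())


def compute_gradient(depth: DepthImage) -> GradientField:
    """Finite-difference gradient of depth (central interior, one-sided edges).

    Pixels whose 3x3 neighborhood touches an invalid pixel are flagged
    invalid; values there are computed from nearest-valid-filled depth so
    they are finite but should not be trusted.
    """
    mask = depth.valid_mask
    valid_rows = (mask.any(axis=1)).sum()
    valid_cols = (mask.any(axis=0)).sum()
    if valid_rows < 2 or valid_cols < 2:
        raise DegenerateInputError("need at least 2 valid rows and columns")
    values = _fill_invalid(depth.values, mask)
    v, u = np.gradient(values)  # axis 0 = rows (y), axis 1 = cols (x)
    grad_valid = ndimage.binary_erosion(mask, structure=_FULL_3X3,
                                        border_value=1)
    return GradientField(u=u, v=v, valid_mask=grad_valid)


def rotate_field_clockwise(fld: GradientField) -> GradientField:
    """Rotate every vector 90 degrees screen-clockwise: (u, v) -> (-v, u).

    Under the image convention (x right, y down) this is the rotation that
    turns an outward radial field into a positively-circulating vortex.
    """
    return GradientField(u=-fld.v, v=fld.u, valid_mask=fld.valid_mask)


def normalize_field(fld: GradientField, eps: float = 1e-12) -> GradientField:
    """Scale every vector to unit length; zero vectors stay zero."""
    mag = fld.magnitude()
    scale = np.where(mag > eps, 1.0 / np.maximum(mag, eps), 0.0)
    return GradientField(u=fld.u * scale, v=fld.v * scale,
                         valid_mask=fld.valid_mask)


def condition_field(fld: GradientField, floor: float, ceiling: float
                    ) -> GradientField:
    """Direction-emphasising reweighting used by the detection branch.

    Each vector is rescaled to magnitude ``|g| / (|g| + floor)`` — close to
    unit length for real object gradients, damped toward zero for the weak
    gradients of sensor noise and gentle background relief (``floor`` is in
    depth-gradient units, mm/px).  Vectors stronger than ``ceiling`` are
    zeroed entirely: they only occur at depth discontinuities (fruit
    silhouettes, branch edges), whose spurious circulation would otherwise
    drown the center signal.
    """
    if floor <= 0 or ceiling <= floor:
        raise ParameterError("need 0 < floor < ceiling")
    mag = fld.magnitude()
    scale = np.where(mag <= ceiling, 1.0 / (mag + floor), 0.0)
    return GradientField(u=fld.u * scale, v=fld.v * scale,
                         valid_mask=fld.valid_mask)


def compute_vorticity(fld: GradientField) -> VorticityMap:
    """z-component of the curl: omega = dv/dx - du/dy (same stencils as
    :func:`compute_gradient`)."""
    dv_dx = np.gradient(fld.v, axis=1)
    du_dy = np.gradient(fld.u, axis=0)
    omega = dv_dx - du_dy
    valid = ndimage.binary_erosion(fld.valid_mask, structure=_FULL_3X3,
                                   border_value=1)
    return VorticityMap(omega=omega, valid_mask=valid)


_NUMERICAL_FLOOR = 1e-9


def detect_centers(vorticity: VorticityMap, params: PipelineConfig
                   ) -> CenterSet:
    """Find fruit centers as positive vorticity peaks.

    The vorticity map is integrated over neighborhoods at two scales,
    ``omega_smoothing_sigma`` and twice it, each response multiplied by its
    sigma (scale normalization, so fruits of different pixel radius score
    comparably), and the per-pixel maximum over scales taken.  Local maxima
    of that score that exceed ``vorticity_threshold`` times the global
    maximum and survive non-maximum suppression with radius
    ``center_min_distance`` are returned, strongest first.  No peak above
    threshold yields an empty set, not an error.
    """
    omega = np.where(vorticity.valid_mask, vorticity.omega, 0.0)
    if not np.isfinite(omega).all():
        raise InputError("vorticity contains non-finite values")
    base = params.omega_smoothing_sigma
    score = np.max(
        [sig * ndimage.gaussian_filter(omega, sig)
         for sig in (base, 2.0 * base)], axis=0)
    # image borders carry smoothing/one-sided-stencil artifacts over a band
    # of roughly the largest integration scale; peaks there are not trusted
    margin = min(int(round(2.0 * base)),
                 (min(score.shape) - 1) // 2)
    interior = np.zeros_like(score, dtype=bool)
    interior[margin:score.shape[0] - margin,
             margin:score.shape[1] - margin] = True
    interior &= vorticity.valid_mask
    detection_params = {
        "vorticity_threshold": params.vorticity_threshold,
        "center_min_distance": params.center_min_distance,
        "omega_smoothing_sigma": params.omega_smoothing_sigma,
    }
    peak_max = score.max(initial=0.0, where=interior)
    if peak_max <= _NUMERICAL_FLOOR:
        return CenterSet(centers=[], detection_params=detection_params)
    threshold = params.vorticity_threshold * peak_max
    coords = peak_local_max(
        score,
        min_distance=int(params.center_min_distance),
        threshold_abs=threshold,
        exclude_border=margin,
    )
    centers = [(int(r), int(c), float(score[r, c])) for r, c in coords]
    centers.sort(key=lambda t: -t[2])
    return CenterSet(centers=centers, detection_params=detection_params)


def smooth_and_inpaint(depth: DepthImage, sigma: float) -> DepthImage:
    """Like :func:`smooth_depth`, but holes receive the renormalized
    neighborhood average instead of staying zero, and the result is fully
    valid.  Used by the detection branch so that sensor holes do not punch
    gaps into the gradient field."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    mask = depth.valid_mask
    if sigma == 0:
        values = _fill_invalid(depth.values, mask)
    else:
        weighted = ndimage.gaussian_filter(depth.values * mask, sigma)
        weight = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
        covered = weight > 1e-12
        values = np.zeros_like(depth.values)
        values[covered] = weighted[covered] / weight[covered]
        if not covered.all():
            values = _fill_invalid(values, covered)
    return DepthImage(values, np.ones_like(mask))


def locate_fruit_centers(depth: DepthImage, config: PipelineConfig
                         ) -> CenterSet:
    """Full center-location branch.

    smooth+inpaint -> gradient -> rotate 90 deg CW -> direction-emphasising
    conditioning -> vorticity -> multi-scale peak detection.
    """
    smoothed = smooth_and_inpaint(depth, config.smoothing_sigma)
    grad = compute_gradient(smoothed)
    rotated = rotate_field_clockwise(grad)
    conditioned = condition_field(rotated, config.gradient_floor,
                                  config.gradient_ceiling)
    vort = compute_vorticity(conditioned)
    return detect_centers(vort, config)


def iso_contours(depth: DepthImage, interval: float) -> ContourMap:
    """Marching-squares iso-depth curves at min+interval, min+2*interval, ...

    Visualization aid only; nothing downstream consumes the result.
    """
    if interval <= 0:
        raise ParameterError("contour interval must be positive")
    values = _fill_invalid(depth.values, depth.valid_mask)
    lo = float(values.min())
    hi = float(values.max())
    levels = [lo + k * interval
              for k in range(1, int(np.floor((hi - lo) / interval)) + 1)]
    polylines = {}
    for level in levels:
        polylines[level] = measure.find_contours(values, level)
    return ContourMap(levels=levels, polylines=polylines)
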