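"""En-face uptake quantification.

The measurement chain: correct the x-y sensitivity bias with a flat-field
calibration image, correct the z-intensity falloff with a gain-versus-depth
curve, detect the luminal surface by thresholding the autofluorescence
channel, take the maximum tracer intensity 0-25 µm into the wall from that
surface at each x-y location, and average circumferentially per lengthwise
station.  Output stays in the input's arbitrary fluorescence units; no
normalisation is introduced.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .types import DepthMap, EnFaceStack, UptakeProfile

__all__ = [
    "correct_flat_field",
    "correct_z_attenuation",
    "detect_luminal_surface",
    "depth_windowed_max",
    "circumferential_average",
    "average_segments",
    "group_mean_sem",
    "uptake_pipeline",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Calibration data unusable (non-positive values, wrong extent)."""


def correct_flat_field(channel: np.ndarray, calibration: np.ndarray) -> np.ndarray:
    """Divide out the x-y sensitivity bias measured on a uniformly
    fluorescing slide: corrected = raw * mean(calibration) / calibration,
    applied to every z-plane.  Mean intensity is preserved for a spatially
    uniform specimen."""
    channel = np.asarray(channel, dtype=float)
    calibration = np.asarray(calibration, dtype=float)
    if calibration.ndim != 2:
        raise CalibrationError("calibration image must be 2-D (y, x)")
    if channel.shape[-2:] != calibration.shape:
        raise CalibrationError("calibration must match the channel's x-y shape")
    if (calibration <= 0).any():
        raise CalibrationError("calibration contains zero or negative pixels")
    gain = calibration / calibration.mean()
    return channel / gain[None, :, :] if channel.ndim == 3 else channel / gain


def correct_z_attenuation(channel: np.ndarray, attenuation_curve: np.ndarray) -> np.ndarray:
    """Divide each z-plane by its relative gain from the depth calibration."""
    channel = np.asarray(channel, dtype=float)
    curve = np.asarray(attenuation_curve, dtype=float)
    if curve.ndim != 1:
        raise CalibrationError("attenuation curve must be 1-D (gain vs z-plane)")
    if curve.size < channel.shape[0]:
        raise CalibrationError("attenuation curve shorter than stack depth")
    if (curve[: channel.shape[0]] <= 0).any():
        raise CalibrationError("attenuation curve contains non-positive gains")
    return channel / curve[: channel.shape[0], None, None]


def detect_luminal_surface(
    autofluorescence: np.ndarray,
    threshold: float | str = "otsu",
    z_spacing: float = 2.0,
    smooth: bool = True,
) -> DepthMap:
    """Detect the luminal surface by thresholding the autofluorescence stack.

    Per (x, y) column the surface is the first voxel from the luminal face
    whose intensity reaches the threshold; columns never reaching it are
    marked missing.  ``threshold`` is either a fixed non-negative value or
    ``"otsu"`` (per-stack Otsu, the parameter-free default).  By default each
    z-plane is 3x3 median filtered first, which suppresses glare-focus
    outliers at the cuff margins.
    """
    auto = np.asarray(autofluorescence, dtype=float)
    if auto.size == 0:
        raise ValueError("empty autofluorescence channel")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        if np.ptp(auto) == 0:
            thr = np.inf  # featureless stack: nothing detectable
        else:
            thr = float(threshold_otsu(auto))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError("fixed threshold must be non-negative")
    work = median_filter(auto, size=(1, 3, 3)) if smooth else auto
    above = work >= thr
    hit = above.any(axis=0)
    first = above.argmax(axis=0)
    depth = (first + 0.5) * z_spacing
    missing = ~hit
    if missing.all():
        logger.warning("luminal surface not found in any column")
    return DepthMap(depth=np.where(missing, np.nan, depth), missing=missing)


def depth_windowed_max(
    channel: np.ndarray,
    depth_map: DepthMap,
    window: tuple[float, float] = (0.0, 25.0),
    z_spacing: float = 2.0,
) -> np.ndarray:
    """Maximum intensity over voxels whose depth below the detected surface
    lies in the closed ``window`` (µm), per (x, y).  Missing surface columns
    propagate to NaN output."""
    channel = np.asarray(channel, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("empty depth window")
    nz = channel.shape[0]
    if w1 > nz * z_spacing:
        raise ValueError("window extends beyond the stack depth")
    z = (np.arange(nz) + 0.5) * z_spacing
    rel = z[:, None, None] - np.nan_to_num(depth_map.depth, nan=0.0)[None, :, :]
    in_window = (rel >= w0) & (rel <= w1)
    in_window &= ~depth_map.missing[None, :, :]
    masked = np.where(in_window, channel, -np.inf)
    out = masked.max(axis=0)
    out[~in_window.any(axis=0)] = np.nan
    return out


def circumferential_average(
    intensity_map: np.ndarray,
    x: np.ndarray | None = None,
    pixel_size_xy: float = 3.0,
    x_offset: float = 0.0,
    min_fraction: float = 0.25,
) -> UptakeProfile:
    """Average the (y, x) intensity map over the circumferential (y) axis per
    lengthwise station.  Stations where fewer than ``min_fraction`` of the
    circumference is present are reported missing (n_pixels set to 0)."""
    m = np.asarray(intensity_map, dtype=float)
    if m.size == 0:
        raise ValueError("empty intensity map")
    ny, nx = m.shape
    if x is None:
        x = x_offset + (np.arange(nx) + 0.5) * pixel_size_xy
    valid = np.isfinite(m)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(valid, m, 0.0), axis=0)
                        / np.maximum(n, 1), np.nan)
    sparse = n < min_fraction * ny
    mean = np.where(sparse, np.nan, mean)
    n = np.where(sparse, 0, n)
    return UptakeProfile(x=np.asarray(x, float), intensity=mean, n_pixels=n)


def _overlap_grid(a: UptakeProfile, b: UptakeProfile) -> np.ndarray:
    lo = max(a.x.min(), b.x.min())
    hi = min(a.x.max(), b.x.max())
    if hi <= lo:
        raise ValueError("profiles have non-overlapping x ranges")
    return a.x[(a.x >= lo) & (a.x <= hi)]


def _interp_profile(p: UptakeProfile, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    good = p.valid
    if good.sum() < 2:
        raise ValueError("profile has fewer than 2 valid stations")
    intensity = np.interp(grid, p.x[good], p.intensity[good])
    n = np.interp(grid, p.x, p.n_pixels.astype(float))
    return intensity, n


def average_segments(a: UptakeProfile, b: UptakeProfile) -> UptakeProfile:
    """Pointwise mean of the two longitudinal-half profiles of one vessel,
    resampled by linear interpolation onto the overlap of their x ranges."""
    grid = _overlap_grid(a, b)
    ia, na = _interp_profile(a, grid)
    ib, nb = _interp_profile(b, grid)
    mean = 0.5 * (ia + ib)
    n = np.round(0.5 * (na + nb)).astype(int)
    n = np.maximum(n, 1)
    return UptakeProfile(x=grid, intensity=mean, n_pixels=n)


def group_mean_sem(profiles: list[UptakeProfile]) -> tuple[UptakeProfile, np.ndarray, int]:
    """Pointwise group mean and standard error (sample SD / sqrt(n)) over
    per-mouse profiles, on the overlap grid of the group.  With n < 2 the SEM
    is reported missing (NaN)."""
    if not profiles:
        raise ValueError("empty group")
    grid = profiles[0].x
    lo = max(p.x.min() for p in profiles)
    hi = min(p.x.max() for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have non-overlapping x ranges")
    grid = grid[(grid >= lo) & (grid <= hi)]
    stackd = np.array([_interp_profile(p, grid)[0] for p in profiles])
    n = len(profiles)
    mean = stackd.mean(axis=0)
    if n >= 2:
        sem = stackd.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full(grid.shape, np.nan)
    prof = UptakeProfile(x=grid, intensity=mean,
                         n_pixels=np.full(grid.shape, n, dtype=int))
    return prof, sem, n


def uptake_pipeline(
    stack: EnFaceStack,
    calibration: np.ndarray | None = None,
    attenuation_curve: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 25.0),
    threshold: float | str = "otsu",
    smooth_surface: bool = True,
    min_fraction: float = 0.25,
) -> UptakeProfile:
    """Full per-stack chain: corrections -> surface detection -> depth-windowed
    max projection -> circumferential average."""
    tracer = stack.tracer
    auto = stack.autofluorescence
    if calibration is not None:
        tracer = correct_flat_field(tracer, calibration)
        auto = correct_flat_field(auto, calibration)
    if attenuation_curve is not None:
        tracer = correct_z_attenuation(tracer, attenuation_curve)
        auto = correct_z_attenuation(auto, attenuation_curve)
    surface = detect_luminal_surface(auto, threshold=threshold,
                                     z_spacing=stack.z_spacing,
                                     smooth=smooth_surface)
    proj = depth_windowed_max(tracer, surface, window=window,
                              z_spacing=stack.z_spacing)
    return circumferential_average(proj, x=stack.x_coords,
                                   min_fraction=min_fraction)
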