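"""Lumen morphometrics along a centreline.

Cross-sections are taken at uniform arc-length stations (default 5 µm) in the
plane orthogonal to the local tangent of a lightly smoothed centreline.  Per
contour we report area A, perimeter P, Shape Index SI = 4*pi*A/P**2 (1 for a
circle, tending to 0 for a line) and the maximum inscribed circle radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .types import CuffSpec, DepthMap, LumenGeometry

__all__ = [
    "CrossSectionMetrics",
    "CuffPlacement",
    "sample_cross_sections",
    "contour_metrics",
    "shape_index",
    "equivalent_diameter",
    "max_inscribed_circle",
    "wall_thickness_map",
    "fit_cuff",
    "geometry_metrics",
]


@dataclass(frozen=True)
class CrossSectionMetrics:
    """Planar metrics of one lumen cross-section."""

    area: float          # µm²
    perimeter: float     # µm
    shape_index: float   # dimensionless, (0, 1]
    r_inscribed: float | None = None  # µm


@dataclass(frozen=True)
class CuffPlacement:
    """Result of fitting the cuff model to a reconstructed lumen."""

    throat_s: float
    throat_point: np.ndarray
    axis_point: np.ndarray      # centreline point one cuff length away
    axis: np.ndarray            # unit vector from axis_point to throat
    contact_first_s: float | None
    contact_last_s: float | None


def _smooth_centerline(points: np.ndarray, window_um: float = 25.0) -> np.ndarray:
    """Arc-length moving-average smoothing of a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("degenerate centerline (repeated points)")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    mean_step = s[-1] / (len(s) - 1)
    half = max(1, int(round(window_um / (2 * mean_step))))
    out = points.copy()
    for i in range(len(points)):
        lo, hi = max(0, i - half), min(len(points), i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    # keep the endpoints anchored so the arc extent is preserved
    out[0], out[-1] = points[0], points[-1]
    return out


def sample_cross_sections(geometry: LumenGeometry, spacing: float = 5.0,
                          smooth_window: float = 25.0) -> LumenGeometry:
    """Resample the geometry at uniform arc-length stations.

    Contours are interpolated vertex-wise between the bracketing input
    stations (vertex counts must agree); each output contour lies in the plane
    orthogonal to the local tangent of the smoothed centreline.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    cl = _smooth_centerline(geometry.centerline, smooth_window)
    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < spacing:
        raise ValueError("centerline arc length shorter than the spacing")
    n_out = int(np.floor(total / spacing + 1e-9)) + 1
    s_new = np.arange(n_out) * spacing

    nv = {c.shape[0] for c in geometry.contours}
    if len(nv) != 1:
        raise ValueError("contours must share a vertex count for resampling")

    # input stations in the smoothed arc-length parameterization
    s_in = np.interp(geometry.s, geometry.s, geometry.s)  # identity; clarity
    s_in = (s_in - s_in[0]) * (total / (s_in[-1] - s_in[0]))

    contour_arr = np.stack(geometry.contours)  # (N, M, 2)
    new_contours: list[np.ndarray] = []
    frames = []
    cl_new = np.empty((n_out, 3))
    for j, sj in enumerate(s_new):
        i = int(np.clip(np.searchsorted(s_in, sj) - 1, 0, len(s_in) - 2))
        w = (sj - s_in[i]) / (s_in[i + 1] - s_in[i])
        w = float(np.clip(w, 0.0, 1.0))
        new_contours.append((1 - w) * contour_arr[i] + w * contour_arr[i + 1])
        # centreline point and tangent frame at sj
        k = int(np.clip(np.searchsorted(s, sj) - 1, 0, len(s) - 2))
        u = (sj - s[k]) / (s[k + 1] - s[k])
        p = (1 - u) * cl[k] + u * cl[k + 1]
        t = cl[k + 1] - cl[k]
        t = t / np.linalg.norm(t)
        # stable normal pair orthogonal to t
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ref, t)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        cl_new[j] = p
        frames.append((p, e1, e2))
    return LumenGeometry(centerline=cl_new, contours=new_contours, s=s_new,
                         station_spacing=spacing, frames=frames)


def _polygon(contour: np.ndarray) -> Polygon:
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise ValueError("contour must be an (M >= 3, 2) polygon")
    poly = Polygon(contour)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("self-intersecting or degenerate contour")
    return poly


def contour_metrics(contour: np.ndarray, inscribed: bool = False,
                    resolution: float = 1.0) -> CrossSectionMetrics:
    """Area, perimeter and shape index of a simple closed polygon
    (orientation-independent)."""
    poly = _polygon(contour)
    a, p = poly.area, poly.length
    r = max_inscribed_circle(contour, resolution)[1] if inscribed else None
    return CrossSectionMetrics(area=a, perimeter=p,
                               shape_index=shape_index(a, p), r_inscribed=r)


def shape_index(area: float, perimeter: float) -> float:
    """SI = 4*pi*A/P**2; 1 for a circle, 0 in the line limit.  Values above 1
    within numerical tolerance are clipped to exactly 1."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    si = 4.0 * np.pi * area / perimeter ** 2
    if 1.0 < si <= 1.0 + 1e-9:
        si = 1.0
    return float(si)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area, 2*sqrt(A/pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return float(2.0 * np.sqrt(area / np.pi))


def max_inscribed_circle(contour: np.ndarray, resolution: float = 1.0
                         ) -> tuple[np.ndarray, float]:
    """Largest circle fully inside the polygon: the interior point maximising
    distance to the boundary, located to ``resolution`` (µm)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    poly = _polygon(contour)
    ls = shapely.maximum_inscribed_circle(poly, tolerance=resolution / 4.0)
    center = np.array(ls.coords[0])
    return center, float(ls.length)


def wall_thickness_map(inner: DepthMap, outer: DepthMap
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Wall thickness = adventitial depth - luminal depth per (x, y).

    Returns (thickness, invalid) where invalid flags crossing surfaces
    (negative thickness) or missing pixels; thickness is NaN there.
    """
    if inner.depth.shape != outer.depth.shape:
        raise ValueError("misaligned depth maps")
    thickness = outer.depth - inner.depth
    invalid = inner.missing | outer.missing | (thickness < 0)
    return np.where(invalid, np.nan, thickness), invalid


def geometry_metrics(geometry: LumenGeometry, inscribed: bool = False,
                     resolution: float = 1.0) -> pd.DataFrame:
    """Per-station morphometrics table (s_um, area_um2, perimeter_um,
    shape_index, equiv_diameter_um[, r_insc_um])."""
    rows = []
    for s, c in zip(geometry.s, geometry.contours):
        m = contour_metrics(c, inscribed=inscribed, resolution=resolution)
        row = {
            "s_um": s,
            "area_um2": m.area,
            "perimeter_um": m.perimeter,
            "shape_index": m.shape_index,
            "equiv_diameter_um": equivalent_diameter(m.area),
        }
        if inscribed:
            row["r_insc_um"] = m.r_inscribed
        rows.append(row)
    return pd.DataFrame(rows)


def fit_cuff(geometry: LumenGeometry, cuff: CuffSpec,
             shrinkage: float = 0.10, wall_fraction: float = 0.10
             ) -> CuffPlacement:
    """Fit the cuff model to a lumen reconstruction.

    The cuff's narrow end is placed at the station of minimum equivalent
    diameter 2*sqrt(A/pi); its axis runs through that point and the centreline
    point one cuff length upstream (downstream for a reversed cuff).  Contact
    stations are reported under the conventions that the wall occupies
    ``wall_fraction`` of the luminal diameter on each side and the cast shrank
    by ``shrinkage`` during setting.
    """
    if geometry.arc_length <= cuff.length:
        raise ValueError("geometry shorter than the cuff")
    metrics = geometry_metrics(geometry)
    d = metrics["equiv_diameter_um"].to_numpy()
    s = metrics["s_um"].to_numpy()
    i_min = int(np.argmin(d))
    if i_min in (0, len(d) - 1):
        raise ValueError("no interior diameter minimum (no stenosis)")
    throat_s = float(s[i_min])
    throat_point = geometry.centerline[i_min]

    sign = -1.0 if cuff.orientation == "forward" else 1.0
    s_axis = throat_s + sign * cuff.length
    s_axis = float(np.clip(s_axis, s[0], s[-1]))
    j = int(np.argmin(np.abs(s - s_axis)))
    axis_point = geometry.centerline[j]
    axis = throat_point - axis_point
    axis = axis / np.linalg.norm(axis)

    # contact: outer vessel surface (shrinkage-corrected lumen + wall) vs bore
    outer_d = d / (1.0 - shrinkage) * (1.0 + 2.0 * wall_fraction)
    x_rel = s - throat_s  # cuff frame: throat at 0
    in_cuff = cuff.contains(x_rel)
    bore = cuff.bore_diameter(x_rel)
    contact = in_cuff & (outer_d >= bore)
    first_s = last_s = None
    if contact.any():
        idx = np.flatnonzero(contact)
        first_s, last_s = float(s[idx[0]]), float(s[idx[-1]])
    return CuffPlacement(throat_s=throat_s, throat_point=throat_point,
                         axis_point=axis_point, axis=axis,
                         contact_first_s=first_s, contact_last_s=last_s)
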