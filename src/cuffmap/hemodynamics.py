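"""Hemodynamic surface-field post-processing and flow bookkeeping.

Wall scalar fields (shear stress or pressure, Pa) mapped to rectangular
(s, theta) parametric space are summarised in contiguous 40 µm longitudinal
bands: per band the mean and the "band minimum", the mean of the lower 5th
percentile of nodal values.  Pressure band profiles are shifted so a
reference band downstream of the throat reads zero.  A quasi-1D viscous
(Poiseuille) surrogate provides WSS and pressure trends along a stenosis:
tau = 32*mu*Q/(pi*D**3), dp/dx = -128*mu*Q/(pi*D**4), appropriate at the low
Reynolds numbers of the mouse carotid where viscous losses dominate and there
is almost no pressure recovery after a throat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .types import FluidProperties, SurfaceField

__all__ = [
    "BandSummary",
    "band_statistics",
    "bands_to_frame",
    "subtract_reference_pressure",
    "murray_flow_split",
    "reynolds_number",
    "centerline_to_mean_velocity",
    "scale_velocity",
    "quasi_1d_stenosis",
    "REFERENCE_OFFSET_UM",
    "VELOCITY_SCALES",
]

#: reference-pressure band location downstream of the throat, µm
REFERENCE_OFFSET_UM = {"forward": 2000.0, "reversed": 3000.0}

#: inlet-velocity scalings relative to the anaesthetised measurement
VELOCITY_SCALES = {
    "anaesthetised": 1.0,
    "conscious_min": 1.05,
    "conscious_max": 1.72,
    "active": 1.72 * 1.88,
}


@dataclass
class BandSummary:
    """Statistics of one 40 µm longitudinal band of a wall scalar field."""

    band_center: float   # µm
    mean_value: float    # Pa
    low5_mean: float     # mean of the lower 5th percentile, Pa
    n_nodes: int


def _low5_mean(values: np.ndarray) -> float:
    """Mean of the lower-5th-percentile set (nearest rank); with fewer than
    20 nodes the set degenerates to the single minimum."""
    n = values.size
    m = int(np.ceil(0.05 * n)) if n >= 20 else 1
    return float(np.sort(values)[:m].mean())


def band_statistics(field: SurfaceField, band_length: float = 40.0
                    ) -> list[BandSummary]:
    """Partition nodes into contiguous half-open bands [k*L, (k+1)*L) anchored
    at the upstream end of the mapped domain and summarise each."""
    if band_length <= 0:
        raise ValueError("band_length must be positive")
    s0 = field.s.min()
    idx = np.floor((field.s - s0) / band_length).astype(int)
    out = []
    for k in np.unique(idx):
        sel = field.values[idx == k]
        out.append(BandSummary(
            band_center=float(s0 + (k + 0.5) * band_length),
            mean_value=float(sel.mean()),
            low5_mean=_low5_mean(sel),
            n_nodes=int(sel.size),
        ))
    return out


def bands_to_frame(bands: list[BandSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bands])


def subtract_reference_pressure(
    bands: list[BandSummary],
    throat_s: float = 0.0,
    ref_offset: float | None = None,
    orientation: str = "forward",
) -> list[BandSummary]:
    """Shift band mean pressures so the band at throat + ref_offset reads 0.

    The default offset is 2 mm downstream of the throat for a forward cuff
    and 3 mm for a reversed one.  Idempotent.
    """
    if not bands:
        raise ValueError("no bands")
    if ref_offset is None:
        ref_offset = REFERENCE_OFFSET_UM[orientation]
    ref_s = throat_s + ref_offset
    centers = np.array([b.band_center for b in bands])
    half = 0.5 * (centers[1] - centers[0]) if len(centers) > 1 else np.inf
    j = int(np.argmin(np.abs(centers - ref_s)))
    if abs(centers[j] - ref_s) > max(half, 1e-9):
        raise ValueError("reference location outside the banded domain")
    ref = bands[j].mean_value
    return [BandSummary(b.band_center, b.mean_value - ref,
                        b.low5_mean - ref, b.n_nodes) for b in bands]


def murray_flow_split(radii) -> np.ndarray:
    """Flow fractions at a bifurcation by Murray's law: r_i**3 / sum r_j**3."""
    r = np.asarray(radii, dtype=float)
    if (r < 0).any():
        raise ValueError("radii must be non-negative")
    cubes = r ** 3
    total = cubes.sum()
    if total == 0:
        raise ValueError("all radii are zero")
    return cubes / total


def reynolds_number(v_mean: float, diameter: float,
                    props: FluidProperties | None = None) -> float:
    """Re = rho * v * D / mu (SI units: m/s, m)."""
    props = props or FluidProperties()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if v_mean < 0:
        raise ValueError("velocity must be non-negative")
    return props.rho * v_mean * diameter / props.mu


def centerline_to_mean_velocity(v_centerline: float) -> float:
    """Cross-sectionally averaged velocity of a parabolic (Poiseuille)
    profile is half the centreline velocity."""
    return v_centerline / 2.0


def scale_velocity(v: float, condition: str) -> float:
    """Scale an anaesthetised-mouse velocity to another physiological state:
    x1.05 / x1.72 for the minimum / maximum effect of anaesthesia, a further
    x1.88 for active rather than resting mice."""
    try:
        return v * VELOCITY_SCALES[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(VELOCITY_SCALES)}") from None


def quasi_1d_stenosis(
    x: np.ndarray,
    area: np.ndarray,
    flow: float,
    props: FluidProperties | None = None,
    p_in: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-1D fully developed viscous flow through a varying-area tube.

    Inputs in SI (x in m, area in m², flow in m³/s).  Returns wall shear
    tau(x) = 32*mu*Q/(pi*D**3) and pressure p(x) = p_in - integral of
    128*mu*Q/(pi*D**4) dx (trapezoidal), with D(x) = 2*sqrt(A/pi).  Pressure
    is strictly decreasing for any positive area profile — there is no
    Bernoulli recovery in this viscous-dominated regime.
    """
    props = props or FluidProperties()
    x = np.asarray(x, dtype=float)
    area = np.asarray(area, dtype=float)
    if x.shape != area.shape or x.ndim != 1:
        raise ValueError("x and area must be matching 1-D arrays")
    if (area <= 0).any():
        raise ValueError("area must be positive everywhere")
    if flow <= 0:
        raise ValueError("flow must be positive")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    d = 2.0 * np.sqrt(area / np.pi)
    tau = 32.0 * props.mu * flow / (np.pi * d ** 3)
    dpdx = 128.0 * props.mu * flow / (np.pi * d ** 4)
    p = p_in - cumulative_trapezoid(dpdx, x, initial=0.0)
    return tau, p
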