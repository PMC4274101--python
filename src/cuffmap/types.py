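"""Core domain objects shared across the pipeline.

All lengths are in micrometres (µm) unless a name says otherwise; the
longitudinal coordinate ``x`` is expressed in the *cuff frame*: x = 0 at the
cuff's narrow end (the throat), with flow running in +x.  A forward-oriented
cuff (wide end upstream) occupies [-length, 0]; a reversed cuff (narrow end
upstream) occupies [0, +length].  In image stacks, z is depth from the luminal
face, increasing into the wall; voxel centres sit at (i + 0.5) * spacing for
0-based index i.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CuffSpec",
    "EnFaceStack",
    "DepthMap",
    "UptakeProfile",
    "LumenGeometry",
    "SurfaceField",
    "DopplerTrace",
    "FluidProperties",
    "GroundTruth",
]


@dataclass(frozen=True)
class CuffSpec:
    """Tapered perivascular cuff: a rigid bore narrowing linearly from
    ``wide_diameter`` to ``narrow_diameter`` over ``length``."""

    length: float = 1500.0
    wide_diameter: float = 500.0
    narrow_diameter: float = 250.0
    orientation: Literal["forward", "reversed"] = "forward"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cuff length must be positive")
        if not (self.wide_diameter > self.narrow_diameter > 0):
            raise ValueError("need wide_diameter > narrow_diameter > 0")
        if self.orientation not in ("forward", "reversed"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def upstream_margin(self) -> float:
        """x of the cuff end facing the flow."""
        return -self.length if self.orientation == "forward" else 0.0

    @property
    def downstream_margin(self) -> float:
        return 0.0 if self.orientation == "forward" else self.length

    def bore_diameter(self, x: np.ndarray | float) -> np.ndarray:
        """Inner (bore) diameter of the cuff at cuff-frame position x.

        Outside the cuff extent the value is clamped to the nearest end.
        """
        x = np.asarray(x, dtype=float)
        if self.orientation == "forward":
            frac = np.clip((x + self.length) / self.length, 0.0, 1.0)
            return self.wide_diameter + frac * (self.narrow_diameter - self.wide_diameter)
        frac = np.clip(x / self.length, 0.0, 1.0)
        return self.narrow_diameter + frac * (self.wide_diameter - self.narrow_diameter)

    def contains(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = sorted((self.upstream_margin, self.downstream_margin))
        return (x >= lo) & (x <= hi)


@dataclass
class EnFaceStack:
    """Two-channel en-face confocal stack, axes (z, y, x).

    ``tracer`` holds labelled-albumin fluorescence, ``autofluorescence`` the
    intrinsic tissue channel used for surface detection.  ``x_offset`` maps
    column 0 to the cuff frame.
    """

    tracer: np.ndarray
    autofluorescence: np.ndarray
    pixel_size_xy: float = 3.0
    z_spacing: float = 2.0
    x_offset: float = 0.0

    def __post_init__(self) -> None:
        self.tracer = np.asarray(self.tracer, dtype=float)
        self.autofluorescence = np.asarray(self.autofluorescence, dtype=float)
        if self.tracer.ndim != 3:
            raise ValueError("channels must be 3-D (z, y, x)")
        if self.tracer.shape != self.autofluorescence.shape:
            raise ValueError("channels must share a shape")
        if self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ValueError("voxel spacings must be positive")
        if (self.tracer < 0).any() or (self.autofluorescence < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tracer.shape

    @property
    def x_coords(self) -> np.ndarray:
        """Cuff-frame x of each column (voxel centres)."""
        nx = self.shape[2]
        return self.x_offset + (np.arange(nx) + 0.5) * self.pixel_size_xy

    @property
    def z_coords(self) -> np.ndarray:
        """Depth of each plane's voxel centre from the luminal face of the stack."""
        nz = self.shape[0]
        return (np.arange(nz) + 0.5) * self.z_spacing


@dataclass
class DepthMap:
    """Per-(y, x) depth of a detected surface, µm from the stack's luminal face."""

    depth: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.depth.shape != self.missing.shape:
            raise ValueError("depth and missing mask must share a shape")
        if self.depth.ndim != 2:
            raise ValueError("depth map must be 2-D (y, x)")


@dataclass
class UptakeProfile:
    """Circumferentially averaged intensity versus cuff-frame x.

    ``n_pixels`` counts the circumferential samples contributing per station;
    stations with n_pixels == 0 carry NaN intensity.
    """

    x: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if not (self.x.shape == self.intensity.shape == self.n_pixels.shape):
            raise ValueError("x, intensity and n_pixels must share a shape")
        if self.x.ndim != 1:
            raise ValueError("profile arrays must be 1-D")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        present = self.n_pixels > 0
        if not np.isfinite(self.intensity[present]).all():
            raise ValueError("intensity must be finite where n_pixels > 0")

    @property
    def valid(self) -> np.ndarray:
        return self.n_pixels > 0


@dataclass
class LumenGeometry:
    """Centreline plus closed planar cross-section contours.

    ``centerline`` is an (N, 3) polyline in µm; ``contours`` holds one (M, 2)
    closed polygon per station, expressed in the plane orthogonal to the local
    centreline tangent (first vertex not repeated).  ``s`` is arc length.
    """

    centerline: np.ndarray
    contours: list[np.ndarray]
    s: np.ndarray
    station_spacing: float = 5.0
    frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be (N, 3)")
        if len(self.contours) != len(self.s):
            raise ValueError("one contour per station required")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("stations must be ordered by arc length")

    @property
    def n_stations(self) -> int:
        return len(self.s)

    @property
    def arc_length(self) -> float:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return float(seg.sum())

    def contour3d(self, i: int) -> np.ndarray:
        """Embed contour i back into 3-D using its stored frame."""
        if self.frames is None:
            raise ValueError("geometry has no stored frames")
        origin, e1, e2 = self.frames[i]
        c = self.contours[i]
        return origin[None, :] + c[:, 0:1] * e1[None, :] + c[:, 1:2] * e2[None, :]


@dataclass
class SurfaceField:
    """Scalar field (e.g. WSS or pressure, Pa) on a tubular surface mapped to
    rectangular parametric space: s longitudinal (µm), theta circumferential
    (rad)."""

    s: np.ndarray
    theta: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.s.shape == self.theta.shape == self.values.shape):
            raise ValueError("s, theta, values must share a shape")
        if self.s.size == 0:
            raise ValueError("field must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("field values must be finite")


@dataclass
class DopplerTrace:
    """Maximum-velocity envelope of a Doppler spectrum, uniformly sampled."""

    t: np.ndarray
    v: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be matching 1-D arrays")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood surrogate."""

    mu: float = 0.004    # kg/(m s)
    rho: float = 1015.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass
class GroundTruth:
    """Truth bundle stored alongside every generated artifact.

    Only the fields relevant to the generating operation are populated; the
    rest stay None.  Regeneration with the same seed is bit-identical.
    """

    seed: int
    true_uptake_profile: UptakeProfile | None = None
    true_surface_depth: np.ndarray | None = None
    true_wall_thickness: np.ndarray | None = None
    true_peak_centers: dict[str, float] | None = None
    true_beat_metrics: dict[str, np.ndarray] | None = None
    flat_field_image: np.ndarray | None = None
    attenuation_curve: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, UptakeProfile):
                return {"x": o.x.tolist(), "intensity": o.intensity.tolist(),
                        "n_pixels": o.n_pixels.tolist()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=enc)
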