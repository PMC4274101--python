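"""Synthetic input generators with stored ground truth.

Every generator is a pure function of (config, seed): the same arguments give
bit-identical output, so each pipeline stage can be tested against known truth
without any external data.

The en-face stack generator emulates a half-vessel mounted luminal side down:
a gently curved luminal surface, tracer signal decaying with depth into the
wall, a flat low-level autofluorescence channel with glare foci at the cuff
margins, a smooth multiplicative x-y sensitivity bias, z-attenuation, and
shot-like (Poisson) noise.  The geometry generator emulates a carotid lumen
constrained by the cuff's linear 500 -> 250 µm taper over 1.5 mm; the Doppler
generator emulates pulsatile velocity envelopes with breathing modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .types import (
    CuffSpec,
    DepthMap,
    DopplerTrace,
    EnFaceStack,
    GroundTruth,
    LumenGeometry,
    SurfaceField,
    UptakeProfile,
)

__all__ = [
    "StackConfig",
    "gen_enface_stack",
    "true_uptake_profile",
    "gen_lumen_geometry",
    "cuff_bore_geometry",
    "gen_doppler_trace",
    "gen_surface_field",
    "gen_wall_depth_maps",
]


# ---------------------------------------------------------------------------
# En-face stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackConfig:
    """Parameters of a synthetic en-face stack.

    Defaults describe the study conditions: a ~0.5 x 5 mm field at 3 µm pixels,
    a cuff-frame window running from 2 mm upstream of the upstream cuff margin
    to 1.5 mm past the throat, two uptake peaks of roughly cuff length (the
    upstream one centred on the upstream cuff margin, the downstream one 0.5 mm
    beyond the narrow end), 10% multiplicative sensitivity bias and shot noise.
    """

    length_um: float = 5000.0
    width_um: float = 500.0
    pixel_size_xy: float = 3.0
    z_spacing: float = 2.0
    n_z: int = 40
    x_offset: float = -3500.0
    cuff: CuffSpec | None = field(default_factory=CuffSpec)
    # uptake profile (arbitrary fluorescence units)
    baseline: float = 100.0
    upstream_peak_amp: float = 400.0
    downstream_peak_amp: float = 250.0
    peak_width: float | None = None      # default: cuff length
    peak_sigma: float = 150.0            # Gaussian smoothing of the top-hat
    downstream_peak_offset: float = 500.0  # past the narrow end
    # luminal surface: shallow parabolic sag across y plus a slight x tilt
    surface_depth0: float = 6.0
    surface_sag: float = 8.0
    surface_tilt: float = 0.5            # µm per mm of x
    # wall / optics
    decay_scale: float = 20.0            # tracer depth decay below surface, µm
    window: tuple[float, float] = (0.0, 25.0)
    auto_fraction: float = 0.2           # autofluorescence level vs baseline
    glare_amp_fraction: float = 0.5      # glare foci amplitude vs baseline
    n_glare_foci: int = 3                # per cuff margin
    glare_sigma: float = 30.0
    # degradations
    bias_amplitude: float = 0.10         # peak-to-mean x-y sensitivity bias
    attenuation_coeff: float = 0.01      # 1/µm, exp z falloff
    noise: float = 1.0                   # shot-noise quantum (0 disables)
    calibration_noise: float = 0.01      # relative noise on the flat-field image
    # scenarios
    tracer_administered: bool = True
    lname: bool = False
    # wall thickness truth (for thickness mapping): base + cuff remodelling
    wall_thickness_base: float = 40.0
    wall_thinning_fraction: float = 0.3
    wall_margin_bump: float = 15.0
    wall_margin_sigma: float = 150.0

    def __post_init__(self) -> None:
        for name in ("length_um", "width_um", "pixel_size_xy", "z_spacing",
                     "baseline", "decay_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_z < 2:
            raise ValueError("n_z must be at least 2")
        for name in ("upstream_peak_amp", "downstream_peak_amp", "auto_fraction",
                     "glare_amp_fraction", "bias_amplitude", "attenuation_coeff",
                     "noise", "calibration_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        w0, w1 = self.window
        if not (0 <= w0 < w1):
            raise ValueError("window must be a non-empty interval starting >= 0")
        max_surface = self.surface_depth0 + self.surface_sag + \
            self.surface_tilt * self.length_um / 1000.0
        if max_surface + w1 > self.n_z * self.z_spacing:
            raise ValueError("depth window extends beyond the stack "
                             "(window larger than stack)")

    @property
    def nx(self) -> int:
        return int(round(self.length_um / self.pixel_size_xy))

    @property
    def ny(self) -> int:
        return int(round(self.width_um / self.pixel_size_xy))


def _peak_profile(x: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    """Smoothed top-hat: a rectangle of ``width`` centred on ``center``
    convolved with a Gaussian of ``sigma`` (analytic erf form)."""
    from scipy.special import erf

    if sigma <= 0:
        return ((x >= center - width / 2) & (x <= center + width / 2)).astype(float)
    a = (x - (center - width / 2)) / (np.sqrt(2) * sigma)
    b = (x - (center + width / 2)) / (np.sqrt(2) * sigma)
    return 0.5 * (erf(a) - erf(b))


def _effective_amplitudes(config: StackConfig) -> tuple[float, float, float]:
    """Baseline and the two peak amplitudes after applying the L-NAME scenario
    flag (peak difference set to 0, baseline halved)."""
    up, down, base = (config.upstream_peak_amp, config.downstream_peak_amp,
                      config.baseline)
    if config.lname:
        mean_amp = 0.5 * (up + down)
        up = down = mean_amp
        base = base / 2.0
    return base, up, down


def true_uptake_profile(config: StackConfig, x: np.ndarray | None = None) -> UptakeProfile:
    """Noise-free circumferential-mean uptake truth on the stack's x grid."""
    if x is None:
        x = config.x_offset + (np.arange(config.nx) + 0.5) * config.pixel_size_xy
    base, up_amp, down_amp = _effective_amplitudes(config)
    intensity = np.full_like(x, base, dtype=float)
    if config.cuff is not None and config.tracer_administered:
        cuff = config.cuff
        width = config.peak_width if config.peak_width is not None else cuff.length
        up_center = cuff.upstream_margin
        down_center = cuff.downstream_margin + config.downstream_peak_offset
        intensity = intensity \
            + up_amp * _peak_profile(x, up_center, width, config.peak_sigma) \
            + down_amp * _peak_profile(x, down_center, width, config.peak_sigma)
    if not config.tracer_administered:
        # tracer channel carries only bleed-through at the autofluorescence level
        intensity = np.full_like(x, base * config.auto_fraction)
    n = np.full(x.shape, 1, dtype=int)
    return UptakeProfile(x=x, intensity=intensity, n_pixels=n)


def _surface_depth(config: StackConfig) -> np.ndarray:
    """Continuous true luminal surface depth (y, x), µm from stack top."""
    x = config.x_offset + (np.arange(config.nx) + 0.5) * config.pixel_size_xy
    y = (np.arange(config.ny) + 0.5) * config.pixel_size_xy
    yc = config.width_um / 2.0
    sag = config.surface_sag * ((y - yc) / yc) ** 2
    tilt = config.surface_tilt * (x - x[0]) / 1000.0
    return config.surface_depth0 + sag[:, None] + tilt[None, :]


def _bias_field(config: StackConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative x-y sensitivity bias, mean ~1."""
    if config.bias_amplitude == 0:
        return np.ones((config.ny, config.nx))
    x = np.linspace(0, 1, config.nx)
    y = np.linspace(0, 1, config.ny)
    phx, phy, phd = rng.uniform(0, 2 * np.pi, size=3)
    fx, fy = rng.uniform(1.0, 2.5, size=2)
    pattern = (np.cos(2 * np.pi * fx * x + phx)[None, :]
               + np.cos(2 * np.pi * fy * y + phy)[:, None]
               + 0.5 * np.cos(2 * np.pi * (x[None, :] + y[:, None]) + phd))
    pattern = pattern / np.abs(pattern).max()
    bias = 1.0 + config.bias_amplitude * pattern
    return bias / bias.mean()


def _glare_foci(config: StackConfig, rng: np.random.Generator,
                x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """High-intensity autofluorescence blobs at the cuff margins, (y, x)."""
    out = np.zeros((y.size, x.size))
    if config.cuff is None or config.glare_amp_fraction == 0:
        return out
    amp = config.glare_amp_fraction * config.baseline
    for margin in (config.cuff.upstream_margin, config.cuff.downstream_margin):
        for _ in range(config.n_glare_foci):
            cx = margin + rng.normal(0, config.glare_sigma)
            cy = rng.uniform(0, config.width_um)
            a = amp * rng.uniform(0.5, 1.5)
            out += a * np.exp(-((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2)
                              / (2 * config.glare_sigma ** 2))
    return out


def gen_enface_stack(config: StackConfig, seed: int) -> tuple[EnFaceStack, GroundTruth]:
    """Generate a two-channel en-face stack plus ground truth.

    The tracer channel is the longitudinal uptake profile times an exponential
    depth decay below the (voxelised) luminal surface, degraded by the bias
    field, z-attenuation and shot noise; the autofluorescence channel is a low
    flat level inside the wall plus glare foci at the cuff margins.  The truth
    bundle carries the noise-free profile, the voxelised surface depth, the
    wall-thickness pattern, the peak centres and the calibration artifacts
    (flat-field image, attenuation curve) needed by the corrections.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = config.nx, config.ny, config.n_z
    x = config.x_offset + (np.arange(nx) + 0.5) * config.pixel_size_xy
    y = (np.arange(ny) + 0.5) * config.pixel_size_xy
    z = (np.arange(nz) + 0.5) * config.z_spacing

    profile = true_uptake_profile(config, x)
    surface = _surface_depth(config)                       # (y, x), continuous
    surf_idx = np.ceil(surface / config.z_spacing - 0.5).astype(int)
    surf_idx = np.clip(surf_idx, 0, nz - 1)
    surf_depth_vox = (surf_idx + 0.5) * config.z_spacing   # voxel-centre truth

    # depth of each voxel centre below the surface voxel centre
    rel = z[:, None, None] - surf_depth_vox[None, :, :]    # (z, y, x)
    wall = rel >= 0
    decay = np.where(wall, np.exp(-np.clip(rel, 0, None) / config.decay_scale), 0.0)

    tracer_clean = profile.intensity[None, None, :] * decay
    base, _, _ = _effective_amplitudes(config)
    auto_level = config.auto_fraction * base
    glare = _glare_foci(config, rng, x, y)
    auto_clean = np.where(wall, auto_level + glare[None, :, :], 0.0)

    bias = _bias_field(config, rng)
    atten = np.exp(-config.attenuation_coeff * z)

    def degrade(clean: np.ndarray) -> np.ndarray:
        out = clean * bias[None, :, :] * atten[:, None, None]
        if config.noise > 0:
            out = rng.poisson(out / config.noise).astype(float) * config.noise
        return out

    stack = EnFaceStack(
        tracer=degrade(tracer_clean),
        autofluorescence=degrade(auto_clean),
        pixel_size_xy=config.pixel_size_xy,
        z_spacing=config.z_spacing,
        x_offset=config.x_offset,
    )

    # flat-field calibration image: the bias as seen on a uniform slide
    calib_level = 1000.0
    calib = calib_level * bias
    if config.calibration_noise > 0:
        calib = calib * (1.0 + config.calibration_noise * rng.standard_normal(calib.shape))
        calib = np.clip(calib, calib_level * 0.1, None)

    thickness = _wall_thickness_truth(config, x)[None, :] * np.ones((ny, 1))

    peaks = None
    if config.cuff is not None and config.tracer_administered:
        peaks = {
            "upstream": config.cuff.upstream_margin,
            "downstream": config.cuff.downstream_margin + config.downstream_peak_offset,
        }

    truth = GroundTruth(
        seed=seed,
        true_uptake_profile=profile,
        true_surface_depth=surf_depth_vox,
        true_wall_thickness=thickness,
        true_peak_centers=peaks,
        flat_field_image=calib,
        attenuation_curve=atten,
        extras={"surface_index": surf_idx, "bias_field": bias},
    )
    return stack, truth


def _wall_thickness_truth(config: StackConfig, x: np.ndarray) -> np.ndarray:
    """Wall thickness pattern: thinned inside the cuff, thickened at the
    throat and where the wide end loses contact with the vessel."""
    t = np.full_like(x, config.wall_thickness_base, dtype=float)
    if config.cuff is None:
        return t
    cuff = config.cuff
    inside = cuff.contains(x)
    t[inside] *= (1.0 - config.wall_thinning_fraction)
    for margin in (cuff.upstream_margin, cuff.downstream_margin):
        t += config.wall_margin_bump * np.exp(-((x - margin) ** 2)
                                              / (2 * config.wall_margin_sigma ** 2))
    return t


def gen_wall_depth_maps(config: StackConfig, seed: int) -> tuple[DepthMap, DepthMap, np.ndarray]:
    """Luminal and adventitial depth maps whose difference is the wall
    thickness truth (both voxelised on the stack's z grid)."""
    nx, ny = config.nx, config.ny
    x = config.x_offset + (np.arange(nx) + 0.5) * config.pixel_size_xy
    surface = _surface_depth(config)
    thickness = _wall_thickness_truth(config, x)[None, :] * np.ones((ny, 1))

    def voxelise(d: np.ndarray) -> np.ndarray:
        idx = np.ceil(d / config.z_spacing - 0.5)
        return (idx + 0.5) * config.z_spacing

    inner = voxelise(surface)
    outer = voxelise(surface + thickness)
    missing = np.zeros(inner.shape, dtype=bool)
    return (DepthMap(inner, missing), DepthMap(outer, missing.copy()),
            outer - inner)


# ---------------------------------------------------------------------------
# Lumen geometry
# ---------------------------------------------------------------------------

def _circle_contour(rx: float, ry: float, n: int = 128,
                    jitter: np.ndarray | None = None) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = np.ones(n)
    if jitter is not None:
        r = r + jitter
    return np.column_stack([rx * r * np.cos(th), ry * r * np.sin(th)])


def gen_lumen_geometry(
    cuff: CuffSpec | None = None,
    vessel_diameter: float = 500.0,
    entrance_narrowing: float = 0.0,
    throat_ellipticity: float = 1.0,
    n_stations: int | None = None,
    seed: int = 0,
    extent: tuple[float, float] = (-3000.0, 3000.0),
    wall_fraction: float = 0.10,
    n_vertices: int = 128,
    contour_jitter: float = 0.0,
) -> tuple[LumenGeometry, GroundTruth]:
    """Generate a straight carotid lumen, optionally constrained by a cuff.

    Inside the cuff the maximal lumen is bounded by the linearly tapering bore
    minus the wall: with wall thickness a fraction ``wall_fraction`` of the
    luminal diameter, lumen = bore / (1 + 2 * wall_fraction).  The throat
    contour is an area-preserving ellipse of the requested ellipticity
    (semi-axis ratio); ``entrance_narrowing`` is the fractional cross-section
    area reduction (inward remodelling) at the wide upstream end.
    """
    cuff = cuff if cuff is not None else CuffSpec()
    if vessel_diameter < 0.8 * cuff.wide_diameter:
        raise ValueError("vessel_diameter must be >= 0.8 x cuff wide_diameter")
    if throat_ellipticity < 1:
        raise ValueError("ellipticity must be >= 1")
    if not (0 <= entrance_narrowing < 1):
        raise ValueError("entrance_narrowing must be in [0, 1)")
    x0, x1 = extent
    if n_stations is None:
        n_stations = int(round((x1 - x0) / 5.0)) + 1
    if n_stations < 2:
        raise ValueError("need at least 2 stations")

    rng = np.random.default_rng(seed)
    x = np.linspace(x0, x1, n_stations)
    bore = cuff.bore_diameter(x)
    in_cuff = cuff.contains(x)

    lumen_d = np.full_like(x, float(vessel_diameter))
    constrained = bore / (1.0 + 2.0 * wall_fraction)
    lumen_d = np.where(in_cuff, np.minimum(lumen_d, constrained), lumen_d)

    if entrance_narrowing > 0:
        # inward remodelling centred on the wide end of the cuff
        wide_x = (cuff.upstream_margin if cuff.orientation == "forward"
                  else cuff.downstream_margin)
        bump = np.exp(-((x - wide_x) ** 2) / (2 * 300.0 ** 2))
        lumen_d = lumen_d * np.sqrt(1.0 - entrance_narrowing * bump)

    # ellipticity ramps up toward the throat (x = 0)
    ell = 1.0 + (throat_ellipticity - 1.0) * np.exp(-(x ** 2) / (2 * 250.0 ** 2))

    centerline = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    contours: list[np.ndarray] = []
    frames = []
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    for i in range(n_stations):
        r = lumen_d[i] / 2.0
        a = r * np.sqrt(ell[i])
        b = r / np.sqrt(ell[i])
        jitter = None
        if contour_jitter > 0:
            jitter = contour_jitter * rng.standard_normal(n_vertices)
        contours.append(_circle_contour(a, b, n_vertices, jitter))
        frames.append((centerline[i], e1, e2))

    s = x - x0
    geom = LumenGeometry(centerline=centerline, contours=contours, s=s,
                         station_spacing=float(s[1] - s[0]), frames=frames)
    truth = GroundTruth(
        seed=seed,
        extras={
            "x": x,
            "bore_diameter": bore,
            "lumen_diameter": lumen_d,
            "ellipticity": ell,
            "throat_x": 0.0,
            "wall_fraction": wall_fraction,
        },
    )
    return geom, truth


def cuff_bore_geometry(cuff: CuffSpec | None = None, spacing: float = 5.0,
                       n_vertices: int = 256) -> LumenGeometry:
    """The cuff bore itself as a tubular geometry (circular cross-sections
    along the linear taper), for morphometric verification."""
    cuff = cuff if cuff is not None else CuffSpec()
    lo, hi = sorted((cuff.upstream_margin, cuff.downstream_margin))
    n = int(round((hi - lo) / spacing)) + 1
    x = np.linspace(lo, hi, n)
    centerline = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    contours = []
    frames = []
    for i in range(n):
        r = float(cuff.bore_diameter(x[i])) / 2.0
        contours.append(_circle_contour(r, r, n_vertices))
        frames.append((centerline[i], e1, e2))
    return LumenGeometry(centerline=centerline, contours=contours, s=x - lo,
                         station_spacing=spacing, frames=frames)


# ---------------------------------------------------------------------------
# Doppler traces
# ---------------------------------------------------------------------------

def _beat_waveform(phase: np.ndarray, peak: float, edv: float,
                   systolic_phase: float, decay_q: float) -> np.ndarray:
    """One cardiac cycle of the envelope: a sin^2 upstroke peaking at
    ``systolic_phase`` then a power-law decay reaching EDV exactly at the beat
    boundary, so the pre-systolic boundary is the strict within-beat minimum."""
    ph = np.mod(phase, 1.0)
    rise = np.sin(np.pi * ph / (2 * systolic_phase)) ** 2
    fall = ((1.0 - ph) / (1.0 - systolic_phase)) ** decay_q
    g = np.where(ph < systolic_phase, rise, fall)
    return edv + (peak - edv) * g


def gen_doppler_trace(
    heart_rate_hz: float = 7.0,
    peak_v: float = 47.0,
    edv_v: float = 8.4,
    mean_v: float | None = None,
    n_beats: int = 10,
    breathing_mod: float = 0.1,
    noise: float = 0.005,
    sample_rate: float = 1000.0,
    seed: int = 0,
    systolic_phase: float = 0.15,
    decay_q: float = 3.0,
) -> tuple[DopplerTrace, GroundTruth]:
    """Pulsatile velocity envelope with per-beat truth metrics.

    ``mean_v`` (cycle-averaged velocity) may be given instead of the decay
    exponent; it must lie strictly between EDV + (peak-EDV)*systolic_phase/2
    and the value reached with decay exponent 1.  ``breathing_mod`` scales the
    whole envelope by 1 + m sin(2 pi t / T_breath) with one breathing cycle
    per 10 beats.  ``noise`` is multiplicative envelope jitter.
    """
    if not (peak_v > edv_v >= 0):
        raise ValueError("need peak_v > edv_v >= 0")
    if n_beats < 1:
        raise ValueError("need n_beats >= 1")
    if sample_rate < 20 * heart_rate_hz:
        raise ValueError("sample rate too low to resolve beats "
                         "(< 20 samples/beat)")
    if not (0 < systolic_phase < 1):
        raise ValueError("systolic_phase must be in (0, 1)")
    if mean_v is not None:
        frac = (mean_v - edv_v) / (peak_v - edv_v)
        lo = systolic_phase / 2
        hi = lo + (1 - systolic_phase) / 2
        if not (lo < frac < hi):
            raise ValueError("mean_v incompatible with peak/EDV and waveform")
        decay_q = (1 - systolic_phase) / (frac - lo) - 1.0

    rng = np.random.default_rng(seed)
    period = 1.0 / heart_rate_hz
    # pre/post-roll of 0.3 beat so every beat boundary is an interior minimum
    roll = 0.3
    n_samples = int(round((n_beats + 2 * roll) * period * sample_rate))
    t = np.arange(n_samples) / sample_rate
    phase = t / period - roll

    v0 = _beat_waveform(phase, peak_v, edv_v, systolic_phase, decay_q)
    if breathing_mod > 0:
        f_breath = heart_rate_hz / 10.0
        v0 = v0 * (1.0 + breathing_mod * np.sin(2 * np.pi * f_breath * t))
    v = v0.copy()
    if noise > 0:
        v = v0 * (1.0 + noise * rng.standard_normal(n_samples))
        v = np.clip(v, 0.0, None)

    # truth boundaries: the noise-free envelope's minimum sample around each
    # analytic beat boundary (k + roll) * period
    half = max(1, int(round(0.2 * period * sample_rate)))
    boundaries = []
    for k in range(n_beats + 1):
        a = int(round((k + roll) * period * sample_rate))
        lo, hi = max(0, a - half), min(n_samples, a + half + 1)
        boundaries.append(lo + int(np.argmin(v0[lo:hi])))
    boundaries = np.array(boundaries)

    peaks, edvs, means = [], [], []
    for k in range(n_beats):
        seg = v0[boundaries[k]:boundaries[k + 1]]
        peaks.append(seg.max())
        edvs.append(seg[0])
        means.append(seg.mean())
    truth = GroundTruth(
        seed=seed,
        true_beat_metrics={
            "peak_v": np.array(peaks),
            "edv": np.array(edvs),
            "cycle_mean": np.array(means),
        },
        extras={"boundaries": boundaries, "period_s": period,
                "decay_q": decay_q},
    )
    trace = DopplerTrace(t=t, v=v, sample_rate=sample_rate)
    return trace, truth


# ---------------------------------------------------------------------------
# Surface fields
# ---------------------------------------------------------------------------

def gen_surface_field(
    geometry: LumenGeometry,
    longitudinal_pattern: Callable[[np.ndarray], np.ndarray],
    circumferential_pattern: Callable[[np.ndarray], np.ndarray] | None = None,
    noise: float = 0.0,
    seed: int = 0,
    n_theta: int = 48,
    band_length: float = 40.0,
) -> tuple[SurfaceField, GroundTruth]:
    """Scalar field on the geometry's parametric (s, theta) surface.

    value(s, theta) = f(s) * g(theta) (+ Gaussian noise).  Truth stores the
    per-band mean and lower-5th-percentile mean of the noise-free values,
    computed by a direct per-node partition.
    """
    if geometry.frames is None:
        raise ValueError("geometry without parameterization")
    rng = np.random.default_rng(seed)
    s_st = geometry.s
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    S, TH = np.meshgrid(s_st, th, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.asarray(longitudinal_pattern(S.ravel()), dtype=float)
        g = (np.asarray(circumferential_pattern(TH.ravel()), dtype=float)
             if circumferential_pattern is not None else 1.0)
        vals = f * g
    if not np.isfinite(vals).all():
        raise ValueError("pattern not finite on the domain")
    clean = vals.copy()
    if noise > 0:
        vals = vals + noise * rng.standard_normal(vals.shape)

    field = SurfaceField(s=S.ravel(), theta=TH.ravel(), values=vals)

    # truth per contiguous 40 µm band, brute-force partition of clean values
    s0 = field.s.min()
    idx = np.floor((field.s - s0) / band_length).astype(int)
    band_mean, band_low5, centers = [], [], []
    for k in sorted(set(idx.tolist())):
        sel = clean[idx == k]
        m = int(np.ceil(0.05 * sel.size)) if sel.size >= 20 else 1
        low = np.sort(sel)[:m].mean()
        band_mean.append(sel.mean())
        band_low5.append(low)
        centers.append(s0 + (k + 0.5) * band_length)
    truth = GroundTruth(
        seed=seed,
        extras={
            "band_center": np.array(centers),
            "band_mean": np.array(band_mean),
            "band_low5_mean": np.array(band_low5),
            "band_length": band_length,
        },
    )
    return field, truth
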