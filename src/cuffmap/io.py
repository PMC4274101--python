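"""Readers and writers for the pipeline's on-disk formats.

Stacks travel as multi-page ImageJ-style TIFF (axes ZCYX, channel order
tracer / autofluorescence, 16-bit) with physical spacings in a YAML sidecar;
profiles, traces, surface fields and band tables as CSV; ground truth as
JSON; lumen surfaces as STL (trimesh) plus a centreline CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .doppler import BeatMetrics
from .types import DopplerTrace, EnFaceStack, LumenGeometry, SurfaceField, UptakeProfile

__all__ = [
    "save_stack", "load_stack",
    "save_profile", "load_profile",
    "save_trace", "load_trace",
    "save_field", "load_field",
    "save_metrics_json",
    "save_geometry", "load_centerline",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_stack(path: str | Path, stack: EnFaceStack) -> None:
    path = Path(path)
    data = np.stack([stack.tracer, stack.autofluorescence], axis=1)  # Z,C,Y,X
    hi = data.max()
    if hi > np.iinfo(np.uint16).max:
        raise ValueError("intensities exceed the 16-bit range")
    tifffile.imwrite(path, np.round(data).astype(np.uint16), imagej=True,
                     metadata={"axes": "ZCYX"})
    meta = {
        "pixel_size_xy_um": float(stack.pixel_size_xy),
        "z_spacing_um": float(stack.z_spacing),
        "x_offset_um": float(stack.x_offset),
        "channels": ["tracer", "autofluorescence"],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_stack(path: str | Path) -> EnFaceStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError("expected a 2-channel ZCYX stack")
    meta = yaml.safe_load(_sidecar(path).read_text())
    return EnFaceStack(
        tracer=data[:, 0], autofluorescence=data[:, 1],
        pixel_size_xy=meta["pixel_size_xy_um"],
        z_spacing=meta["z_spacing_um"],
        x_offset=meta["x_offset_um"],
    )


def save_profile(path: str | Path, profile: UptakeProfile) -> None:
    pd.DataFrame({
        "x_um": profile.x,
        "intensity": profile.intensity,
        "n_pixels": profile.n_pixels,
    }).to_csv(path, index=False)


def load_profile(path: str | Path) -> UptakeProfile:
    df = pd.read_csv(path)
    return UptakeProfile(x=df["x_um"].to_numpy(),
                         intensity=df["intensity"].to_numpy(),
                         n_pixels=df["n_pixels"].to_numpy())


def save_trace(path: str | Path, trace: DopplerTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "v_cm_s": trace.v}).to_csv(path, index=False)


def load_trace(path: str | Path) -> DopplerTrace:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return DopplerTrace(t=t, v=df["v_cm_s"].to_numpy(), sample_rate=rate)


def save_field(path: str | Path, field: SurfaceField) -> None:
    pd.DataFrame({"s_um": field.s, "theta_rad": field.theta,
                  "value_pa": field.values}).to_csv(path, index=False)


def load_field(path: str | Path) -> SurfaceField:
    df = pd.read_csv(path)
    return SurfaceField(s=df["s_um"].to_numpy(),
                        theta=df["theta_rad"].to_numpy(),
                        values=df["value_pa"].to_numpy())


def save_metrics_json(path: str | Path, metrics: BeatMetrics) -> None:
    Path(path).write_text(json.dumps({
        "peak_v_cm_s": metrics.peak_v,
        "edv_cm_s": metrics.edv,
        "cycle_mean_cm_s": metrics.cycle_mean,
        "n_beats": metrics.n_beats,
        "per_beat": {
            "peak_v": metrics.peak_v_beats.tolist(),
            "edv": metrics.edv_beats.tolist(),
            "cycle_mean": metrics.cycle_mean_beats.tolist(),
        },
    }, indent=2))


def save_geometry(mesh_path: str | Path, centerline_path: str | Path,
                  geometry: LumenGeometry) -> None:
    """Export the tubular surface as STL and the centreline as CSV."""
    if geometry.frames is None:
        raise ValueError("geometry without stored frames cannot be meshed")
    rings = [geometry.contour3d(i) for i in range(geometry.n_stations)]
    m = len(rings[0])
    verts = np.concatenate(rings)
    faces = []
    for i in range(len(rings) - 1):
        base, nxt = i * m, (i + 1) * m
        for j in range(m):
            k = (j + 1) % m
            faces.append([base + j, nxt + j, nxt + k])
            faces.append([base + j, nxt + k, base + k])
    trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                    process=False).export(str(mesh_path))
    pd.DataFrame(geometry.centerline, columns=["x_um", "y_um", "z_um"]) \
        .to_csv(centerline_path, index=False)


def load_centerline(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um", "z_um"]].to_numpy()
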