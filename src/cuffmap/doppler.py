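"""Doppler velocity-envelope metrics.

Beats are delimited at end-diastolic (pre-systolic) minima; per beat we read
the systolic peak (max of the envelope), the end-diastolic velocity (envelope
value at the beat boundary) and the cycle-averaged velocity (time average over
the beat), then average each over 10 contiguous beats — roughly one breathing
cycle, so respiratory modulation cancels.  Optional insonation-angle
correction divides by cos(theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .types import DopplerTrace

__all__ = [
    "BeatMetrics",
    "InsufficientBeatsError",
    "segment_beats",
    "beat_metrics",
    "angle_correct",
    "analyze_trace",
]


class InsufficientBeatsError(ValueError):
    """Fewer complete beats in the trace than the analysis requires."""


@dataclass
class BeatMetrics:
    """Per-beat velocities and their n-beat averages (cm/s)."""

    peak_v_beats: np.ndarray
    edv_beats: np.ndarray
    cycle_mean_beats: np.ndarray
    peak_v: float
    edv: float
    cycle_mean: float
    n_beats: int


def segment_beats(trace: DopplerTrace, expected_rate_hz: float,
                  smooth: bool = True) -> np.ndarray:
    """Find beat boundaries (end-diastolic minima) in an envelope trace.

    Minima are detected on an optionally low-pass-filtered copy of the
    envelope with a minimum separation of 0.6 / expected_rate; each boundary
    is then refined to the local argmin of the working signal.  Returns the
    boundary sample indices (one per detected beat start).
    """
    if expected_rate_hz <= 0:
        raise ValueError("expected_rate_hz must be positive")
    v = trace.v
    fs = trace.sample_rate
    min_len = int(np.ceil(2 * fs / expected_rate_hz))
    if v.size < min_len:
        raise ValueError("trace shorter than 2 beats at the expected rate")
    if np.ptp(v) == 0 or np.std(v) < 1e-12 * max(1.0, abs(v.mean())):
        raise ValueError("no detectable periodicity (constant trace)")
    work = v
    if smooth:
        # keep ~5 harmonics of the heart rate; enough to preserve minima
        cutoff = min(5.0 * expected_rate_hz, 0.45 * fs)
        b, a = butter(2, cutoff / (fs / 2), btype="low")
        work = filtfilt(b, a, v)
    # systolic peaks are the robust landmarks; boundaries are the envelope
    # minima between consecutive peaks (and in the leading/trailing margins)
    distance = max(1, int(round(0.6 * fs / expected_rate_hz)))
    prominence = 0.3 * np.ptp(work)
    peaks, _ = find_peaks(work, distance=distance, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("no detectable periodicity in the trace")
    period = fs / expected_rate_hz
    boundaries = []
    if peaks[0] > 0.25 * period:
        boundaries.append(int(np.argmin(work[: peaks[0]])))
    for a_, b_ in zip(peaks[:-1], peaks[1:]):
        boundaries.append(a_ + int(np.argmin(work[a_:b_])))
    if v.size - peaks[-1] > 0.5 * period:
        boundaries.append(peaks[-1] + int(np.argmin(work[peaks[-1]:])))
    return np.asarray(boundaries, dtype=int)


def beat_metrics(trace: DopplerTrace, boundaries: np.ndarray,
                 n_beats: int = 10) -> BeatMetrics:
    """Per-beat peak / end-diastolic / cycle-average velocities, averaged over
    the first ``n_beats`` contiguous complete beats."""
    boundaries = np.asarray(boundaries, dtype=int)
    n_complete = boundaries.size - 1
    if n_complete < n_beats:
        raise InsufficientBeatsError(
            f"analysis requires {n_beats} complete beats, trace has {n_complete}")
    peaks = np.empty(n_beats)
    edvs = np.empty(n_beats)
    means = np.empty(n_beats)
    for k in range(n_beats):
        seg = trace.v[boundaries[k]:boundaries[k + 1]]
        peaks[k] = seg.max()
        edvs[k] = seg[0]
        means[k] = seg.mean()
    return BeatMetrics(
        peak_v_beats=peaks, edv_beats=edvs, cycle_mean_beats=means,
        peak_v=float(peaks.mean()), edv=float(edvs.mean()),
        cycle_mean=float(means.mean()), n_beats=n_beats,
    )


def angle_correct(v_beam: float | np.ndarray, theta_deg: float):
    """Correct a beam-projected velocity for the insonation angle:
    v = v_beam / cos(theta)."""
    if not (0 <= theta_deg < 90):
        raise ValueError("insonation angle must lie in [0, 90) degrees")
    return v_beam / np.cos(np.deg2rad(theta_deg))


def analyze_trace(trace: DopplerTrace, expected_rate_hz: float,
                  n_beats: int = 10, angle_deg: float | None = None,
                  smooth: bool = True) -> BeatMetrics:
    """segment_beats + beat_metrics, with optional angle correction applied
    to the envelope first."""
    if angle_deg is not None:
        trace = DopplerTrace(t=trace.t, v=angle_correct(trace.v, angle_deg),
                             sample_rate=trace.sample_rate)
    boundaries = segment_beats(trace, expected_rate_hz, smooth=smooth)
    return beat_metrics(trace, boundaries, n_beats=n_beats)
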