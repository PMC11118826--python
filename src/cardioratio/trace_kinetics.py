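"""Kinetic parameters of Ca2+ transient (CaT) ratio traces.

Extracts, per chamber: systolic ratio (highest ratio in the cardiac
cycle), diastolic ratio (lowest), CaT amplitude (systolic - diastolic)
and atrial CaT frequency in min^-1, averaged over all cardiac cycles of
a continuous recording.  Also classifies atrioventricular conduction
from the atrial and ventricular event counts (a conducted ventricular
CaT accompanies every atrial CaT in a healthy heart; a drop in
ventricular CaT count marks an AV block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .ratio_imaging import RatioTrace

__all__ = [
    "CycleSet",
    "CaTMetrics",
    "AvBlockReport",
    "smooth_trace",
    "segment_cycles",
    "cat_metrics",
    "detect_av_block",
    "analyze_av_conduction",
]


@dataclass
class CycleSet:
    """Detected peaks and trough-to-trough cycle intervals of one trace.

    ``cycle_bounds`` are half-open frame intervals, each containing
    exactly one peak; leading/trailing partial cycles are discarded.
    A flat (quiescent) trace yields zero peaks, not an error.
    """

    peak_indices: np.ndarray
    cycle_bounds: list[tuple[int, int]]
    refractory: float
    quiescent: bool = False

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds)


@dataclass
class CaTMetrics:
    """Per-chamber kinetic summary averaged over all cardiac cycles."""

    systolic: float
    diastolic: float
    amplitude: float
    frequency: float
    frequency_interval: float
    n_cycles: int
    recording_duration: float


@dataclass
class AvBlockReport:
    """Atrioventricular conduction assessment from chamber event counts."""

    atrial_count: int
    ventricular_count: int
    conduction_ratio_estimate: float
    block_present: bool
    block_class: str


def _fill_missing(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN samples (edges held at nearest value)."""
    v = np.asarray(values, dtype=float)
    bad = ~np.isfinite(v)
    if not bad.any():
        return v.copy()
    if bad.all():
        raise ValueError("trace contains no finite samples")
    idx = np.arange(len(v))
    out = v.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return out


def smooth_trace(trace: RatioTrace, window: int = 11, polyorder: int = 3) -> RatioTrace:
    """Savitzky-Golay least-squares polynomial smoothing.

    Missing samples are linearly interpolated before filtering and
    re-flagged as missing afterwards; length is preserved.  A polynomial
    of degree <= polyorder passes through unchanged on interior points.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > len(trace.values):
        raise ValueError("window longer than the trace")
    filled = _fill_missing(trace.values)
    smoothed = savgol_filter(filled, window_length=window, polyorder=polyorder)
    smoothed[~np.isfinite(trace.values)] = np.nan
    return replace(trace, values=smoothed)


def segment_cycles(
    trace: RatioTrace,
    prominence_fraction: float = 0.3,
    refractory: float = 0.1,
    min_amplitude: float | None = None,
) -> CycleSet:
    """Detect CaT peaks and delimit cardiac cycles trough-to-trough.

    Peaks are local maxima with prominence >= prominence_fraction x the
    trace's robust amplitude (95th - 5th percentile) spaced at least
    ``refractory`` seconds apart.  ``min_amplitude`` optionally sets an
    absolute floor on the robust amplitude below which the trace is
    declared quiescent (used to reject noise peaks in a chamber whose
    transients have stopped, e.g. the ventricle under complete AV
    block); without it, a trace whose robust amplitude is numerically
    zero is quiescent.

    Cycle bounds run from each inter-peak minimum to the next, plus the
    post-trace-final minimum after the last peak, so ``m`` detected peaks
    yield ``m - 1`` complete cycles; the leading partial cycle (before
    the first trough) is discarded.
    """
    if len(trace.values) < 3:
        raise ValueError("trace too short to segment")
    if not (0 < prominence_fraction < 1):
        raise ValueError("prominence_fraction must be in (0, 1)")
    v = _fill_missing(trace.values)
    dt = trace.time_step
    robust_amp = float(np.percentile(v, 95) - np.percentile(v, 5))
    floor = min_amplitude if min_amplitude is not None else 1e-9 * max(
        1.0, abs(float(np.median(v)))
    )
    if robust_amp <= floor:
        return CycleSet(
            peak_indices=np.array([], dtype=int),
            cycle_bounds=[],
            refractory=refractory,
            quiescent=True,
        )
    distance = max(1, int(math.ceil(refractory / dt)))
    peaks, _ = find_peaks(
        v, prominence=prominence_fraction * robust_amp, distance=distance
    )
    if len(peaks) < 2:
        return CycleSet(
            peak_indices=peaks, cycle_bounds=[], refractory=refractory
        )
    troughs = [
        peaks[i] + int(np.argmin(v[peaks[i] : peaks[i + 1] + 1]))
        for i in range(len(peaks) - 1)
    ]
    troughs.append(peaks[-1] + int(np.argmin(v[peaks[-1] :])))
    bounds = [
        (int(troughs[i]), int(troughs[i + 1])) for i in range(len(troughs) - 1)
    ]
    return CycleSet(
        peak_indices=peaks, cycle_bounds=bounds, refractory=refractory
    )


def cat_metrics(trace: RatioTrace, cycles: CycleSet) -> CaTMetrics:
    """Cycle-averaged systolic/diastolic ratio, amplitude and frequency.

    Systolic (diastolic) is the mean over complete cycles of the
    per-cycle maximum (minimum) ratio; amplitude is their difference.
    Frequency is canonical as peak count / recording duration x 60; the
    mean inter-peak interval estimate is reported alongside.  A
    quiescent trace reports frequency 0 and missing level metrics.
    """
    if len(trace.values) == 0:
        raise ValueError("empty trace")
    v = _fill_missing(trace.values)
    duration = trace.duration
    freq = cycles.n_peaks / duration * 60.0
    if cycles.n_peaks >= 2:
        intervals = np.diff(trace.time[cycles.peak_indices])
        freq_iv = 60.0 / float(np.mean(intervals))
    else:
        freq_iv = float("nan")
    if cycles.n_cycles == 0:
        return CaTMetrics(
            systolic=float("nan"),
            diastolic=float("nan"),
            amplitude=float("nan"),
            frequency=freq,
            frequency_interval=freq_iv,
            n_cycles=0,
            recording_duration=duration,
        )
    maxima = [float(np.max(v[a : b + 1])) for a, b in cycles.cycle_bounds]
    minima = [float(np.min(v[a : b + 1])) for a, b in cycles.cycle_bounds]
    systolic = float(np.mean(maxima))
    diastolic = float(np.mean(minima))
    return CaTMetrics(
        systolic=systolic,
        diastolic=diastolic,
        amplitude=systolic - diastolic,
        frequency=freq,
        frequency_interval=freq_iv,
        n_cycles=cycles.n_cycles,
        recording_duration=duration,
    )


def detect_av_block(
    atrial: CycleSet, ventricular: CycleSet, duration: float
) -> AvBlockReport:
    """Classify atrioventricular conduction from chamber event counts.

    Block is called when the ventricle shows at least two fewer CaTs
    than the atrium (one event of slack absorbs window-edge effects).
    An atrial:ventricular count ratio within 0.1 of an integer n >= 2 is
    reported as "n:1"; a silent ventricle with active atrium is a
    complete block, reported as "irregular"; other deficits are
    "irregular" too.
    """
    if duration <= 0:
        raise ValueError("zero-duration window")
    a, v = atrial.n_peaks, ventricular.n_peaks
    block = a > 0 and v <= a - 2
    ratio = a / v if v > 0 else float("inf")
    if not block:
        cls = "none"
    elif v == 0:
        cls = "irregular"
    else:
        n = round(ratio)
        cls = f"{n}:1" if n >= 2 and abs(ratio - n) <= 0.1 else "irregular"
    return AvBlockReport(
        atrial_count=a,
        ventricular_count=v,
        conduction_ratio_estimate=ratio,
        block_present=bool(block),
        block_class=cls,
    )


def analyze_av_conduction(
    atrial_trace: RatioTrace,
    ventricular_trace: RatioTrace,
    window: int = 11,
    polyorder: int = 3,
    prominence_fraction: float = 0.3,
    refractory: float = 0.1,
    ventricular_floor_fraction: float = 0.4,
) -> AvBlockReport:
    """Smooth both chamber traces, count CaTs, and classify conduction.

    The ventricular quiescence floor is set to
    ``ventricular_floor_fraction`` x the atrial robust amplitude:
    conducted ventricular transients are comparable in size to atrial
    ones, so a ventricle whose excursion falls well below that scale has
    stopped transienting rather than merely quieted down.
    """
    sm_a = smooth_trace(atrial_trace, window, polyorder)
    sm_v = smooth_trace(ventricular_trace, window, polyorder)
    va = _fill_missing(sm_a.values)
    atrial_amp = float(np.percentile(va, 95) - np.percentile(va, 5))
    cyc_a = segment_cycles(sm_a, prominence_fraction, refractory)
    cyc_v = segment_cycles(
        sm_v,
        prominence_fraction,
        refractory,
        min_amplitude=ventricular_floor_fraction * atrial_amp,
    )
    return detect_av_block(cyc_a, cyc_v, atrial_trace.duration)
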