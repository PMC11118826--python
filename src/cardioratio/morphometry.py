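"""Chamber and yolk areas, and the fractional area change (FAC).

FAC = (end-diastolic area - end-systolic area) / end-diastolic area is
the 2-D index of contraction strength.  The canonical area measurement
is the raster (pixel-count) area, matching analysis on pixel images;
the polygon-exact shoelace area is reported alongside for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ratio_imaging import RatioTrace, Roi
from .trace_kinetics import segment_cycles

__all__ = [
    "ChamberAreas",
    "RoiArea",
    "ExtremeSelection",
    "roi_area",
    "fractional_area_change",
    "frame_select_extremes",
    "fac_from_area_trace",
]


@dataclass
class RoiArea:
    """Area of one ROI: raster (canonical) and polygon shoelace (QC)."""

    raster_area: float
    shoelace_area: float
    n_pixels: int


@dataclass
class ChamberAreas:
    """End-diastolic/end-systolic chamber areas (um^2) and their FAC."""

    end_diastolic_area: float
    end_systolic_area: float
    fac: float


@dataclass
class ExtremeSelection:
    """Frames selected as end-diastole / end-systole on an area trace.

    When no full cycle of area oscillation is present the global
    extremes are returned, flagged ``no_cycle``.
    """

    end_diastolic_frames: np.ndarray
    end_systolic_frames: np.ndarray
    end_diastolic_area: float
    end_systolic_area: float
    no_cycle: bool


def roi_area(roi: Roi, pixel_size: float) -> RoiArea:
    """ROI area in um^2: mask-pixel count x pixel_size^2, plus shoelace."""
    n = int(roi.mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    return RoiArea(
        raster_area=n * pixel_size**2,
        shoelace_area=roi.shoelace_area_px() * pixel_size**2,
        n_pixels=n,
    )


def fractional_area_change(end_diastolic: float, end_systolic: float) -> float:
    """FAC = (ED - ES)/ED.  Negative values (swapped frames) are allowed
    and should be flagged by the caller as anomalous, not clamped."""
    if end_diastolic <= 0:
        raise ValueError("end-diastolic area must be positive")
    if end_systolic < 0:
        raise ValueError("end-systolic area cannot be negative")
    return (end_diastolic - end_systolic) / end_diastolic


def frame_select_extremes(
    area_trace: np.ndarray,
    time_step: float,
    prominence_fraction: float = 0.3,
    refractory: float = 0.1,
) -> ExtremeSelection:
    """Per-cycle end-diastolic (max) and end-systolic (min) area frames.

    Applies the same cycle-segmentation logic used for CaT kinetics to
    the area trace: per-cycle maxima/minima are located and their areas
    averaged.  A trace without a full oscillation cycle falls back to
    the global max/min, flagged ``no_cycle``.
    """
    area = np.asarray(area_trace, dtype=float)
    if area.size == 0:
        raise ValueError("empty area trace")
    time = np.arange(len(area)) * time_step
    trace = RatioTrace(values=area, time=time, roi_label="area")
    if len(area) >= 3:
        cycles = segment_cycles(trace, prominence_fraction, refractory)
    else:
        cycles = None
    if cycles is None or cycles.n_cycles == 0:
        ed = int(np.argmax(area))
        es = int(np.argmin(area))
        return ExtremeSelection(
            end_diastolic_frames=np.array([ed]),
            end_systolic_frames=np.array([es]),
            end_diastolic_area=float(area[ed]),
            end_systolic_area=float(area[es]),
            no_cycle=True,
        )
    ed_frames, es_frames = [], []
    for a, b in cycles.cycle_bounds:
        seg = area[a : b + 1]
        ed_frames.append(a + int(np.argmax(seg)))
        es_frames.append(a + int(np.argmin(seg)))
    return ExtremeSelection(
        end_diastolic_frames=np.asarray(ed_frames),
        end_systolic_frames=np.asarray(es_frames),
        end_diastolic_area=float(np.mean(area[ed_frames])),
        end_systolic_area=float(np.mean(area[es_frames])),
        no_cycle=False,
    )


def fac_from_area_trace(
    area_trace: np.ndarray, time_step: float, **kwargs
) -> ChamberAreas:
    """Cycle-averaged FAC of a chamber from its area-per-frame trace."""
    sel = frame_select_extremes(area_trace, time_step, **kwargs)
    return ChamberAreas(
        end_diastolic_area=sel.end_diastolic_area,
        end_systolic_area=sel.end_systolic_area,
        fac=fractional_area_change(sel.end_diastolic_area, sel.end_systolic_area),
    )
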