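"""Motion-robust ratiometric analysis of dual-emission-channel movies.

The processing chain mirrors standard ratiometric optical-mapping
practice: correct the fixed pixel shift between the two emission
channels, form the emission ratio pixel-by-pixel at each time point,
invalidate pixels whose ratio falls outside the credible range (near-
background pixels produce unbounded ratios), and average the ratio over
an ROI with per-pixel weights equal to the mean intensity of the two
channels.  Because tissue motion modulates both channels identically,
the per-pixel ratio — and hence the weighted ROI trace — is insensitive
to contraction, while either single channel is not.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

__all__ = [
    "DualChannelMovie",
    "RatioMovie",
    "Roi",
    "RatioTrace",
    "estimate_pixel_shift",
    "apply_shift",
    "compute_ratio_movie",
    "roi_weighted_ratio",
    "render_ratio_display",
    "read_imagej_roi_zip",
]


@dataclass
class DualChannelMovie:
    """Time-aligned pair of emission-channel stacks (T x H x W, counts).

    ``numerator_stack`` holds the Ca2+-reporting channel (FRET acceptor,
    or the Ca2+-sensitive channel of a reference-fused sensor);
    ``denominator_stack`` the donor or reference channel.
    ``field_mask`` marks pixels with valid data in both channels (pixels
    lost to shift correction are excluded, not zero-filled).
    """

    numerator_stack: np.ndarray
    denominator_stack: np.ndarray
    time_step: float
    pixel_size: float = 1.45
    channel_roles: tuple[str, str] = ("acceptor", "donor")
    declared_shift: tuple[int, int] | None = None
    field_mask: np.ndarray | None = None

    def __post_init__(self):
        num, den = self.numerator_stack, self.denominator_stack
        if num.shape != den.shape or num.ndim != 3:
            raise ValueError("channel stacks must share one T x H x W shape")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if np.nanmin(num) < 0 or np.nanmin(den) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.numerator_stack.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.numerator_stack.shape[1:]

    @property
    def time(self) -> np.ndarray:
        """Frame-start timestamps, half-open [0, duration)."""
        return np.arange(self.n_frames) * self.time_step

    def in_field(self) -> np.ndarray:
        if self.field_mask is None:
            return np.ones(self.image_shape, dtype=bool)
        return self.field_mask


@dataclass
class RatioMovie:
    """Per-pixel ratio stack plus the validity mask from the clipping rule.

    A pixel at a time point is valid iff the denominator is positive and
    the ratio lies within [clip_low, clip_high] where clip_low is the
    minimum displayed ratio / 4 and clip_high the maximum displayed
    ratio x 4.  Invalid pixels are excluded from ROI statistics rather
    than clamped; clamping is applied only for display rendering.
    """

    ratio_stack: np.ndarray
    valid_mask: np.ndarray
    display_range: tuple[float, float]
    time_step: float

    @property
    def clip_low(self) -> float:
        return self.display_range[0] / 4.0

    @property
    def clip_high(self) -> float:
        return self.display_range[1] * 4.0


@dataclass
class Roi:
    """Polygonal region of interest on the image grid.

    Vertices are (row, col) pixel coordinates, 0-based; a pixel belongs
    to the ROI if its center lies inside the polygon.
    """

    label: str
    polygon: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_polygon(cls, label: str, vertices, image_shape) -> "Roi":
        polygon = np.asarray(vertices, dtype=float)
        if polygon.ndim != 2 or polygon.shape[1] != 2 or len(polygon) < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        h, w = image_shape
        path = _MplPath(polygon[:, ::-1])  # matplotlib paths are (x, y)
        yy, xx = np.mgrid[:h, :w]
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        mask = path.contains_points(centers).reshape(h, w)
        if not mask.any():
            raise ValueError(f"ROI {label!r} covers no pixel centers")
        return cls(label=label, polygon=polygon, mask=mask)

    def shoelace_area_px(self) -> float:
        y, x = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class RatioTrace:
    """ROI ratio time series; frames without valid pixels hold NaN."""

    values: np.ndarray
    time: np.ndarray
    roi_label: str = ""
    n_valid_pixels_per_frame: np.ndarray | None = None

    @property
    def time_step(self) -> float:
        if len(self.time) > 1:
            return float(self.time[1] - self.time[0])
        return float("nan")

    @property
    def duration(self) -> float:
        """Recording length on the half-open time axis."""
        return len(self.values) * self.time_step


# ---------------------------------------------------------------------------
# Pixel-shift correction
# ---------------------------------------------------------------------------


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def estimate_pixel_shift(movie: DualChannelMovie, max_shift: int = 5):
    """Integer (dy, dx) displacement of the denominator channel.

    Maximizes the normalized cross-correlation between the time-averaged
    channel images over all integer shifts within +-max_shift.  Ties are
    broken toward the smaller Euclidean shift, then lexicographically.
    The returned shift is the one to pass to :func:`apply_shift`.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    avg_num = movie.numerator_stack.mean(axis=0)
    avg_den = movie.denominator_stack.mean(axis=0)
    if avg_num.std() == 0 or avg_den.std() == 0:
        raise ValueError("flat channel image: pixel shift is indeterminate")
    h, w = avg_num.shape
    best = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys0 = slice(max(-dy, 0), h + min(-dy, 0))
            xs0 = slice(max(-dx, 0), w + min(-dx, 0))
            score = _ncc(avg_num[ys0, xs0], avg_den[ys, xs])
            if np.isnan(score):
                continue
            key = (-score, dy * dy + dx * dx, dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx))
    if best is None:
        raise ValueError("no valid shift found within max_shift")
    return best[1]


def apply_shift(movie: DualChannelMovie, shift: tuple[int, int]) -> DualChannelMovie:
    """Undo the denominator-channel displacement ``shift``.

    The denominator stack is translated by -shift; pixels whose source
    falls outside the field of view are marked invalid in the movie's
    ``field_mask`` (and excluded from all downstream statistics), never
    zero-filled.
    """
    dy, dx = int(shift[0]), int(shift[1])
    h, w = movie.image_shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError("shift larger than the image")
    den = np.empty_like(movie.denominator_stack)
    den[:] = np.nan
    ys = slice(max(-dy, 0), h + min(-dy, 0))
    xs = slice(max(-dx, 0), w + min(-dx, 0))
    ys_src = slice(max(dy, 0), h + min(dy, 0))
    xs_src = slice(max(dx, 0), w + min(dx, 0))
    den[:, ys, xs] = movie.denominator_stack[:, ys_src, xs_src]
    field = movie.in_field().copy()
    valid = np.zeros((h, w), dtype=bool)
    valid[ys, xs] = True
    field &= valid
    den = np.where(field[None], den, 0.0)
    return DualChannelMovie(
        numerator_stack=movie.numerator_stack.copy(),
        denominator_stack=den,
        time_step=movie.time_step,
        pixel_size=movie.pixel_size,
        channel_roles=movie.channel_roles,
        declared_shift=(0, 0),
        field_mask=field,
    )


# ---------------------------------------------------------------------------
# Ratio computation
# ---------------------------------------------------------------------------


def compute_ratio_movie(
    movie: DualChannelMovie, display_range: tuple[float, float] = (0.5, 3.0)
) -> RatioMovie:
    """Pixel-by-pixel emission ratio at each time point, with clipping mask.

    A pixel is invalid when its denominator is <= 0 (or out of field) or
    when the ratio falls below display minimum / 4 or above display
    maximum x 4 — near-background pixels can reach unbounded ratios and
    would otherwise dominate ROI statistics.
    """
    lo, hi = display_range
    if not (0 < lo < hi):
        raise ValueError("display_range must satisfy 0 < min < max")
    num = movie.numerator_stack
    den = movie.denominator_stack
    field = movie.in_field()
    pos = (den > 0) & field[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pos, num / np.where(pos, den, 1.0), np.nan)
    valid = pos & (ratio >= lo / 4.0) & (ratio <= hi * 4.0)
    return RatioMovie(
        ratio_stack=ratio,
        valid_mask=valid,
        display_range=(float(lo), float(hi)),
        time_step=movie.time_step,
    )


def roi_weighted_ratio(
    ratio: RatioMovie, movie: DualChannelMovie, roi: Roi
) -> RatioTrace:
    """Intensity-weighted mean ratio over an ROI, per frame.

    Each valid pixel contributes with weight (I_num + I_den)/2, the
    average intensity of the two channels; frames with no valid pixel
    yield NaN and are reported through ``n_valid_pixels_per_frame``.
    """
    if roi.mask.shape != movie.image_shape:
        raise ValueError("ROI mask does not match the movie geometry")
    if not roi.mask.any():
        raise ValueError("empty ROI")
    sel = ratio.valid_mask & roi.mask[None]
    weights = 0.5 * (movie.numerator_stack + movie.denominator_stack)
    weights = np.where(sel, weights, 0.0)
    wsum = weights.sum(axis=(1, 2))
    wr = np.where(sel, weights * ratio.ratio_stack, 0.0).sum(axis=(1, 2))
    n_valid = sel.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(wsum > 0, wr / np.where(wsum > 0, wsum, 1.0), np.nan)
    return RatioTrace(
        values=values,
        time=movie.time,
        roi_label=roi.label,
        n_valid_pixels_per_frame=n_valid,
    )


def render_ratio_display(
    ratio: RatioMovie, movie: DualChannelMovie, frame: int
) -> np.ndarray:
    """Pseudocolor rendering: hue codes the ratio, brightness the intensity.

    Hue is mapped linearly over the display range (values outside are
    clamped to the range ends for display only, blue = low to red =
    high); brightness is proportional to the mean channel intensity.
    Invalid pixels are dark.  Purely presentational — never feeds any
    measurement.  Returns an H x W x 3 float RGB image in [0, 1].
    """
    from matplotlib.colors import hsv_to_rgb

    if not (0 <= frame < ratio.ratio_stack.shape[0]):
        raise IndexError("frame out of range")
    lo, hi = ratio.display_range
    r = ratio.ratio_stack[frame]
    valid = ratio.valid_mask[frame]
    rn = np.clip((np.where(valid, r, lo) - lo) / (hi - lo), 0.0, 1.0)
    hue = (1.0 - rn) * (2.0 / 3.0)  # blue -> red
    intensity = 0.5 * (
        movie.numerator_stack[frame] + movie.denominator_stack[frame]
    )
    peak = intensity[valid].max() if valid.any() else 1.0
    value = np.where(valid, intensity / max(peak, 1e-12), 0.0)
    hsv = np.stack([hue, np.ones_like(hue), np.clip(value, 0, 1)], axis=-1)
    return hsv_to_rgb(hsv)


# ---------------------------------------------------------------------------
# ImageJ ROI import (read-only)
# ---------------------------------------------------------------------------

_IJ_POLYGON, _IJ_RECT, _IJ_FREEHAND = 0, 1, 7


def _parse_imagej_roi(data: bytes, name: str):
    if data[:4] != b"Iout":
        raise ValueError(f"{name}: not an ImageJ ROI file")
    roi_type = data[6]
    top, left, bottom, right, n = struct.unpack(">hhhhh", data[8:18])
    if roi_type == _IJ_RECT:
        verts = [(top, left), (top, right), (bottom, right), (bottom, left)]
        return np.asarray(verts, dtype=float)
    if roi_type in (_IJ_POLYGON, _IJ_FREEHAND):
        xs = struct.unpack(f">{n}h", data[64 : 64 + 2 * n])
        ys = struct.unpack(f">{n}h", data[64 + 2 * n : 64 + 4 * n])
        return np.column_stack(
            [np.asarray(ys, dtype=float) + top, np.asarray(xs, dtype=float) + left]
        )
    raise ValueError(f"{name}: unsupported ImageJ ROI type {roi_type}")


def read_imagej_roi_zip(path, image_shape) -> list[Roi]:
    """Read polygon/rectangle/freehand ROIs from an ImageJ ROI zip archive."""
    rois = []
    with zipfile.ZipFile(path) as zf:
        for entry in sorted(zf.namelist()):
            if not entry.lower().endswith(".roi"):
                continue
            verts = _parse_imagej_roi(zf.read(entry), entry)
            label = entry[:-4].rsplit("/", 1)[-1]
            rois.append(Roi.from_polygon(label, verts, image_shape))
    return rois
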