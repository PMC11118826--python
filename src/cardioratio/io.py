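"""File formats: multi-page TIFF movies, trace/metric CSV, config YAML."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ratio_imaging import DualChannelMovie, RatioTrace, Roi
from .synthetic_heart import GroundTruth, HeartSimConfig

__all__ = [
    "write_movie_pair",
    "write_movie_split",
    "read_movie_pair",
    "read_movie_split",
    "write_trace_csv",
    "read_trace_csv",
    "write_rois_json",
    "read_rois_json",
    "write_config_yaml",
    "read_config_yaml",
    "write_ground_truth",
]


def _to_uint16(stack: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16)


def write_movie_pair(movie: DualChannelMovie, base_path) -> tuple[Path, Path]:
    """Write the two channels as <base>_ch1.tif / <base>_ch2.tif (16-bit)."""
    base = Path(base_path)
    p1 = base.with_name(base.name + "_ch1.tif")
    p2 = base.with_name(base.name + "_ch2.tif")
    tifffile.imwrite(p1, _to_uint16(movie.numerator_stack))
    tifffile.imwrite(p2, _to_uint16(movie.denominator_stack))
    return p1, p2


def write_movie_split(movie: DualChannelMovie, path) -> Path:
    """Write one split-frame stack: numerator left, denominator right.

    Emulates an image-splitter acquisition dividing the camera field
    into two half-frames along the vertical midline.
    """
    path = Path(path)
    frames = np.concatenate(
        [_to_uint16(movie.numerator_stack), _to_uint16(movie.denominator_stack)],
        axis=2,
    )
    tifffile.imwrite(path, frames)
    return path


def read_movie_pair(
    path_num, path_den, time_step: float, pixel_size: float = 1.45, **kwargs
) -> DualChannelMovie:
    num = tifffile.imread(path_num).astype(float)
    den = tifffile.imread(path_den).astype(float)
    return DualChannelMovie(num, den, time_step=time_step, pixel_size=pixel_size, **kwargs)


def read_movie_split(
    path,
    time_step: float,
    pixel_size: float = 1.45,
    split: str = "vertical",
    numerator_side: str = "left",
    **kwargs,
) -> DualChannelMovie:
    """Read a split-frame stack; halves along the declared midline."""
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    axis = 2 if split == "vertical" else 1
    if frames.shape[axis] % 2:
        raise ValueError("cannot split an odd-sized axis into two half-frames")
    first, second = np.split(frames, 2, axis=axis)
    if numerator_side in ("left", "top"):
        num, den = first, second
    else:
        num, den = second, first
    return DualChannelMovie(num, den, time_step=time_step, pixel_size=pixel_size, **kwargs)


def write_trace_csv(trace: RatioTrace, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time": trace.time, "value": trace.values})
    if trace.n_valid_pixels_per_frame is not None:
        df["n_valid"] = trace.n_valid_pixels_per_frame
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path, roi_label: str = "") -> RatioTrace:
    df = pd.read_csv(path)
    return RatioTrace(
        values=df["value"].to_numpy(dtype=float),
        time=df["time"].to_numpy(dtype=float),
        roi_label=roi_label or Path(path).stem,
        n_valid_pixels_per_frame=(
            df["n_valid"].to_numpy() if "n_valid" in df else None
        ),
    )


def write_rois_json(rois: list[Roi], path) -> Path:
    path = Path(path)
    payload = [
        {"label": r.label, "polygon": np.asarray(r.polygon).tolist()} for r in rois
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_rois_json(path, image_shape) -> list[Roi]:
    payload = json.loads(Path(path).read_text())
    return [
        Roi.from_polygon(item["label"], item["polygon"], image_shape)
        for item in payload
    ]


def write_config_yaml(config: HeartSimConfig, path) -> Path:
    path = Path(path)
    data = asdict(config)
    for key in ("image_shape", "channel_pixel_shift"):
        data[key] = list(data[key])
    for key in ("ca_diastolic", "ca_systolic"):
        if isinstance(data[key], tuple):
            data[key] = list(data[key])
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_config_yaml(path) -> HeartSimConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("image_shape", "channel_pixel_shift"):
        if key in data:
            data[key] = tuple(data[key])
    for key in ("ca_diastolic", "ca_systolic"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return HeartSimConfig(**data)


def write_ground_truth(gt: GroundTruth, base_path) -> tuple[Path, Path]:
    """Ground truth as JSON (scalars/events) + CSV (per-frame traces)."""
    base = Path(base_path)
    scalars = {
        "atrial_event_times": gt.atrial_event_times.tolist(),
        "ventricular_event_times": gt.ventricular_event_times.tolist(),
        "true_frequency": gt.true_frequency,
        "end_diastolic_area": gt.end_diastolic_area,
        "end_systolic_area": gt.end_systolic_area,
        "true_fac": gt.true_fac,
    }
    p_json = base.with_name(base.name + "_truth.json")
    p_json.write_text(json.dumps(scalars, indent=2))
    cols = {
        "time": gt.time,
        "atrial_ca": gt.atrial_ca,
        "ventricular_ca": gt.ventricular_ca,
    }
    for chamber, ratio in gt.true_ratio_trace.items():
        cols[f"ratio_{chamber}"] = ratio
    if gt.ventricular_area is not None:
        cols["ventricular_area"] = gt.ventricular_area
    p_csv = base.with_name(base.name + "_truth.csv")
    pd.DataFrame(cols).to_csv(p_csv, index=False)
    return p_json, p_csv
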