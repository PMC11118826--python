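"""Orchestration: simulate -> ratio -> kinetics -> morphometry -> stats.

A run is fully described by a :class:`RunConfig` (scenario groups with
per-group n, seeds derived from one base seed, and the parameter blocks
of every analysis stage).  Rerunning the same config reproduces every
numeric output bit-for-bit.

Two pipeline levels are supported:

* ``render_movies=True`` — each larva is rendered as a dual-channel
  movie; shift correction, pixel-wise ratioing and intensity-weighted
  ROI averaging produce the ratio traces, and the ventricular area is
  measured by counting chamber-mask pixels per frame.
* ``render_movies=False`` — the measurement chain is emulated at trace
  level: the forward-model ratio trace plus Gaussian measurement noise
  (a stated fraction of the CaT amplitude).  This is how large
  repeated-seed designs are run; the imaging stages are validated
  separately on rendered movies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry, trace_kinetics
from .group_stats import GroupTable, TestResult
from .ratio_imaging import (
    RatioTrace,
    Roi,
    apply_shift,
    compute_ratio_movie,
    estimate_pixel_shift,
    roi_weighted_ratio,
)
from .synthetic_heart import (
    CHAMBERS,
    chamber_polygon,
    jitter_config,
    render_dual_channel_movie,
    scenario_preset,
    simulate_ca_dynamics,
    ventricular_area_truth,
)

__all__ = ["GroupSpec", "RunConfig", "ExperimentResult", "validate_config",
           "run_experiment", "larva_seed"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("systolic", "diastolic", "amplitude", "frequency")


@dataclass
class GroupSpec:
    """One experimental group: a scenario preset, its size, and overrides."""

    name: str
    scenario: str
    n: int
    overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment end to end."""

    groups: list[GroupSpec]
    base_seed: int = 0
    render_movies: bool = True
    noise_sd_fraction: float = 0.1
    area_noise_fraction: float = 0.005
    jitter_level_cv: float = 0.05
    jitter_fac_sd: float = 0.02
    display_range: tuple[float, float] = (0.5, 3.0)
    smooth_window: int = 11
    smooth_polyorder: int = 3
    prominence_fraction: float = 0.3
    refractory: float = 0.1
    max_shift: int = 5
    stats_mode: str = "all_pairs"
    control_group: str | None = None
    out_dir: str | None = None


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    group_table: GroupTable
    stats: pd.DataFrame
    av_reports: pd.DataFrame
    manifest: dict
    out_dir: Path | None = None


def validate_config(config: RunConfig) -> list[str]:
    """All config-invariant violations, each with its parameter path."""
    problems = []
    if not config.groups:
        problems.append("groups: at least one group is required")
    names = [g.name for g in config.groups]
    if len(set(names)) != len(names):
        problems.append("groups: duplicate group names")
    for g in config.groups:
        if g.n < 1:
            problems.append(f"groups[{g.name}].n: must be >= 1")
        try:
            scenario_preset(g.scenario, **g.overrides)
        except (KeyError, ValueError, TypeError) as exc:
            problems.append(f"groups[{g.name}].scenario: {exc}")
    if config.smooth_window % 2 == 0:
        problems.append("smooth_window: must be odd")
    if config.smooth_window <= config.smooth_polyorder:
        problems.append("smooth_window: must exceed smooth_polyorder")
    if not (0 < config.prominence_fraction < 1):
        problems.append("prominence_fraction: must be in (0, 1)")
    if not (0 < config.display_range[0] < config.display_range[1]):
        problems.append("display_range: must satisfy 0 < min < max")
    if not (0 <= config.noise_sd_fraction):
        problems.append("noise_sd_fraction: must be >= 0")
    seeds = [
        larva_seed(config.base_seed, gi, i)
        for gi, g in enumerate(config.groups)
        for i in range(max(g.n, 0))
    ]
    if len(set(seeds)) != len(seeds):
        problems.append("base_seed: derived per-larva seeds are not unique")
    return problems


def larva_seed(base_seed: int, group_index: int, larva_index: int) -> int:
    """Deterministic per-larva seed below 2^31."""
    ss = np.random.SeedSequence([base_seed, group_index, larva_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _measure_movie_larva(cfg, run: RunConfig):
    """Imaging pipeline: render, shift-correct, ratio, ROI traces, areas."""
    movie, gt = render_dual_channel_movie(cfg)
    shift = estimate_pixel_shift(movie, max_shift=run.max_shift)
    corrected = apply_shift(movie, shift)
    ratio = compute_ratio_movie(corrected, display_range=run.display_range)
    traces = {}
    for chamber in CHAMBERS:
        roi = Roi.from_polygon(
            chamber, chamber_polygon(cfg, chamber), cfg.image_shape
        )
        traces[chamber] = roi_weighted_ratio(ratio, corrected, roi)
    area_px = gt.chamber_masks_per_frame["ventricle"].sum(axis=(1, 2))
    area = area_px.astype(float) * cfg.pixel_size**2
    return traces, area, gt


def _measure_trace_larva(cfg, run: RunConfig, rng: np.random.Generator):
    """Trace-level pipeline: forward-model ratio + measurement noise."""
    gt = simulate_ca_dynamics(cfg)
    traces = {}
    for chamber in CHAMBERS:
        clean = gt.true_ratio_trace[chamber]
        amp = float(clean.max() - clean.min())
        ref_amp = amp
        if chamber == "ventricle" and amp == 0:
            # silent ventricle: noise scale carried over from the atrium
            a = gt.true_ratio_trace["atrium"]
            ref_amp = float(a.max() - a.min())
        noisy = clean + run.noise_sd_fraction * ref_amp * rng.standard_normal(
            clean.shape
        )
        traces[chamber] = RatioTrace(values=noisy, time=gt.time, roi_label=chamber)
    area = ventricular_area_truth(cfg, gt)
    area = area + run.area_noise_fraction * area[0] * rng.standard_normal(area.shape)
    return traces, area, gt


def _analyze_larva(traces, area, cfg, run: RunConfig):
    rows = {}
    for chamber, trace in traces.items():
        sm = trace_kinetics.smooth_trace(
            trace, run.smooth_window, run.smooth_polyorder
        )
        cycles = trace_kinetics.segment_cycles(
            sm, run.prominence_fraction, run.refractory
        )
        rows[chamber] = trace_kinetics.cat_metrics(sm, cycles)
    fac = morphometry.fac_from_area_trace(
        area,
        1.0 / cfg.frame_rate,
        prominence_fraction=run.prominence_fraction,
        refractory=run.refractory,
    ).fac
    av = trace_kinetics.analyze_av_conduction(
        traces["atrium"],
        traces["ventricle"],
        window=run.smooth_window,
        polyorder=run.smooth_polyorder,
        prominence_fraction=run.prominence_fraction,
        refractory=run.refractory,
    )
    return rows, fac, av


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Simulate every larva, run all analysis stages, summarize by group."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid RunConfig:\n" + "\n".join(problems))

    metric_rows, long_rows, av_rows = [], [], []
    for gi, group in enumerate(config.groups):
        base_cfg = scenario_preset(group.scenario, **group.overrides)
        for i in range(group.n):
            seed = larva_seed(config.base_seed, gi, i)
            larva_id = f"{group.name}_{i:03d}"
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
            cfg = jitter_config(
                base_cfg, rng, config.jitter_level_cv, config.jitter_fac_sd
            )
            cfg.seed = seed
            logger.info("simulating larva %s (seed %d)", larva_id, seed)
            try:
                if config.render_movies:
                    traces, area, _ = _measure_movie_larva(cfg, config)
                else:
                    traces, area, _ = _measure_trace_larva(cfg, config, rng)
                per_chamber, fac, av = _analyze_larva(traces, area, cfg, config)
            except Exception as exc:
                raise RuntimeError(
                    f"larva {larva_id}: analysis stage failed: {exc}"
                ) from exc
            for chamber, m in per_chamber.items():
                row = {
                    "group": group.name,
                    "larva_id": larva_id,
                    "chamber": chamber,
                    "systolic": m.systolic,
                    "diastolic": m.diastolic,
                    "amplitude": m.amplitude,
                    "frequency": m.frequency,
                    "n_cycles": m.n_cycles,
                    "fac": fac if chamber == "ventricle" else np.nan,
                }
                metric_rows.append(row)
                for name in METRIC_NAMES:
                    long_rows.append({
                        "group": group.name,
                        "larva_id": larva_id,
                        "metric": f"{name}_{chamber}",
                        "value": row[name],
                    })
                if chamber == "ventricle":
                    long_rows.append({
                        "group": group.name,
                        "larva_id": larva_id,
                        "metric": "fac",
                        "value": fac,
                    })
            av_rows.append({
                "group": group.name,
                "larva_id": larva_id,
                "atrial_count": av.atrial_count,
                "ventricular_count": av.ventricular_count,
                "conduction_ratio_estimate": av.conduction_ratio_estimate,
                "block_present": av.block_present,
                "block_class": av.block_class,
            })

    metrics = pd.DataFrame(metric_rows)
    table = GroupTable(pd.DataFrame(long_rows))
    av_reports = pd.DataFrame(av_rows)

    stats_rows = []
    if len(config.groups) >= 2:
        for metric in sorted(table.df["metric"].unique()):
            values = table.groups_for(metric)
            if any(np.isfinite(v).sum() < 3 for v in values.values()):
                continue
            try:
                res = table.compare(
                    metric, mode=config.stats_mode, control=config.control_group
                )
            except ValueError as exc:
                logger.warning("stats skipped for %s: %s", metric, exc)
                continue
            stats_rows.append(_stats_row(metric, res))
    stats = pd.DataFrame(stats_rows)

    manifest = {
        "config": _config_dict(config),
        "package": "cardioratio",
        "files": {},
    }
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {
            "metrics.csv": metrics,
            "group_table.csv": table.df,
            "stats.csv": stats,
            "av_reports.csv": av_reports,
        }
        for name, df in written.items():
            path = out_dir / name
            df.to_csv(path, index=False)
            manifest["files"][name] = _sha256(path)
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ExperimentResult(
        metrics=metrics,
        group_table=table,
        stats=stats,
        av_reports=av_reports,
        manifest=manifest,
        out_dir=out_dir,
    )


def _stats_row(metric: str, res: TestResult) -> dict:
    return {
        "metric": metric,
        "test": res.test_name,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "branch": res.branch,
        "significance": res.significance_code,
        "posthoc": json.dumps(
            [[list(pair), p] for pair, p in res.posthoc]
        ),
    }


def _config_dict(config: RunConfig) -> dict:
    data = asdict(config)
    data["display_range"] = list(data["display_range"])
    return data


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
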