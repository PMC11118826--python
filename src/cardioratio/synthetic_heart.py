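"""Synthetic beating-heart data generator with known ground truth.

Renders dual-emission-channel fluorescence movies and aequorin
bioluminescence traces of a simulated two-chamber larval zebrafish heart.
Every downstream analysis stage (pixel-shift correction, pixel-wise
ratioing, kinetic parameter extraction, fractional area change,
luminescence consumption bookkeeping) can be validated against the exact
signals the movie was rendered from.

The model is deliberately simple where the analysis does not care:

* Chamber Ca2+ is spatially uniform within each chamber at each frame;
  the analysis only ever averages whole-chamber ROIs.
* Chambers are ellipses whose area oscillates in phase with the
  ventricular Ca2+ transient, scaled by the configured contraction
  fraction (target FAC).  The deformation moves bright tissue across
  fixed pixels, which is exactly the motion-artifact mechanism that
  ratiometric imaging is meant to cancel.
* The camera model is Poisson shot noise on (signal + background)
  followed by additive Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HeartSimConfig",
    "GroundTruth",
    "SensorModel",
    "simulate_ca_dynamics",
    "sensor_response",
    "render_dual_channel_movie",
    "simulate_aequorin_trace",
    "aequorin_counts",
    "scenario_preset",
    "washout_series",
    "jitter_config",
    "SCENARIOS",
]

CHAMBERS = ("atrium", "ventricle")

# Chamber layout as fractions of the image (center_y, center_x, semi_y, semi_x).
# The ventricle is drawn larger and caudal to the atrium; both stay well
# inside the field of view at the default 128x128 geometry.
_LAYOUT = {
    "atrium": (0.30, 0.50, 0.125, 0.155),
    "ventricle": (0.69, 0.50, 0.17, 0.22),
}


def _as_pair(value) -> tuple[float, float]:
    """Normalize a per-chamber parameter to an (atrium, ventricle) pair."""
    if np.isscalar(value):
        return (float(value), float(value))
    a, v = value
    return (float(a), float(v))


@dataclass
class HeartSimConfig:
    """Full parameterization of one synthetic larva.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames/s (50 for fluorescence movies,
        1 for time-averaged bioluminescence).
    duration : float
        Recording length in seconds; ``frame_rate * duration`` must be an
        integer frame count.
    image_shape : (int, int)
        Movie height and width in pixels.
    pixel_size : float
        Microns per pixel (1.45 um/pixel for the fluorescence geometry).
    heart_rate : float
        Atrial pacemaker rate in beats/min.
    av_delay : float
        Atrioventricular conduction delay in seconds.
    conduction_ratio : int
        n atrial events per conducted ventricular event (1 = normal,
        2 = 2:1 block, ...).  0 means complete block: no atrial event
        conducts to the ventricle.
    ca_diastolic, ca_systolic : float or (float, float)
        Chamber Ca2+ levels in uM, scalar or (atrium, ventricle).
    transient_rise_tau, transient_decay_tau : float
        Time constants (s) of the peak-normalized double-exponential
        transient (1 - exp(-t/tau_rise)) * exp(-t/tau_decay).
    contraction_fraction : float
        Target ventricular fractional area change in [0, 1).
    sensor_model : {"fret", "ref_fused", "aequorin"}
        FRET pair (donor down / acceptor up with Ca2+), intensiometric
        sensor fused to a Ca2+-insensitive reference, or a consumable
        photoprotein.
    sensor_kd : float
        Apparent Kd for Ca2+ in uM (2.8 uM for the troponin-C FRET
        sensor; 0.375 uM for the calmodulin-based intensiometric one).
    sensor_hill : float
        Hill coefficient of the saturation curve.
    donor_dynamic_range, acceptor_dynamic_range : float
        Fractional emission modulation at saturation.  For the
        reference-fused model the acceptor range plays the role of the
        Ca2+-sensitive channel's dynamic range.
    channel_pixel_shift : (int, int)
        (dy, dx) translation of the denominator channel relative to the
        numerator, emulating the beamsplitter offset.
    background_level : float
        Camera background in counts per pixel per frame.
    photon_scale : float
        Counts per unit emission; sets the shot-noise regime.
    read_noise_sd : float
        Gaussian read noise (counts), added after Poisson sampling.
    shot_noise : bool
        Disable to obtain noise-free renders (read noise is also keyed
        off this switch only through ``read_noise_sd``).
    aequorin_pool : float
        Initial photoprotein pool A0 (arbitrary emission units).
    aequorin_kmax : float
        Consumption rate constant at sensor saturation, 1/s.
    seed : int
        Seed for all stochastic draws; identical config + seed gives
        byte-identical output.
    """

    frame_rate: float = 50.0
    duration: float = 5.0
    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 1.45
    heart_rate: float = 150.0
    av_delay: float = 0.08
    conduction_ratio: int = 1
    ca_diastolic: float | tuple[float, float] = 0.10
    ca_systolic: float | tuple[float, float] = 1.00
    transient_rise_tau: float = 0.04
    transient_decay_tau: float = 0.18
    contraction_fraction: float = 0.30
    sensor_model: str = "fret"
    sensor_kd: float = 2.8
    sensor_hill: float = 1.0
    donor_dynamic_range: float = 0.4
    acceptor_dynamic_range: float = 0.4
    channel_pixel_shift: tuple[int, int] = (0, 0)
    background_level: float = 100.0
    photon_scale: float = 2000.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    aequorin_pool: float = 1.0e6
    aequorin_kmax: float = 3.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_frames(self) -> int:
        n = self.frame_rate * self.duration
        return int(round(n))

    @property
    def time(self) -> np.ndarray:
        """Frame-start timestamps on the half-open interval [0, duration)."""
        return np.arange(self.n_frames) / self.frame_rate

    def ca_levels(self, chamber: str) -> tuple[float, float]:
        i = CHAMBERS.index(chamber)
        return _as_pair(self.ca_diastolic)[i], _as_pair(self.ca_systolic)[i]

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        n = self.frame_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"frame_rate x duration must be an integer frame count, got {n}"
            )
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not (isinstance(self.conduction_ratio, (int, np.integer))):
            raise ValueError("conduction_ratio must be an integer")
        if self.conduction_ratio < 0:
            raise ValueError("conduction_ratio must be >= 1 (or 0 for complete block)")
        dia, sys_ = _as_pair(self.ca_diastolic), _as_pair(self.ca_systolic)
        for d, s in zip(dia, sys_):
            if not (s >= d > 0):
                raise ValueError("require ca_systolic >= ca_diastolic > 0 per chamber")
        if not (0 <= self.contraction_fraction < 1):
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.sensor_model not in ("fret", "ref_fused", "aequorin"):
            raise ValueError(f"unknown sensor_model {self.sensor_model!r}")
        if self.sensor_kd <= 0 or self.sensor_hill <= 0:
            raise ValueError("sensor_kd and sensor_hill must be positive")
        if self.aequorin_pool <= 0:
            raise ValueError("aequorin_pool (A0) must be positive")


@dataclass
class GroundTruth:
    """True signals a synthetic movie or luminescence trace was rendered from."""

    time: np.ndarray
    atrial_ca: np.ndarray
    ventricular_ca: np.ndarray
    atrial_event_times: np.ndarray
    ventricular_event_times: np.ndarray
    true_ratio_trace: dict[str, np.ndarray]
    true_frequency: float
    end_diastolic_area: float | None = None
    end_systolic_area: float | None = None
    true_fac: float | None = None
    ventricular_area: np.ndarray | None = None
    chamber_masks_per_frame: dict[str, np.ndarray] | None = None

    def ca(self, chamber: str) -> np.ndarray:
        return self.atrial_ca if chamber == "atrium" else self.ventricular_ca


# ---------------------------------------------------------------------------
# Sensor photophysics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorModel:
    """Hill-saturation emission model for a two-channel Ca2+ biosensor."""

    kind: str = "fret"
    kd: float = 2.8
    hill: float = 1.0
    donor_range: float = 0.4
    acceptor_range: float = 0.4

    @classmethod
    def from_config(cls, config: HeartSimConfig) -> "SensorModel":
        return cls(
            kind=config.sensor_model,
            kd=config.sensor_kd,
            hill=config.sensor_hill,
            donor_range=config.donor_dynamic_range,
            acceptor_range=config.acceptor_dynamic_range,
        )

    def saturation(self, ca):
        ca = np.asarray(ca, dtype=float)
        if np.any(ca < 0):
            raise ValueError("Ca2+ concentration must be non-negative")
        c = ca**self.hill
        return c / (c + self.kd**self.hill)

    def ratio(self, ca):
        num, den = sensor_response(ca, self)
        return num / den


def sensor_response(ca, model: SensorModel):
    """Channel emissions (numerator, denominator) for Ca2+ level(s) in uM.

    fret:      donor falls, acceptor rises with Ca2+; ratio = acceptor/donor.
    ref_fused: Ca2+-sensitive channel rises, reference is flat;
               ratio = sensitive/reference.
    The returned ratio is strictly increasing in ca for either model.
    """
    s = model.saturation(ca)
    if model.kind == "fret":
        donor = 1.0 - model.donor_range * s
        acceptor = 1.0 + model.acceptor_range * s
        return acceptor, donor
    if model.kind == "ref_fused":
        sensitive = 1.0 + model.acceptor_range * s
        reference = np.ones_like(s)
        return sensitive, reference
    raise ValueError(f"sensor_response undefined for sensor kind {model.kind!r}")


# ---------------------------------------------------------------------------
# Ca2+ dynamics
# ---------------------------------------------------------------------------


def _transient_kernel(t, rise_tau, decay_tau):
    """Peak-normalized (1 - e^(-t/tau_r)) e^(-t/tau_d) for t >= 0, else 0."""
    t = np.asarray(t, dtype=float)
    g = np.where(
        t >= 0,
        (1.0 - np.exp(-np.maximum(t, 0) / rise_tau))
        * np.exp(-np.maximum(t, 0) / decay_tau),
        0.0,
    )
    t_peak = rise_tau * math.log1p(decay_tau / rise_tau)
    peak = (1.0 - math.exp(-t_peak / rise_tau)) * math.exp(-t_peak / decay_tau)
    return g / peak


def _event_train(events, time, dia, sys_, rise_tau, decay_tau):
    trace = np.full_like(time, dia, dtype=float)
    amp = sys_ - dia
    if amp == 0 or len(events) == 0:
        return trace
    for t0 in events:
        trace += amp * _transient_kernel(time - t0, rise_tau, decay_tau)
    return trace


def simulate_ca_dynamics(
    config: HeartSimConfig, sample_rate: float | None = None
) -> GroundTruth:
    """Chamber Ca2+ traces and excitation event times (no imaging).

    The atrium fires periodically at ``heart_rate``; every
    ``conduction_ratio``-th atrial event conducts to the ventricle after
    ``av_delay`` seconds (none conduct when conduction_ratio is 0).  Each
    event launches a peak-normalized rise/decay double-exponential
    transient between the diastolic and systolic Ca2+ level.
    """
    config.validate()
    fs = sample_rate or config.frame_rate
    n = int(round(fs * config.duration))
    time = np.arange(n) / fs

    period = 60.0 / config.heart_rate
    n_atrial = int(math.ceil(config.duration / period - 1e-12))
    atrial_events = np.arange(n_atrial) * period
    atrial_events = atrial_events[atrial_events < config.duration]

    if config.conduction_ratio == 0:
        conducted = np.array([])
    else:
        conducted = atrial_events[:: config.conduction_ratio]
    vent_events = conducted + config.av_delay
    vent_events = vent_events[vent_events < config.duration]

    a_dia, a_sys = config.ca_levels("atrium")
    v_dia, v_sys = config.ca_levels("ventricle")
    atrial_ca = _event_train(
        atrial_events, time, a_dia, a_sys,
        config.transient_rise_tau, config.transient_decay_tau,
    )
    vent_ca = _event_train(
        vent_events, time, v_dia, v_sys,
        config.transient_rise_tau, config.transient_decay_tau,
    )

    if config.sensor_model in ("fret", "ref_fused"):
        sensor = SensorModel.from_config(config)
        ratio = {
            "atrium": sensor.ratio(atrial_ca),
            "ventricle": sensor.ratio(vent_ca),
        }
    else:
        ratio = {}

    return GroundTruth(
        time=time,
        atrial_ca=atrial_ca,
        ventricular_ca=vent_ca,
        atrial_event_times=atrial_events,
        ventricular_event_times=vent_events,
        true_ratio_trace=ratio,
        true_frequency=len(atrial_events) / config.duration * 60.0,
    )


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


def _contraction_phase(ca, dia, sys_, time=None, period=None):
    """Mechanical activation in [0, 1], in phase with the Ca2+ trace.

    The raw activation (ca - dia)/(sys - dia) never returns to zero
    between beats because transient decay tails overlap, whereas chamber
    dimensions do return to end-diastole each cycle.  The activation is
    therefore renormalized to the steady-state range of the trace
    (evaluated after the first beat) so the area oscillates fully
    between its end-diastolic and end-systolic values every cycle.
    """
    if sys_ == dia:
        return np.zeros_like(ca)
    raw = (ca - dia) / (sys_ - dia)
    if time is not None and period is not None:
        steady = raw[time >= period]
        if len(steady) and np.ptp(steady) > 0:
            lo, hi = steady.min(), steady.max()
            raw = (raw - lo) / (hi - lo)
    return np.clip(raw, 0.0, 1.0)


def chamber_geometry(config: HeartSimConfig, chamber: str):
    """Diastolic ellipse (cy, cx, semi_y, semi_x) in pixels."""
    h, w = config.image_shape
    fy, fx, fa, fb = _LAYOUT[chamber]
    return fy * h, fx * w, fa * h, fb * w


def chamber_polygon(config: HeartSimConfig, chamber: str, n_vertices: int = 48):
    """Diastolic outline of a chamber as (row, col) polygon vertices."""
    cy, cx, sa, sb = chamber_geometry(config, chamber)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cy + sa * np.sin(theta), cx + sb * np.cos(theta)])


def _ellipse_mask(shape, cy, cx, semi_y, semi_x):
    """Pixel-center-inside rasterization of an ellipse."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / semi_y) ** 2 + ((xx - cx) / semi_x) ** 2 <= 1.0


def ventricular_area_truth(config: HeartSimConfig, gt: GroundTruth) -> np.ndarray:
    """Analytic ventricular area (um^2) per frame of the ground-truth motion."""
    _, _, sa, sb = chamber_geometry(config, "ventricle")
    v_dia, v_sys = config.ca_levels("ventricle")
    phase = _contraction_phase(
        gt.ventricular_ca, v_dia, v_sys, gt.time, 60.0 / config.heart_rate
    )
    area_px = math.pi * sa * sb * (1.0 - config.contraction_fraction * phase)
    return area_px * config.pixel_size**2


def _shift_stack(stack, dy, dx, fill):
    """Translate every frame of a T x H x W stack by (dy, dx), filling with bg."""
    if dy == 0 and dx == 0:
        return stack.copy()
    out = np.full_like(stack, fill)
    h, w = stack.shape[1:]
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[:, ys, xs] = stack[:, ys_src, xs_src]
    return out


def render_dual_channel_movie(config: HeartSimConfig, keep_masks: bool = True):
    """Render the two emission channels of a beating two-chamber heart.

    Returns ``(DualChannelMovie, GroundTruth)``.  Both channels share the
    same geometric motion (the motion-artifact source); the denominator
    channel is additionally translated by ``channel_pixel_shift``.  Shot
    noise is Poisson on (background + photon_scale x emission) and read
    noise is Gaussian, both reproducible from ``config.seed``.
    """
    from .ratio_imaging import DualChannelMovie  # deferred: avoid cycle

    config.validate()
    if config.sensor_model not in ("fret", "ref_fused"):
        raise ValueError("render_dual_channel_movie requires a fluorescent sensor")

    gt = simulate_ca_dynamics(config)
    sensor = SensorModel.from_config(config)
    h, w = config.image_shape
    n = config.n_frames

    dy, dx = config.channel_pixel_shift
    margin = max(abs(dy), abs(dx))
    for chamber in CHAMBERS:
        cy, cx, sa, sb = chamber_geometry(config, chamber)
        if (cy - sa < margin or cy + sa > h - 1 - margin
                or cx - sb < margin or cx + sb > w - 1 - margin):
            raise ValueError(
                f"{chamber} ellipse exceeds the image bounds (geometry error)"
            )

    num = np.zeros((n, h, w), dtype=float)
    den = np.zeros((n, h, w), dtype=float)
    masks = {c: np.zeros((n, h, w), dtype=bool) for c in CHAMBERS}

    for chamber in CHAMBERS:
        cy, cx, sa, sb = chamber_geometry(config, chamber)
        dia, sys_ = config.ca_levels(chamber)
        phase = _contraction_phase(
            gt.ca(chamber), dia, sys_, gt.time, 60.0 / config.heart_rate
        )
        scale = np.sqrt(1.0 - config.contraction_fraction * phase)
        em_num, em_den = sensor_response(gt.ca(chamber), sensor)
        for t in range(n):
            mask = _ellipse_mask((h, w), cy, cx, sa * scale[t], sb * scale[t])
            masks[chamber][t] = mask
            num[t][mask] += em_num[t]
            den[t][mask] += em_den[t]

    expected_num = config.background_level + config.photon_scale * num
    expected_den = config.background_level + config.photon_scale * _shift_stack(
        den, dy, dx, fill=0.0
    )

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.shot_noise:
        frames_num = rng.poisson(expected_num).astype(float)
        frames_den = rng.poisson(expected_den).astype(float)
        if config.read_noise_sd > 0:
            frames_num += rng.normal(0, config.read_noise_sd, frames_num.shape)
            frames_den += rng.normal(0, config.read_noise_sd, frames_den.shape)
        frames_num = np.clip(frames_num, 0, None)
        frames_den = np.clip(frames_den, 0, None)
    else:
        frames_num, frames_den = expected_num, expected_den

    _, _, sa_v, sb_v = chamber_geometry(config, "ventricle")
    ed_area = math.pi * sa_v * sb_v * config.pixel_size**2
    gt.end_diastolic_area = ed_area
    gt.end_systolic_area = ed_area * (1.0 - config.contraction_fraction)
    gt.true_fac = config.contraction_fraction
    gt.ventricular_area = ventricular_area_truth(config, gt)
    if keep_masks:
        gt.chamber_masks_per_frame = masks

    roles = (
        ("acceptor", "donor") if config.sensor_model == "fret"
        else ("sensitive", "reference")
    )
    movie = DualChannelMovie(
        numerator_stack=frames_num,
        denominator_stack=frames_den,
        time_step=1.0 / config.frame_rate,
        pixel_size=config.pixel_size,
        channel_roles=roles,
        declared_shift=(dy, dx),
    )
    return movie, gt


# ---------------------------------------------------------------------------
# Aequorin bioluminescence
# ---------------------------------------------------------------------------


def aequorin_counts(
    ca: np.ndarray,
    dt: float,
    exposure: float,
    kmax: float,
    pool: float,
    kd: float,
    hill: float,
    photon_scale: float = 1.0,
    background: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Integrate photoprotein consumption over a Ca2+ trace.

    dA/dt = -k(ca) A with k(ca) = kmax * s(ca), s the Hill saturation.
    ``ca`` is sampled at step ``dt``; emitted counts are accumulated into
    frames of length ``exposure`` (k is held at the frame-averaged value
    of s(ca) within each frame).  Returns (counts_per_frame, light_per_frame)
    where light is the noise-free photon_scale * consumed pool.
    """
    if pool <= 0:
        raise ValueError("initial aequorin pool A0 must be positive")
    if exposure <= 0:
        raise ValueError("frame exposure must be positive")
    ca = np.asarray(ca, dtype=float)
    model = SensorModel(kind="ref_fused", kd=kd, hill=hill)
    s = model.saturation(ca)
    per_frame = int(round(exposure / dt))
    if per_frame < 1 or abs(per_frame * dt - exposure) > 1e-9:
        raise ValueError("exposure must be an integer multiple of the ca step")
    n_frames = len(ca) // per_frame
    s_frame = s[: n_frames * per_frame].reshape(n_frames, per_frame).mean(axis=1)
    k = kmax * s_frame
    # A after each frame: A_j+1 = A_j exp(-k_j * exposure)
    log_decay = -k * exposure
    a_bounds = pool * np.exp(np.concatenate([[0.0], np.cumsum(log_decay)]))
    emitted = a_bounds[:-1] - a_bounds[1:]
    light = photon_scale * emitted
    expected = light + background
    if rng is None:
        counts = expected
    else:
        counts = rng.poisson(expected).astype(float)
    return counts, light


def simulate_aequorin_trace(config: HeartSimConfig, internal_rate: float = 200.0):
    """Raw bioluminescence counts per frame from the ventricular ROI.

    The heart's ventricular Ca2+ trace is simulated on a fine time grid
    and drives photoprotein consumption; counts are binned into frames of
    1/frame_rate seconds (1 s frames give the time-averaged luminescence
    signal).  Returns (counts, GroundTruth).
    """
    if config.sensor_model != "aequorin":
        raise ValueError("simulate_aequorin_trace requires sensor_model='aequorin'")
    exposure = 1.0 / config.frame_rate
    gt = simulate_ca_dynamics(config, sample_rate=internal_rate)
    rng = (
        np.random.default_rng(np.random.SeedSequence(config.seed))
        if config.shot_noise
        else None
    )
    counts, light = aequorin_counts(
        gt.ventricular_ca,
        dt=1.0 / internal_rate,
        exposure=exposure,
        kmax=config.aequorin_kmax,
        pool=config.aequorin_pool,
        kd=config.sensor_kd,
        hill=config.sensor_hill,
        photon_scale=config.photon_scale,
        background=config.background_level,
        rng=rng,
    )
    return counts, gt


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

# Fixture constants for the four study conditions.  Magnitudes are
# documented modelling choices (the direction of each effect is what the
# analysis is validated against): suppressing contraction elevates
# systolic and diastolic Ca2+ and lowers the heart rate; washout reverts
# both partially.
SCENARIOS: dict[str, dict] = {
    "control": dict(
        heart_rate=150.0, contraction_fraction=0.30,
        ca_diastolic=0.10, ca_systolic=1.00,
    ),
    "tnnt2a_mo": dict(
        heart_rate=105.0, contraction_fraction=0.0,
        ca_diastolic=0.30, ca_systolic=1.60,
    ),
    "pab": dict(
        heart_rate=110.0, contraction_fraction=0.02,
        ca_diastolic=0.30, ca_systolic=1.55,
    ),
    "pab_washout": dict(
        heart_rate=135.0, contraction_fraction=0.25,
        ca_diastolic=0.14, ca_systolic=1.15,
    ),
}

# Five-condition incubation/washout series with inverse coupling between
# contraction strength and Ca2+ levels.
WASHOUT_SERIES: dict[str, dict] = {
    "control": SCENARIOS["control"],
    "pab_1h": dict(
        heart_rate=125.0, contraction_fraction=0.15,
        ca_diastolic=0.20, ca_systolic=1.30,
    ),
    "pab_2h": dict(
        heart_rate=110.0, contraction_fraction=0.02,
        ca_diastolic=0.30, ca_systolic=1.55,
    ),
    "washout_2h": dict(
        heart_rate=128.0, contraction_fraction=0.18,
        ca_diastolic=0.18, ca_systolic=1.25,
    ),
    "washout_4h": dict(
        heart_rate=135.0, contraction_fraction=0.25,
        ca_diastolic=0.14, ca_systolic=1.15,
    ),
}


def scenario_preset(name: str, **overrides) -> HeartSimConfig:
    """Configuration for a named study condition.

    ``control`` beats with full contraction at baseline Ca2+;
    ``tnnt2a_mo`` (troponin knockdown) and ``pab`` (myosin inhibition)
    suppress contraction, elevate Ca2+ levels and amplitude and slow the
    rate; ``pab_washout`` shows partial recovery.  Keyword overrides are
    applied on top (e.g. ``conduction_ratio=2`` for the morphant 2:1
    atrioventricular block variant).
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    params = {**SCENARIOS[name], **overrides}
    return HeartSimConfig(**params)


def washout_series(**overrides) -> dict[str, HeartSimConfig]:
    """Configs for the five-condition PAB incubation/washout experiment."""
    return {
        name: HeartSimConfig(**{**params, **overrides})
        for name, params in WASHOUT_SERIES.items()
    }


def jitter_config(
    config: HeartSimConfig,
    rng: np.random.Generator,
    level_cv: float = 0.05,
    fac_sd: float = 0.02,
) -> HeartSimConfig:
    """Per-larva biological variability around a scenario preset.

    Heart rate and Ca2+ levels receive multiplicative Gaussian jitter
    (CV ``level_cv``); the contraction fraction receives additive jitter
    (SD ``fac_sd``), clipped to [0, 0.95].
    """
    dia = _as_pair(config.ca_diastolic)
    sys_ = _as_pair(config.ca_systolic)
    hr = config.heart_rate * max(0.5, 1.0 + level_cv * rng.standard_normal())
    f_dia = max(0.5, 1.0 + level_cv * rng.standard_normal())
    f_sys = max(0.5, 1.0 + level_cv * rng.standard_normal())
    cf = float(np.clip(
        config.contraction_fraction + fac_sd * rng.standard_normal(), 0.0, 0.95
    ))
    return replace(
        config,
        heart_rate=hr,
        ca_diastolic=tuple(d * f_dia for d in dia),
        ca_systolic=tuple(max(s * f_sys, d * f_dia) for s, d in zip(sys_, dia)),
        contraction_fraction=cf,
    )
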