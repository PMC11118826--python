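"""Consumption-normalized quantification of aequorin bioluminescence.

Aequorin is consumed as it emits, so raw light decays even at constant
Ca2+.  The normalization divides the luminescence rate L (counts/s) at
each time point by Lmax, the light still available in the remaining
photoprotein pool — estimated as the sum of all counts detected from
that time point to the end of the record.  L/Lmax is proportional to the
Ca2+ level and independent of expression level and detector gain.

Bookkeeping convention: Lconsumed[t] sums frames strictly before t and
Lmax[t] sums frames from t onward (inclusive), so
Lconsumed[t] + Lmax[t] = Ltotal holds exactly at every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LumTrace",
    "rlu_to_rate",
    "consumption_transform",
    "time_averaged_ca_proxy",
]


@dataclass
class LumTrace:
    """Luminescence rate trace with consumption bookkeeping.

    ``L_over_Lmax`` (1/s) is defined only where the remaining pool
    exceeds ``lmax_floor_fraction`` of Ltotal; beyond that the estimate
    is noise-dominated and division would blow up as Lmax -> 0.
    """

    time: np.ndarray
    L: np.ndarray
    Ltotal: float
    Lconsumed: np.ndarray
    Lmax: np.ndarray
    L_over_Lmax: np.ndarray
    exposure: float
    lmax_floor_fraction: float
    background: float = 0.0

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.L_over_Lmax).sum())


def rlu_to_rate(raw, exposure: float, background: float = 0.0):
    """Background-subtracted luminescence rate L in counts/s.

    L = (raw - background)/exposure, floored at zero.  ``background`` is
    in counts per frame (estimate it from a pre-reconstitution or
    off-heart segment, or supply a constant).  Returns (L, n_clipped)
    where n_clipped counts the frames floored at zero.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    raw = np.asarray(raw, dtype=float)
    net = raw - background
    n_clipped = int((net < 0).sum())
    return np.clip(net, 0.0, None) / exposure, n_clipped


def consumption_transform(
    L,
    exposure: float = 1.0,
    lmax_floor_fraction: float = 0.05,
    background: float = 0.0,
) -> LumTrace:
    """Ltotal, Lconsumed, Lmax and L/Lmax from a luminescence-rate trace.

    Ltotal = sum of L[t] x exposure over the record;
    Lconsumed[t] = counts emitted before frame t (exclusive);
    Lmax[t] = Ltotal - Lconsumed[t], the counts from frame t to the end.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 1 or len(L) < 2:
        raise ValueError("need a 1-D luminescence trace of length >= 2")
    if np.any(L < 0):
        raise ValueError("luminescence rate must be non-negative")
    if not (0 <= lmax_floor_fraction < 1):
        raise ValueError("lmax_floor_fraction must be in [0, 1)")
    counts = L * exposure
    ltotal = float(counts.sum())
    if ltotal == 0:
        raise ValueError("no signal: the luminescence trace is all zero")
    lconsumed = np.concatenate([[0.0], np.cumsum(counts)[:-1]])
    lmax = ltotal - lconsumed
    with np.errstate(divide="ignore", invalid="ignore"):
        l_over_lmax = np.where(
            lmax > lmax_floor_fraction * ltotal, L / lmax, np.nan
        )
    return LumTrace(
        time=np.arange(len(L)) * exposure,
        L=L,
        Ltotal=ltotal,
        Lconsumed=lconsumed,
        Lmax=lmax,
        L_over_Lmax=l_over_lmax,
        exposure=exposure,
        lmax_floor_fraction=lmax_floor_fraction,
        background=background,
    )


def time_averaged_ca_proxy(lum: LumTrace, window: tuple[float, float] | None = None):
    """Mean L/Lmax over a time window — the time-averaged Ca2+ proxy.

    Missing (floored) samples are ignored; returns (mean, n_samples).
    Raises if the window holds no defined sample.
    """
    if window is None:
        sel = np.ones(len(lum.time), dtype=bool)
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window must satisfy t0 < t1")
        sel = (lum.time >= t0) & (lum.time < t1)
    vals = lum.L_over_Lmax[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("window contains no defined L/Lmax sample")
    return float(np.mean(vals)), int(len(vals))
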