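"""Cycle-level circadian properties via the analytic-signal phase.

The Hilbert transform of the extracted CRHR gives a complex analytic signal
whose argument is the instantaneous circadian phase: zero at the oscillation
peak and -pi/+pi at the troughs (the standard convention for a cosine).  The
wrapped phase therefore "wraps" — jumps from near +pi to near -pi — exactly
at each trough, and those wrap events split the rhythm into individual
(approximately daily) cycles.  Per cycle:

* period    — time between the two bounding troughs, minutes;
* acrophase — local clock time of day of the zero-phase crossing (the peak),
              minutes-of-day in [0, 1440);
* amplitude — CRHR at the peak minus CRHR at the preceding trough, bpm.

Half a cycle (12 h) is trimmed at each end of the run before cycle
construction to suppress Hilbert edge distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .rhythm import CircadianComponent

__all__ = [
    "PhaseSeries",
    "Cycle",
    "hilbert_phase",
    "split_cycles",
    "cycle_period",
    "cycle_acrophase",
    "cycle_amplitude",
    "cycles_from_component",
]

logger = logging.getLogger(__name__)

EDGE_TRIM_S = 12 * 3600.0  # half a circadian cycle at each run end
MIN_CYCLE_S = 12 * 3600.0  # boundaries closer than this are merged
MIN_RUN_S = 2 * 86400.0  # runs shorter than 2 days are skipped


@dataclass
class PhaseSeries:
    """Wrapped instantaneous phase of one run's CRHR.

    Phase is in (-pi, pi], zero at the CRHR peak, sharing the run's grid.
    """

    component: CircadianComponent
    phase: np.ndarray  # wrapped, radians
    unwrapped: np.ndarray  # monotone-ish companion used for interpolation

    def times(self) -> np.ndarray:
        return self.component.times()


@dataclass
class Cycle:
    """One circadian cycle, trough to trough."""

    participant_id: str
    run_start: float
    start_time: float  # seconds since epoch
    end_time: float
    period_min: float
    acrophase_min: float  # local minutes-of-day in [0, 1440)
    amplitude_bpm: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("cycle end must follow its start")


def hilbert_phase(crhr: CircadianComponent) -> PhaseSeries:
    """Instantaneous phase of the CRHR from its analytic signal."""
    n = crhr.n
    if (n - 1) * crhr.run.interval < MIN_RUN_S:
        raise ValueError("CRHR shorter than 2 days; run skipped")
    analytic = hilbert(crhr.values)
    phase = np.angle(analytic)  # in (-pi, pi], zero at peaks of a cosine
    unwrapped = np.unwrap(phase)
    return PhaseSeries(component=crhr, phase=phase, unwrapped=unwrapped)


def _crossing_times(
    t: np.ndarray, u: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """Interpolated times where the unwrapped phase u crosses each level."""
    out = []
    for lev in levels:
        idx = np.flatnonzero((u[:-1] < lev) & (u[1:] >= lev))
        for i in idx:
            frac = (lev - u[i]) / (u[i + 1] - u[i])
            out.append(t[i] + frac * (t[i + 1] - t[i]))
    return np.sort(np.asarray(out))


def split_cycles(phase: PhaseSeries) -> np.ndarray:
    """Cycle boundary times: the trough (phase wrap) instants of the run.

    A boundary is placed wherever the unwrapped phase crosses an odd
    multiple of pi (the wrapped phase steps from near +pi to near -pi),
    refined to sub-sample precision by linear interpolation.  Boundaries
    within the 12-h edge-trim zones are discarded, and boundaries closer
    than 12 h are merged keeping the first.
    """
    t = phase.times()
    u = phase.unwrapped
    lo = np.floor((u.min() - np.pi) / (2 * np.pi))
    hi = np.ceil((u.max() + np.pi) / (2 * np.pi))
    levels = np.arange(lo, hi + 1) * 2 * np.pi + np.pi  # odd multiples of pi
    levels = levels[(levels > u.min()) & (levels < u.max())]
    bounds = _crossing_times(t, u, levels)
    # suppress edge artifacts
    keep = (bounds >= t[0] + EDGE_TRIM_S) & (bounds <= t[-1] - EDGE_TRIM_S)
    bounds = bounds[keep]
    if bounds.size == 0:
        return bounds
    merged = [bounds[0]]
    for b in bounds[1:]:
        if b - merged[-1] >= MIN_CYCLE_S:
            merged.append(b)
    return np.asarray(merged)


def cycle_period(start: float, end: float) -> float:
    """Cycle duration in minutes between consecutive trough boundaries."""
    return (end - start) / 60.0


def _minutes_of_day(t_epoch: float, utc_offset_min: float) -> float:
    return float(np.mod(t_epoch / 60.0 + utc_offset_min, 1440.0))


def cycle_acrophase(
    start: float,
    end: float,
    phase: PhaseSeries,
    utc_offset_min: float = 0.0,
) -> float | None:
    """Local clock time (minutes-of-day) of the zero-phase crossing.

    The acrophase is where the unwrapped phase crosses the even multiple of
    2 pi inside the cycle; ``None`` (pathological: no crossing) drops the
    cycle upstream.
    """
    t = phase.times()
    u = phase.unwrapped
    a = np.interp(start, t, u)
    b = np.interp(end, t, u)
    k_lo = np.ceil(a / (2 * np.pi))
    k_hi = np.floor(b / (2 * np.pi))
    if k_hi < k_lo:
        return None
    levels = np.arange(k_lo, k_hi + 1) * 2 * np.pi
    times = _crossing_times(t, u, levels)
    times = times[(times >= start) & (times <= end)]
    if times.size == 0:
        return None
    return _minutes_of_day(float(times[0]), utc_offset_min)


def cycle_amplitude(
    start: float,
    acrophase_time: float,
    crhr: CircadianComponent,
) -> float:
    """CRHR at the acrophase minus CRHR at the preceding trough, bpm."""
    t = crhr.times()
    peak = float(np.interp(acrophase_time, t, crhr.values))
    trough = float(np.interp(start, t, crhr.values))
    return peak - trough


def cycles_from_component(crhr: CircadianComponent) -> list[Cycle]:
    """All per-cycle properties of one run's CRHR.

    Cycles with no interior zero-phase crossing, or with a negative
    peak-minus-trough amplitude (possible only for pathological phase
    estimates), are dropped with a log message.
    """
    try:
        phase = hilbert_phase(crhr)
    except ValueError as exc:
        logger.info("run %s skipped: %s", crhr.run.start_time, exc)
        return []
    bounds = split_cycles(phase)
    if bounds.size < 2:
        return []
    utc_offset = crhr.run.utc_offset_min
    t = crhr.times()
    u = phase.unwrapped
    cycles: list[Cycle] = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        # acrophase: first even-2pi crossing strictly inside the cycle
        a = np.interp(start, t, u)
        b = np.interp(end, t, u)
        k_lo, k_hi = np.ceil(a / (2 * np.pi)), np.floor(b / (2 * np.pi))
        if k_hi < k_lo:
            logger.info("cycle at %s dropped: no zero-phase crossing", start)
            continue
        acro_times = _crossing_times(t, u, np.arange(k_lo, k_hi + 1) * 2 * np.pi)
        acro_times = acro_times[(acro_times >= start) & (acro_times <= end)]
        if acro_times.size == 0:
            logger.info("cycle at %s dropped: no zero-phase crossing", start)
            continue
        acro_t = float(acro_times[0])
        amp = cycle_amplitude(start, acro_t, crhr)
        if amp < 0:
            logger.info("cycle at %s dropped: negative amplitude %.3f", start, amp)
            continue
        cycles.append(
            Cycle(
                participant_id=crhr.run.participant_id,
                run_start=crhr.run.start_time,
                start_time=float(start),
                end_time=float(end),
                period_min=cycle_period(float(start), float(end)),
                acrophase_min=_minutes_of_day(acro_t, utc_offset),
                amplitude_bpm=amp,
            )
        )
    return cycles
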