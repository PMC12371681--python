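"""Turn raw, gappy wearable heart-rate series into uniform runs.

A wearable heart-rate recording is a sequence of timestamped bpm samples at
a nominal interval (5 s for wrist PPG devices) with missing stretches where
the watch was off, charging, or failed to sync.  The decomposition stages
downstream need a continuous, uniformly sampled signal, so this module

1. linearly interpolates gaps shorter than 8 h onto the nominal grid,
2. splits the series into "runs" at the remaining (>= 8 h) gaps,
3. decides participant eligibility (at least one run strictly longer than
   7 days), and
4. optionally downsamples runs by non-overlapping window means to a coarser
   working interval so month-scale decomposition stays tractable.

Timestamps are seconds since the Unix epoch (UTC).  Each participant carries
a fixed UTC offset (minutes) used later to express acrophase in local clock
time; daylight-saving transitions are deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HeartRateSeries",
    "Run",
    "interpolate_short_gaps",
    "split_runs",
    "eligible",
    "downsample",
    "preprocess_series",
    "ProcessingReport",
]

#: A spacing larger than this multiple of the nominal interval is a gap.
#: Tolerates device timing jitter without declaring a gap at every sample.
GAP_FACTOR = 2.0

#: Gaps shorter than this are linearly interpolated; gaps at least this long
#: split the recording into separate runs.
DEFAULT_MAX_GAP_H = 8.0

#: Participants need at least one run strictly longer than this to be kept.
DEFAULT_MIN_RUN_DAYS = 7.0


@dataclass
class HeartRateSeries:
    """Timestamped heart-rate samples for one participant.

    Gaps are represented by absent timestamps, never by sentinel values.
    """

    participant_id: str
    timestamps: np.ndarray  # seconds since epoch, strictly increasing
    values: np.ndarray  # bpm, finite and > 0
    nominal_interval: float = 5.0  # seconds
    utc_offset_min: float = 0.0  # fixed local-midnight offset
    interpolated: np.ndarray | None = None  # per-sample flag, set after filling

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.timestamps.size and not np.all(np.isfinite(self.values)):
            raise ValueError("bpm values must be finite")
        if self.timestamps.size and np.any(self.values <= 0):
            raise ValueError("bpm values must be positive")
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be positive")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.timestamps.size, dtype=bool)

    @property
    def span(self) -> float:
        """Total recorded span in seconds (first to last sample)."""
        if self.timestamps.size < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class Run:
    """A contiguous, uniformly sampled stretch eligible for decomposition."""

    participant_id: str
    start_time: float  # seconds since epoch
    interval: float  # seconds between samples
    values: np.ndarray  # bpm on the uniform grid, no missing samples
    interpolated_mask: np.ndarray  # True where a sample was filled in
    utc_offset_min: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if self.values.size < 2:
            raise ValueError("a run needs at least two samples")
        if self.interpolated_mask.shape != self.values.shape:
            raise ValueError("mask and values must have equal length")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n - 1) * self.interval

    @property
    def duration_days(self) -> float:
        return (self.n - 1) * self.interval / 86400.0

    def times(self) -> np.ndarray:
        return self.start_time + self.interval * np.arange(self.n)


def _gap_indices(ts: np.ndarray, nominal: float, min_gap_s: float) -> np.ndarray:
    """Indices i where the spacing ts[i+1]-ts[i] is a gap of >= min_gap_s."""
    dt = np.diff(ts)
    return np.flatnonzero((dt > GAP_FACTOR * nominal) & (dt >= min_gap_s))


def interpolate_short_gaps(
    series: HeartRateSeries, max_gap_h: float = DEFAULT_MAX_GAP_H
) -> HeartRateSeries:
    """Linearly fill every gap shorter than ``max_gap_h`` hours.

    Filled samples are placed on the nominal grid anchored at the sample
    preceding the gap and flagged in ``interpolated``.  Gaps of at least
    ``max_gap_h`` are left untouched (they later split the series into runs).
    """
    if series.timestamps.size == 0:
        raise ValueError("cannot interpolate an empty series")
    ts, vals = series.timestamps, series.values
    flags = series.interpolated
    nominal = series.nominal_interval
    max_gap_s = max_gap_h * 3600.0

    dt = np.diff(ts)
    fill_at = np.flatnonzero((dt > GAP_FACTOR * nominal) & (dt < max_gap_s))
    if fill_at.size == 0:
        return replace(series, timestamps=ts.copy(), values=vals.copy(),
                       interpolated=flags.copy())

    t_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    f_parts: list[np.ndarray] = []
    prev = 0
    for i in fill_at:
        t_parts.append(ts[prev : i + 1])
        v_parts.append(vals[prev : i + 1])
        f_parts.append(flags[prev : i + 1])
        # grid anchored at the sample before the gap, strictly inside it
        n_new = int(np.floor((ts[i + 1] - ts[i]) / nominal - 1e-9))
        t_new = ts[i] + nominal * np.arange(1, n_new + 1)
        t_new = t_new[t_new < ts[i + 1] - 1e-9]
        v_new = np.interp(t_new, [ts[i], ts[i + 1]], [vals[i], vals[i + 1]])
        t_parts.append(t_new)
        v_parts.append(v_new)
        f_parts.append(np.ones(t_new.size, dtype=bool))
        prev = i + 1
    t_parts.append(ts[prev:])
    v_parts.append(vals[prev:])
    f_parts.append(flags[prev:])

    return replace(
        series,
        timestamps=np.concatenate(t_parts),
        values=np.concatenate(v_parts),
        interpolated=np.concatenate(f_parts),
    )


def split_runs(
    series: HeartRateSeries, min_gap_h: float = DEFAULT_MAX_GAP_H
) -> list[Run]:
    """Split at every remaining gap of at least ``min_gap_h`` hours.

    Each run is resampled onto a uniform grid at the nominal interval,
    anchored at the run's first timestamp.  Expects short gaps to have been
    interpolated already; sub-threshold spacings inside a run are absorbed
    by the resampling.
    """
    ts, vals = series.timestamps, series.values
    flags = series.interpolated
    if ts.size < 2:
        return []
    nominal = series.nominal_interval
    cuts = _gap_indices(ts, nominal, min_gap_h * 3600.0)
    bounds = np.concatenate(([0], cuts + 1, [ts.size]))
    runs: list[Run] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        t0, t1 = ts[a], ts[b - 1]
        n = int(np.floor((t1 - t0) / nominal + 1e-9)) + 1
        grid = t0 + nominal * np.arange(n)
        v = np.interp(grid, ts[a:b], vals[a:b])
        # a grid point is "interpolated" if its nearest source sample was
        near = np.searchsorted(ts[a:b], grid)
        near = np.clip(near, 0, b - a - 1)
        m = flags[a:b][near]
        runs.append(
            Run(
                participant_id=series.participant_id,
                start_time=float(t0),
                interval=nominal,
                values=v,
                interpolated_mask=m,
                utc_offset_min=series.utc_offset_min,
            )
        )
    return runs


def eligible(runs: list[Run], min_run_days: float = DEFAULT_MIN_RUN_DAYS) -> bool:
    """True iff at least one run is strictly longer than ``min_run_days``."""
    return any(r.duration_days > min_run_days for r in runs)


def downsample(run: Run, working_interval_s: float = 60.0) -> Run:
    """Average non-overlapping windows down to ``working_interval_s``.

    A 24-h rhythm is attenuated only by sinc(pi * dt / P), negligible for
    minute-scale windows, so this preserves circadian content while making
    month-scale decomposition tractable.
    """
    if working_interval_s < run.interval:
        raise ValueError(
            "working interval must not be shorter than the run's interval"
        )
    factor = working_interval_s / run.interval
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("working interval must be a multiple of the run interval")
    factor = int(round(factor))
    if factor == 1:
        return run
    n_win = run.n // factor
    if n_win < 2:
        raise ValueError("run too short for the requested working interval")
    v = run.values[: n_win * factor].reshape(n_win, factor).mean(axis=1)
    m = run.interpolated_mask[: n_win * factor].reshape(n_win, factor).any(axis=1)
    # window means represent window centres; anchor the grid there
    start = run.start_time + (factor - 1) * run.interval / 2.0
    return Run(
        participant_id=run.participant_id,
        start_time=start,
        interval=float(working_interval_s),
        values=v,
        interpolated_mask=m,
        utc_offset_min=run.utc_offset_min,
    )


@dataclass
class ProcessingReport:
    """Per-participant accounting of the preprocessing stage.

    Exposes both gap time and short-run time so either discard accounting
    (time lost to gaps vs time in runs too short to analyse) can be read.
    """

    participant_id: str
    span_days: float
    n_runs_total: int
    n_runs_kept: int
    days_in_kept_runs: float
    days_in_short_runs: float
    days_in_gaps: float
    is_eligible: bool

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "span_days": round(self.span_days, 4),
            "n_runs_total": self.n_runs_total,
            "n_runs_kept": self.n_runs_kept,
            "days_in_kept_runs": round(self.days_in_kept_runs, 4),
            "days_in_short_runs": round(self.days_in_short_runs, 4),
            "days_in_gaps": round(self.days_in_gaps, 4),
            "eligible": self.is_eligible,
        }


def preprocess_series(
    series: HeartRateSeries,
    max_gap_h: float = DEFAULT_MAX_GAP_H,
    min_run_days: float = DEFAULT_MIN_RUN_DAYS,
    working_interval_s: float = 60.0,
) -> tuple[list[Run], ProcessingReport]:
    """Full preprocessing for one participant.

    Interpolates short gaps, splits into runs, keeps runs strictly longer
    than ``min_run_days``, downsamples each kept run to the working interval,
    and reports the accounting.  Returns ``([], report)`` for ineligible
    participants.
    """
    filled = interpolate_short_gaps(series, max_gap_h=max_gap_h)
    runs = split_runs(filled, min_gap_h=max_gap_h)
    kept = [r for r in runs if r.duration_days > min_run_days]
    short = [r for r in runs if r.duration_days <= min_run_days]
    span_days = series.span / 86400.0
    kept_days = sum(r.duration_days for r in kept)
    short_days = sum(r.duration_days for r in short)
    report = ProcessingReport(
        participant_id=series.participant_id,
        span_days=span_days,
        n_runs_total=len(runs),
        n_runs_kept=len(kept),
        days_in_kept_runs=kept_days,
        days_in_short_runs=short_days,
        days_in_gaps=max(span_days - kept_days - short_days, 0.0),
        is_eligible=bool(kept),
    )
    down = [downsample(r, working_interval_s) for r in kept] if kept else []
    return down, report
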