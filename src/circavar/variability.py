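"""Intraindividual average and variability over 7-cycle segments.

Per-cycle circadian properties are grouped, within each run, into
consecutive non-overlapping segments of 7 cycles (one nominal week).  Each
segment yields a mean and an SD per property; a participant's
*intraindividual average* is the unweighted mean of segment means and their
*intraindividual variability* the unweighted mean of segment SDs.  The fixed
segment size keeps the per-segment sample size constant, so recording
length differences between participants cannot bias the SD.

Acrophase lives on the 24-h circle: a peak drifting across midnight sits at
1435 min one day and 5 min the next.  Dispersion is therefore computed on
signed minimal deviations from the circular mean (each in (-720, 720]) —
the naive linear SD would be catastrophically wrong near midnight.  A naive
linear mode is kept for sensitivity analysis.

Segments are also labelled against a seizure diary (containing / free /
outside-diary) for the paired seizure analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cycles import Cycle
from .synthetic import SeizureDiary

__all__ = [
    "Segment",
    "ParticipantSummary",
    "PROPERTIES",
    "segment_cycles",
    "segment_stats",
    "intraindividual_summary",
    "label_segments",
    "seizure_frequency",
    "split_summary_by_label",
    "circular_mean_minutes",
    "circular_deviations",
]

logger = logging.getLogger(__name__)

SEGMENT_CYCLES = 7
PROPERTIES = ("period", "acrophase", "amplitude")
DAY_MIN = 1440.0


def circular_mean_minutes(values: np.ndarray, period: float = DAY_MIN) -> float:
    """Circular mean of clock values on a ``period``-minute circle, in [0, period)."""
    ang = 2.0 * np.pi * np.asarray(values, dtype=float) / period
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(np.mod(mean_ang * period / (2.0 * np.pi), period))


def circular_deviations(
    values: np.ndarray, center: float, period: float = DAY_MIN
) -> np.ndarray:
    """Signed minimal deviations from ``center``, each in (-period/2, period/2]."""
    dev = np.mod(np.asarray(values, dtype=float) - center, period)
    dev = np.where(dev > period / 2.0, dev - period, dev)
    # map the boundary -period/2 to +period/2 so the interval is half-open below
    dev = np.where(dev <= -period / 2.0, dev + period, dev)
    return dev


@dataclass
class Segment:
    """Seven consecutive cycles of one run, with per-property statistics."""

    participant_id: str
    segment_index: int
    cycles: list[Cycle]
    start_time: float  # first cycle start (epoch s)
    end_time: float  # last cycle end (epoch s); span is [start, end)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    seizure_label: str = "outside-diary"  # containing | free | outside-diary


def segment_stats(
    cycles: list[Cycle], circular_acrophase: bool = True
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-property (mean, SD) over one segment's cycles.

    Period and amplitude use the arithmetic mean and sample SD (n-1).
    Acrophase uses the circular mean (as minutes-of-day) and the sample SD
    of signed minimal deviations from that mean, unless
    ``circular_acrophase`` is False (naive linear sensitivity mode).
    """
    periods = np.array([c.period_min for c in cycles])
    amps = np.array([c.amplitude_bpm for c in cycles])
    acros = np.array([c.acrophase_min for c in cycles])
    means = {
        "period": float(periods.mean()),
        "amplitude": float(amps.mean()),
    }
    sds = {
        "period": float(periods.std(ddof=1)),
        "amplitude": float(amps.std(ddof=1)),
    }
    if circular_acrophase:
        center = circular_mean_minutes(acros)
        dev = circular_deviations(acros, center)
        means["acrophase"] = center
        sds["acrophase"] = float(dev.std(ddof=1))
    else:
        means["acrophase"] = float(acros.mean())
        sds["acrophase"] = float(acros.std(ddof=1))
    return means, sds


def segment_cycles(
    cycles: list[Cycle], circular_acrophase: bool = True
) -> list[Segment]:
    """Group a participant's cycles into consecutive 7-cycle segments.

    Segments never span runs; trailing partial blocks within a run are
    discarded.  Cycles must be time-ordered within each run.
    """
    by_run: dict[float, list[Cycle]] = {}
    for c in cycles:
        by_run.setdefault(c.run_start, []).append(c)
    segments: list[Segment] = []
    idx = 0
    for run_start in sorted(by_run):
        run_cycles = by_run[run_start]
        n_full = len(run_cycles) // SEGMENT_CYCLES
        for k in range(n_full):
            block = run_cycles[k * SEGMENT_CYCLES : (k + 1) * SEGMENT_CYCLES]
            means, sds = segment_stats(block, circular_acrophase)
            segments.append(
                Segment(
                    participant_id=block[0].participant_id,
                    segment_index=idx,
                    cycles=block,
                    start_time=block[0].start_time,
                    end_time=block[-1].end_time,
                    means=means,
                    sds=sds,
                )
            )
            idx += 1
    return segments


@dataclass
class ParticipantSummary:
    """Final intraindividual average and variability for one participant."""

    participant_id: str
    group: str
    n_segments: int
    averages: dict[str, float]  # mean of segment means (acrophase: circular)
    variability: dict[str, float]  # mean of segment SDs
    seizure_frequency: float | None = None  # per week, if a diary exists


def intraindividual_summary(
    segments: list[Segment], group: str = ""
) -> ParticipantSummary:
    """Average the per-segment means and SDs into the participant summary."""
    if not segments:
        raise ValueError("participant has no complete 7-cycle segment")
    averages: dict[str, float] = {}
    variability: dict[str, float] = {}
    for prop in PROPERTIES:
        seg_means = np.array([s.means[prop] for s in segments])
        seg_sds = np.array([s.sds[prop] for s in segments])
        if prop == "acrophase":
            averages[prop] = circular_mean_minutes(seg_means)
        else:
            averages[prop] = float(seg_means.mean())
        variability[prop] = float(seg_sds.mean())
    return ParticipantSummary(
        participant_id=segments[0].participant_id,
        group=group,
        n_segments=len(segments),
        averages=averages,
        variability=variability,
    )


def label_segments(
    segments: list[Segment], diary: SeizureDiary | None
) -> list[Segment]:
    """Label each segment containing / free / outside-diary, in place.

    Only segments lying fully inside the diary span participate in the
    seizure analyses; a segment is "containing" when at least one event
    falls in its half-open span [start, end).
    """
    if diary is None:
        for s in segments:
            s.seizure_label = "outside-diary"
        return segments
    d0, d1 = diary.span
    events = diary.event_times
    for s in segments:
        if s.start_time >= d0 and s.end_time <= d1:
            n_in = int(np.sum((events >= s.start_time) & (events < s.end_time)))
            s.seizure_label = "containing" if n_in > 0 else "free"
        else:
            s.seizure_label = "outside-diary"
    return segments


def seizure_frequency(
    segments: list[Segment], diary: SeizureDiary
) -> float | None:
    """Seizures per week of segmented recording inside the diary span.

    One 7-cycle segment counts as one week; only events falling inside an
    in-span segment are counted (events in discarded partial weeks are not).
    Returns None when no segment lies in the diary span.
    """
    in_span = [s for s in segments if s.seizure_label != "outside-diary"]
    if not in_span:
        return None
    count = 0
    for s in in_span:
        count += int(
            np.sum(
                (diary.event_times >= s.start_time)
                & (diary.event_times < s.end_time)
            )
        )
    return count / len(in_span)


MIN_SEGMENTS_PER_LABEL = 5


def split_summary_by_label(
    segments: list[Segment], group: str = ""
) -> tuple[ParticipantSummary, ParticipantSummary] | None:
    """(containing, free) summaries for the paired seizure analysis.

    Requires at least five segments of each label; otherwise the
    participant is excluded (returns None).
    """
    containing = [s for s in segments if s.seizure_label == "containing"]
    free = [s for s in segments if s.seizure_label == "free"]
    if len(containing) < MIN_SEGMENTS_PER_LABEL or len(free) < MIN_SEGMENTS_PER_LABEL:
        return None
    return (
        intraindividual_summary(containing, group=group),
        intraindividual_summary(free, group=group),
    )
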