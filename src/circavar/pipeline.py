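"""End-to-end orchestration: simulate -> preprocess -> extract -> cycles ->
summarize -> compare, with CSV/JSON artifacts and a reproducibility manifest.

The pipeline is deterministic for a fixed configuration and master seed:
per-participant sub-seeds are spawned with ``numpy.random.SeedSequence`` so
adding a participant never perturbs the draws of any other.  Each stage
records per-participant attrition (recruited -> eligible -> correlation
cohort -> paired cohort) in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import rhythm, stats, variability
from .preprocessing import HeartRateSeries, preprocess_series
from .synthetic import (
    CohortParticipant,
    GeneratorConfig,
    SeizureDiary,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "load_heart_rate_csv",
    "load_diary_csv",
    "write_heart_rate_csv",
    "write_diary_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run depends on."""

    working_interval_s: float = 60.0
    ssa_window_days: float = 2.0
    ssa_rank: int = 20
    ssa_band_factor: float | None = 5.0 / 3.0
    ssa_complete_band: bool = True
    segment_cycles: int = 7
    min_run_days: float = 7.0
    max_gap_h: float = 8.0
    subsample_n: int = 28
    subsample_iterations: int = 10_000
    circular_acrophase: bool = True
    seed: int = 0
    out_dir: str | None = None
    # simulation inputs (used when no CSVs are given)
    sim_config_a: GeneratorConfig | None = None
    sim_config_b: GeneratorConfig | None = None
    sim_n_a: int = 0
    sim_n_b: int = 0

    def validate(self) -> None:
        for name in ("working_interval_s", "ssa_window_days", "ssa_rank",
                     "segment_cycles", "min_run_days", "max_gap_h",
                     "subsample_n", "subsample_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    cycles: pd.DataFrame
    segments: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: list[stats.GroupComparison]
    manifest: dict
    summaries_by_participant: dict[str, variability.ParticipantSummary]


def summarize_participant(
    series: HeartRateSeries,
    config: PipelineConfig,
    diary: SeizureDiary | None = None,
    group: str = "",
):
    """Run one participant through preprocessing to the summary.

    Returns ``(summary, cycles, segments, report, skip_reason)``; the
    summary is None when the participant drops out, with the reason set.
    """
    runs, report = preprocess_series(
        series,
        max_gap_h=config.max_gap_h,
        min_run_days=config.min_run_days,
        working_interval_s=config.working_interval_s,
    )
    if not runs:
        return None, [], [], report, "no run longer than the minimum"
    window = int(round(config.ssa_window_days * 86400.0 / config.working_interval_s))
    all_cycles: list[cyc.Cycle] = []
    for run in runs:
        try:
            crhr = rhythm.extract_circadian(
                run,
                window_length=window,
                rank=config.ssa_rank,
                band_factor=config.ssa_band_factor,
                complete_band=config.ssa_complete_band,
            )
        except ValueError as exc:
            logger.info("%s: run skipped (%s)", series.participant_id, exc)
            continue
        if crhr is None:
            continue
        all_cycles.extend(cyc.cycles_from_component(crhr))
    if not all_cycles:
        return None, [], [], report, "no circadian cycles extracted"
    segments = variability.segment_cycles(
        all_cycles, circular_acrophase=config.circular_acrophase
    )
    if not segments:
        return None, all_cycles, [], report, "fewer than 7 cycles in every run"
    variability.label_segments(segments, diary)
    summary = variability.intraindividual_summary(segments, group=group)
    if diary is not None:
        summary.seizure_frequency = variability.seizure_frequency(segments, diary)
    return summary, all_cycles, segments, report, None


def _cycles_frame(cycles: list[cyc.Cycle]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": c.participant_id,
                "run_start": c.run_start,
                "start": c.start_time,
                "end": c.end_time,
                "period_min": c.period_min,
                "acrophase_min": c.acrophase_min,
                "amplitude_bpm": c.amplitude_bpm,
            }
            for c in cycles
        ]
    )


def _segments_frame(segments: list[variability.Segment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        row = {
            "participant_id": s.participant_id,
            "segment_index": s.segment_index,
            "start": s.start_time,
            "end": s.end_time,
            "seizure_label": s.seizure_label,
        }
        for prop in variability.PROPERTIES:
            row[f"mean_{prop}"] = s.means[prop]
            row[f"sd_{prop}"] = s.sds[prop]
        rows.append(row)
    return pd.DataFrame(rows)


def _summaries_frame(
    summaries: dict[str, variability.ParticipantSummary]
) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        row = {
            "participant_id": s.participant_id,
            "group": s.group,
            "n_segments": s.n_segments,
        }
        for prop in variability.PROPERTIES:
            row[f"mean_{prop}"] = s.averages[prop]
            row[f"var_{prop}"] = s.variability[prop]
        row["seizure_freq_per_week"] = s.seizure_frequency
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    participants: list[CohortParticipant] | None = None,
) -> PipelineResult:
    """Execute the full pipeline on a simulated (or supplied) cohort."""
    config.validate()
    if participants is None:
        if config.sim_config_a is None or config.sim_config_b is None:
            raise ValueError("either participants or simulation configs required")
        participants = generate_cohort(
            config.sim_config_a,
            config.sim_config_b,
            config.sim_n_a,
            config.sim_n_b,
            seed=config.seed,
        )

    summaries: dict[str, variability.ParticipantSummary] = {}
    all_cycles: list[cyc.Cycle] = []
    all_segments: list[variability.Segment] = []
    skipped: dict[str, str] = {}
    for part in participants:
        try:
            summary, cycles_, segments, _report, reason = summarize_participant(
                part.series, config, diary=part.diary, group=part.group
            )
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(
                f"pipeline failed for participant {part.participant_id}: {exc}"
            ) from exc
        all_cycles.extend(cycles_)
        all_segments.extend(segments)
        if summary is None:
            skipped[part.participant_id] = reason
            continue
        summaries[part.participant_id] = summary

    groups = sorted({p.group for p in participants})
    comparisons: list[stats.GroupComparison] = []
    if len(groups) == 2:
        # convention: the group listed first in cohort order is the case group
        order = []
        for p in participants:
            if p.group not in order:
                order.append(p.group)
        a = [s for s in summaries.values() if s.group == order[0]]
        b = [s for s in summaries.values() if s.group == order[1]]
        if len(a) >= 2 and len(b) >= 2:
            comparisons = stats.compare_groups(a, b)

    manifest = {
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not k.startswith("sim_")
        },
        "n_input": len(participants),
        "n_eligible": len(summaries),
        "n_excluded": len(skipped),
        "skip_reasons": skipped,
        "groups": {
            g: sum(1 for s in summaries.values() if s.group == g) for g in groups
        },
    }
    result = PipelineResult(
        cycles=_cycles_frame(all_cycles),
        segments=_segments_frame(all_segments),
        summaries=_summaries_frame(summaries),
        comparisons=comparisons,
        manifest=manifest,
        summaries_by_participant=summaries,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.cycles.to_csv(out / "cycles.csv", index=False)
        result.segments.to_csv(out / "segments.csv", index=False)
        result.summaries.to_csv(out / "summaries.csv", index=False)
        report = {
            "manifest": manifest,
            "comparisons": [c.to_dict() for c in comparisons],
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return result


# ------------------------------------------------------------------- CSV I/O

def write_heart_rate_csv(series_list: list[HeartRateSeries], path: str | Path) -> None:
    """Write the heart-rate CSV: participant_id, timestamp (ISO-8601 UTC), bpm."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": pd.to_datetime(s.timestamps, unit="s", utc=True),
                    "bpm": s.values,
                }
            )
        )
    df = pd.concat(frames) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", "bpm"]
    )
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def load_heart_rate_csv(
    path: str | Path, nominal_interval: float = 5.0
) -> list[HeartRateSeries]:
    """Read the heart-rate CSV back into per-participant series.

    Rows are sorted per participant; malformed timestamps or non-positive
    bpm raise with the offending line numbers.
    """
    df = pd.read_csv(path)
    expected = {"participant_id", "timestamp", "bpm"}
    if set(df.columns) != expected:
        raise ValueError(
            f"unexpected columns {sorted(set(df.columns) ^ expected)} in {path}"
        )
    if df.empty:
        return []
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        raise ValueError(f"unparseable timestamps at CSV lines {list(bad + 2)}")
    bpm = pd.to_numeric(df["bpm"], errors="coerce")
    bad = df.index[bpm.isna() | (bpm <= 0)]
    if len(bad):
        raise ValueError(f"invalid bpm values at CSV lines {list(bad + 2)}")
    df = df.assign(_t=ts.astype("int64") / 1e9, _v=bpm)
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("_t")
        out.append(
            HeartRateSeries(
                participant_id=str(pid),
                timestamps=grp["_t"].to_numpy(),
                values=grp["_v"].to_numpy(),
                nominal_interval=nominal_interval,
            )
        )
    return out


def write_diary_csv(diaries: list[SeizureDiary], path: str | Path) -> None:
    """Write the diary CSV: participant_id, seizure_time (ISO-8601 UTC)."""
    rows = []
    for d in diaries:
        for t in d.event_times:
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "seizure_time": pd.Timestamp(t, unit="s", tz="UTC"),
                }
            )
    df = pd.DataFrame(rows, columns=["participant_id", "seizure_time"])
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def load_diary_csv(path: str | Path) -> list[SeizureDiary]:
    """Read the diary CSV; the span falls back to first-to-last event."""
    df = pd.read_csv(path)
    expected = {"participant_id", "seizure_time"}
    if set(df.columns) != expected:
        raise ValueError(f"unexpected columns in {path}")
    out = []
    if df.empty:
        return out
    ts = pd.to_datetime(df["seizure_time"], utc=True, errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        raise ValueError(f"unparseable timestamps at CSV lines {list(bad + 2)}")
    df = df.assign(_t=ts.astype("int64") / 1e9)
    for pid, grp in df.groupby("participant_id", sort=True):
        times = np.sort(grp["_t"].to_numpy())
        out.append(
            SeizureDiary(
                participant_id=str(pid),
                event_times=times,
                span=(float(times[0]), float(times[-1])),
            )
        )
    return out
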