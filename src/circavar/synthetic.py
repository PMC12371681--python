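"""Synthetic wearable heart-rate cohorts with known circadian ground truth.

The generator builds, per participant, a ~24-h oscillation whose period,
acrophase, and amplitude jitter from day to day, plus ultradian tones and
autocorrelated (AR(1)) sensor noise, then punches missing-data gaps into the
record and (optionally) draws a Poisson seizure diary.  Because each cycle's
true period, acrophase, and peak-minus-trough amplitude are recorded, every
downstream stage can be validated by parameter recovery.

Cycle construction.  Troughs are laid down sequentially; cycle ``d`` has
period ``P_d = period_mean - kappa * drift_d + eps_d`` where ``drift_d`` is
the accumulated acrophase displacement from the anchor clock time and
``eps_d`` is Gaussian.  ``kappa`` (``mean_reversion``) in [0, 1] pulls the
acrophase back toward the anchor so that, as in entrained humans, the time
of day of the peak stays bounded over months.  ``eps`` is scaled so that the
realized per-cycle period SD equals ``period_sd`` regardless of ``kappa``
(for the drift AR(1) recursion, Var(P) = 2 sigma_eps^2 / (2 - kappa)).
Within a cycle the phase advances linearly from -pi (trough) through 0
(peak) to +pi (next trough), and the heart rate is

    HR(t) = mesor + A_d cos(Phi(t)) + sum_k a_k cos(2 pi t / p_k + phi_k) + AR1(t)

with per-cycle amplitude ``A_d ~ N(amplitude_mean, amplitude_sd)`` truncated
positive.  Ground-truth amplitude is recorded as ``2 A_d`` — the cosine's
peak minus its preceding trough, which is how the cycle metrics downstream
define amplitude (not the cosinor half-amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import HeartRateSeries

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SeizureDiary",
    "generate_participant",
    "inject_gaps",
    "generate_seizure_diary",
    "generate_cohort",
]

#: All synthetic timestamps are offsets from this local midnight (UTC).
EPOCH_ORIGIN = 1_609_459_200.0  # 2021-01-01T00:00:00Z

MINUTE = 60.0
DAY_MIN = 1440.0


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic participant's recording."""

    n_days: int = 70
    sampling_interval_s: float = 5.0
    mesor: float = 75.0  # bpm
    amplitude_mean: float = 10.0  # bpm (cosine half-amplitude)
    amplitude_sd: float = 2.0  # bpm, day-to-day
    period_mean: float = 1440.0  # minutes
    period_sd: float = 30.0  # minutes, day-to-day
    acrophase_anchor: float = 900.0  # minutes-of-day (15:00)
    mean_reversion: float = 0.2  # kappa in [0, 1]
    ultradian: tuple[tuple[float, float], ...] = ((12.0, 2.0), (8.0, 1.0))
    # (period h, amplitude bpm) pairs
    noise_ar1_phi: float = 0.9  # at 5-s sampling
    noise_sd: float = 3.0  # bpm, marginal
    gap_rate: float = 0.5  # gaps per day
    gap_duration_log_mean: float = 0.0  # log-hours (median 1 h)
    gap_duration_log_sd: float = 1.2  # log-hours
    seizures_per_week: float = 0.0
    utc_offset_min: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")
        if self.period_sd < 0:
            raise ValueError("period_sd must be non-negative")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be non-negative")
        if not self.mesor > self.amplitude_mean:
            raise ValueError(
                "mesor must exceed amplitude_mean so heart rate stays positive"
            )
        if not 0.0 <= self.mean_reversion <= 1.0:
            raise ValueError("mean_reversion must lie in [0, 1]")
        if not 0.0 <= self.noise_ar1_phi < 1.0:
            raise ValueError("noise_ar1_phi must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gap_rate < 0:
            raise ValueError("gap_rate must be non-negative")
        if self.seizures_per_week < 0:
            raise ValueError("seizures_per_week must be non-negative")


@dataclass
class GroundTruth:
    """Realized per-cycle circadian properties of one synthetic participant.

    One record per generated cycle (trough to trough), restricted to cycles
    fully inside the sampled span.
    """

    participant_id: str
    trough_times: np.ndarray  # cycle start timestamps, seconds since epoch
    periods_min: np.ndarray  # realized P_d
    acrophase_times: np.ndarray  # peak timestamps, seconds since epoch
    acrophases_min_of_day: np.ndarray  # local clock minutes in [0, 1440)
    amplitudes_bpm: np.ndarray  # peak minus preceding trough = 2 A_d

    @property
    def n_cycles(self) -> int:
        return int(self.periods_min.size)


@dataclass
class SeizureDiary:
    """Self-reported seizure events and the span over which reporting ran."""

    participant_id: str
    event_times: np.ndarray  # seconds since epoch, sorted
    span: tuple[float, float]  # [start, end] of diary-keeping

    def __post_init__(self) -> None:
        self.event_times = np.sort(np.asarray(self.event_times, dtype=float))


def _draw_cycles(
    cfg: GeneratorConfig, rng: np.random.Generator, span_min: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential trough times (minutes from origin) and per-cycle periods."""
    kappa = cfg.mean_reversion
    sigma_eps = cfg.period_sd * np.sqrt((2.0 - kappa) / 2.0)
    troughs = [cfg.acrophase_anchor - cfg.period_mean / 2.0 - cfg.period_mean]
    periods = []
    drift = 0.0
    while troughs[-1] < span_min + cfg.period_mean:
        eps = rng.normal(0.0, sigma_eps) if sigma_eps > 0 else 0.0
        p = cfg.period_mean - kappa * drift + eps
        p = max(p, 0.5 * cfg.period_mean)  # guard against absurd draws
        drift += p - cfg.period_mean
        periods.append(p)
        troughs.append(troughs[-1] + p)
    return np.asarray(troughs), np.asarray(periods)


def generate_participant(
    config: GeneratorConfig, participant_id: str = "P000"
) -> tuple[HeartRateSeries, GroundTruth]:
    """Generate one gap-free recording plus its cycle-level ground truth.

    Deterministic given ``config`` (including its seed).  Gaps are injected
    separately by :func:`inject_gaps` so that ground truth always refers to
    the complete underlying rhythm.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    span_min = config.n_days * DAY_MIN
    troughs, periods = _draw_cycles(config, rng, span_min)
    amps = rng.normal(config.amplitude_mean, config.amplitude_sd, periods.size)
    while np.any(amps <= 0):  # truncate to positive
        bad = amps <= 0
        amps[bad] = rng.normal(config.amplitude_mean, config.amplitude_sd, bad.sum())

    dt_min = config.sampling_interval_s / MINUTE
    t = np.arange(0.0, span_min + dt_min / 2, dt_min)

    idx = np.clip(np.searchsorted(troughs, t, side="right") - 1, 0, periods.size - 1)
    phase = -np.pi + 2.0 * np.pi * (t - troughs[idx]) / periods[idx]
    hr = config.mesor + amps[idx] * np.cos(phase)

    for period_h, amp_bpm in config.ultradian:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        hr += amp_bpm * np.cos(2.0 * np.pi * t / (period_h * 60.0) + phi0)

    if config.noise_sd > 0:
        # phi is defined per 5-s step; rescale so the noise process (its
        # correlation time and marginal SD) is invariant to the sampling
        # interval chosen for a given realization
        phi = config.noise_ar1_phi ** (config.sampling_interval_s / 5.0)
        w = rng.normal(0.0, config.noise_sd * np.sqrt(1.0 - phi * phi), t.size)
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -phi], w)
        hr += noise

    hr = np.maximum(hr, 1.0)  # physical floor; essentially never binds

    series = HeartRateSeries(
        participant_id=participant_id,
        timestamps=EPOCH_ORIGIN + t * MINUTE,
        values=hr,
        nominal_interval=config.sampling_interval_s,
        utc_offset_min=config.utc_offset_min,
    )

    # ground truth: cycles fully inside the sampled span
    inside = (troughs[:-1] >= 0.0) & (troughs[1:] <= span_min)
    tr = troughs[:-1][inside]
    pd_ = periods[inside]
    acro_min = tr + pd_ / 2.0
    truth = GroundTruth(
        participant_id=participant_id,
        trough_times=EPOCH_ORIGIN + tr * MINUTE,
        periods_min=pd_,
        acrophase_times=EPOCH_ORIGIN + acro_min * MINUTE,
        acrophases_min_of_day=np.mod(acro_min + config.utc_offset_min, DAY_MIN),
        amplitudes_bpm=2.0 * amps[inside],
    )
    return series, truth


def inject_gaps(
    series: HeartRateSeries, config: GeneratorConfig, seed: int | None = None
) -> HeartRateSeries:
    """Remove samples inside randomly drawn gap intervals.

    Gap count is Poisson with ``gap_rate`` per day; gap starts are uniform
    over the span; durations are log-normal in hours, so one mechanism
    yields both interpolatable (< 8 h) and run-splitting (>= 8 h) gaps.
    """
    config.validate()
    if config.gap_rate == 0:
        return series
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    span_s = series.span
    n_gaps = rng.poisson(config.gap_rate * span_s / 86400.0)
    if n_gaps == 0:
        return series
    starts = series.timestamps[0] + rng.uniform(0.0, span_s, n_gaps)
    durations = rng.lognormal(
        config.gap_duration_log_mean, config.gap_duration_log_sd, n_gaps
    ) * 3600.0
    keep = np.ones(series.timestamps.size, dtype=bool)
    for s, d in zip(starts, durations):
        keep &= ~((series.timestamps >= s) & (series.timestamps < s + d))
    return replace(
        series,
        timestamps=series.timestamps[keep],
        values=series.values[keep],
        interpolated=series.interpolated[keep],
    )


def generate_seizure_diary(
    rate_per_week: float,
    span: tuple[float, float],
    seed: int = 0,
    participant_id: str = "P000",
) -> SeizureDiary:
    """Homogeneous Poisson seizure diary over ``span`` (epoch seconds)."""
    if rate_per_week < 0:
        raise ValueError("seizure rate must be non-negative")
    start, end = span
    if end < start:
        raise ValueError("diary span end precedes start")
    rng = np.random.default_rng(seed)
    weeks = (end - start) / (7 * 86400.0)
    n = rng.poisson(rate_per_week * weeks)
    times = np.sort(rng.uniform(start, end, n))
    return SeizureDiary(participant_id=participant_id, event_times=times, span=span)


@dataclass
class CohortParticipant:
    """One generated participant with everything downstream needs."""

    participant_id: str
    group: str
    series: HeartRateSeries  # with gaps injected
    truth: GroundTruth
    diary: SeizureDiary | None


def generate_cohort(
    config_a: GeneratorConfig,
    config_b: GeneratorConfig,
    n_a: int,
    n_b: int,
    seed: int = 0,
    labels: tuple[str, str] = ("pwe", "control"),
) -> list[CohortParticipant]:
    """Two labelled groups of independent participants.

    Per-participant sub-seeds are spawned from the master seed with
    ``numpy.random.SeedSequence`` so adding a participant never perturbs
    the draws of any other.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("each group needs at least one participant")
    config_a.validate()
    config_b.validate()
    ss = np.random.SeedSequence(seed)
    stream_a, stream_b = ss.spawn(2)  # one stream per group: adding to one
    children = stream_a.spawn(n_a) + stream_b.spawn(n_b)  # never shifts the other
    out: list[CohortParticipant] = []
    specs = [(labels[0], config_a)] * n_a + [(labels[1], config_b)] * n_b
    for i, ((group, cfg), child) in enumerate(zip(specs, children)):
        sub = child.generate_state(3)
        pid = f"{group}_{i:03d}"
        p_cfg = replace(cfg, seed=int(sub[0] % (2**31)))
        series, truth = generate_participant(p_cfg, participant_id=pid)
        gappy = inject_gaps(series, p_cfg, seed=int(sub[1] % (2**31)))
        diary = None
        if cfg.seizures_per_week > 0:
            diary = generate_seizure_diary(
                cfg.seizures_per_week,
                (series.timestamps[0], series.timestamps[-1]),
                seed=int(sub[2] % (2**31)),
                participant_id=pid,
            )
        out.append(CohortParticipant(pid, group, gappy, truth, diary))
    return out
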