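import numpy as np
import pytest

from circavar import HeartRateSeries, Run
from circavar.rhythm import CircadianComponent


def make_series(
    times_s: np.ndarray,
    values: np.ndarray,
    nominal: float = 5.0,
    pid: str = "P000",
) -> HeartRateSeries:
    return HeartRateSeries(
        participant_id=pid,
        timestamps=np.asarray(times_s, dtype=float),
        values=np.asarray(values, dtype=float),
        nominal_interval=nominal,
    )


def cosine_run(
    days: float = 10.0,
    interval_s: float = 300.0,
    half_amplitude: float = 10.0,
    period_h: float = 24.0,
    mesor: float = 70.0,
    peak_time_h: float = 0.0,
    start_time: float = 0.0,
) -> Run:
    """Uniform run carrying mesor + A*cos(2*pi*(t - peak)/period)."""
    n = int(days * 86400 / interval_s) + 1
    t = interval_s * np.arange(n)
    vals = mesor + half_amplitude * np.cos(
        2 * np.pi * (t - peak_time_h * 3600.0) / (period_h * 3600.0)
    )
    return Run(
        participant_id="COS",
        start_time=start_time,
        interval=interval_s,
        values=vals,
        interpolated_mask=np.zeros(n, dtype=bool),
    )


def component_of(run: Run, period_h: float = 24.0) -> CircadianComponent:
    """Wrap a zero-meaned run as a ready-made circadian component."""
    return CircadianComponent(
        run=run,
        values=run.values - run.values.mean(),
        central_period_h=period_h,
        candidate_periods_h=np.array([period_h]),
        group=(0,),
    )


@pytest.fixture
def pure_cosine_run() -> Run:
    return cosine_run()
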