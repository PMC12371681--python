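"""Circadian rhythm extraction by singular spectrum analysis (SSA).

Each uniformly sampled run is lag-embedded into a Hankel trajectory matrix,
decomposed by (truncated) singular value decomposition, and each eigentriple
is reconstructed by anti-diagonal averaging.  A clean oscillation shows up
as a pair of frequency-matched eigentriples (sine/cosine quadrature pair),
so eigentriples are grouped by central frequency before the component whose
period is closest to 24 h is selected as the circadian rhythm of heart rate
(CRHR).

For month-scale runs the trajectory matrix is never formed: its matvec is a
correlation with the run, evaluated with FFT convolutions, and a truncated
SVD (ARPACK) extracts only the leading eigentriples.  The run mean is
removed first and tracked as the trend baseline; slow components (period
beyond 48 h) are kept out of circadian candidacy so multiday rhythms cannot
masquerade as circadian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel
from scipy.signal import fftconvolve
from scipy.sparse.linalg import LinearOperator, svds

from .preprocessing import Run

__all__ = [
    "SSADecomposition",
    "CircadianComponent",
    "ssa_decompose",
    "component_central_period",
    "group_components_by_frequency",
    "merge_circadian_band",
    "select_circadian",
    "complete_circadian_band",
    "extract_circadian",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_DAYS = 2.0
DEFAULT_RANK = 20
#: Components slower than this are treated as trend, not circadian candidates.
TREND_PERIOD_H = 48.0
#: Warn when the selected component's period falls outside this band.
PLAUSIBLE_BAND_H = (20.0, 28.0)
#: Relative RMS below which a component is flagged aperiodic/degenerate.
APERIODIC_RMS = 1e-10

# dense SVD only when the trajectory matrix stays comfortably in memory
_DENSE_LIMIT = 30_000_000


@dataclass
class SSADecomposition:
    """An SSA decomposition of one run, possibly after grouping.

    ``series`` holds one reconstructed component per (group of)
    eigentriple(s); ``sigma`` the corresponding singular-value mass;
    ``periods_h`` the central period of each component (NaN = aperiodic).
    """

    run: Run
    window_length: int
    rank: int
    sigma: np.ndarray  # singular value (or group root-sum-square), descending
    series: list[np.ndarray]  # reconstructions on the run grid
    periods_h: np.ndarray  # central periods, hours (NaN for aperiodic)
    mean: float  # removed baseline
    groups: list[tuple[int, ...]]  # eigentriple indices behind each component

    @property
    def n_components(self) -> int:
        return len(self.series)


@dataclass
class CircadianComponent:
    """The selected ~24-h component of one run, on the run's grid."""

    run: Run
    values: np.ndarray  # bpm, zero-mean
    central_period_h: float
    candidate_periods_h: np.ndarray  # selection diagnostics
    group: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return self.run.times()


def _hankel_operator(x: np.ndarray, L: int) -> LinearOperator:
    """The L x K trajectory matrix H[i, j] = x[i + j] as a LinearOperator."""
    K = x.size - L + 1

    def mv(v: np.ndarray) -> np.ndarray:
        return fftconvolve(x, v[::-1].ravel(), mode="valid")

    def rmv(u: np.ndarray) -> np.ndarray:
        return fftconvolve(x, u[::-1].ravel(), mode="valid")

    return LinearOperator((L, K), matvec=mv, rmatvec=rmv, dtype=float)


def _diagonal_average(s: float, u: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    """Reconstruct the series of rank-one term s * u v^T by anti-diagonal means."""
    num = s * np.convolve(u, v)
    counts = np.convolve(np.ones(u.size), np.ones(v.size))
    assert num.size == n
    return num / counts


def ssa_decompose(
    run: Run,
    window_length: int | None = None,
    rank: int = DEFAULT_RANK,
) -> SSADecomposition:
    """Decompose a run into elementary SSA eigentriples.

    The run mean is removed first and kept as the baseline.  ``rank``
    eigentriples are extracted with a truncated SVD; when ``rank`` reaches
    the window length the decomposition is exact and the eigentriples sum
    back to the original series.
    """
    x_full = np.asarray(run.values, dtype=float)
    n = x_full.size
    if window_length is None:
        window_length = int(round(DEFAULT_WINDOW_DAYS * 86400.0 / run.interval))
    L = int(window_length)
    if not 2 <= L <= n - 1:
        raise ValueError("window_length must satisfy 2 <= L <= len(run) - 1")
    if n < 2 * L:
        raise ValueError(
            f"run of {n} samples is shorter than twice the window ({L}); "
            "lower the window length"
        )
    if rank > L:
        raise ValueError("rank cannot exceed the window length")
    mean = float(x_full.mean())
    x = x_full - mean
    K = n - L + 1

    if np.max(np.abs(x)) <= APERIODIC_RMS * max(abs(mean), 1.0):
        # constant run: nothing oscillates after mean removal
        zeros = [np.zeros(n) for _ in range(rank)]
        return SSADecomposition(
            run=run,
            window_length=L,
            rank=rank,
            sigma=np.zeros(rank),
            series=zeros,
            periods_h=np.full(rank, np.nan),
            mean=mean,
            groups=[(i,) for i in range(rank)],
        )

    if rank >= min(L, K):  # full decomposition: dense SVD required
        if L * K > _DENSE_LIMIT:
            raise ValueError(
                "full-rank SSA of a matrix this large is not supported; "
                "reduce the rank or the window"
            )
        H = hankel(x[:L], x[L - 1 :])
        u_mat, s, vt = np.linalg.svd(H, full_matrices=False)
        k_eff = min(rank, s.size)
        u_mat, s, vt = u_mat[:, :k_eff], s[:k_eff], vt[:k_eff]
    else:
        op = _hankel_operator(x, L)
        v0 = np.full(min(L, K), 1.0 / np.sqrt(min(L, K)))
        u_mat, s, vt = svds(op, k=rank, v0=v0, which="LM")
        order = np.argsort(s)[::-1]
        u_mat, s, vt = u_mat[:, order], s[order], vt[order]

    series = [
        _diagonal_average(s[i], u_mat[:, i], vt[i], n) for i in range(s.size)
    ]
    periods = np.array(
        [component_central_period(c, run.interval) for c in series]
    )
    return SSADecomposition(
        run=run,
        window_length=L,
        rank=int(s.size),
        sigma=s,
        series=series,
        periods_h=periods,
        mean=mean,
        groups=[(i,) for i in range(s.size)],
    )


def component_central_period(
    component_values: np.ndarray, interval_s: float
) -> float:
    """Central period (hours) of a component via its zero-padded periodogram.

    The FFT is padded so the frequency resolution near 24 h is much finer
    than 0.25 h, and the periodogram peak is refined by quadratic
    interpolation.  Returns NaN for an (all but) all-zero component, which
    is thereby flagged aperiodic and excluded from circadian candidacy.
    """
    x = np.asarray(component_values, dtype=float)
    n = x.size
    rms = np.sqrt(np.mean(x * x))
    scale = max(np.abs(x).max(), 1.0)
    if rms <= APERIODIC_RMS * scale:
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(max(8 * n, 2**18))))
    spec = np.abs(np.fft.rfft(x - x.mean(), nfft)) ** 2
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return float("inf")
    # quadratic peak interpolation on log power
    if 1 <= k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        a, b, c = np.log(spec[k - 1 : k + 2])
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = (k + delta) / (nfft * interval_s)  # Hz
    return 1.0 / freq / 3600.0


def group_components_by_frequency(
    decomp: SSADecomposition, rel_tol: float = 0.05
) -> SSADecomposition:
    """Merge quadrature eigentriple pairs into single oscillatory components.

    Eigentriples whose central frequencies differ by less than ``rel_tol``
    (relative) and whose singular values are within a factor of 2 are merged
    (reconstructions summed), then each group is re-scored by its central
    period.  Group singular mass is the root-sum-square of member values.
    """
    n_comp = decomp.n_components
    freqs = np.where(np.isfinite(decomp.periods_h), 1.0 / decomp.periods_h, np.nan)
    used = np.zeros(n_comp, dtype=bool)
    groups: list[list[int]] = []
    for i in range(n_comp):
        if used[i]:
            continue
        used[i] = True
        members = [i]
        for j in range(i + 1, n_comp):
            if used[j]:
                continue
            if not (np.isfinite(freqs[i]) and np.isfinite(freqs[j])):
                continue
            rel = abs(freqs[i] - freqs[j]) / ((freqs[i] + freqs[j]) / 2.0)
            ratio = max(decomp.sigma[i], decomp.sigma[j]) / max(
                min(decomp.sigma[i], decomp.sigma[j]), 1e-300
            )
            if rel_tol > 0 and rel < rel_tol and ratio < 2.0:
                used[j] = True
                members.append(j)
        groups.append(members)

    series = [sum(decomp.series[m] for m in g) for g in groups]
    sigma = np.array(
        [np.sqrt(sum(decomp.sigma[m] ** 2 for m in g)) for g in groups]
    )
    order = np.argsort(sigma)[::-1]
    series = [series[i] for i in order]
    groups = [tuple(decomp.groups[m][0] for m in groups[i]) for i in order]
    sigma = sigma[order]
    periods = np.array(
        [component_central_period(c, decomp.run.interval) for c in series]
    )
    return SSADecomposition(
        run=decomp.run,
        window_length=decomp.window_length,
        rank=decomp.rank,
        sigma=sigma,
        series=series,
        periods_h=periods,
        mean=decomp.mean,
        groups=groups,
    )


#: Components within this factor of the selected circadian period are part
#: of its frequency-modulation sideband structure and get merged into it.
DEFAULT_BAND_FACTOR = 5.0 / 3.0


def merge_circadian_band(
    decomp: SSADecomposition, band_factor: float | None = DEFAULT_BAND_FACTOR
) -> SSADecomposition:
    """Fold frequency-modulation sidebands into the circadian component.

    A rhythm whose period jitters from day to day is a frequency-modulated
    oscillation: its energy spreads into sidebands around the ~24-h carrier,
    which the decomposition returns as separate components (e.g. ~16 h and
    ~32 h).  Keeping only the carrier pair yields an artificially pure tone
    whose instantaneous phase under-reports the day-to-day period
    variability, so every oscillatory component whose central period lies
    within ``band_factor`` of the provisional circadian winner is merged
    into it.  The default factor (5/3, a band of roughly 14-40 h around
    24 h) keeps the 12-h ultradian harmonic and faster rhythms out.
    ``band_factor`` of None or 1.0 disables merging.
    """
    if band_factor is None or band_factor <= 1.0:
        return decomp
    periods = decomp.periods_h
    candidates = [
        i
        for i in range(decomp.n_components)
        if np.isfinite(periods[i]) and periods[i] <= TREND_PERIOD_H
    ]
    if not candidates:
        return decomp
    best = min(candidates, key=lambda i: (abs(periods[i] - 24.0), i))
    p0 = periods[best]
    members = [
        i
        for i in range(decomp.n_components)
        if np.isfinite(periods[i]) and p0 / band_factor <= periods[i] <= p0 * band_factor
    ]
    if len(members) <= 1:
        return decomp
    rest = [i for i in range(decomp.n_components) if i not in members]
    series = [sum(decomp.series[i] for i in members)] + [
        decomp.series[i] for i in rest
    ]
    sigma = np.array(
        [np.sqrt(sum(decomp.sigma[i] ** 2 for i in members))]
        + [decomp.sigma[i] for i in rest]
    )
    groups = [tuple(j for i in members for j in decomp.groups[i])] + [
        decomp.groups[i] for i in rest
    ]
    order = np.argsort(sigma)[::-1]
    series = [series[i] for i in order]
    groups = [groups[i] for i in order]
    sigma = sigma[order]
    new_periods = np.array(
        [component_central_period(c, decomp.run.interval) for c in series]
    )
    return SSADecomposition(
        run=decomp.run,
        window_length=decomp.window_length,
        rank=decomp.rank,
        sigma=sigma,
        series=series,
        periods_h=new_periods,
        mean=decomp.mean,
        groups=groups,
    )


def select_circadian(decomp: SSADecomposition) -> CircadianComponent | None:
    """Pick the grouped component whose period is closest to 24 h.

    Aperiodic components and slow trend components (period > 48 h) are not
    candidates.  Exact ties go to the group with larger singular-value mass
    (lower index after energy ordering).  Returns None, with the reason
    logged, when no oscillatory candidate exists.
    """
    periods = decomp.periods_h
    candidates = [
        i
        for i in range(decomp.n_components)
        if np.isfinite(periods[i]) and periods[i] <= TREND_PERIOD_H
    ]
    if not candidates:
        logger.warning(
            "run starting %s: no oscillatory component; run skipped",
            decomp.run.start_time,
        )
        return None
    dist = {i: abs(periods[i] - 24.0) for i in candidates}
    best = min(candidates, key=lambda i: (dist[i], i))
    ties = [i for i in candidates if dist[i] == dist[best] and i != best]
    if ties:
        logger.info("circadian selection tie broken by singular mass: %s", ties)
    period = float(periods[best])
    if not PLAUSIBLE_BAND_H[0] <= period <= PLAUSIBLE_BAND_H[1]:
        logger.warning(
            "selected circadian period %.2f h lies outside [%g, %g] h",
            period,
            *PLAUSIBLE_BAND_H,
        )
    return CircadianComponent(
        run=decomp.run,
        values=decomp.series[best],
        central_period_h=period,
        candidate_periods_h=periods[candidates],
        group=decomp.groups[best],
    )


def _bandpass(x: np.ndarray, interval_s: float, lo_h: float, hi_h: float) -> np.ndarray:
    """Zero-phase FFT band projection onto periods [lo_h, hi_h] hours."""
    n = x.size
    f = np.fft.rfftfreq(n, d=interval_s)
    spec = np.fft.rfft(x)
    keep = (f >= 1.0 / (hi_h * 3600.0)) & (f <= 1.0 / (lo_h * 3600.0))
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n)


def complete_circadian_band(
    crhr: CircadianComponent, band_factor: float = DEFAULT_BAND_FACTOR
) -> CircadianComponent:
    """Add the in-band remainder of the run to the selected component.

    A truncated decomposition keeps only the strongest eigentriples, so the
    weak tails of the circadian frequency-modulation spectrum — which carry
    the fast cycle-to-cycle timing information — end up discarded or leaked
    into other components.  At full rank, grouping eigentriples by frequency
    converges to the Fourier band split of the run, so the exact circadian
    group is recovered by adding back everything in the circadian band
    (within ``band_factor`` of the selected period) that the truncated
    group missed.  The Hilbert stage's 12-h edge trim also covers the band
    filter's edge transients.
    """
    run = crhr.run
    x = np.asarray(run.values, dtype=float)
    x = x - x.mean()
    resid = x - crhr.values
    p0 = crhr.central_period_h
    vals = crhr.values + _bandpass(
        resid, run.interval, p0 / band_factor, p0 * band_factor
    )
    return CircadianComponent(
        run=run,
        values=vals,
        central_period_h=p0,
        candidate_periods_h=crhr.candidate_periods_h,
        group=crhr.group,
    )


def extract_circadian(
    run: Run,
    window_length: int | None = None,
    rank: int = DEFAULT_RANK,
    rel_tol: float = 0.05,
    band_factor: float | None = DEFAULT_BAND_FACTOR,
    complete_band: bool = True,
) -> CircadianComponent | None:
    """Decompose, group, band-merge, select, and complete, in one call."""
    decomp = ssa_decompose(run, window_length=window_length, rank=rank)
    grouped = group_components_by_frequency(decomp, rel_tol=rel_tol)
    merged = merge_circadian_band(grouped, band_factor=band_factor)
    crhr = select_circadian(merged)
    if crhr is not None and complete_band and band_factor and band_factor > 1.0:
        crhr = complete_circadian_band(crhr, band_factor=band_factor)
    return crhr
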