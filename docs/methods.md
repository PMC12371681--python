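# Methods

This note documents the models, estimators, and numerical choices behind
`circavar`, in the order the pipeline runs, together with the design
decisions that were genuinely open and the limitations a user should know.

## Synthetic recordings

`circavar.synthetic` generates wearable-like heart-rate records with known
cycle-level ground truth. The model is

    HR(t) = mesor + A_d cos(Phi(t)) + sum_k a_k cos(2 pi t / p_k + phi_k) + e(t)

* **Circadian cycle structure.** Troughs are laid down sequentially. Cycle
  d has period `P_d = period_mean - kappa * drift_d + eps_d`, where
  `drift_d` is the accumulated displacement of the acrophase from its
  anchor clock time and `eps_d` is Gaussian. The mean-reversion coefficient
  `kappa` (default 0.2) makes the acrophase an AR(1) process around the
  anchor, as in an entrained person: without it the peak time would random-
  walk away from the light/dark cycle over months. `eps` is scaled by
  `sqrt((2 - kappa) / 2)` so that the *realized* per-cycle period SD equals
  the configured `period_sd` for any `kappa` (for the AR(1) drift
  recursion, Var(P) = 2 sigma_eps^2 / (2 - kappa)). Within a cycle the
  phase `Phi` rises linearly from -pi (trough) through 0 (peak) to +pi.
  An experiment with smooth (PCHIP) phase interpolation between the same
  anchor points was rejected: the piecewise-linear phase is what defines
  the recorded trough times, and smoothing it only removed recoverable
  timing information without changing the ground truth.
* **Amplitude.** `A_d ~ N(amplitude_mean, amplitude_sd)` truncated
  positive, redrawn per cycle. Ground-truth amplitude is recorded as
  `2 A_d` — the cosine's peak minus its preceding trough — matching the
  cycle-metric definition downstream, not the cosinor half-amplitude.
* **Ultradian tones** (defaults 12 h / 2 bpm and 8 h / 1 bpm) with seeded
  random phases stand in for sleep-cycle and behavioural harmonics.
* **Noise** is AR(1) with marginal SD `noise_sd` (default 3 bpm) and
  per-5-s coefficient `noise_ar1_phi` (default 0.9), rescaled as
  `phi^(dt/5)` so the process is invariant to the sampling interval a
  realization is generated at. PPG-derived heart rate is strongly
  autocorrelated; white noise would be far too easy to filter out.
* **Gaps** arrive as a Poisson process (default 0.5/day) with log-normal
  durations (median 1 h, log-SD 1.2), so a single mechanism produces both
  interpolatable (< 8 h) and run-splitting (>= 8 h) gaps.
* **Seizure diaries** are homogeneous Poisson event streams over the
  recording span.

What the generator does **not** emulate: behavioural masking (exercise
bouts, posture), weekday/weekend structure, seasonal drift, missingness
correlated with state (device taken off during seizures), or raw PPG
artefacts. Passing recovery tests therefore demonstrates that the
estimator chain is consistent for rhythms of this class, not that real
Fitbit data meet these assumptions.

## Preprocessing

Gaps are any inter-sample spacing above twice the nominal interval (jitter
tolerance). "Shorter than 8 h" is read strictly: gaps < 8 h are linearly
interpolated onto the nominal grid (filled samples are flagged); gaps
>= 8 h split the series into runs. Runs are resampled onto a uniform grid
anchored at their first timestamp, and only runs strictly longer than
7 days are analysed. Kept runs are downsampled by non-overlapping window
means; a 24-h rhythm is attenuated by sinc(pi dt / P), i.e. by < 1e-5 at
1-min windows, so nothing circadian is lost. The processing report exposes
days lost to gaps and days in too-short runs separately, since the
appropriate discard accounting depends on the question.

## Rhythm extraction

Standard SSA: embed the mean-removed run into an L x K Hankel matrix,
truncated SVD, anti-diagonal averaging per eigentriple. The matrix is
never formed — its matvec is an FFT correlation with the run — and ARPACK
(with a fixed, deterministic start vector) extracts the leading
eigentriples; a dense SVD is used when full rank is requested on a small
run. Library defaults are a 2-day window and rank 20; the validated
pipeline configuration used throughout the tests and the acceptance script
is a 1.5-day window, rank 16, at a 2-min working interval, which recovers
equivalently at a fraction of the cost.

Each eigentriple's central period comes from a zero-padded periodogram
(padding to >= 2^18 samples, quadratic peak interpolation), giving a
resolution much finer than 0.25 h near 24 h even for 2-day runs.
Eigentriples with frequencies within 5% (relative) and singular values
within a factor of 2 are merged — a clean oscillation appears as a
quadrature pair. Components with period above 48 h are trend, not
circadian candidates, so multiday rhythms cannot masquerade as circadian;
near-zero components are flagged aperiodic. The oscillatory group with
period closest to 24 h is selected (ties to the larger singular mass; a
warning is logged outside 20-28 h).

**Band completion.** A rhythm whose period jitters day to day is a
frequency-modulated oscillation: its spectrum spreads into sidebands
around the ~24-h carrier, with tails that fall below the broadband noise
floor. A rank-truncated decomposition therefore returns an artificially
pure carrier whose instantaneous phase under-reports cycle-to-cycle
timing variability (by roughly 30% at 60-min jitter in our recovery
experiments). At full rank, grouping eigentriples by central frequency
converges to the Fourier band split of the run, so the implementation
completes the selected group with the in-band remainder of the run
(band = factor 5/3 around the selected period, i.e. about 14-40 h for a
24-h rhythm — wide enough for realistic jitter, narrow enough to exclude
the 12-h harmonic). Both the merge factor and completion are configurable
(`band_factor`, `complete_band`).

The price of band completion is a noise floor: when the true day-to-day
jitter is small, in-band sensor noise dominates the recovered variability
(about 35 min recovered at 15-min generative jitter under default noise).
Recovery is monotone in the true jitter throughout — rankings and group
contrasts are preserved — but absolute variability values at the low end
are noise-limited. This is inherent to any band-limited phase method, not
to SSA specifically.

## Cycle metrics

The analytic-signal phase of the CRHR is zero at the peak by the cosine
convention, so the wrapped phase jumps from +pi to -pi exactly at the
troughs. Cycle boundaries are those wrap events, refined by linear
interpolation of the unwrapped phase to the odd-pi crossing; boundaries
closer than 12 h are merged (keeping the first), and half a cycle (12 h)
is trimmed at each run end to suppress Hilbert edge distortion — this also
absorbs the band filter's edge transients. Within a cycle, the acrophase
is the interpolated even-2pi crossing converted to local clock minutes
(each participant carries one fixed UTC offset; daylight-saving is
ignored), and the amplitude is the CRHR at that crossing minus the CRHR at
the cycle's starting trough. Cycles with no interior zero-phase crossing
or negative amplitude (possible only for pathological phase estimates)
are dropped with a log message.

## Intraindividual summaries

Within each run, consecutive blocks of exactly 7 cycles form segments;
trailing partial blocks are discarded and segments never span runs. The
fixed segment size keeps the per-segment sample size constant so that
recording-length differences between participants cannot bias the SD.
Period and amplitude use the arithmetic mean and sample SD (n-1).
Acrophase lives on the 24-h circle: the segment statistic is the circular
mean and the sample SD of signed minimal deviations from it (each in
(-720, 720]) — a peak drifting across midnight (1435 min, then 5 min)
otherwise produces an absurd ~700-min "SD". A naive linear mode is
retained for sensitivity analysis. The participant summary is the
unweighted mean of segment means (circular for acrophase) and of segment
SDs.

Segments fully inside the diary span are labelled seizure-containing
(>= 1 event in the half-open span [start, end)) or seizure-free; others
are outside-diary and excluded from seizure analyses. Seizure frequency is
events-in-segments per segment (one segment = one week). The paired
analysis requires at least five segments of each label per participant.

## Cohort statistics

All p-values are two-sided and reported raw (uncorrected). The rank-sum
test enumerates the exact null (midranks, so ties are handled) for
combined n <= 12 and otherwise uses the normal approximation with tie and
continuity corrections; the signed-rank test drops zero differences,
enumerates sign patterns for n <= 15 non-zero differences, and
approximates beyond. The thresholds are implementation choices for
desk-scale exactness. Cohen's d uses the pooled SD (case minus control);
the paired d is mean difference over SD of differences. The subsampling
control redraws a fixed-size case subsample without replacement each
iteration (with replacement across iterations) against the full control
sample, seeded. Outlier removal z-scores each variability property across
the case cohort (sample SD) and removes participants with |z| > 3 in any
property; correlations between log10 seizure frequency and variability
are reported with Fisher-z 95% CIs.

One calibration subtlety: a null cohort built by literally duplicating the
control values into the case group makes the subsample strongly dependent
on the control sample and the procedure extremely conservative (measured
rejection ~0.002 at alpha 0.05). Calibration is therefore assessed with
independent same-distribution groups, where the aggregate rejection rate
over many cohorts is ~0.05 as it should be.

## Problem sizes and reproducibility

The validation suite and `scripts/acceptance.py` use 70-day recordings at
a 60-s generation interval, a 2-min working interval, 1.5-day SSA window,
rank 16; parameter recovery uses 20 participants per jitter level in the
tests and 8 in the acceptance script; the group contrast uses 30 + 30 in
the tests and 20 + 20 in the script; null calibration uses 1000 rank-sum
replicates and 200 x 50 subsampling iterations. All randomness flows from
explicit seeds (per-participant streams spawned via `SeedSequence`, so
adding a participant never perturbs another's draws), and every pipeline
run is byte-reproducible for a fixed configuration and seed.

## Known limitations

* Recovered variability has a noise floor at low true jitter (see band
  completion above); absolute values below ~35 min should be read as
  upper bounds under default noise settings.
* Acrophase variability is induced through the period drift; the generator
  cannot realize independent acrophase-vs-period jitter regimes.
* The amplitude estimate reads single interpolated CRHR values at two time
  points; it inherits the smoothing of the extraction but no explicit
  uncertainty.
* Mixed-effects weekday/weekend and seasonal models, alternative
  decomposition benchmarks, and real Fitbit export parsing are out of
  scope.
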