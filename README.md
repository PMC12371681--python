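# circavar

Quantifying the day-to-day (intraindividual) variability of the circadian
rhythm of heart rate (CRHR) from long-term wearable recordings.

Wrist wearables measure heart rate by photoplethysmography around the clock
for months at a time. Heart rate carries a strong ~24-h rhythm, and how much
that rhythm wanders from one day to the next — in *when* it peaks, *how
long* a cycle lasts, and *how strong* it is — is a candidate marker of
circadian disruption in conditions such as epilepsy. `circavar` implements
the full analysis chain for cohort studies of this kind, together with a
synthetic-data generator with cycle-level ground truth so that every stage
can be validated by parameter recovery.

## Method

For each participant's heart-rate series (nominally one sample per 5 s,
with gaps):

1. **Gap handling** — gaps shorter than 8 h are linearly interpolated; the
   series is split into *runs* at the remaining gaps; participants without
   a run longer than 7 days are excluded. Runs are downsampled by window
   means to a working resolution (default 1 min).
2. **Rhythm extraction** — each run is decomposed by singular spectrum
   analysis (SSA): lag-embedding into a Hankel trajectory matrix, truncated
   SVD, anti-diagonal averaging. Eigentriples are grouped by the central
   frequency of their reconstructions, and the group with period closest to
   24 h is selected as the CRHR; components within a band around it
   (frequency-modulation sidebands of a jittering rhythm) are folded in.
3. **Cycle metrics** — the Hilbert transform gives the analytic signal of
   the CRHR; its argument is the circadian phase (zero at the peak). Phase
   wraps mark the troughs, splitting the rhythm into daily cycles. Per
   cycle: *period* (trough-to-trough duration, min), *acrophase* (clock
   time of the zero-phase crossing, min-of-day), *amplitude* (peak minus
   preceding trough, bpm).
4. **Intraindividual summaries** — cycles are grouped into consecutive
   non-overlapping 7-cycle segments. With per-segment mean m_s and sample
   SD s_s of a property, the participant's *intraindividual average* is
   mean_s(m_s) and their *intraindividual variability* is mean_s(s_s).
   Acrophase dispersion is computed circularly (deviations from the
   circular mean on the 24-h clock face).
5. **Cohort statistics** — two-sided Wilcoxon rank-sum tests with Cohen's d
   for group contrasts (exact enumeration at small n, midranks for ties), a
   10 000-iteration random-subsampling control for unbalanced group sizes,
   Pearson correlation of variability with log10 seizure frequency
   (|z| > 3 outliers excluded), and paired Wilcoxon signed-rank tests of
   seizure-containing vs seizure-free segments.

## Worked example

Simulate one participant with known ground truth (70 days, day-to-day
period jitter of SD 60 min, realistic gaps and sensor noise) and run the
pipeline:

```python
from circavar import GeneratorConfig, generate_participant, inject_gaps
from circavar.pipeline import PipelineConfig, summarize_participant

cfg = GeneratorConfig(n_days=70, sampling_interval_s=60.0, period_sd=60.0,
                      gap_rate=0.3, seed=42)
series, truth = generate_participant(cfg, "demo")
gappy = inject_gaps(series, cfg)

analysis = PipelineConfig(working_interval_s=120.0, ssa_window_days=1.5,
                          ssa_rank=16)
summary, cycles, segments, report, _ = summarize_participant(gappy, analysis)
print(f"cycles extracted: {len(cycles)}; 7-day segments: {summary.n_segments}")
for p in ("period", "acrophase", "amplitude"):
    print(f"{p:9s}  average = {summary.averages[p]:7.1f}"
          f"   variability = {summary.variability[p]:5.1f}")
```

prints

```
cycles extracted: 65; 7-day segments: 9
period     average =  1441.0   variability =  44.2
acrophase  average =   913.9   variability =  41.8
amplitude  average =    19.3   variability =   2.3
```

The average period is ~1440 min (one day), the rhythm peaks around minute
914 of the day (~15:14, the generator's anchor is 15:00), and the cycle
amplitude averages ~19 bpm (the generator's peak-trough amplitude is
2 x 10 bpm). The intraindividual period variability of 44.2 min recovers
this recording's realized segment-level truth of 47.3 min.

A `circavar` command-line tool wraps the same machinery
(`circavar simulate | analyze | run-all | compare`); see `circavar --help`.

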