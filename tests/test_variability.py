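"""Segmenting, circular acrophase statistics, summaries, seizure labelling."""

import numpy as np
import pytest

from circavar.cycles import Cycle
from circavar.synthetic import SeizureDiary
from circavar.variability import (
    Segment,
    circular_mean_minutes,
    intraindividual_summary,
    label_segments,
    segment_cycles,
    segment_stats,
    seizure_frequency,
    split_summary_by_label,
)

DAY = 86400.0


def make_cycles(n, run_start=0.0, period=1440.0, acrophase=600.0, amplitude=10.0,
                pid="P"):
    out = []
    t = run_start
    for i in range(n):
        p = period[i] if np.ndim(period) else period
        a = acrophase[i] if np.ndim(acrophase) else acrophase
        amp = amplitude[i] if np.ndim(amplitude) else amplitude
        out.append(
            Cycle(
                participant_id=pid,
                run_start=run_start,
                start_time=t,
                end_time=t + p * 60.0,
                period_min=p,
                acrophase_min=a,
                amplitude_bpm=amp,
            )
        )
        t += p * 60.0
    return out


class TestSegmenting:
    def test_sixteen_cycles_two_segments(self):
        segs = segment_cycles(make_cycles(16))
        assert len(segs) == 2
        assert all(len(s.cycles) == 7 for s in segs)

    def test_segments_never_span_runs(self):
        cycles = make_cycles(10, run_start=0.0) + make_cycles(
            10, run_start=30 * DAY
        )
        segs = segment_cycles(cycles)
        assert len(segs) == 2

    def test_too_few_cycles_no_segment(self):
        assert segment_cycles(make_cycles(6)) == []


class TestSegmentStats:
    def test_identical_cycles_zero_sd(self):
        means, sds = segment_stats(make_cycles(7))
        assert all(v == 0 for v in sds.values())
        assert means["period"] == 1440.0
        assert means["acrophase"] == pytest.approx(600.0)

    def test_acrophase_near_midnight_uses_circular_dispersion(self):
        acros = [1430.0, 10, 1435, 5, 1425, 15, 0]
        means, sds = segment_stats(make_cycles(7, acrophase=np.array(acros)))
        # brute-force circular oracle: mean 0, sample SD of minimal
        # deviations 10.80 min -- NOT the naive linear SD (~760 min)
        assert min(means["acrophase"], 1440 - means["acrophase"]) < 1e-6
        assert sds["acrophase"] == pytest.approx(10.8012344973, abs=1e-6)
        _, naive = segment_stats(
            make_cycles(7, acrophase=np.array(acros)), circular_acrophase=False
        )
        assert naive["acrophase"] > 700

    def test_period_sample_sd_matches_hand_formula(self):
        periods = np.array([1440.0, 1500, 1440, 1500, 1440, 1500, 1440])
        _, sds = segment_stats(make_cycles(7, period=periods))
        assert sds["period"] == pytest.approx(periods.std(ddof=1))
        assert sds["period"] == pytest.approx(32.0713490295, abs=1e-6)


class TestIntraindividualSummary:
    def test_figure_worked_example(self):
        """Segment acrophase SDs of 34 and 59 min average to 46.5 min."""
        segs = []
        for i, sd in enumerate([34.0, 59.0]):
            # seven values with sample SD exactly sd: m, m +/- sd (x3)
            acros = 600.0 + sd * np.array([-1, 1, -1, 1, -1, 1, 0])
            segs.extend(
                segment_cycles(make_cycles(7, run_start=i * 10 * DAY,
                                           acrophase=acros))
            )
        summary = intraindividual_summary(segs)
        assert summary.variability["acrophase"] == pytest.approx(46.5)

    def test_single_segment_variability_is_its_sd(self):
        periods = 1440 + np.array([-3.0, 3, -3, 3, -3, 3, 0])
        segs = segment_cycles(make_cycles(7, period=periods))
        summary = intraindividual_summary(segs)
        assert summary.variability["period"] == pytest.approx(3.0)

    def test_identical_cycles_zero_variability(self):
        summary = intraindividual_summary(segment_cycles(make_cycles(21)))
        assert all(v == pytest.approx(0) for v in summary.variability.values())

    def test_zero_segments_rejected(self):
        with pytest.raises(ValueError):
            intraindividual_summary([])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        periods = 1440 + rng.normal(0, 30, 21)
        segs = segment_cycles(make_cycles(21, period=periods))
        s1 = intraindividual_summary(segs)
        s2 = intraindividual_summary(segs[::-1])
        assert s1.variability == s2.variability
        assert s1.averages == s2.averages

    def test_constant_offset_invariance_of_period_variability(self):
        rng = np.random.default_rng(2)
        jitter = rng.normal(0, 20, 14)
        a = intraindividual_summary(
            segment_cycles(make_cycles(14, period=1440 + jitter))
        )
        b = intraindividual_summary(
            segment_cycles(make_cycles(14, period=1500 + jitter))
        )
        assert a.variability["period"] == pytest.approx(b.variability["period"])

    def test_clock_shift_invariance_of_acrophase_variability(self):
        rng = np.random.default_rng(3)
        acro = (600 + rng.normal(0, 40, 14)) % 1440
        a = intraindividual_summary(segment_cycles(make_cycles(14, acrophase=acro)))
        b = intraindividual_summary(
            segment_cycles(make_cycles(14, acrophase=(acro + 300) % 1440))
        )
        assert a.variability["acrophase"] == pytest.approx(
            b.variability["acrophase"], abs=1e-9
        )
        shift = (b.averages["acrophase"] - a.averages["acrophase"]) % 1440
        assert shift == pytest.approx(300.0, abs=1e-6)

    def test_summary_stable_in_recording_length(self):
        # stationary generator: 10 vs 40 segments differ only by sampling error
        rng = np.random.default_rng(4)
        periods = 1440 + rng.normal(0, 60, 7 * 40)
        segs = segment_cycles(make_cycles(7 * 40, period=periods))
        short = intraindividual_summary(segs[:10])
        full = intraindividual_summary(segs)
        assert short.variability["period"] == pytest.approx(
            full.variability["period"], rel=0.15
        )


def labelled_segments(n_seg, events, span):
    segs = segment_cycles(make_cycles(7 * n_seg))
    diary = SeizureDiary("P", np.array(events, dtype=float), span)
    return label_segments(segs, diary), diary


class TestSeizureLabelling:
    def test_event_at_segment_start_counts_in_that_segment(self):
        segs, _ = labelled_segments(3, [7 * DAY], (0.0, 21 * DAY))
        assert [s.seizure_label for s in segs] == ["free", "containing", "free"]

    def test_event_at_segment_end_counts_in_next(self):
        segs, _ = labelled_segments(3, [14 * DAY], (0.0, 21 * DAY))
        assert segs[1].seizure_label == "free"
        assert segs[2].seizure_label == "containing"

    def test_empty_diary_with_span_all_free(self):
        segs, _ = labelled_segments(3, [], (0.0, 21 * DAY))
        assert all(s.seizure_label == "free" for s in segs)

    def test_segments_outside_span_excluded(self):
        segs, _ = labelled_segments(3, [1 * DAY], (0.0, 10 * DAY))
        assert segs[0].seizure_label == "containing"
        assert segs[1].seizure_label == "outside-diary"
        assert segs[2].seizure_label == "outside-diary"

    def test_missing_diary_all_outside(self):
        segs = label_segments(segment_cycles(make_cycles(14)), None)
        assert all(s.seizure_label == "outside-diary" for s in segs)


class TestSeizureFrequency:
    def test_six_events_three_segments(self):
        events = [1 * DAY, 2 * DAY, 8 * DAY, 9 * DAY, 15 * DAY, 16 * DAY]
        segs, diary = labelled_segments(3, events, (0.0, 21 * DAY))
        assert seizure_frequency(segs, diary) == pytest.approx(2.0)

    def test_zero_events_zero_frequency(self):
        segs, diary = labelled_segments(3, [], (0.0, 21 * DAY))
        assert seizure_frequency(segs, diary) == 0.0

    def test_events_in_discarded_partial_week_not_counted(self):
        # 16 cycles -> 2 segments; an event in the dropped 2-cycle tail
        segs = segment_cycles(make_cycles(16))
        diary = SeizureDiary("P", np.array([15.5 * DAY]), (0.0, 16 * DAY))
        label_segments(segs, diary)
        assert seizure_frequency(segs, diary) == 0.0

    def test_no_in_span_segment_undefined(self):
        segs, diary = labelled_segments(2, [], (100 * DAY, 110 * DAY))
        assert seizure_frequency(segs, diary) is None


class TestSplitByLabel:
    def test_balanced_identical_segments_give_equal_summaries(self):
        segs, diary = labelled_segments(
            10, [i * 7 * DAY + DAY for i in range(0, 10, 2)], (0.0, 70 * DAY)
        )
        pair = split_summary_by_label(segs)
        assert pair is not None
        containing, free = pair
        assert containing.n_segments == 5
        assert free.n_segments == 5
        assert containing.variability == free.variability

    def test_insufficient_label_count_excluded(self):
        segs, diary = labelled_segments(
            24, [i * 7 * DAY + DAY for i in range(4)], (0.0, 24 * 7 * DAY)
        )
        assert split_summary_by_label(segs) is None


class TestCircularMean:
    def test_wraps_midnight(self):
        assert circular_mean_minutes(np.array([1430.0, 10.0])) == pytest.approx(
            0.0, abs=1e-9
        ) or circular_mean_minutes(np.array([1430.0, 10.0])) == pytest.approx(
            1440.0, abs=1e-9
        )

    def test_plain_average_far_from_wrap(self):
        assert circular_mean_minutes(np.array([500.0, 700.0])) == pytest.approx(600.0)
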