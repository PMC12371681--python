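"""Cohort-level statistics: group comparisons, subsampling, correlations.

All tests are nonparametric and reported raw (no multiple-comparison
correction).  Group comparisons use the two-sided Wilcoxon rank-sum
(Mann-Whitney) test with Cohen's d (pooled SD) as the effect size; paired
seizure-segment comparisons use the two-sided Wilcoxon signed-rank test
with a paired d (mean difference over SD of differences).  Because group
sizes in this design are badly imbalanced (many more cases than controls),
a subsampling control repeatedly compares the whole control sample to a
random case subsample of fixed size.

Small samples get exact null distributions (full enumeration with midranks,
so ties are handled correctly); larger samples use the normal approximation
with tie correction and continuity correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .variability import PROPERTIES, ParticipantSummary

__all__ = [
    "GroupComparison",
    "SubsampleResult",
    "cohens_d",
    "paired_cohens_d",
    "ranksum_test",
    "signed_rank_test",
    "subsample_comparison",
    "exclude_outliers",
    "seizure_frequency_correlation",
    "paired_seizure_test",
    "compare_groups",
]

logger = logging.getLogger(__name__)

EXACT_RANKSUM_N = 12  # combined n at or below which rank-sum is exact
EXACT_SIGNRANK_N = 15  # non-zero differences at or below which signed-rank is exact
ALPHA = 0.05


# ---------------------------------------------------------------- effect sizes

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled SD; sign is mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        logger.warning("zero pooled SD; Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def paired_cohens_d(diff: np.ndarray) -> float:
    """Paired Cohen's d: mean difference over the SD of differences."""
    diff = np.asarray(diff, dtype=float)
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diff.mean() / sd)


# ------------------------------------------------------------------ rank tests

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def ranksum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U statistic of the first sample, two-sided p).  Exact null by
    full enumeration of group assignments (midranks, so ties are fine) when
    the combined n is at most 12; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 1 or nb < 1:
        raise ValueError("each group needs at least one value")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    if na + nb <= EXACT_RANKSUM_N:
        mu = na * nb / 2.0
        n_tot = na + nb
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_tot), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def signed_rank_test(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical Wilcoxon convention).  Exact
    null by enumeration of all sign assignments (midranks on |diff|) for up
    to 15 non-zero differences; otherwise normal approximation with tie
    correction.  Returns (W+ statistic, two-sided p); all-zero differences
    give (0, 1).
    """
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return 0.0, 1.0
    ranks = _midranks(np.abs(diff))
    w_obs = float(ranks[diff > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_SIGNRANK_N:
        count = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
        return w_obs, count / total
    res = sps.wilcoxon(diff, alternative="two-sided", method="approx",
                       correction=True)
    return w_obs, float(res.pvalue)


# ------------------------------------------------------------------ containers

@dataclass
class GroupComparison:
    """One property x measure comparison between the two groups."""

    property_name: str
    measure: str  # "average" | "variability"
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    cohens_d: float

    def to_dict(self) -> dict:
        return {
            "property": self.property_name,
            "measure": self.measure,
            "n_pwe": self.n_a,
            "n_control": self.n_b,
            "median_pwe": self.median_a,
            "median_control": self.median_b,
            "ranksum_statistic": self.statistic,
            "p_value": self.p_value,
            "cohens_d": self.cohens_d,
        }


@dataclass
class SubsampleResult:
    """Outcome of the repeated-subsampling control for imbalanced groups."""

    iterations: int
    n_sub: int
    p_values: np.ndarray
    d_values: np.ndarray
    alpha: float = ALPHA

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < self.alpha))

    @property
    def median_d(self) -> float:
        return float(np.median(self.d_values))

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "n_sub": self.n_sub,
            "fraction_significant": self.fraction_significant,
            "median_d": self.median_d,
        }


# ------------------------------------------------------------------ procedures

def subsample_comparison(
    pwe: np.ndarray,
    ctrl: np.ndarray,
    n_sub: int = 28,
    iterations: int = 10_000,
    seed: int = 0,
) -> SubsampleResult:
    """Compare all controls to repeated random case subsamples.

    Each iteration draws ``n_sub`` cases without replacement (with
    replacement across iterations) and runs the rank-sum test and Cohen's d
    against the full control sample.  Reproducible given the seed.
    """
    pwe = np.asarray(pwe, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if pwe.size < n_sub:
        raise ValueError("case sample smaller than the requested subsample")
    rng = np.random.default_rng(seed)
    ps = np.empty(iterations)
    ds = np.empty(iterations)
    for i in range(iterations):
        sub = rng.choice(pwe, size=n_sub, replace=False)
        _, ps[i] = ranksum_test(sub, ctrl)
        ds[i] = cohens_d(sub, ctrl)
    return SubsampleResult(iterations=iterations, n_sub=n_sub,
                           p_values=ps, d_values=ds)


def exclude_outliers(
    values: np.ndarray, z_threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusion mask over participants from per-property z-scores.

    ``values`` is (participants x properties); a participant is excluded
    when any property's |z| exceeds ``z_threshold``.  Returns (mask, z)
    where mask is True for retained participants.  A zero-SD property
    excludes nobody (warning logged).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least three participants for z-scores")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    z = np.zeros_like(values)
    for j in range(values.shape[1]):
        if sd[j] == 0:
            logger.warning("property %d has zero SD; no exclusions from it", j)
            continue
        z[:, j] = (values[:, j] - mean[j]) / sd[j]
    mask = ~np.any(np.abs(z) > z_threshold, axis=1)
    return mask, z


def seizure_frequency_correlation(
    summaries: list[ParticipantSummary],
    z_threshold: float = 3.0,
) -> dict[str, dict]:
    """Pearson r between log10 seizure frequency and each variability.

    Participants without any recorded seizures, without a defined seizure
    frequency, or with outlying variability (|z| > 3 in any property, over
    the remaining case cohort) are removed first.  Reports two-sided p and
    the Fisher-z 95% CI per property.
    """
    cands = [
        s
        for s in summaries
        if s.seizure_frequency is not None and s.seizure_frequency > 0
    ]
    if len(cands) < 3:
        raise ValueError("need at least three participants with seizures")
    var_matrix = np.array(
        [[s.variability[p] for p in PROPERTIES] for s in cands]
    )
    mask, _ = exclude_outliers(var_matrix, z_threshold)
    kept = [s for s, m in zip(cands, mask) if m]
    if len(kept) < 3:
        raise ValueError("fewer than three participants after outlier removal")
    logf = np.log10([s.seizure_frequency for s in kept])
    out: dict[str, dict] = {}
    for prop in PROPERTIES:
        y = np.array([s.variability[prop] for s in kept])
        r, p = sps.pearsonr(logf, y)
        n = logf.size
        if n > 3 and abs(r) < 1:
            zf = np.arctanh(r)
            half = 1.959963984540054 / np.sqrt(n - 3)
            ci = (float(np.tanh(zf - half)), float(np.tanh(zf + half)))
        else:
            ci = (float("nan"), float("nan"))
        out[prop] = {"r": float(r), "p": float(p), "ci95": ci, "n": int(n)}
    return out


def paired_seizure_test(
    pairs: list[tuple[ParticipantSummary, ParticipantSummary]],
) -> dict[str, dict]:
    """Signed-rank comparison of seizure-containing vs seizure-free summaries.

    ``pairs`` holds per-participant (containing, free) summaries.  For each
    property and measure the paired differences (containing minus free) are
    tested two-sided with the signed-rank test; a paired Cohen's d is
    reported alongside.
    """
    if not pairs:
        raise ValueError("no participants eligible for the paired analysis")
    out: dict[str, dict] = {}
    for measure in ("average", "variability"):
        for prop in PROPERTIES:
            diffs = np.array(
                [
                    getattr(c, "averages" if measure == "average" else "variability")[prop]
                    - getattr(f, "averages" if measure == "average" else "variability")[prop]
                    for c, f in pairs
                ]
            )
            w, p = signed_rank_test(diffs)
            out[f"{measure}_{prop}"] = {
                "statistic": float(w),
                "p": float(p),
                "d": paired_cohens_d(diffs) if diffs.size > 1 else 0.0,
                "n": int(diffs.size),
            }
    return out


def compare_groups(
    summaries_a: list[ParticipantSummary],
    summaries_b: list[ParticipantSummary],
) -> list[GroupComparison]:
    """Rank-sum + Cohen's d for every property x measure, a minus b."""
    out: list[GroupComparison] = []
    for measure in ("average", "variability"):
        attr = "averages" if measure == "average" else "variability"
        for prop in PROPERTIES:
            a = np.array([getattr(s, attr)[prop] for s in summaries_a])
            b = np.array([getattr(s, attr)[prop] for s in summaries_b])
            stat, p = ranksum_test(a, b)
            out.append(
                GroupComparison(
                    property_name=prop,
                    measure=measure,
                    n_a=a.size,
                    n_b=b.size,
                    median_a=float(np.median(a)),
                    median_b=float(np.median(b)),
                    statistic=stat,
                    p_value=p,
                    cohens_d=cohens_d(a, b),
                )
            )
    return out
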