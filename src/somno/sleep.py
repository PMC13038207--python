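"""Sleep bout detection, architecture metrics, rebound, and group comparisons.

Fly sleep is scored behaviourally: a sleep bout is a maximal run of
consecutive zero-activity bins lasting at least ``min_inactive_min`` minutes
(field convention, default 5).  Bouts spanning the ZT0 (lights-on) or ZT12
(lights-off) boundary are split, each fragment contributing sleep time and
one bout to its own period; this keeps the light-period (LP) and dark-period
(DP) totals summing exactly to the 24-h total.  Missing bins break
inactivity runs so recording gaps never fabricate sleep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ActivityTrace, logger

HALF_DAY_MIN = 720
DAY_MIN = 1440

#: Shapiro-Wilk significance level of the normality gate that chooses
#: between the unpaired t test and the Mann-Whitney U test.
NORMALITY_ALPHA = 0.05


@dataclass
class SleepBout:
    """One (possibly boundary-split) sleep episode in ZT minutes."""

    onset_min: int
    duration_min: int
    period: str  # "LP" or "DP"


@dataclass
class SleepMetrics:
    """Per-fly sleep architecture, averaged across whole days.

    Totals and bout counts are per-day averages; ``lp_mean_bout_min`` is the
    mean duration of all LP bouts pooled over days.  Latencies are minutes
    from lights-on (ZT0) or lights-off (ZT12) to the first bout onset in
    that period, averaged over days where defined, and NaN when the period
    never contains sleep.
    """

    fly_id: str
    n_days: int
    lp_total_sleep_min: float
    lp_n_bouts: float
    lp_mean_bout_min: float
    dp_total_sleep_min: float
    dp_n_bouts: float
    dp_mean_bout_min: float
    latency_on_min: float
    latency_off_min: float

    @property
    def total_sleep_min(self) -> float:
        return self.lp_total_sleep_min + self.dp_total_sleep_min


@dataclass
class GroupComparison:
    """Two-group test on one metric with Bonferroni-corrected p value."""

    metric: str
    case_mean: float
    control_mean: float
    test: str  # t_unpaired | mann_whitney | t_paired
    statistic: float
    p_raw: float
    p_bonferroni: float
    n_tests: int
    percent_change: float  # 100 * (control - case) / control
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Bout detection
# ---------------------------------------------------------------------------

def _split_at_boundaries(onset: int, duration: int) -> list[tuple[int, int]]:
    """Split [onset, onset+duration) at every multiple of 720 ZT minutes."""
    pieces = []
    start, end = onset, onset + duration
    while start < end:
        next_boundary = (math.floor(start / HALF_DAY_MIN) + 1) * HALF_DAY_MIN
        stop = min(end, next_boundary)
        pieces.append((start, stop - start))
        start = stop
    return pieces


def _period_of(zt_onset: int) -> str:
    return "LP" if (zt_onset % DAY_MIN) < HALF_DAY_MIN else "DP"


def detect_sleep(trace: ActivityTrace, min_inactive_min: int = 5) -> list[SleepBout]:
    """Detect sleep bouts as maximal zero-activity runs of sufficient length.

    Returns boundary-split bouts ordered by onset.  A trace shorter than one
    threshold window yields an empty list with a warning.
    """
    if min_inactive_min % trace.bin_minutes != 0:
        raise ValueError(
            f"bin_minutes={trace.bin_minutes} does not divide "
            f"min_inactive_min={min_inactive_min}"
        )
    min_bins = min_inactive_min // trace.bin_minutes
    if trace.n_bins < min_bins:
        logger.warning(
            "trace %s shorter than one %d-min window; no bouts detectable",
            trace.fly_id, min_inactive_min,
        )
        return []

    inactive = (trace.counts == 0) & ~trace.missing
    bouts: list[SleepBout] = []
    # maximal runs of inactive bins
    padded = np.concatenate(([False], inactive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_bins:
            continue
        onset = trace.zt_min(int(start))
        duration = int(end - start) * trace.bin_minutes
        for frag_onset, frag_dur in _split_at_boundaries(onset, duration):
            bouts.append(SleepBout(frag_onset, frag_dur, _period_of(frag_onset)))
    return bouts


# ---------------------------------------------------------------------------
# Architecture metrics
# ---------------------------------------------------------------------------

def architecture_metrics(bouts: Sequence[SleepBout], trace: ActivityTrace) -> SleepMetrics:
    """Summarise bouts into per-period sleep architecture for one fly.

    Only whole recorded days are used; metrics are per-day averages.
    """
    n_days = (trace.n_bins * trace.bin_minutes) // DAY_MIN
    if n_days == 0:
        raise ValueError(f"trace {trace.fly_id} shorter than one full day")
    span = n_days * DAY_MIN
    kept = [b for b in bouts if 0 <= b.onset_min < span]

    per_period: dict[str, list[SleepBout]] = {"LP": [], "DP": []}
    for b in kept:
        per_period[b.period].append(b)

    def _totals(period: str) -> tuple[float, float, float]:
        bs = per_period[period]
        total = sum(b.duration_min for b in bs) / n_days
        n = len(bs) / n_days
        mean = float(np.mean([b.duration_min for b in bs])) if bs else float("nan")
        return total, n, mean

    lp_total, lp_n, lp_mean = _totals("LP")
    dp_total, dp_n, dp_mean = _totals("DP")

    lat_on, lat_off = [], []
    for d in range(n_days):
        lp0, dp0 = d * DAY_MIN, d * DAY_MIN + HALF_DAY_MIN
        lp_onsets = [b.onset_min - lp0 for b in per_period["LP"] if lp0 <= b.onset_min < dp0]
        dp_onsets = [b.onset_min - dp0 for b in per_period["DP"] if dp0 <= b.onset_min < lp0 + DAY_MIN]
        if lp_onsets:
            lat_on.append(min(lp_onsets))
        if dp_onsets:
            lat_off.append(min(dp_onsets))

    return SleepMetrics(
        fly_id=trace.fly_id,
        n_days=n_days,
        lp_total_sleep_min=lp_total,
        lp_n_bouts=lp_n,
        lp_mean_bout_min=lp_mean,
        dp_total_sleep_min=dp_total,
        dp_n_bouts=dp_n,
        dp_mean_bout_min=dp_mean,
        latency_on_min=float(np.mean(lat_on)) if lat_on else float("nan"),
        latency_off_min=float(np.mean(lat_off)) if lat_off else float("nan"),
    )


def viability_filter(
    traces: Sequence[ActivityTrace], dead_window_h: float = 6.0
) -> tuple[list[ActivityTrace], list[str]]:
    """Drop flies with zero activity throughout the final window (dead flies)."""
    kept, dropped = [], []
    for tr in traces:
        window_bins = int(round(dead_window_h * 60 / tr.bin_minutes))
        if tr.n_bins < window_bins:
            raise ValueError(f"trace {tr.fly_id} shorter than dead window")
        if (tr.counts[-window_bins:] == 0).all():
            dropped.append(tr.fly_id)
        else:
            kept.append(tr)
    if dropped:
        logger.info("viability filter dropped %d flies: %s", len(dropped), dropped)
    return kept, dropped


def sleep_profile(
    traces: Sequence[ActivityTrace],
    bin_min: int = 30,
    min_inactive_min: int = 5,
):
    """Mean +/- SEM fraction of time asleep per ZT bin across a group.

    Days are folded onto one 24-h cycle before averaging, so the profile
    mean over bins times 1440 equals the group's mean total daily sleep.
    Returns a DataFrame with columns ``zt_min``, ``mean``, ``sem``.
    """
    import pandas as pd

    if not traces:
        raise ValueError("sleep_profile needs at least one trace")
    if DAY_MIN % bin_min != 0:
        raise ValueError(f"bin_min={bin_min} does not divide 1440")
    n_bins = DAY_MIN // bin_min

    per_fly = []
    for tr in traces:
        n_days = (tr.n_bins * tr.bin_minutes) // DAY_MIN
        asleep = np.zeros(n_days * DAY_MIN, dtype=bool)
        for b in detect_sleep(tr, min_inactive_min):
            if 0 <= b.onset_min and b.onset_min + b.duration_min <= asleep.size:
                asleep[b.onset_min:b.onset_min + b.duration_min] = True
        folded = asleep.reshape(n_days, DAY_MIN).mean(axis=0)
        per_fly.append(folded.reshape(n_bins, bin_min).mean(axis=1))

    arr = np.vstack(per_fly)
    return pd.DataFrame(
        {
            "zt_min": np.arange(n_bins) * bin_min,
            "mean": arr.mean(axis=0),
            "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(n_bins),
        }
    )


# ---------------------------------------------------------------------------
# Rebound after sleep deprivation
# ---------------------------------------------------------------------------

@dataclass
class ReboundResult:
    """Paired early-morning (ZT0-3) rebound test after overnight deprivation."""

    comparison: GroupComparison
    mean_gain_min: float
    percent_sleep_lost: float | None = None


def rebound_analysis(
    baseline_zt0_3: Mapping[str, float],
    deprived_zt0_3: Mapping[str, float],
    baseline_night: Mapping[str, float] | None = None,
    deprivation_night: Mapping[str, float] | None = None,
) -> ReboundResult:
    """Paired t test on ZT0-3 total sleep, baseline vs. post-deprivation.

    Both mappings are ``fly_id -> minutes of sleep during ZT0-3`` and must
    cover identical flies.  If night-time (ZT12-24) totals for the baseline
    and deprivation nights are supplied, the overnight percent sleep lost is
    reported alongside.
    """
    ids = sorted(baseline_zt0_3)
    if set(ids) != set(deprived_zt0_3):
        raise ValueError("baseline and deprived arms must cover identical fly_ids")
    base = np.array([baseline_zt0_3[i] for i in ids], dtype=float)
    post = np.array([deprived_zt0_3[i] for i in ids], dtype=float)
    diffs = post - base
    mean_gain = float(diffs.mean())

    degenerate = bool(np.allclose(diffs, diffs[0]))
    if degenerate and np.isclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        t_stat, p = float("nan"), 1.0
    else:
        t_stat, p = stats.ttest_rel(post, base)
        t_stat, p = float(t_stat), float(p)
        degenerate = False

    comp = GroupComparison(
        metric="zt0_3_total_sleep_min",
        case_mean=float(post.mean()),
        control_mean=float(base.mean()),
        test="t_paired",
        statistic=t_stat,
        p_raw=p,
        p_bonferroni=min(1.0, p),
        n_tests=1,
        percent_change=_percent_change(float(post.mean()), float(base.mean())),
        degenerate=degenerate,
    )

    pct_lost = None
    if baseline_night is not None and deprivation_night is not None:
        b = np.array([baseline_night[i] for i in ids], dtype=float)
        d = np.array([deprivation_night[i] for i in ids], dtype=float)
        pct_lost = float(100.0 * (b.mean() - d.mean()) / b.mean()) if b.mean() > 0 else float("nan")
    return ReboundResult(comparison=comp, mean_gain_min=mean_gain, percent_sleep_lost=pct_lost)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _percent_change(case_mean: float, control_mean: float) -> float:
    if control_mean == 0:
        return float("nan")
    return 100.0 * (control_mean - case_mean) / control_mean


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.allclose(values, values[0]):
        return False
    return stats.shapiro(values).pvalue >= NORMALITY_ALPHA


def compare_groups(
    case: Sequence[float],
    control: Sequence[float],
    metric: str,
    n_tests: int = 1,
) -> GroupComparison:
    """Two-tailed unpaired comparison with a Shapiro-Wilk normality gate.

    Both groups Gaussian (Shapiro-Wilk p >= 0.05) -> unpaired t test;
    otherwise Mann-Whitney U.  Bonferroni correction multiplies the raw p by
    ``n_tests`` (clipped at 1).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 flies per group")

    degenerate = bool(
        np.allclose(case, case[0]) and np.allclose(control, control[0])
        and np.isclose(case[0], control[0])
    )
    if degenerate:
        test, statistic, p = "mann_whitney", float("nan"), 1.0
    elif _is_normal(case) and _is_normal(control):
        res = stats.ttest_ind(case, control)
        test, statistic, p = "t_unpaired", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(case, control, alternative="two-sided")
        test, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)

    return GroupComparison(
        metric=metric,
        case_mean=float(case.mean()),
        control_mean=float(control.mean()),
        test=test,
        statistic=statistic,
        p_raw=p,
        p_bonferroni=min(1.0, p * n_tests),
        n_tests=n_tests,
        percent_change=_percent_change(float(case.mean()), float(control.mean())),
        degenerate=degenerate,
    )


def compare_sleep_groups(
    case_metrics: Sequence[SleepMetrics],
    control_metrics: Sequence[SleepMetrics],
    metric_names: Sequence[str] = (
        "lp_total_sleep_min",
        "dp_total_sleep_min",
        "lp_mean_bout_min",
        "dp_mean_bout_min",
        "lp_n_bouts",
        "dp_n_bouts",
    ),
    n_tests: int | None = None,
) -> list[GroupComparison]:
    """Compare per-fly sleep metrics between a case and a control genotype.

    ``n_tests`` defaults to the number of metrics compared, matching a
    Bonferroni correction for the tests performed per genotype.
    """
    if n_tests is None:
        n_tests = len(metric_names)
    out = []
    for name in metric_names:
        case = [getattr(m, name) for m in case_metrics]
        control = [getattr(m, name) for m in control_metrics]
        out.append(compare_groups(case, control, metric=name, n_tests=n_tests))
    return out
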