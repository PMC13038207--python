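"""Free-running rest/activity rhythm analysis in constant darkness.

The rhythmicity index (RI) is the height of the autocorrelogram at its
highest local maximum inside a circadian lag window (default 18-30 h); a
self-sustained ~24-h rhythm produces a pronounced peak near lag 24 h, while
arrhythmic activity decays into the white-noise band.  The rhythmicity
statistic RS = RI / (2/sqrt(N)) normalises the peak by the approximate 95%
confidence band of white-noise autocorrelation, so RS ~ 1 marks the edge of
chance-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import argrelmax

from .io_formats import ActivityTrace
from .sleep import GroupComparison, compare_groups

#: (rhythmic, weakly rhythmic) RS thresholds; below the lower one the fly is
#: classified arrhythmic.
DEFAULT_RS_THRESHOLDS = (1.5, 1.0)


@dataclass
class RhythmResult:
    """Per-fly rhythmicity: autocorrelation peak, normalised statistic, label."""

    fly_id: str
    ri: float
    rs: float
    label: str  # rhythmic | weakly_rhythmic | arrhythmic
    peak_lag_min: float
    no_peak: bool = False


def autocorrelogram(
    trace: ActivityTrace, max_lag_h: float = 72.0
) -> tuple[np.ndarray, np.ndarray]:
    """Biased, mean-removed, variance-normalised autocorrelation of activity.

    Returns ``(lags_min, ac)`` for lags 0 .. max_lag_h.  The biased estimator
    divides every lag product sum by N, which shrinks values smoothly toward
    zero at long lags and keeps the sequence bounded by 1.
    """
    if trace.schedule != "DD":
        raise ValueError("autocorrelogram requires a constant-darkness (DD) trace")
    x = trace.counts.astype(float)
    n = x.size
    max_lag = int(round(max_lag_h * 60 / trace.bin_minutes))
    if n < 2 * max_lag:
        raise ValueError(
            f"trace length {n} bins is shorter than twice the maximum lag ({2 * max_lag})"
        )
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("constant signal: autocorrelation undefined")
    from scipy.signal import fftconvolve

    full = fftconvolve(x, x[::-1], mode="full")
    ac = full[n - 1 : n + max_lag] / denom
    lags = np.arange(max_lag + 1) * trace.bin_minutes
    return lags, ac


def rhythmicity_index(
    lags: np.ndarray,
    ac: np.ndarray,
    n_bins: int,
    search_window_h: tuple[float, float] = (18.0, 30.0),
    smooth_min: float = 60.0,
) -> tuple[float, float, float, bool]:
    """RI, RS, peak lag (min) and a no-peak flag from an autocorrelogram.

    RI is the autocorrelation at the highest local maximum inside the search
    window, evaluated on a correlogram smoothed with a ``smooth_min``-wide
    moving average.  Smoothing is what keeps the statistic calibrated: the
    maximum over a 12-h window of raw white-noise autocorrelations sits near
    3/sqrt(N) by selection alone, whereas a genuine circadian peak is hours
    wide and loses under 1% of its height to a 1-h average.  If no local
    maximum exists in the window, the window maximum is used and flagged.
    RS = RI / (2/sqrt(N)) with N the number of bins analysed.
    """
    lo, hi = (search_window_h[0] * 60, search_window_h[1] * 60)
    in_window = (lags >= lo) & (lags <= hi)
    if not in_window.any():
        raise ValueError("search window outside computed lag range")
    idx = np.flatnonzero(in_window)

    if smooth_min > 0 and lags.size > 1:
        step = float(lags[1] - lags[0])
        m = max(1, int(round(smooth_min / step)) | 1)  # odd width
        kernel = np.ones(m) / m
        ac = np.convolve(ac, kernel, mode="same")

    peaks = argrelmax(ac)[0]
    peaks = peaks[np.isin(peaks, idx)]
    if peaks.size:
        best = peaks[np.argmax(ac[peaks])]
        no_peak = False
    else:
        best = idx[np.argmax(ac[idx])]
        no_peak = True
    ri = float(ac[best])
    rs = ri / (2.0 / np.sqrt(n_bins))
    return ri, float(rs), float(lags[best]), no_peak


def classify_rhythmicity(
    rs: float, thresholds: tuple[float, float] = DEFAULT_RS_THRESHOLDS
) -> str:
    """Map the rhythmicity statistic to rhythmic / weakly_rhythmic / arrhythmic."""
    upper, lower = thresholds
    if not upper > lower:
        raise ValueError("thresholds must be strictly decreasing (upper, lower)")
    if rs >= upper:
        return "rhythmic"
    if rs >= lower:
        return "weakly_rhythmic"
    return "arrhythmic"


def analyze_rhythm(
    trace: ActivityTrace,
    max_lag_h: float = 72.0,
    search_window_h: tuple[float, float] = (18.0, 30.0),
    thresholds: tuple[float, float] = DEFAULT_RS_THRESHOLDS,
    skip_first_days: int = 0,
) -> RhythmResult:
    """Full per-fly pipeline: autocorrelogram -> RI/RS -> label.

    ``skip_first_days`` optionally drops the first days of constant darkness
    (transient after entrainment) before analysis.
    """
    if skip_first_days:
        start = skip_first_days * trace.bins_per_day
        trace = ActivityTrace(
            fly_id=trace.fly_id,
            genotype=trace.genotype,
            counts=trace.counts[start:],
            bin_minutes=trace.bin_minutes,
            schedule=trace.schedule,
            missing=trace.missing[start:],
        )
    lags, ac = autocorrelogram(trace, max_lag_h=max_lag_h)
    ri, rs, peak_lag, no_peak = rhythmicity_index(
        lags, ac, n_bins=trace.n_bins, search_window_h=search_window_h
    )
    return RhythmResult(
        fly_id=trace.fly_id,
        ri=ri,
        rs=rs,
        label=classify_rhythmicity(rs, thresholds),
        peak_lag_min=peak_lag,
        no_peak=no_peak,
    )


def cohort_rhythmicity(
    results_by_group: Mapping[str, Sequence[RhythmResult]],
) -> tuple[dict[str, dict[str, float]], GroupComparison | None]:
    """Per-group label percentages plus a two-group RI comparison.

    Percentages sum to 100 within each group.  When exactly two groups are
    given, their RI distributions are compared with a two-tailed unpaired t
    test (first group treated as case); otherwise the comparison is None.
    """
    labels = ("rhythmic", "weakly_rhythmic", "arrhythmic")
    percents: dict[str, dict[str, float]] = {}
    for group, results in results_by_group.items():
        n = len(results)
        if n == 0:
            raise ValueError(f"group {group!r} has no flies")
        percents[group] = {
            lab: 100.0 * sum(r.label == lab for r in results) / n for lab in labels
        }

    comparison = None
    if len(results_by_group) == 2:
        (g_case, case), (g_ctrl, ctrl) = results_by_group.items()
        from scipy import stats

        res = stats.ttest_ind([r.ri for r in case], [r.ri for r in ctrl])
        comparison = GroupComparison(
            metric="rhythmicity_index",
            case_mean=float(np.mean([r.ri for r in case])),
            control_mean=float(np.mean([r.ri for r in ctrl])),
            test="t_unpaired",
            statistic=float(res.statistic),
            p_raw=float(res.pvalue),
            p_bonferroni=float(res.pvalue),
            n_tests=1,
            percent_change=(
                100.0
                * (np.mean([r.ri for r in ctrl]) - np.mean([r.ri for r in case]))
                / np.mean([r.ri for r in ctrl])
                if np.mean([r.ri for r in ctrl]) != 0
                else float("nan")
            ),
        )
    return percents, comparison
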