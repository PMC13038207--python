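"""Clinical-side statistics: questionnaire prevalence, diary metrics, tests.

Sleep-diary scoring follows the standard decomposition of a night anchored
at the in-bed time: sleep onset latency (SOL) from in-bed to sleep onset,
wake after sleep onset (WASO) as the summed awakenings between onset and
the final wake, wake after sleep offset (WASF) from the final wake to
out-of-bed, and total sleep time (TST) as the onset-to-final-wake span
minus WASO.  These components partition time in bed exactly, so sleep
efficiency = 100 * TST / TIB.  Fixed clinical references implemented here:
SOL above 30 minutes, efficiency below 85%, and early waking defined as a
final wake before 05:00.  The ICSD-3 frequency rule flags a complaint as
disorder-level when it occurs at least 3 times per week.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

EARLY_WAKE_CUTOFF_MIN = 5 * 60  # 05:00
SOL_REFERENCE_MIN = 30.0
EFFICIENCY_REFERENCE_PCT = 85.0
ICSD3_TIMES_PER_WEEK = 3


# ---------------------------------------------------------------------------
# Prevalence and frequency flags
# ---------------------------------------------------------------------------

def prevalence(k: int, n: int) -> int:
    """Percent affected, rounded half away from zero (5/7 -> 71, 4/6 -> 67)."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= k <= n:
        raise ValueError("affected count must lie in [0, n]")
    return int(math.floor(100.0 * k / n + 0.5))


def icsd3_flag(times_per_week: float) -> bool:
    """True when a complaint reaches disorder-level frequency (>= 3 per week)."""
    if times_per_week < 0:
        raise ValueError("times_per_week must be non-negative")
    return times_per_week >= ICSD3_TIMES_PER_WEEK


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> tuple[float, str]:
    """Per-test significance threshold alpha / n_tests.

    Returns the full-precision value plus a 6-decimal display string
    (e.g. alpha = 0.05 over 33 tests -> "0.001515").
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    value = alpha / n_tests
    return value, f"{value:.6f}"


# ---------------------------------------------------------------------------
# Sleep diaries
# ---------------------------------------------------------------------------

def _parse_clock(t) -> int:
    """Clock time as minutes after midnight (accepts 'HH:MM' or minutes)."""
    if isinstance(t, str) and ":" in t:
        h, m = t.split(":")
        return int(h) * 60 + int(m)
    return int(t)


@dataclass
class DiaryRecord:
    """One night of a graphical sleep diary, in clock times.

    Times may be ``"HH:MM"`` strings or minutes after midnight.  The night
    is anchored at ``in_bed``: any time with a clock value earlier than
    in-bed is taken as next-day (a single midnight crossing).
    """

    individual_id: str
    night: str
    in_bed: int
    sleep_onset: int
    awakenings: list[tuple[int, int]]
    final_wake: int
    out_of_bed: int

    def __post_init__(self) -> None:
        self.in_bed = _parse_clock(self.in_bed)
        self.sleep_onset = _parse_clock(self.sleep_onset)
        self.final_wake = _parse_clock(self.final_wake)
        self.out_of_bed = _parse_clock(self.out_of_bed)
        self.awakenings = [
            (_parse_clock(a), _parse_clock(b)) for a, b in self.awakenings
        ]

    def _unrolled(self) -> tuple[int, int, list[tuple[int, int]], int, int]:
        """Times in minutes since in-bed, unrolling one midnight crossing."""
        anchor = self.in_bed

        def rel(t: int) -> int:
            return (t - anchor) % (24 * 60)

        onset = rel(self.sleep_onset)
        wake = rel(self.final_wake)
        out = rel(self.out_of_bed)
        intervals = [(rel(a), rel(b)) for a, b in self.awakenings]
        ordered = (
            0 <= onset <= wake <= out
            and all(onset < a <= b < wake for a, b in intervals)
            and all(
                b0 <= a1
                for (_, b0), (a1, _) in zip(sorted(intervals), sorted(intervals)[1:])
            )
        )
        if not ordered:
            raise ValueError(
                f"night {self.night} of {self.individual_id}: "
                "times violate in_bed <= onset <= awakenings <= final_wake <= out_of_bed"
            )
        return 0, onset, intervals, wake, out


@dataclass
class DiaryMetrics:
    """Scored night: components partition time in bed exactly."""

    individual_id: str
    night: str
    sol_min: float
    waso_min: float
    wasf_min: float
    tst_min: float
    tib_min: float
    efficiency_pct: float
    early_wake: bool
    sol_gt_30: bool
    efficiency_lt_85: bool


def diary_metrics(record: DiaryRecord) -> DiaryMetrics:
    """Score one diary night into SOL / WASO / WASF / TST / TIB / efficiency."""
    _, onset, intervals, wake, out = record._unrolled()
    sol = float(onset)
    waso = float(sum(b - a for a, b in intervals))
    wasf = float(out - wake)
    tst = float(wake - onset) - waso
    tib = float(out)
    eff = 100.0 * tst / tib if tib > 0 else float("nan")
    return DiaryMetrics(
        individual_id=record.individual_id,
        night=record.night,
        sol_min=sol,
        waso_min=waso,
        wasf_min=wasf,
        tst_min=tst,
        tib_min=tib,
        efficiency_pct=eff,
        early_wake=record.final_wake < EARLY_WAKE_CUTOFF_MIN,
        sol_gt_30=sol > SOL_REFERENCE_MIN,
        efficiency_lt_85=eff < EFFICIENCY_REFERENCE_PCT,
    )


def diary_summary(records: Sequence[DiaryRecord]) -> dict[str, dict]:
    """Per-individual medians across nights, plus reference flags.

    Nights that violate the ordering invariants are rejected individually
    (collected under ``"rejected"``) rather than failing the whole summary.
    Early-waking frequency is the fraction of scored nights with a final
    wake before 05:00.
    """
    per_individual: dict[str, list[DiaryMetrics]] = {}
    rejected: list[tuple[str, str, str]] = []
    for rec in records:
        try:
            m = diary_metrics(rec)
        except ValueError as exc:
            rejected.append((rec.individual_id, rec.night, str(exc)))
            continue
        per_individual.setdefault(rec.individual_id, []).append(m)

    out: dict[str, dict] = {}
    for ind, ms in sorted(per_individual.items()):
        med_sol = float(np.median([m.sol_min for m in ms]))
        med_eff = float(np.median([m.efficiency_pct for m in ms]))
        out[ind] = {
            "n_nights": len(ms),
            "median_sol_min": med_sol,
            "median_waso_min": float(np.median([m.waso_min for m in ms])),
            "median_wasf_min": float(np.median([m.wasf_min for m in ms])),
            "median_tst_min": float(np.median([m.tst_min for m in ms])),
            "median_efficiency_pct": med_eff,
            "early_wake_fraction": float(np.mean([m.early_wake for m in ms])),
            "sol_gt_30": med_sol > SOL_REFERENCE_MIN,
            "efficiency_lt_85": med_eff < EFFICIENCY_REFERENCE_PCT,
        }
    if rejected:
        out["rejected"] = rejected  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
    family: Sequence[Sequence[Sequence[int]]] | None = None,
) -> float | tuple[float, np.ndarray]:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    The two-sided p sums the probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  With
    ``family`` (a list of 2x2 tables including comparable tests), the
    BH-FDR-adjusted p values across the family are returned as well.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        p = 1.0
    else:
        p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    if family is None:
        return p
    from .robust_de import bh_adjust

    ps = [fisher_exact_2x2(tab) for tab in family]
    return p, bh_adjust(ps)


def spearman_rho(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    The p value is computed by exact permutation enumeration for
    n <= ``exact_max_n`` and by the t approximation otherwise.  Constant
    input leaves rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t_stat = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 2))
    return rho, float(p)
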