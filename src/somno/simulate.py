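"""Seeded generators for every input modality, with machine-readable truth.

Each generator emulates one data stream the pipeline consumes and returns
its ground truth alongside, closing the testing loop without any external
data:

* ``gen_sleep_activity`` — an alternating renewal process of sleep and wake
  bouts with geometric (memoryless, minute-resolution) durations.  The
  fragmentation knob ``f`` divides both the sleep- and wake-bout means, so
  raising it shortens bouts and multiplies their number while leaving the
  expected total sleep unchanged.  In *exact* mode every wake minute
  carries at least one beam crossing, making bout detection a zero-mismatch
  oracle against the emitted bout ledger.
* ``gen_freerun_activity`` — Poisson counts with a sinusoidally modulated
  rate, for rhythmicity analysis in constant darkness.
* ``gen_foci`` — a proximal/distal two-component Gaussian point cloud of
  fluorescence maxima, optionally rendered to an image with landmarks.
* ``gen_counts`` — negative-binomial RNA-seq counts with planted fold
  changes and sporadic multiplicative outliers.
* ``gen_cohort`` — Bernoulli questionnaire features and normally
  distributed diary times truncated to a valid night ordering.

One global seed fans out deterministically to per-component child seeds via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import DiaryRecord
from .io_formats import ActivityTrace
from .morphometry import FociSet
from .robust_de import CountMatrix
from .sleep import DAY_MIN, SleepBout, _period_of, _split_at_boundaries


def child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic fan-out of one global seed into n independent streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Sleep/wake activity
# ---------------------------------------------------------------------------

@dataclass
class SleepSimParams:
    """Conditions for the alternating sleep/wake renewal process.

    Bout-duration means are in minutes; wake activity is ``lambda_w`` beam
    crossings per minute.  Fragmentation ``f >= 1`` divides both the sleep-
    and wake-bout means, emulating the fragmented-sleep phenotype: more,
    shorter bouts at an unchanged expected total sleep fraction.
    """

    n_flies: int = 16
    days: int = 2
    bin_minutes: int = 1
    sleep_mean_lp_min: float = 20.0
    sleep_mean_dp_min: float = 45.0
    wake_mean_lp_min: float = 20.0
    wake_mean_dp_min: float = 10.0
    lambda_w: float = 2.0
    fragmentation: float = 1.0
    mode: str = "exact"  # exact | realistic
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")
        if min(self.sleep_mean_lp_min, self.sleep_mean_dp_min,
               self.wake_mean_lp_min, self.wake_mean_dp_min) <= 0:
            raise ValueError("bout-duration means must be positive")
        if self.mode not in ("exact", "realistic"):
            raise ValueError("mode must be 'exact' or 'realistic'")


def _geometric_minutes(rng: np.random.Generator, mean: float) -> int:
    """Geometric duration in whole minutes, support >= 1, with the given mean."""
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def split_ledger(
    raw_bouts: list[tuple[int, int]], min_inactive_min: int = 1
) -> list[SleepBout]:
    """Apply the detector's threshold + ZT-boundary split rule to true bouts.

    ``detect_sleep(trace, m)`` on an exact-mode trace equals
    ``split_ledger(raw, m)`` because every wake minute carries activity.
    """
    out = []
    for onset, dur in raw_bouts:
        if dur < min_inactive_min:
            continue
        for fo, fd in _split_at_boundaries(onset, dur):
            out.append(SleepBout(fo, fd, _period_of(fo)))
    return out


def gen_sleep_activity(
    params: SleepSimParams, seed: int
) -> tuple[list[ActivityTrace], dict[str, list[tuple[int, int]]]]:
    """Simulate per-fly activity traces plus the true bout ledger.

    The ledger maps fly id -> every true sleep bout as (onset ZT minute,
    duration minutes), unsplit; :func:`split_ledger` converts it to the
    detector's output convention.  In exact mode each wake minute carries at
    least one beam crossing, so zero-count runs coincide exactly with true
    sleep bouts.
    """
    rngs = child_seeds(seed, params.n_flies)
    total_min = params.days * DAY_MIN
    f = params.fragmentation
    traces, ledger = [], {}

    for i, rng in enumerate(rngs):
        fly_id = f"{params.genotype}_{i:03d}"
        counts = np.zeros(total_min, dtype=np.int64)
        raw_bouts: list[tuple[int, int]] = []
        t = 0
        asleep = bool(rng.integers(0, 2))
        while t < total_min:
            lp = (t % DAY_MIN) < DAY_MIN // 2
            if asleep:
                mean = (params.sleep_mean_lp_min if lp else params.sleep_mean_dp_min)
                dur = min(_geometric_minutes(rng, mean / f), total_min - t)
                raw_bouts.append((t, dur))
            else:
                mean = (params.wake_mean_lp_min if lp else params.wake_mean_dp_min)
                dur = min(_geometric_minutes(rng, mean / f), total_min - t)
                if params.mode == "exact":
                    lam = max(params.lambda_w - 1.0, 0.0)
                    counts[t:t + dur] = 1 + rng.poisson(lam, size=dur)
                else:
                    counts[t:t + dur] = rng.poisson(params.lambda_w, size=dur)
            t += dur
            asleep = not asleep

        traces.append(
            ActivityTrace(
                fly_id=fly_id,
                genotype=params.genotype,
                counts=counts,
                bin_minutes=params.bin_minutes,
                schedule="LD",
            )
        )
        ledger[fly_id] = raw_bouts
    return traces, ledger


# ---------------------------------------------------------------------------
# Free-running activity
# ---------------------------------------------------------------------------

@dataclass
class RhythmSimParams:
    """Sinusoidally modulated Poisson activity: rate(t) = lam0*(1 + a*cos)."""

    days: int = 7
    lam0: float = 1.0
    amplitude: float = 0.8
    period_h: float = 24.0
    phase_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must lie in [0, 1]")


def gen_freerun_activity(
    params: RhythmSimParams, seed: int, fly_id: str = "dd_000", genotype: str = "sim"
) -> ActivityTrace:
    """One constant-darkness trace of per-minute Poisson counts."""
    rng = np.random.default_rng(seed)
    t_min = np.arange(params.days * DAY_MIN, dtype=float)
    rate = params.lam0 * (
        1.0 + params.amplitude * np.cos(
            2 * np.pi * (t_min / 60.0 - params.phase_h) / params.period_h
        )
    )
    counts = rng.poisson(np.maximum(rate, 0.0))
    return ActivityTrace(
        fly_id=fly_id, genotype=genotype, counts=counts, schedule="DD"
    )


# ---------------------------------------------------------------------------
# Foci point clouds
# ---------------------------------------------------------------------------

@dataclass
class FociSimParams:
    """Bimodal (proximal/distal) fluorescence-maxima cloud along the dorsal axis.

    ``distal_weight`` is the probability a focus belongs to the distal
    component — the quantity the distal-region percentage estimates when the
    boundary falls between the components.
    """

    n_foci_mean: float = 40.0
    distal_weight: float = 0.5
    proximal_center_um: tuple[float, float] = (0.0, 5.0)
    proximal_sigma_um: float = 2.0
    distal_center_um: tuple[float, float] = (0.0, 20.0)
    distal_sigma_um: float = 2.0
    #: optional hard-core radius: resample foci closer than this to any other
    #: (emulates maxima resolvable at the imaging point-spread function)
    min_separation_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.distal_weight <= 1:
            raise ValueError("distal_weight must lie in [0, 1]")
        if min(self.proximal_sigma_um, self.distal_sigma_um) <= 0:
            raise ValueError("component sigmas must be positive")


def gen_foci(
    params: FociSimParams,
    seed: int,
    brain_id: str = "brain_000",
    genotype: str = "sim",
    timepoint: str = "ZT1-3",
    n_foci: int | None = None,
) -> tuple[FociSet, np.ndarray]:
    """Sample a foci set; returns (FociSet, distal membership truth vector).

    ``n_foci`` overrides the Poisson draw for fixed-size experiments.
    """
    rng = np.random.default_rng(seed)
    n = int(n_foci) if n_foci is not None else max(1, int(rng.poisson(params.n_foci_mean)))
    distal = rng.random(n) < params.distal_weight
    centers = np.where(
        distal[:, None],
        np.asarray(params.distal_center_um),
        np.asarray(params.proximal_center_um),
    )
    sigmas = np.where(distal, params.distal_sigma_um, params.proximal_sigma_um)
    pts = centers + rng.standard_normal((n, 2)) * sigmas[:, None]
    if params.min_separation_um > 0:
        for i in range(1, n):
            for _ in range(200):
                d = np.hypot(*(pts[:i] - pts[i]).T).min()
                if d >= params.min_separation_um:
                    break
                pts[i] = centers[i] + rng.standard_normal(2) * sigmas[i]
    return (
        FociSet(brain_id=brain_id, genotype=genotype, timepoint=timepoint, foci_um=pts),
        distal,
    )


def render_foci_image(
    fociset: FociSet,
    seed: int,
    um_per_px: float = 0.5,
    shape: tuple[int, int] = (256, 256),
    origin_px: tuple[float, float] = (128.0, 200.0),
    psf_sigma_px: float = 1.5,
    amplitude: float = 200.0,
    background: float = 5.0,
) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Render a foci set as Gaussian spots plus Poisson noise.

    The anatomical frame is placed with +y (dorsal) pointing up in the
    image; returns ``(image, origin_px, dorsal_ref_px)`` so detection can be
    mapped back through :func:`somno.morphometry.to_anatomical`.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    ox, oy = origin_px
    # anatomical (x, y) um -> pixel (col, row); dorsal +y is up (smaller row)
    cols = ox + fociset.foci_um[:, 0] / um_per_px
    rows = oy - fociset.foci_um[:, 1] / um_per_px
    yy, xx = np.mgrid[0:h, 0:w]
    image = np.full((h, w), background, dtype=float)
    for c, r in zip(cols, rows):
        image += amplitude * np.exp(
            -((xx - c) ** 2 + (yy - r) ** 2) / (2 * psf_sigma_px**2)
        )
    image = rng.poisson(image).astype(float)
    dorsal_ref_px = (ox, oy - 50.0)
    return image, (ox, oy), dorsal_ref_px


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class CountsSimParams:
    """Negative-binomial count simulation with planted fold changes.

    Per-gene baseline means are lognormal; counts are NB with a common
    dispersion (var = mu + dispersion * mu^2).  ``n_de`` genes receive the
    log2 fold changes in ``lfc_values`` (recycled); with probability
    ``outlier_prob`` a count is multiplied by Uniform(5, 20), exercising the
    robustness of the estimator.
    """

    n_genes: int = 500
    n_per_genotype: int = 4
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    n_de: int = 50
    lfc_values: tuple[float, ...] = (1.0, -1.0)
    outlier_prob: float = 0.0
    outlier_range: tuple[float, float] = (5.0, 20.0)

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_prob < 1:
            raise ValueError("outlier_prob must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")


def gen_counts(params: CountsSimParams, seed: int) -> tuple[CountMatrix, dict]:
    """Simulate a CountMatrix plus a truth table of planted effects.

    Truth dict: ``lfc`` (per-gene planted log2 fold change, 0 for nulls),
    ``is_de`` (bool mask), ``outlier_mask`` (gene x sample).
    """
    rng = np.random.default_rng(seed)
    G, S = params.n_genes, 2 * params.n_per_genotype
    genotype = np.repeat([0, 1], params.n_per_genotype)
    mu0 = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=G))

    lfc = np.zeros(G)
    de_idx = rng.choice(G, size=params.n_de, replace=False)
    lfc[de_idx] = np.resize(np.asarray(params.lfc_values, float), params.n_de)

    size_factors = rng.uniform(0.8, 1.2, size=S)
    mu = mu0[:, None] * np.power(2.0, lfc[:, None] * genotype[None, :]) * size_factors
    r = 1.0 / params.dispersion  # NB shape
    counts = rng.negative_binomial(r, r / (r + mu))

    outlier_mask = rng.random((G, S)) < params.outlier_prob
    if outlier_mask.any():
        mult = rng.uniform(*params.outlier_range, size=int(outlier_mask.sum()))
        counts = counts.astype(float)
        counts[outlier_mask] *= mult
        counts = np.round(counts).astype(np.int64)

    matrix = CountMatrix(
        genes=[f"gene_{i:05d}" for i in range(G)],
        samples=[f"s{j:02d}_{'mut' if g else 'ctl'}" for j, g in enumerate(genotype)],
        counts=counts,
        genotype=genotype,
    )
    truth = {"lfc": lfc, "is_de": lfc != 0, "outlier_mask": outlier_mask}
    return matrix, truth


# ---------------------------------------------------------------------------
# Cohort questionnaires and diaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Questionnaire prevalences and diary timing distributions.

    Diary times are normal in minutes (SD around typical pediatric values)
    and re-drawn until the night ordering is valid.  ``early_wake_rate``
    sets the per-night probability that the final wake falls before 05:00.
    """

    n_individuals: int = 20
    n_nights: int = 14
    feature_prevalences: dict[str, float] = field(
        default_factory=lambda: {"night_waking": 0.56, "early_waking": 0.44}
    )
    in_bed_mean: int = 21 * 60
    in_bed_sd: float = 30.0
    sol_mean: float = 25.0
    sol_sd: float = 15.0
    waso_mean: float = 20.0
    waso_sd: float = 15.0
    sleep_span_mean: float = 9.5 * 60
    sleep_span_sd: float = 40.0
    wasf_mean: float = 15.0
    wasf_sd: float = 10.0
    early_wake_rate: float | None = None


def gen_cohort(
    params: CohortSimParams, seed: int
) -> tuple[dict[str, dict[str, bool]], list[DiaryRecord]]:
    """Simulate questionnaire features and nightly diary records.

    Returns ``(cohort_table, diary_records)`` where the cohort table maps
    individual id -> {feature: flag}.  Generated records always satisfy the
    diary ordering invariants by construction.
    """
    rng = np.random.default_rng(seed)
    cohort: dict[str, dict[str, bool]] = {}
    records: list[DiaryRecord] = []
    day = 24 * 60

    for i in range(params.n_individuals):
        ind = f"ind_{i:03d}"
        cohort[ind] = {
            feat: bool(rng.random() < p)
            for feat, p in params.feature_prevalences.items()
        }
        for night in range(params.n_nights):
            in_bed = int(round(rng.normal(params.in_bed_mean, params.in_bed_sd))) % day
            sol = max(0, int(round(rng.normal(params.sol_mean, params.sol_sd))))
            waso = max(0, int(round(rng.normal(params.waso_mean, params.waso_sd))))
            span = max(waso + 60, int(round(
                rng.normal(params.sleep_span_mean, params.sleep_span_sd))))
            wasf = max(0, int(round(rng.normal(params.wasf_mean, params.wasf_sd))))
            if params.early_wake_rate is not None:
                # pin the final wake clock time on the requested side of 05:00
                target_early = rng.random() < params.early_wake_rate
                wake_clock = (
                    int(rng.uniform(3.5 * 60, 5 * 60 - 1)) if target_early
                    else int(rng.uniform(5 * 60 + 1, 8 * 60))
                )
                span = (wake_clock - (in_bed + sol)) % day
                span = max(span, waso + 60)
            onset = in_bed + sol
            wake = onset + span
            out = wake + wasf
            # single awakening of length waso, centred in the sleep span
            awakenings = []
            if waso > 0 and span > waso + 2:
                a = onset + (span - waso) // 2
                awakenings = [(a % day, (a + waso) % day)]
            records.append(
                DiaryRecord(
                    individual_id=ind,
                    night=f"n{night:02d}",
                    in_bed=in_bed % day,
                    sleep_onset=onset % day,
                    awakenings=awakenings,
                    final_wake=wake % day,
                    out_of_bed=out % day,
                )
            )
    return cohort, records
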