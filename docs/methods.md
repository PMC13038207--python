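# Methods

This note documents the models, estimators, parameter defaults and design
choices behind each analysis stage, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## Time conventions

All internal times are Zeitgeber minutes (ZT0 = lights-on; ZT0–720 = light
period LP, ZT720–1440 = dark period DP under 12:12 LD).  Conversion from
wall-clock time happens only inside readers.  Monitor rows whose status
field is not 1 become *missing* bins; sleep detection treats a missing bin
as breaking any inactivity run, so recording gaps can shorten detected
sleep but never fabricate it.

## Sleep architecture

A sleep bout is a maximal run of consecutive zero-count bins of length at
least `min_inactive_min` (default 5 min, the fly-field convention; the bin
size must divide it).  Bouts are split at every ZT0/ZT12 boundary and each
fragment contributes its duration and one bout to its own period.  The
split rule was chosen over assigning a boundary-crossing bout to the period
of its onset because it makes LP + DP sleep equal the 24-h total exactly —
a conservation identity the tests rely on — at the cost of counting one
biological episode as two period-level bouts.  Consequences: a fly asleep
at lights-off has a DP bout fragment starting exactly at ZT12, so its
lights-off latency is 0; latency is reported missing (NaN) when a period
contains no sleep at all, never coerced to 0 or 720.

Multi-day recordings are scored over whole days only; totals and bout
counts are per-day averages, computed per fly before any group statistic.
Dead flies are removed by a viability filter (zero activity throughout the
final 6 h window by default).

Group comparisons follow an explicit, testable version of the common
either/or policy: Shapiro–Wilk at α = 0.05 on both groups; if either is
non-normal (or too small for the test, n < 3), Mann–Whitney U, otherwise
the unpaired two-tailed t test.  Bonferroni correction multiplies the raw p
by the number of tests performed per genotype (clipped at 1).  The percent
change 100·(control − case)/control is computed on group means
(configurable to medians) and is invariant to common rescaling of both
groups.  Rebound after overnight deprivation is a paired t on per-fly
ZT0–3 sleep; a zero-variance difference vector is reported as p = 1 with a
degenerate-data flag rather than an undefined statistic.

## Free-running rhythmicity

For a constant-darkness trace the autocorrelogram uses the biased
(divide-by-N), mean-removed, variance-normalised estimator: it equals 1 at
lag 0, is bounded by 1, and decays smoothly because of its (1 − lag/N)
taper.  That taper also tilts a genuine circadian peak slightly early: for
a pure 24-h cosine over 6 days the maximum of (1 − l/N)·cos(2πl/1440) sits
~10 min before lag 1440 with height ≈ 1 − 1440/N ≈ 0.833.

The rhythmicity index RI is the autocorrelation at the highest local
maximum inside an 18–30 h lag window, and RS = RI/(2/√N) normalises by the
approximate 95% white-noise band.  **Calibration choice:** the peak is
located and read on a correlogram smoothed with a 60-min moving average.
Without smoothing the statistic is badly mis-calibrated under the null —
the maximum over ~720 near-independent lags of white-noise autocorrelation
sits near 3/√N by selection alone, so flat traces would routinely exceed
the 2/√N band.  A 1-h average shrinks null fluctuations ~√61-fold while
attenuating an hours-wide circadian peak by under 1%, so amplitude-zero
traces classify arrhythmic essentially always and strong oscillators keep
RS ≫ 1.5.  Classification thresholds: rhythmic RS ≥ 1.5, weakly rhythmic
1 ≤ RS < 1.5, arrhythmic otherwise; both thresholds, the window, and the
smoothing width are configurable, and the first days of darkness can be
dropped to exclude the post-entrainment transient (default keeps all).

Note that RI is *not* invariant to the Poisson rate of the underlying
activity: the sinusoidal signal variance scales with λ² while shot noise
scales with λ, so brighter (more active) flies of equal relative amplitude
score higher RI.  The normalised autocorrelogram *is* exactly invariant to
deterministic rescaling of counts.

## Clock-neuron terminal morphometry

Foci detection: Gaussian smoothing (σ = 1 px), local maxima separated by at
least 3 px and brighter than mean + 2·SD of the smoothed image; a constant
image yields zero foci with a warning; coordinate ties resolve to the
lexicographically smallest pixel so output is deterministic.

The two landmarks (primary axonal branching point = origin; a dorsal
reference point) are *inputs* — automatic branch-point detection is
error-prone and is not attempted.  The anatomical transform is rigid
(translation + rotation + isotropic µm scaling): the origin maps to (0, 0),
+y points toward the dorsal landmark, and +x is chosen toward the foci
centroid (flagged arbitrary if the centroid lies on the axis).  This makes
the result independent of image-axis conventions and of any rigid motion
applied jointly to the image and its landmarks, which the tests verify to
1e-9.

The distal region ("area 2") is radial: foci farther than `r_boundary_um`
from the origin.  A radial partition is the simplest rotation-invariant
geometry consistent with "distal terminals"; the boundary has **no
default** and must be supplied, because the proper value depends on the
imaging calibration.  Dispersion profiles are per-axis percentage
histograms over symmetric bin ranges (default 5 µm bins) summing to 100.
Per-brain distal percentages are compared across genotypes with a
two-tailed unpaired t test.

## Robust differential expression

Counts are normalised as log2(1 + CPM); a zero count maps to exactly 0 and
the transform is invariant to library scaling.  CPM is the minimal,
explicit library-size correction; a different normaliser can be plugged in
upstream of the per-gene fit.  PCA QC centres each gene across samples and
reports sample coordinates and variance fractions.

Per gene, y = β₀ + β₁·genotype is fitted by Huber M-estimation via IRLS:
weights w(r) = min(1, k·s/|r|) with k = 1.345 (95% Gaussian efficiency)
and scale s = 1.4826·MAD of the current residuals, re-estimated each
iteration; iteration stops when the coefficient change drops below 1e-8.
When no residual exceeds k·s the weights are all 1 and the fit *is* OLS.
A zero MAD (more than half the residuals identical) falls back to the
unweighted fit with a flag; non-convergence is flagged and the last
iterate reported.  The standard error comes from the weighted-LS
covariance σ̂²(XᵀWX)⁻¹ with σ̂² = Σwr²/(n−2).

**Inference choice:** the statistic β₁/se is referred by default to a t
distribution with *effective* degrees of freedom
df = #{i : |rᵢ| ≤ k·s} − 2 — the number of observations in the linear
region of ψ minus the fitted coefficients.  Clipped observations carry
ψ′ = 0 and contribute nothing to the curvature of the objective, and at
the small replicate counts typical of RNA-seq the classical n − 2
reference is markedly anticonservative for robust fits (simulations in the
test suite put the realised null tail ~3–4× its nominal level with n − 2,
and on target with the effective df).  `df_mode="classical"` restores
n − 2.

Genes with zero counts in every sample are excluded; the
Benjamini–Hochberg step-up family is all tested genes; direction (up/down)
is assigned at p_FDR < α by the sign of β₁.  Over-representation of a hit
list within GMT gene sets uses the hypergeometric upper tail P(X ≥ k)
after intersecting each set with the universe (default: all tested genes,
not the genome), with Storey q-values across sets.  Storey's π̂₀ uses a
single fixed λ = 0.5 — the simplest published variant; with π̂₀ = 1 the q
values coincide with BH.

## Clinical cohort statistics

Prevalence percentages round half away from zero, reproducing printed
values such as 5/7 → 71 and 4/6 → 67.  The ICSD-3 frequency rule flags a
complaint at ≥ 3 occurrences per week.  Diary nights are anchored at the
in-bed time with a single midnight crossing allowed: any clock time earlier
than in-bed is next-day.  SOL = onset − in-bed; WASO = summed awakenings
between onset and final wake; WASF = out-of-bed − final wake (out-of-bed is
used as the endpoint; a desired rise time is not modelled); TST =
(final wake − onset) − WASO.  These partition time in bed exactly, so
efficiency = 100·TST/TIB ∈ [0, 100].  Fixed references: SOL > 30 min,
efficiency < 85%, early waking = final wake before 05:00; per-individual
summaries are medians across nights, with nights violating the ordering
invariants rejected individually with a reason.  Fisher's exact test uses
the two-sided point-probability convention (sum of all fixed-margin tables
no more probable than the observed one); Spearman's ρ uses mid-ranks with
an exact permutation p for n ≤ 8 and the t approximation above.

## Synthetic data: what it emulates, and what it does not

Generators draw all randomness from child streams spawned deterministically
from one seed (`numpy` `SeedSequence.spawn`), so equal seeds give byte-equal
outputs.

* **Sleep/wake**: an alternating renewal process with geometric
  (memoryless, whole-minute) bout durations and period-specific means
  (defaults: sleep 20 min LP / 45 min DP, wake 20 min LP / 10 min DP, wake
  activity λ_w = 2 counts/min) — chosen to give the realistic fly pattern
  of more, longer sleep at night at plausible totals.  The fragmentation
  knob f divides both bout means, so expected total sleep is unchanged
  while expected bout count scales by f.  In *exact* mode every wake
  minute carries ≥ 1 count, so zero-count runs coincide exactly with true
  sleep bouts and the detector can be tested for zero mismatches;
  *realistic* mode draws Poisson(λ_w) wake counts, allowing quiet
  wakefulness to masquerade as sleep the way it does in real monitors.
  Geometric durations make renewal expectations analytic; they do not
  reproduce the heavy-tailed bout distributions of real flies (a lognormal
  option is the natural extension).
* **Free-running activity**: per-minute Poisson counts with rate
  λ₀(1 + a·cos(2π(t − φ)/τ)); defaults 7 days, τ = 24 h.  No transient
  after entrainment, no period drift, no activity bouts — it tests the
  statistic, not fly behaviour.
* **Foci**: a two-component (proximal/distal) Gaussian cloud along the
  dorsal axis; the distal weight w is the quantity the distal-region
  percentage estimates when the boundary lies between components.  An
  optional hard-core separation resamples foci closer than the PSF for
  detection tests (unresolvable pairs physically merge into one maximum —
  no detector can recover them).  Rendering adds Gaussian spots plus
  Poisson noise and emits the landmark coordinates.
* **Counts**: negative-binomial with lognormal baseline means, common
  dispersion (default 0.1), planted log2 fold changes on `n_de` genes, and
  ε-probability multiplicative outliers (×U(5, 20)) exercising the robust
  estimator.  Library composition effects and batch structure are not
  modelled.
* **Cohort/diaries**: Bernoulli questionnaire features at set prevalences;
  nightly diary times from truncated normal distributions centred on
  typical paediatric values, always satisfying the ordering invariants by
  construction; an optional early-wake rate pins the final-wake clock time
  on the requested side of 05:00.

Passing tests on these generators demonstrates correctness of the
estimators and detectors under the stated models; they do not validate the
biological realism of those models, and real-data quirks (arousal without
beam crossings, optical artefacts, batch effects, diary recall bias) are
out of scope by design.

## Problem sizes

The test suite and the acceptance script use deliberately modest problem
sizes chosen to make the statistical checks sharp but quick: 1000 random
traces for the bout-detection oracle, 80 flies for fragmentation recovery,
200 seeds per amplitude for classification rates, 500 foci for the
distal-weight binomial check, 400 genes (4 replicates per genotype) for the
planted-effect run and 50 × 200-gene null simulations for FDR control.

## Known limitations

Latency conventions, the inactivity threshold, the rhythmicity thresholds
and the area-2 boundary are field conventions or user inputs, not values
with a single canonical source; all are exposed as parameters.  Robust
per-gene regression with 3–4 replicates has limited power at |LFC| < 1.5;
the effective-df reference trades a little power for calibrated error
control.  Diary scoring assumes at most one midnight crossing per night
and ignores naps.  Images are treated as 2-D projections; 3-D stacks,
axon tracing and intensity normalisation across brains are out of scope.
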