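# Methods

## Estimand and measurement model

A well holds N worms exposed to a lethal stressor. Worm *i* dies at time
`t_i` and emits a fluorescence burst

    k(t; t_i) = A_i · (1 − exp(−(t − t_i)/τ_r)) · exp(−(t − t_i)/τ_d),  t ≥ t_i

with rise constant τ_r on the order of minutes and decay constant τ_d of
roughly two hours. The recorded well trace is the baseline plus the sum of
bursts plus read noise. When bursts rise quickly relative to the spread of
death times and decay slowly, the rising phase of the population trace is
approximately proportional to the count of deaths so far, and the time at
which the trace crosses half of its peak equals the sample median of the
death times. That half-maximum time, `t_half`, is the estimand: the
population's median time of death.

Timing of death events in a population behaves as a counting process whose
event-time distribution is well approximated by a normal once the median
time of death exceeds ~30 min; the simulator's default death model is
accordingly Normal(median, sd) truncated at zero, with a conditioned
Poisson-process mode (piecewise-constant rate, event times drawn from the
normalized rate density given the count) available for skew stress tests.

## Per-well pipeline

1. **Gap handling.** Up to two consecutive missing reads are linearly
   interpolated; longer runs mark the well UNFIT (`MISSING_DATA`) rather
   than aborting the plate.
2. **Smoothing.** Moving median then moving mean, both with the same odd
   window (default 5 samples ≈ 10 min at 2-min cadence). The median stage
   removes isolated single-read spikes (bubbles, condensation); the mean
   stage stabilizes the least-squares fit. A window of 1 disables
   smoothing (used by estimator-level tests). On a gentle sigmoid rise the
   cascade distorts the curve by < 1% of amplitude.
3. **Noise scale.** The per-read noise σ is estimated robustly from first
   differences of the *raw* (unsmoothed) trace, σ̂ = 1.4826·MAD(Δf)/√2,
   which is exact for iid Gaussian read noise and insensitive to the
   signal's slow trend. Estimating from smoothed differences would require
   a smoother-dependent attenuation constant, so the raw trace is used.
4. **Peak significance.** Candidate peaks are local maxima of the smoothed
   trace (boundary maxima included via minimum-value sentinels). A peak is
   significant iff its prominence ≥ 5σ̂ and > 0; the most prominent wins,
   ties to the earliest. On flat noise-only wells this criterion produced
   0 false positives in 1000 seeded replicates; scale-free, so it is
   unaffected by gain changes and baseline drift.
5. **Normalization.** `g(t) = (f − F_base)/(f_peak − F_base)` clipped to
   [0, 1] and restricted to the rising phase (window start → peak).
   `F_base` is the 5% quantile of the smoothed pre-peak segment,
   re-estimated after peak detection. `g` is invariant under affine
   transforms of the fluorescence, hence so is `t_half`.
6. **Half-max estimation.**
   * *Interpolation mode* (manual-equivalent): the first upward
     0.5-crossing of `g`, linearly interpolated between the bracketing
     samples. One convention matters for count-like traces: when the
     crossing falls inside a jump out of a flat plateau (two equal samples
     followed by a step through 0.5), the crossing is attributed to the
     jump completion time. This is the right-continuous step-function
     convention, and it makes the half-max time of an
     instantaneous-burst/no-decay trace *exactly* the sample median of the
     death times for odd N. For smooth traces the rule never fires and
     plain interpolation applies.
   * *Auto mode* (default): bounded least squares of the four-parameter
     logistic `F0 + A/(1 + exp(−k(t − t50)))` over the rising phase,
     initialized at `F0 = F_base`, `A = f_peak − F_base`, `t50` = the
     interpolated crossing, `k = 4/(t_0.75 − t_0.25)` from the normalized
     quartile crossings. Two identifiability constraints reflect that only
     part of a sigmoid is observed: the fitted plateau is tied to the
     observed peak (`A ∈ [0.5, 1.3]·(f_peak − F_base)`,
     `F0 ∈ F_base ± 0.25·A₀`), and samples above 95% of the normalized
     rise are excluded because the burst-decay process bends the curve
     away from a logistic there. `t_half` is the time at which the fitted
     curve crosses the half-maximum level (baseline + half the observed
     rise); this coincides with `t50` whenever the fitted plateau matches
     the peak, and keeps the automated and manual estimators aimed at the
     same quantity (they agree to r ≈ 0.997 with median difference below
     one cadence step across medians 30–360 min). Without the plateau
     constraint the fit is mean-unbiased but heavy-tailed on partial
     rises; with it, dispersion halves at the cost of inheriting the
     estimand's decay bias (below).
7. **QC classification.** UNFIT: no significant peak, no dynamic range, no
   half crossing, long data gaps, `t_half` outside
   [first read + cadence, last read − cadence], or `rmse/A > 0.3`.
   REVIEW: interpolation fallback after optimizer failure or
   `0.15 < rmse/A ≤ 0.3`, or a saturated detector (≥ 5% of noisy reads
   pinned at the trace maximum). The review queue (REVIEW + UNFIT wells)
   is exported for human re-analysis. The `rmse/A` thresholds are
   configuration defaults, not claims.

All analysis is deterministic; every random draw lives in the simulator.

## Simulator

Defaults emulate the assay's standard operating points:

| parameter | default | rationale |
|---|---|---|
| burst amplitude | 100 au/worm, CV 0.2 (lognormal) | worm-to-worm brightness varies; CV unmeasured, configurable |
| rise τ_r / decay τ_d | 2 min / 120 min | burst at onset of death; decay over a few hours |
| baseline / drift | 100 au, +0.5 au/h | plate autofluorescence, slow evaporation drift |
| read noise | multiplicative CV 0.10 + additive 1 au | typical monochromator plate reader |
| `stress384` | 384 wells × 16 worms, 2-min cadence, 8 h; medians U(30, 240) min, sd = 20% of median | severe oxidative/thermal assay format |
| `infection96` | 96 wells × 100 worms, 5-min cadence, 4 days; medians U(12, 36) h, sd = 5% of median | infection assays need many worms so consecutive deaths are close enough for bursts to sum into a clear peak; dispersion kept below the decay time, the regime the method is designed for |
| `dose_series` | 4 doses × 6 wells, medians 240/120/60/30 min | monotone dose–response check |

One integer seed drives a plate; each well consumes an independent
substream keyed by (seed, well index), so enlarging a plate never changes
existing wells, and rendered traces are reproducible byte-for-byte.

What the simulator does **not** emulate: developmental or genotype
heterogeneity within a well (death times are exchangeable draws), spectral
shifts between species, photobleaching, well-to-well optical crosstalk,
and detector saturation (saturation handling is exercised with synthetic
clipped traces only). Passing the validation suite therefore shows the
pipeline recovers truth under the stated generative model, not that every
real plate will fit cleanly — the QC statuses exist for the remainder.

## Accuracy and known limitations

* **Decay bias.** The half-maximum time equals the median of death times
  only while the death-time spread is small relative to the burst decay
  constant. Deterministic evaluation of the population curve (normal
  deaths, τ_d = 120 min) puts the bias of the half-max crossing at about
  −2 min for median 90/sd 18, −8 min at 150/30, and −15 to −18 min at
  240/48. On the default `stress384` scenario this yields a median
  absolute recovery error of ≈ 3 min and a 95th-percentile error of
  ≈ 17 min, concentrated in the slowest-dying wells. Assays should be
  designed (stressor dose, worm numbers) so that the death wave is
  compressed relative to τ_d; the `infection96` defaults illustrate the
  compliant regime, where 100-worm wells at 4-day cadence recover the
  true median to within 10 min.
* **Quantization.** The interpolation estimator resolves below one cadence
  step on smooth rises, but step-like traces resolve to the grid.
* **Multi-peak wells** (two death waves, e.g. bimodal susceptibility) are
  not deconvolved; the most prominent peak wins and the rest is visible
  only as elevated fit residual (REVIEW).
* **First-week resistance statistics** use ages 1–7 days of adulthood
  inclusive; other ages are reported per-age but excluded from
  min/mean/max. Pearson correlation is used for the lifespan regression
  (a linear-model question); Kendall's tau for dose ordering (few doses,
  ties likely).
* Bootstrap CIs for group medians are percentile intervals over wells
  (default 2000 resamples, seeded); with a single OK well the interval
  collapses to the point estimate.

## Problem sizes in the test suite

The suite validates on full-size plates where cheap (384-well stress
plate, seconds) and on reduced replicate counts for Monte-Carlo checks
(e.g. 400 noise-only wells for the false-positive rate, 100 bootstrap
coverage replicates, 1000 regression replicates), sizes chosen so each
check's sampling error is small against the margin it tests.
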