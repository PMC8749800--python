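# Methods

## Scope and model

`imugait` estimates the timing of all four ground-contact events of both
feet — heel strike (HS), toe off (TO), opposite heel strike (OHS),
opposite toe off (OTO) — from the motion signal of a single instrumented
foot, and derives from them the temporal gait parameters of bilateral
lower limbs: the two double-support phases and their total, left/right
stance and stride times, and signed symmetry indexes. The premise is
biomechanical: walking phase-locks the two limbs, so load transfer to or
from the contralateral foot changes the instrumented foot's muscle and
joint activity abruptly, which appears as a gradient turning point (GTP)
in the sagittal-plane channels (`A_y`, `A_z`, `G_x`). The detector is
rule-based and causal per stride (fractional anchors use the previous
heel-strike pair's cycle length), so it is portable to an edge device.

## Event detection

* **HS** uses the posterior-acceleration signature: the dominant per-cycle
  `A_y` maximum followed by a sharp valley. "Dominant" is defined by peak
  prominence ≥ `hs_prominence_frac` (default 0.6) of the `A_y`
  peak-to-peak range, with a minimum peak separation of 300 ms; the HS is
  the `A_y` minimum within 100 ms after the maximum. The prominence rule
  is a stand-in for an exact valley-sharpness criterion, with all its
  parameters exposed on `DetectionConfig`.
* **TO** is the first valley (prominence ≥ 0.3 g) of the W-shaped `A_y`
  pattern between 20% and 92% of the cycle — after the foot-flat segment,
  before the next HS signature.
* **GTPs** are localised with the triangle-thresholding construction:
  the sample of the buffered segment farthest (perpendicular distance)
  from the chord joining two reference points; ties take the earliest
  sample. The argmax is invariant to a common positive rescaling of the
  curve and the chord values.
* **Foot-flat**: P_A sits at 20% GC after HS; P_B is the prominent local
  maximum of the configured channel nearest in time to P_A (both
  directions, earlier wins ties; "local maximum" means strictly greater
  than both neighbours, plateaus count their first sample). The search
  stops at 40% GC — a causal buffer, and a guard against the much larger
  pre-TO peak absorbing the prominence scale — and includes a 5%-GC
  pre-HS context so an impact maximum at the stride edge keeps its flank.
  **OTO = foot-flat + 2% GC**, rounded half-up to the sample grid.
* **OHS**: monitoring starts after foot-flat and no earlier than 40% GC;
  the first sample whose deviation from the channel's foot-flat baseline
  (0 for `A_y`/`G_x`, +1 g for `A_z`) exceeds the channel threshold
  (0.15 g / 1.15 g absolute / 30 deg/s) is P_A; P_B is the channel's most
  prominent local maximum (minimum for `A_y`, which swings negative)
  before TO, falling back to the extreme sample when the run-up to TO is
  monotone. The default channel is `G_x`, the best-agreeing feature;
  `A_y`/`A_z` stay selectable for candidate comparison.

Failures are per-stride and non-fatal: a missing pattern leaves that
event absent (with a warning) and the remaining strides untouched.

## Stride handling

Strides are half-open intervals `[HS_i, HS_{i+1})`; timestamps are
integer multiples of the sample period (10 ms at the default 100 Hz).
For parameter estimation the first and last two strides of a trial are
always discarded (gait initiation/termination), and remaining strides
are kept only when their duration-normalised `G_x` waveform correlates
at ≥ 0.8 (configurable, pluggable predicate) with the pointwise-median
stride template — a transparent outlier rule for strides disturbed by
sensor error or accidental events.

## Bilateral parameters

Left-foot stance spans from this stride's OHS to the *next* stride's
OTO, and left stride time from OHS to the next OHS; the pairing rule is
stride-with-successor, and a record is emitted only when the successor's
events exist. `DSTt = DST1 + DST2` holds exactly by construction, and
field-wise k-stride averaging (default k = 5, non-overlapping runs;
sliding optional; k ≈ 5 m of walking at typical stride length) preserves
it. Symmetry indexes keep their sign — direction of asymmetry is
information — and are bounded in (−2, 2) by construction.

## Synthetic gait generator

The generator emits piecewise-linear waveform templates, not a
musculoskeletal simulation: only the morphological features that carry
the events are guaranteed. Defaults encode the canonical healthy-gait
cycle at 100 Hz: 1000 ms cycle (120 steps/min), stance 60% GC,
foot-flat 8% GC, OTO 10% GC, OHS 50% GC, with amplitudes (e.g. 120 deg/s
post-HS rotation burst, ±1.5–2 g HS signature on `A_y`) chosen at the
scale foot-mounted IMUs record in level walking. Slopes of the `G_x`
rise before/after OHS (1.0 and 3.0 deg/s per ms) keep the OHS elbow
strictly convex and place the threshold crossing comfortably between
heel rise and the elbow across the supported asymmetry range.

Two deliberate design points:

* **Smoothing compensation.** Trials are optionally noised (Gaussian,
  SD expressed as a fraction of each channel's peak-to-baseline
  amplitude) and always smoothed with a short moving average (window 3,
  part of the spec). A centred moving average displaces *asymmetric*
  corners by half a window: steep-into-flat settling corners emerge one
  sample late, shallow-into-steep valleys one sample early. The two
  affected knots (the `G_x` settle into foot-flat, the first `A_y` W
  valley) are pre-compensated by that half-width so the observable
  morphology places each event exactly on its programmed grid time.
* **Asymmetry.** A constant nonzero stride-time symmetry index is
  kinematically a drift (one leg would lag further every stride), so
  `asym_tr` is realised as a geometric ramp of cycle durations centred
  on the base cycle, with the per-stride ratio solved exactly from the
  symmetry-index definition; `asym_ta` is a constant shift of the OHS
  fraction, likewise solved in closed form. Ground-truth events land on
  the sample grid, so programmed indexes are exact up to grid rounding
  (≤ 0.005). Stride-to-stride cycle variability (`gc_sd_ms`, default 0)
  is available when naturally varying reference values are needed.

What the generator does *not* emulate: soft-tissue and mounting
artefacts, slope- or turn-induced waveform changes, pathological gaits
with weakened push-off (where the OHS slope break genuinely fades), or
sensor drift. Passing tests therefore demonstrate correctness of the
algorithmic chain and its noise behaviour at the stated levels, not
clinical validity on real recordings.

## Agreement statistics

The pipeline mirrors standard two-system method comparison on
differences `D = test − ref` and averages `A`:

* Normality by one-sample KS against a normal law with estimated
  mean/SD — the stated test of the validation protocol; note that with
  estimated parameters this gate is conservative (true rejection rate
  below α); a Lilliefors variant is selectable. Constant samples are
  non-normal with a NaN p-value.
* Accuracy/precision: mean/SD when normal, else median and quartile
  deviation `(Q3 − Q1)/2`.
* Fixed bias: one-sample t-test or Wilcoxon signed-rank with the
  zero-inclusive Pratt treatment — 10 ms measurement grids guarantee
  exact-zero differences, which the default zero-discarding treatment
  would silently drop.
* Proportional bias: Pearson (D and A both normal) or Spearman; when
  significant at α = 0.05 the limits of agreement become lines.
  Parametric correction regresses D on A (OLS) and offsets the fitted
  line by `1.96·sqrt(π/2)·mean|R|`; since `E|R| = σ·sqrt(2/π)` for
  normal residuals, the half-width equals the classic `1.96σ`.
  Nonparametric correction fits linear quantile regressions (pinball
  loss, iteratively reweighted least squares via statsmodels) at
  τ = 0.025, 0.50, 0.975.
* Agreement coefficient: when both series pass the normality gate,
  ICC(2,1) (single strides) or ICC(2,k) (k-stride averages), two-way
  random effects, absolute agreement, computed from ANOVA mean squares;
  otherwise Kendall's W for two raters with average ranks and the tie
  term subtracted in the denominator, so identical-but-tied series score
  exactly 1 and `W = (ρ_s + 1)/2` holds. Bands: ICC > 0.75 excellent,
  0.60–0.749 good, 0.40–0.599 fair, < 0.40 poor; W > 0.60 strong,
  0.30–0.599 moderate, 0.10–0.299 weak.
* Quantiles use linear interpolation throughout; all significance at
  α = 0.05.

## Numerical choices and degenerate inputs

Half-up rounding snaps fractional-GC arithmetic to the grid. TTA
requires ≥ 3 samples and distinct reference times; reference points are
reordered by time when P_B precedes P_A. Constant difference or average
series short-circuit the correlation and quantile fits with the obvious
constants. Non-uniform time vectors are rejected, never resampled;
values beyond the sensor's ±16 g / ±2000 deg/s ranges are kept but
flagged as saturated.

## Problem sizes

The test suite validates the turning-point primitive against exhaustive
search on 1,000 random segments, event recovery on 20-stride noise-free
trials across 80–140 steps/min, detection precision on a 200-stride
5%-noise trial, and the large-sample statistics identities at n = 10⁵;
the whole suite runs in a few seconds on one core.

## Known limitations

* The HS valley-sharpness rule and the template-correlation outlier rule
  are documented stand-ins; their parameters are configurable.
* Quantile-regression LoA lines on heavily tied, grid-snapped data are
  an estimand with genuine ambiguity; slopes may differ noticeably from
  the parametric fit on such data.
* The detector assumes a clear heel-rise rotation build-up; gaits with
  weak plantarflexion push-off will degrade OHS detection first.
* ICC confidence intervals and repeated-measures Bland–Altman variants
  are out of scope.
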