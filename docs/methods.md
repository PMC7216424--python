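# Methods

This note documents the models, conventions and numerical choices behind
`actirhythm`, in the order data flows through the pipeline.

## Data model

An `ActivitySeries` is a regularly sampled sequence of nonnegative activity
counts (arbitrary units) with a timezone-naive local-clock start time and an
epoch length that divides 3600 s. Epoch timestamps label the epoch *start*
and cover `[t, t + epoch)`; all clock-time windows (day/night, IS clock
bins) are defined on the local clock, which is the frame ward schedules live
in. Recordings at sub-minute epochs are aggregated to one value per minute
(sum by default — count-like semantics — mean available), dropping a
trailing partial minute.

Event logs carry typed events. Interval types (visit, nursing, therapy,
wheelchair, mobilization_outside, device_off, crs_r) can trigger removal;
point types (medication, nutrition, lights on/off, eyes open/closed) never
do — they are context, not confound.

## Correction

1. **Padding.** Each removable interval is widened by a per-type pad:
   nursing 5 min each side; visit and wheelchair 10 min each side; the other
   removable types 0 by default (configurable). Pads exist because staff
   press the start button only after reaching the patient, so the logged
   bounds understate the contaminated span.
2. **Snapping and merging.** Padded intervals are clipped to the recording,
   snapped *outward* to epoch boundaries (floor start, ceil end —
   conservative removal) and merged with any overlapping or touching
   interval into maximal disjoint removal intervals that remember every
   contributing event type.
3. **Imputation.** Rhythm metrics need gap-free data, so removed spans are
   filled: the first ⌈n/2⌉ epochs of each gap take the median of up to
   10 min of clean data immediately preceding it, the rest the median of the
   10 min following it. Two deliberate conventions: (a) for odd gaps the
   *preceding* median gets the extra epoch — a deterministic tie-break;
   (b) the context windows are measured from the merged, padded interval and
   skip epochs belonging to *any* removal interval — padding exists because
   the logged bounds are unreliable, so context must not include potentially
   contaminated minutes. A side with no clean context falls back to the
   other side; if neither side has context the series is uncorrectable.
4. **Exclusion rule.** A recording with more than 90 % of epochs removed
   raises an "uncorrectable series" error (the analysable-data-left
   criterion under which a patient is excluded); above 50 % a warning is
   emitted. Both thresholds are configurable — no published numeric
   threshold exists, these are this package's defaults.
5. A caller-supplied list of extra removal intervals stands in for the
   manual visual-screening pass of a human rater; the automatic stage makes
   no attempt to detect unlogged artifacts itself.

Correction is idempotent (contexts consist of observed epochs only, which
imputation never changes) and leaves a constant series bit-identical.

## Rhythm metrics

**IS / IV.** Series are mean-binned (default 60 min, the classical
convention; `bin_minutes=1` is available since the underlying recordings are
minute-resolution). With `N` total bins, `p` bins per 24 h, clock-bin means
`x̄_h` and grand mean `x̄`:

    IS = N Σ_h (x̄_h − x̄)² / (p Σ_i (x_i − x̄)²)
    IV = N Σ_{i≥2} (x_i − x_{i−1})² / ((N−1) Σ_i (x_i − x̄)²)

IS needs ≥ 2 full days. For white noise over d days E[IS] ≈ 1/d (the
Monte-Carlo suite checks 1/7 ± 0.05 for 7 days); an hourly-binned 24-h
sinusoid has IV = 2(1 − cos 2π/24) ≈ 0.068, iid Gaussian noise E[IV] ≈ 2,
and an alternating two-level sequence reaches 4. Bins inherit the clock slot
of their first epoch, so series need not start at midnight. Zero-variance
input makes both indices undefined; they propagate as `nan`, never as 0.

**Lomb–Scargle.** The classical tau-corrected Scargle periodogram with
normalised power `P_N = P/σ²` (sample variance, ddof = 1), evaluated on a
frequency grid of spacing `1/(ofac·span)` with `ofac = 100`. The evaluation
is an in-package chunked matrix implementation of exactly the reference
formula — verified against `scipy.signal.lombscargle` to ~1e-12 relative
error in the test suite — because the chunked form is several times faster
on dense grids; grids above ~1e7 sample-frequency products run the trig in
single precision (relative power error < ~1e-3, irrelevant against peak
heights of 10–10³ and a significance threshold near `ln(M/α)`).
Per-frequency false-alarm probability is `p = 1 − (1 − e^{−P_N})^M` with the
effective number of independent frequencies `M = N_grid/ofac`
(Horne–Baliunas-style; the noise false-positive Monte-Carlo test bounds the
realised rate at α = 0.001). `lomb_scargle` scans the full grid from the
recording span down to twice the epoch by default; the pipeline's
`MetricOptions` restricts the scan to periods ≥ 2 h, which keeps
minute-resolution grids tractable and still contains every period that can
compete for "closest to 24 h" in practice.

**Peak extraction.** Among strict local maxima (greater than both grid
neighbours) with `p < α`, the peak minimising |period − 24 h| is selected;
exact ties break toward 24 h, then toward higher power. `deviation` is
|period − 24|; a series is *circadian* iff a significant peak exists and
deviation < 1 h strictly (a deviation of exactly 1.0 h is not circadian).
Note one boundary effect the synthetic studies expose: for a true 25-h
rhythm the selected grid point can fall one grid step (~0.03 h at 25 h,
7 days, ofac 100) to either side of 25 h, so the circadian classification of
exactly-1-h-deviant rhythms is borderline by construction; cohort-level
conclusions use medians and proportions, which are robust to it.

**Day/night.** Means over epochs whose start clock time falls in
[07:00, 21:00) (day) and the complement (night); an epoch starting exactly
at 21:00 is night.

## Cohort statistics

Wilcoxon signed-rank (paired) and Mann–Whitney U (independent) use the
tie-corrected normal approximation for Z *without* continuity correction,
two-sided; zero differences are dropped (the effect size still uses the
pre-drop pair count, matching how N is reported for cohort-level r values).
Exact enumeration modes (all 2ⁿ sign assignments / all group assignments of
the pooled ranks) engage automatically for ≤ 10 observations and are the
oracle the tests compare against; both modes also match scipy's
implementations on shared ground. Kendall's tau-b handles the heavy ties of
behavioural scores; its Z is recovered from the two-sided p with tau's sign
so all tests report a uniform `r = |Z|/√N`. Effect-size labels follow the
conventional 0.1/0.3/0.5 cuts; p values in (0.05, 0.1] are flagged as
trends; no multiple-testing correction is applied (matching the analysis
convention this pipeline mirrors). Report output rounds to 2 decimals, half
away from zero.

Contrast tables exclude patients flagged excluded, drop undefined metric
values listwise per metric (logged), and mark paired contrasts with < 5
usable pairs as not computed.

## Synthetic cohorts

The generator emulates the measurement situation, not physiology. Endogenous
activity at minute t is `max(0, mesor + A·cos(2π(t − acrophase)/period) +
noise)` with zero-truncated Gaussian (or Poisson-like) noise. Care events
come from templates (type, clock time, duration, jitter SD, daily
occurrence probability, passive amplitude): each instantiated event *adds*
its passive amplitude to the recorded series — the simplest confound model,
treating recorded activity during care as not the patient's own — and emits
a log entry whose start is pressed late (default 3 min, within the 5-min
nursing pad). Default recording length is 7 days of 1-min epochs, the
typical study-week protocol.

Two stock configurations: a 24-h entrained two-group cohort in which
conscious (MCS/EMCS-like) patients draw higher mesor and amplitude than
unconscious (UWS-like) patients, and the *headline-bias* cohort — weak
free-running 25-h rhythms (mesor 8–16, amplitude 2–6, noise SD 3–5) under a
fixed 24-h ward schedule (morning/midday/evening nursing, morning therapy
5 days/7, afternoon visit 80 % of days, passive amplitudes 40–60) — chosen
once as plausible ward conditions. No quantitative inventory of real care
frequencies/durations is published; these defaults are placeholders at
realistic orders of magnitude. What the simulation does *not* model:
triaxial accelerometry waveforms, sleep staging, nonstationary rhythm
parameters, unlogged care events, or misclassified event types — so passing
tests show the pipeline recovers truth under faithful logging with bounded
latency, not robustness to an unreliable log.

Problem sizes used by the test suite and the acceptance script — 20-patient
cohorts, 7-day recordings, 200-seed Monte-Carlo calibrations — are this
package's standard verification sizes; cohort medians and proportions are
stable at these sizes.

## Known limitations

* The imputation inserts locally constant values, which deflates IV on
  heavily corrected recordings; this is inherent to median filling and is
  shared by the procedure the package implements.
* Significance of periodogram peaks uses the classical independent-frequency
  approximation, which is conservative-to-approximate on oversampled grids;
  the realised false-positive rate is checked by simulation rather than
  derived exactly.
* Events the log misses entirely are not corrected (by design — only a
  manual-screening hook is provided).
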