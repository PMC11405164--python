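# Methods

## Stimulation protocol

The automated swinging-flashlight sequence is: 5 s of darkness (dark
adaptation), a 1 s binocular pulse followed by 3 s of darkness (light
adaptation/conditioning; excluded from scoring), then `n_cycles` (default 3)
cycles of monocular stimulation — a 1 s, 125 lux pulse to one eye followed by
3 s of darkness — with the left eye always stimulated first. Total default
duration 5 + 4 + 3×8 = 33 s at 90 Hz sampling (2970 samples per eye).

The published description of the cycle order is ambiguous between per-cycle
alternation (L,R,L,R,L,R) and a blocked order (L,L,L,R,R,R). The default is
alternation, matching the swinging-flashlight convention; `cycle_order:
blocked` reproduces the other reading. Total duration and per-eye pulse
counts are identical either way. No extra dark time is inserted between the
left- and right-eye profiles.

Time convention: seconds from recording start, half-open intervals
`[start, end)`, sample `i` covering time `i/rate`.

Analysis windows (per light pulse): baseline = the last `baseline_window_s`
(default 0.5 s) of the immediately preceding dark interval; response =
`[onset, onset + response_window_s)` (default 2.5 s). The response window is
sized so the trough of a reflex with ~0.25 s latency always falls inside it;
both windows are configurable.

## Preprocessing

1. **Diameter cut-offs.** Samples < 1 mm or > 9 mm are marked missing, per eye
   independently. Blinks and large eye movements appear as such excursions;
   no gaze-based rejection is attempted (gaze is not part of the input
   contract).
2. **Gap interpolation.** Interior missing runs of ≤ 90 samples (1 s at
   90 Hz) are bridged by shape-preserving piecewise cubic Hermite (PCHIP)
   interpolation through the valid samples (scipy's `PchipInterpolator`);
   interpolation never alters valid samples and cannot overshoot a monotone
   bracket. Leading/trailing runs have no bracketing knot on one side and are
   filled by nearest-valid constant extension rather than extrapolation, to
   avoid fabricating trends. Any run longer than 90 samples fails the quality
   gate: the trace is returned unmodified, no score is emitted, and the log
   asks for a repeat measurement.
3. **Smoothing.** A centered 100-sample running mean. Centered (zero phase)
   rather than trailing so reflex latencies are not biased; at the edges the
   window shrinks symmetrically. Requires a gap-free trace.

Order of operations: the original instrument is described as smoothing first,
then cut-offs, then interpolating the raw data. Averaging across blink spikes
leaks artifact into neighbouring samples, so the default order here is
flag → interpolate → smooth; `preprocess.paper_order: true` reproduces the
literal published sequence (the running mean is then computed over valid
samples only, since missing samples still exist at that stage). On clean
traces the two orders agree.

## Reflex measurement and the RAPD score

For each monocular pulse and each responding pupil: baseline = mean diameter
over the baseline interval, trough = minimum over the response interval,
constriction % = 100·(baseline − trough)/baseline. Negative values (net
dilation, possible in noisy flat responders) are floored at 0 so the ratio
stays defined; the raw value is retained in the measurement record. The
trough-based amplitude is used rather than the value at light-off because it
is the standard pupillary-light-reflex amplitude and robust to latency
variation. Per-(stimulated, responding) replicates across cycles are
aggregated by the mean (median available via config).

**Efferent screen.** For each stimulated side, the two pupils' responses
within that same stimulation are compared; the flag trips iff the same pupil
is the weaker responder under both left- and right-eye stimulation and both
within-stimulation ratios exceed 1.25 (configurable). An afferent deficit
attenuates both pupils together when the affected eye is stimulated and never
trips the flag. A pupil with zero constriction in a denominator is flagged
outright ("non-reactive pupil"). The instrument this emulates states that
consensual responses were screened for efferent defects but not the
criterion; this rule is therefore a documented surrogate, and its threshold a
design choice: 1.25 sits above the measured within-stimulation asymmetry of
noisy symmetric subjects and well below the 1.4+ asymmetry of a mild
(gain 0.7) efferent deficit.

**Score.** Two-tailed score = mean OD direct % / mean OS direct %; one-tailed
score = max(r, 1/r) = stronger/weaker ≥ 1, with the weaker eye reported
(none on an exact tie). Of the two published phrasings of the ratio
(affected/non-affected vs stronger/weaker) only stronger/weaker yields scores
that are always above unity, so that definition is implemented, using the
measured weaker eye rather than any clinical label. Scores are withheld (not
fabricated) on quality failure, efferent flag, or a non-reactive weaker eye.

## Diagnostic evaluation

Positive call: score ≥ threshold. The ROC sweeps the distinct score values
plus ±∞ sentinels; AUROC is the trapezoidal area, which equals the
pair-counting estimator P(case > control) + ½P(tie) exactly. The operating
point maximizes Youden's J = sensitivity + specificity − 1, with ties broken
toward the smallest threshold (maximal sensitivity — a missed RAPD costs more
than a false positive; configurable by passing an explicit threshold).
Confusion metrics: sensitivity, specificity, accuracy, precision (percent)
and the Matthews correlation coefficient; any zero-denominator metric is 0 by
convention and flagged as such.

Two confirmatory re-analyses mirror the instrument's published workflow:

- **Severity stratification:** cases split into mild (clinical grades 1–2)
  and moderate-or-worse (grades ≥ 3), each paired with a seeded random
  control subsample of matching size (without replacement; refused if
  controls are insufficient).
- **Reallocation of low scores:** cases at or below the case-cohort 25th
  percentile (type-7 linear-interpolation quantile) are shuffled with a
  seeded generator and the first ⌊n/2⌋ relabeled as controls, compensating
  for clinical over-diagnosis of physiologic interocular asymmetry. The total
  subject count is invariant; on simulated 77+77 cohorts the AUROC varies by
  about 1 percentage point across allocations.

Rank-sum or distributional hypothesis tests are not re-implemented; the
U-statistic identity U/(n₁n₂) = AUROC and scikit-learn's ROC/MCC serve as
independent oracles in the test suite only.

## Simulator

Each pupil's diameter is

    d_P(t) = B_P · (1 − a_S · e_P · A₀ · k(t)/k_max) + hippus + noise

per pulse stimulating eye S, where `a` is the afferent gain of the stimulated
eye, `e` the efferent gain of the responding pupil, `A₀` the maximal
constriction fraction, and `k(t)` the reflex kernel: zero before the latency
(0.25 s), a saturating rise `1 − exp(−(t−lat)/τ_c)` (τ_c = 0.35 s) while the
drive lasts, then exponential redilation with τ_r = 1.5 s. Normalising by the
pulse-end maximum `k_max = 1 − exp(−pulse/τ_c)` makes a default pulse attain
exactly the commanded `A₀`, so the pipeline's ground truth is closed-form:
one-tailed score = 1/afferent gain of the weaker eye. The binocular
conditioning pulse uses the larger of the two afferent gains; since it is
excluded from scoring, that choice only affects adaptation realism.

Redilation is truncated: the exponential tail is faded to zero (cosine) over
[1.5 s, 1.6 s] after drive end. A pure exponential tail with τ_r = 1.5 s
would still hold ~15% of the response amplitude inside the next pulse's
baseline window — and the centered 100-sample running mean lets the baseline
window see back a further 0.56 s — depressing baselines unequally between
eyes and biasing the score ratio by up to ~12%, which no real healthy pupil
does after a brief pulse (full recovery within ~2 s is physiological). With
the truncation the residual noiseless recovery error is ≤ 0.6% at the most
severe gain tested (0.3), attributable to the remaining smoothing leakage of
the early response into the baseline window.

Nuisance structure: hippus is one conjugate sinusoid (0.1 mm, 0.2 Hz, random
phase) added to both eyes — being common-mode, it largely cancels in the
score ratio, as in real recordings; sensor noise is i.i.d. Gaussian per eye
(0.05 mm); blinks are bilateral Poisson events (0.1 Hz, 0.2 s) producing
missing samples, mirroring tracker dropout rather than occlusion artifacts;
extreme-diameter spikes (0.5/9.5 mm) are injectable via `spike_rate_hz` to
exercise the cut-off filter.

Cohorts: cases draw an affected eye uniformly and an afferent gain from the
severity band — mild (grades 1–2): 0.55–0.85; moderate-or-worse (grades 3–5):
0.20–0.55; default mix 50:27, the composition of the reference cohort.
Controls carry only physiologic asymmetry: interocular gain ratio uniform on
[1, 1.2] (healthy pupillomotor output varies by up to ~20% between eyes), so
control true scores are ≤ 1.2. Per-subject nuisance parameters (baseline
diameter, A₀ ≈ 0.38 ± 0.02 matching healthy-control constriction, latency,
time constants) are jittered around defaults. Everything derives from one
seed; identical seeds give identical traces sample-for-sample.

The grade-to-gain mapping is invented (no published quantitative calibration
of clinical grade to score exists), and the generator omits several features
of real data: pupil-size-dependent noise, monocular blinks and partial lid
occlusion, gaze-driven apparent-diameter changes, accommodation-driven
miosis, non-exponential redilation tails, and inter-cycle fatigue. Passing
tests therefore demonstrate the correctness and internal consistency of the
computation chain under the modeled physiology — not the clinical accuracy of
the instrument, which can only be established on real recordings. In
particular, simulated cohorts separate more cleanly (AUROC ≈ 0.99) than
clinical cohorts, where grading noise and unmodeled variability broaden both
distributions.

## Numerical choices and degenerate inputs

- Intervals half-open; sample selection by `ceil(a·rate) … ceil(b·rate) − 1`
  with 1e-9 boundary tolerance.
- Uniform-sampling validation of trace files at 1e-6 s; trace CSVs are
  written with 9-decimal times so 1/90 s steps survive a round-trip.
- The running mean is computed with a cumulative sum; edge windows shrink
  symmetrically (the window is never empty, so no 0/0).
- Quantile: type-7 (linear interpolation), numpy's default.
- Youden ties → smallest threshold; exact score ties → `weaker_eye = none`.
- Fewer than 2 valid samples in an eye is a quality failure, not an
  exception; an empty measurement interval or a single-class score table is
  an error.
- Problem sizes in the acceptance script (500 subjects for the score bound,
  200 for noisy recovery, 77+77 for the cohort table, 20 reallocation seeds)
  match the study-scale conditions the properties are stated for while
  keeping a full run to a few seconds.

## Known limitations

- The efferent-screen criterion and threshold are surrogates; real instruments
  may use different rules, and anisocoria at baseline is not separately
  modeled or screened.
- Latency, peak velocity, redilation dynamics and post-illumination response
  metrics are out of scope.
- Scores from traces that fail quality are absent rather than imputed; the
  evaluation operates on scorable subjects only.
- The clinical "affected eye" label can disagree with the measured weaker eye
  near score 1; the package always reports the measured weaker eye.
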