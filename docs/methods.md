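# Methods

This note documents the models, parameters, and numerical choices behind
the package: what the synthetic-data generator emulates, how each pipeline
stage is defined at its boundaries, and what passing the test suite does
and does not establish about real data.

## Stimulus model

Scenes are 9 s tone clouds of six concurrent pure-tone streams. Carriers
come from a fixed pool of nine values between 500 and 3,225 Hz. The pool is
constructed by converting both endpoints to ERB-rate numbers
(cam = 21.4·log10(4.37·f/1000 + 1)), placing nine equally spaced cam values
between them, and converting back. Honoring both printed endpoints fixes
the spacing at ≈1.81 cam; the nominal "2 cam" spacing and the printed
endpoints cannot both hold exactly under this ERB formula, and the
endpoints win because both are explicit.

Tone durations and inter-tone intervals (ITIs) are continuous uniform on
[10, 150] ms — mean ITI exactly 80 ms, nominal stream rates 1000/(dur+ITI)
∈ [3.3, 50] Hz. REG streams fix one ITI for the scene; RND streams draw a
fresh ITI for every gap. Phase randomization: each stream starts with a
tone (probability 1/2) or partway through its first silent interval
(uniform jitter within that interval).

Change scheduling: CA scenes carry a seventh stream whose first tone onset
is exactly 6.0 s. CD scenes delete one of the six streams; the change time
is the offset of the last retained tone plus that stream's ITI (REG) or
plus the 80 ms mean ITI (RND) — the expected onset of the first missing
tone — with the last retained tone chosen so this lands nearest 6 s
(realized spread ≈ ±50 ms). Decoy trials silence all streams for 200 ms at
a uniform time in [1.0, 7.8] s. Each block holds 4 trials of each of the
six REG/RND × CA/CD/NC conditions plus one decoy per condition (30 trials);
8 blocks give 240 trials, 32 analyzable per main condition, 48 decoys
(20%). Audio rendering is additive synthesis with 3 ms raised-cosine ramps
per pip, mono, with a Nyquist guard.

## Synthetic ocular sessions

No generative model for the ocular data exists in the literature this
package operationalizes; every distributional choice below is a stand-in,
chosen once to emulate the figure-level morphology of real recordings, and
the ground truth is emitted alongside every simulated session so that
pipeline claims are tested as parameter recovery, never by eye.

**Pupil (per trial segment, 1.5 s pre-onset to 2 s post-offset).**
Baseline ≈1200 arbitrary units (per-participant jitter SD 50), an onset
response with bumps peaking at 0.8 s (amplitude 30) and 3 s (20), a
sustained linear decline from 3 s at −12 (REG) vs −6 (RND) units/s
(between-participant jitter SD 1.5 — the injected regularity effect), a
change-locked phasic dilation (gamma-family bump, shape 2, scale 0.3 s)
with onset delay 0.45 s and amplitude 25 for CA vs 1.0 s and 12 for CD, a
0.2 Hz slow oscillation (amplitude 3, random phase per trial), band-limited
"hippus" pupillary unrest (Gaussian-filtered white noise, SD 6, 150 ms
correlation scale — this gives the clean trace dilation-onset events at a
realistic ~1/s rate), and white instrument noise (SD 4 per eye; the right
eye sits 5 units lower). After scene offset the trace relaxes to baseline
with a 2 s time constant. Ground-truth dilation events are the events of
the *smoothed* clean trace, because the event definition (local minimum
followed by ≥100 ms non-decreasing dilation) presupposes the 150 ms
smoothing stage.

**Gaze (pixels, 1,000 Hz).** Fixational drift is an Ornstein–Uhlenbeck
process (mean-reversion 2/s, diffusion 6 px/√s) shared between the eyes,
plus small per-eye vergence noise and 0.2 px white measurement noise.
Microsaccades arrive as an inhomogeneous Poisson process at base rate
1.5 Hz, thinned by raised-cosine suppression bumps (half-width 100 ms)
centered 200 ms after scene onset (depth 0.5) and 200 ms after the scene
change (depth 0.8, per-participant jitter SD 0.05) — the injected MSI.
Events are conjugate raised-cosine position steps of 6–30 px whose duration
scales with amplitude (8–25 ms, so peak velocity stays detectable), random
direction, inter-eye onset disparity uniform in [0, 4] ms, and onset-to-
onset spacing >50 ms. The steps feed the same leaky drift state, so gaze
stays centered without an explicit refixation model. Blinks arrive at
0.1 Hz: 100–300 ms closures (validity false, pupil zero, gaze frozen)
flanked by 20–50 ms partial-closure edges in which the pupil is
artifactually reduced but the sample still reads valid — exactly the
artifact the 250 ms closure padding must remove.

**Behavior.** Decoy gaps are detected with probability 0.95 at a lognormal
reaction time (median 0.45 s, log-SD 0.3); false alarms occur on 1% of
other trials at a uniform time.

What the generator does *not* emulate: luminance responses, pupil
foreshortening, saccades >1°, smooth pursuit, head motion, tracker dropout
beyond blinks, or any coupling between behavior and ocular state. Passing
recovery tests therefore demonstrates that the pipeline recovers effects of
the injected form at realistic noise levels — not that the pipeline is
robust to every artifact of real recordings.

## Pipeline definitions and boundary conventions

- Missing data: gaze strictly >100 px from fixation, or inside a closure
  padded by 250 ms. Exactly 100.0 px is kept (strict "outside a radius").
- Interpolation: PCHIP through valid samples (monotone, no overshoot);
  leading/trailing gaps hold the nearest valid value. Order is fixed:
  interpolate, then smooth.
- Smoothing: zero-phase unit-area Hann, 151 samples at 1 kHz, reflected
  edges.
- Rejection: missing fraction strictly >50% (pre-interpolation mask);
  outlying epochs have ≥10% of samples strictly >3 SD from the per-time-
  point condition mean, computed once from the epochs that survive the
  missing criterion (single pass, before normalization).
- Normalization: (x − μ)/σ with μ, σ pooled over all baseline samples of
  that condition within the block (baselines: 1 s pre-onset for
  sequence-evoked, 0.5 s pre-change for change-locked pupil). A zero-σ
  block drops its epochs.
- Eye choice: left preferred, right per block when the left is tracked in
  under half the samples.
- Dilation events: strict local minima (plateaus credit their first
  sample), non-decreasing for the full 100 ms window; minima too close to
  the epoch end to verify are not events.
- Causal kernel: w(τ) = α²τe^(−ατ) discretized at the sampling rate,
  truncated below 10⁻⁶ of its maximum, renormalized to unit sum. "α =
  150 ms" is read as the time constant (1/α), making the peak — and the
  stated peak-latency axis shift — exactly 150 ms; a literal rate of
  150 ms⁻¹ is dimensionally impossible and the spike-rate literature this
  kernel comes from uses the time-constant reading.
- Rates: pulse trains summed, divided by trial count, expressed in
  events/s, causally convolved, baseline-corrected (0.5 s sequence /
  0.15 s change-locked for MS; −0.15..0 s for the PDR change-locked
  baseline, which the figure captions give in place of the pupil's 0.5 s),
  axis shifted left 150 ms. The estimator ramps up over the first ~0.5 s of
  an epoch (no events exist before it); the ramp is identical across
  conditions and cancels in differences, which is how rate comparisons are
  read.
- MS criteria: velocity from the 5-sample moving difference; per-axis
  median-based SD over the whole block (σ² = median(v²) − median(v)²);
  elliptic threshold at λ = 6; runs of 5–100 ms inclusive; closures are
  missing, never interpolated, and runs touching missing samples are
  dropped; greedy nearest-onset binocular pairing with strict <10 ms
  disparity; refractory sweep keeping onsets strictly >50 ms after the last
  kept onset. Binocular onset is the earlier eye; amplitude and peak
  velocity are eye means.
- Bootstrap: participants resampled with replacement via multinomial
  weights (exactly equivalent to row resampling); a time point is
  significant when more than 95% of the 1,000 resampled means are strictly
  positive or strictly negative. Under the null this flags ~10% of time
  points (it is two one-sided 5% checks) — the reason every reported effect
  is additionally gated by the noise floor.
- Noise floor: control trials split into random halves per iteration (odd
  counts: larger half on a random side), surrogate difference bootstrapped,
  longest significant run recorded; the decision threshold is the 95th
  percentile of that distribution, taken as the next-higher order statistic
  (a value the surrogate distribution actually produced), exceeded
  strictly. Controls: NC for sustained and vs-NC comparisons, CD for
  CA-vs-CD.
- Divergence latency: 500 outer iterations resampling participants, each
  running the full bootstrap and recording the first significant time at or
  after the change; a `min_run_s` option ignores significant runs shorter
  than a given duration (default 0, the literal procedure). At desk scale,
  participant-constant normalization offsets make short spurious runs
  common, so the recovery analyses read latencies with min_run_s = 0.3.
- Wilcoxon r: |Z|/√N over the paired mean scores at significant time
  points; tie-corrected normal approximation for N > 20, exact signed-rank
  distribution otherwise with Z recovered from the exact two-sided p (at
  extreme orderings this conversion can push r slightly above 1).
- No false-discovery-rate correction anywhere; change-locked MS/PDR
  effects whose first significant time falls outside 100–250 ms are labeled
  "exploratory" in reports, nothing more.
- Statistics run on every 10th sample (100 Hz) of the smoothed series;
  with 150 ms smoothing and a ≥100 ms kernel this loses no temporal
  structure and sets the latency resolution to 10 ms.

## Recovery estimators

Recovery tests compare pipeline output against the generator's ground
truth and may therefore use the generative model:

- **MSI latency** is recovered by Poisson maximum likelihood: the injected
  raised-cosine suppression profile is fitted (latency × depth grid) to the
  pooled per-millisecond counts of the detected change-locked event trains,
  with control epochs pinning the base rate. The kernel-smoothed rate
  trough is intrinsically flat (±0.01 events/s across 200–350 ms), so at
  desk scale the trough location is not an informative latency estimate;
  the train-level fit recovers the injected 200 ms to within ~10 ms from
  ~380 change epochs.
- **Tonic divergence onset** is recovered by extrapolating the late-window
  (5–9 s) linear fit of the group-mean REG−RND difference to its zero
  crossing. The injected divergence is linear by construction, and the
  late-window signal dwarfs the noise, so the crossing estimates the onset
  without the late bias (+0.2..+0.8 s) of the first-significant-time
  readout. The bootstrap's role in that test is the "flagging": a sustained
  significant run of the correct sign covering the late window.

## Desk-scale problem sizes

The analysis drivers and the acceptance script run a 12-participant ×
2-block cohort (≈380 analyzable change epochs, 8 no-change sequence epochs
per condition per participant), detector-oracle comparisons on 500–1,000
random small traces, 500-iteration latency resampling, and 100 null
calibration runs. These sizes make every stage's behaviour measurable in
minutes on one CPU; the full 36 × 8 design runs through the identical code
path via `RunConfig` defaults.

## Known limitations

- The bootstrap's >95% sign-consistency criterion is anti-conservative
  pointwise (~10% under the null); only noise-floor-gated intervals should
  be treated as findings, and the latency distributions inherit the
  contamination unless a minimum-run guard is applied.
- Per-block, per-condition z-normalization with few trials per block adds
  participant-level scale and offset noise that is constant across time;
  at desk scale this produces occasional long spurious runs (visible in
  the null calibration) and interferes with naive changepoint fits.
- The dilation-event definition is sensitive to residual instrument noise:
  detector/ground-truth agreement is ≈0.99/0.98 (recall/precision) at
  0.5 units of white noise, ≈0.94/0.92 at 2, and ≈0.88/0.83 at the
  generator default of 4 (0.33% of diameter). Rate-level analyses are
  insensitive to this jitter; event-level uses of the detector on noisy
  data should smooth more or accept the degradation.
- Gap-crossing interpolation cannot recover pupillary unrest lost during a
  blink; residuals after padding and interpolation are bounded by the
  unrest amplitude, not by the instrument noise.
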