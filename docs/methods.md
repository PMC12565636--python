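# Methods

`gazeseq` analyses brief-exposure eye-tracking trials in which a participant
views a small arrangement of symbols and the designer has a hypothesised
("intended") order in which the symbols should be inspected. The pipeline has
five stages — fixation detection, AOI assignment, scanpath alignment,
attention metrics, paired statistics — plus a synthetic gaze generator that
provides ground truth for testing every stage without any recorded data.

## Fixation detection (I-VT with a dispersion gate)

Raw gaze samples (pixel coordinates at a nominal 120 Hz) are converted to
angular kinematics using the exact chord formula

    angle = 2 · atan(chord_cm / (2 · viewing_distance_cm)),

with the chord taken from the Euclidean pixel displacement and the screen's
physical pixel pitch. Per-sample angular velocity is estimated by centred
neighbour differences (one-sided at the stream ends) followed by a centred
moving average (default 3 samples). Candidate fixations are maximal runs of
samples with smoothed velocity strictly below 30 °/s; a candidate is kept iff

* duration ≥ 100 ms (last-sample time minus first-sample time), and
* Salvucci–Goldberg dispersion (max x − min x) + (max y − min y), converted
  to degrees, ≤ 1.5°.

The velocity criterion defines candidate runs and the dispersion/duration
criteria act as acceptance gates; this composition is one of several
plausible readings of "velocity-based detection with a dispersion threshold"
and is the one implemented here. Invalid-sample gaps of ≤ 2 sample periods
are linearly interpolated; longer gaps break candidate runs, preventing
spurious merging across blinks or track losses.

Defaults that are not observable from data and must be configured:

| parameter | default | why |
|---|---|---|
| viewing distance | 65 cm | typical remote-tracker desktop setup; required for any px→degree conversion |
| physical screen | 53.15 × 29.90 cm | 24-inch 16:9 panel at 1920 × 1080 |
| velocity threshold | 30 °/s | standard I-VT fixation/saccade boundary |
| dispersion threshold | 1.5° | standard stable-gaze bound |
| minimum duration | 100 ms | conventional minimum fixation duration |
| smoothing window | 3 samples | noise robustness at 120 Hz; exposed as a parameter |

A consequence of centred differencing plus smoothing is that each
fixation/saccade boundary erodes by exactly one sample when saccadic steps
stay ≤ ~1.5° per sample interval: detected boundaries sit one sample period
(8.33 ms) inside the true ones, and detected durations are ~2 sample periods
short. The simulator (below) is designed so this erosion never exceeds one
sample, which is what makes exact boundary accounting possible in tests.

## AOI assignment and scanpath strings

AOIs are labelled rectangles or polygons (pixel coordinates, origin
top-left); sets are validated to be non-overlapping, so boundary-inclusive
centroid containment is unambiguous. A trial's scanpath string is the ordered
sequence of AOI labels of its fixations, restricted to fixations starting at
or after stimulus onset (window configurable); fixations outside every AOI
are dropped rather than encoded as a gap symbol, because intended sequences
contain only AOI labels and a gap symbol would inflate distances.
Consecutive same-AOI fixations collapse to one symbol by default (a scanpath
records *visits*; the flag is exposed for fixation-level strings).

## Scanpath alignment

Alignment with the intended sequence uses the unit-cost Levenshtein distance
(insertions, deletions, substitutions; no transpositions) and the similarity
ratio

    ratio = 1 − distance / max(|observed|, |intended|) ∈ [0, 1],

reported also as a percentage. Two empty sequences are defined as identical
(ratio 1), avoiding 0/0. The distance is computed by iterative dynamic
programming and is property-tested against an independent exhaustive
recursion (metric axioms, oracle equality on small alphabets).

## Attention metrics

* **TTFF** — latency from stimulus onset to the *start* of the first
  fixation assigned to the AOI and lasting ≥ 100 ms. Missing (never imputed)
  when no fixation qualifies.
* **Dwell time** — summed duration of qualifying fixations in the AOI.

The analysis window defaults to unbounded after stimulus onset. A bounded
window (e.g. `0:450` ms for the nominal presentation time) is available, but
note that brief-exposure protocols routinely analyse fixations that continue
past the nominal offset — with ~180 ms fixations, restricting to 450 ms
leaves at most two visits and makes dwell on later AOIs structurally zero.
A fixation that starts inside a bounded window counts in full, matching the
"start of fixation" convention used by TTFF.

## Paired statistics

Comparisons pair at participant level: each participant's non-excluded
trials of a condition are aggregated (mean by default, median available),
pairs with a missing member are deleted, and the two-tailed paired t-test is
computed from the textbook formula with p from the t distribution
(df = n − 1). The paired effect size is Cohen's d = mean_diff / sd_diff,
which satisfies d = t/√n exactly; that identity is asserted on every emitted
row. Bonferroni correction divides α by the family size m (e.g. α = 0.025
for a two-AOI family). Degenerate input with zero difference variance yields
t = 0, p = 1 when the mean difference is also zero, and is an error
otherwise. No normality screening or nonparametric fallback is applied.

## Synthetic gaze generator

The generator emulates a within-subjects A/B design: by default 34
participants × 8 conditions (4 guidance strategies, each with treatment and
control variants) at 120 Hz, i.e. 272 trials, with presentation order
counterbalanced by Latin squares. Each trial is: 400 ms fixation cross
outside the stimulus area → stimulus epoch → 400 ms closing cross.

**Attention model.** The trial plans one visit slot per symbol of the
intended sequence. Each slot targets the next intended AOI with probability
`adherence`, otherwise a uniformly random AOI — so `adherence` is the single
dial linking gaze behaviour to the hypothesis, and expected scanpath
similarity is monotone in it. Planned fixation durations are normal
(mean 180 ms, SD 30 ms, clipped at 130 ms so that grid quantisation plus
boundary erosion can never push a planned fixation below the detector's
100 ms gate). Consecutive slots landing on the same AOI merge into one
planned fixation, keeping ground-truth fixation counts unambiguous.

**Kinematics.** Saccades are constant-velocity segments whose duration
scales with amplitude (~1° per sample interval, minimum two intervals),
giving 60–120 °/s — far above the 30 °/s threshold yet slow enough that
3-sample velocity smoothing can blur at most one boundary sample. A fixed
`saccade_duration` can be set instead; very fast fixed saccades will erode
boundaries by more than one sample. Fixational jitter is an
Ornstein–Uhlenbeck drift per axis (stationary SD 0.15°, time constant
300 ms — slow drift, as in real fixations; i.i.d. jitter of that amplitude
at 120 Hz would produce apparent velocities above the detection threshold
and is deliberately not modelled). Tracker noise is white Gaussian per
sample (SD 1.5 px ≈ 0.04°, typical remote-tracker precision).

**Defaults as a stated world.** Condition adherences default to 0.85 for
treatment variants of the three guided strategies, 0.60 for controls, and
0.65/0.60 for the size pair (a near-null contrast). These encode the
directional hypotheses of the emulated design and were chosen once, before
any test was run, as values a practitioner would call plausible; they are
not estimates from any dataset.

**Stimulus epoch length.** The epoch runs until the planned visits complete
(six ~180 ms visits take ~1.3 s), so the nominal 450 ms presentation time is
carried as metadata only. Reconciling a 450 ms exposure with multi-second
dwell statistics is impossible in one window; the unbounded default plus the
`--window` option exposes both readings.

**Ground truth and determinism.** Every trial returns its planned visit
labels and fixation intervals snapped to the sample grid (including the two
cross fixations). All randomness flows through numpy Generators; per-trial
seeds derive from (master seed, participant, trial) via `SeedSequence`, so a
fixed master seed reproduces the experiment bit for bit and any trial can be
regenerated in isolation.

**What a green test does not establish.** The generator has no blinks,
pupil data, calibration drift, express saccades, off-AOI exploratory
fixations, salience-driven capture, or fatigue/learning trends; adherence is
constant within a condition. Detector-recovery and power results on
simulated data therefore certify the pipeline's correctness, not its
performance on real recordings.

## Latin-square ordering

Orders are built in blocks of k rows; each block is a cyclic Latin square,
so every condition appears exactly once per ordinal position within a block
(checked exactly, as integers). Odd blocks use the Williams offset pattern
(0, +1, −1, +2, …), which is first-order carryover-balanced for even k; even
blocks use the negated offsets, also balanced, and sharing no row with the
Williams square for k = 4 or 8 — so 2k distinct orderings exist across two
blocks (e.g. 8 unique sequences for 4 conditions). The Williams square
itself is closed under row reversal for even k, which is why reversal is not
used to generate the second block. Participant counts that are not multiples
of k truncate the last block.

## Known limitations

* Monocular processing only; a binocular average must be formed upstream.
* No saccade/glissade classification and no blink detection beyond validity
  gaps.
* The first-trial-per-block exclusion assumes blocks of consecutive trial
  indices (default block size 4).
* At exactly 2 participants, paired tests on coarse-grained metrics (e.g.
  2-symbol intended sequences) can be degenerate (zero difference variance);
  this raises a documented error rather than fabricating a p-value.
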