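# Methods

## Metric definitions and conventions

All geometry lives in continuous pixel coordinates, corner form
`(x_min, y_min, x_max, y_max)`, origin top-left. Areas are continuous
products with no `+1` correction, so IoU is unambiguous and matches COCO
arithmetic.

Frames may carry several detections of one class; before any metric is
computed, each frame is reduced to the highest-confidence box per class.
Confidence ties keep the earliest-listed box, which makes results
deterministic under the parsers' order-preserving contract. Detector
*evaluation* (mAP) deliberately skips this filtering and scores all
predicted boxes — best-box filtering is a metric-side simplification only.

The five metric families yield seven numbers per trial (times in seconds,
paths in pixels):

| metric | definition |
|---|---|
| total procedure time | frame count / nominal frame rate, shared by both synchronized views |
| usage time (per tool) | detected-frame count / frame rate |
| center path length (per tool) | sum of Euclidean distances between box centers in consecutive *visible* frames |
| corner path length (per tool) | same, summed over the four corners matched in fixed TL, TR, BR, BL order |

Visibility gaps are bridged: the step is taken to the next frame in which
the tool is detected, however distant, with no maximum-gap cutoff.
Consequently deleting frames where a tool is invisible never changes a
path length (a property the tests exercise). Boxes are axis-aligned, so
the fixed corner correspondence is exact; under pure translation the
corner path is exactly four times the center path, and a centered,
symmetric size change moves the corners but not the center.

With two cameras, every usage-time and path metric is computed per view
and maximized over views; total procedure time is identical across views
by synchronization, so the maximum is a no-op there. Frame timing is
`frame_index / frame_rate` with the nominal rate taken from the manifest;
no per-frame timestamps are modeled. Missing frames are represented as
empty frames rather than skipped indices so usage-time denominators stay
well defined.

## Statistics

Both experiments use two-sided p-values from the Student t distribution.

*Novices vs. experts* is a pooled-variance independent t-test per metric
with each trial as one observation: at the full design (6+6 participants,
4 trials each) that is 24 vs 24 and df = 46. Treating repeated trials of
one participant as independent observations understates within-participant
correlation; the package reproduces this trial-level procedure as the
reference analysis and does not silently "fix" it (a mixed-effects model
would be the fix, and is out of scope). Welch's variant is available via a
flag. Novices are group 1, so positive t means novices score higher.

*First vs. last trial* is a paired t-test per metric on each participant's
(trial 1, trial 4) values within a group, df = n_participants − 1 = 5 at
the full design.

No multiple-testing correction is applied; one raw p-value is reported per
metric. Degenerate inputs (zero pooled variance, zero-variance
differences) set a `zero_variance` flag instead of dividing by zero, with
t = 0, p = 1 when the means also agree and t = ±inf, p = 0 otherwise.

*Learning curves* are per-trial-index group means of each metric divided
by the minimum raw value that metric attains over all expert trials, so
1.0 marks the best expert trial. A zero expert minimum (possible only in
degenerate synthetic data) is an error rather than an infinity.

Report formatting renders t to two decimals and p with two decimals at
p ≥ 0.01, three decimals down to 0.002 and two-significant-digit
scientific notation below that (e.g. `1.8e-3`), matching the reporting
style of the study this pipeline reproduces.

## Detector evaluation

Matching is the standard VOC/COCO greedy protocol: within a frame and
class, predictions are processed in descending confidence and each is
matched to the unmatched ground-truth box of highest IoU, a true positive
iff that IoU reaches the threshold (default 0.5, boundary inclusive); each
ground-truth box is used at most once. Detections are pooled over all
frames of the evaluation split before ranking (per-dataset AP, not a
per-frame average). AP integrates the monotone precision envelope over
recall (all-point interpolation, VOC 2010+); the legacy 11-point variant
is exposed as an option. mAP is the unweighted mean over classes present
in the ground truth; a class with neither ground truth nor predictions is
skipped, and predictions without any ground truth score 0 for that class.

The leave-two-user-out fold planner pairs the i-th novice with the i-th
expert as the test set of fold i and uses the cyclically next pair for
validation — the pairing rule is otherwise unspecified in the protocol the
planner reproduces, and the cyclic choice makes it deterministic. Each
participant is tested exactly once; at 6+6 participants that is 6 folds of
2 test / 2 validation / 8 training participants.

## Synthetic studies

The generator emulates the *statistical* structure of a two-camera
training study, not its pixels: it emits bounding-box streams only.

- **Design**: 6 novices + 6 experts, 4 trials each, two synchronized
  640x480 views at a nominal 10 fps.
- **Durations**: log-normal per group, truncated by rejection to
  [105 s, 672 s] (the recording range the design targets). Defaults:
  expert mean 150 s, novice mean 330 s, log-SD 0.35.
- **Motion**: each tool's center follows a target-seeking AR(1) walk
  `x_{t+1} = x_t + κ(target − x_t) + ε_t`, `ε_t ~ N(0, σ²I)`, clamped to
  the frame. Defaults κ = 0.05; σ = 2 px/frame (experts) vs 3 px/frame
  (novices). The model was chosen because it admits closed-form checks:
  with κ = 0 the expected per-step path increment is σ√(π/2), which the
  tests verify on 200 seeded trials.
- **Visibility**: per-tool two-state Markov chains. Probe: p(hide) = 0.02,
  p(show) = 0.10 (stationary visibility ≈ 0.83); needle: 0.05/0.05
  (≈ 0.50), starting hidden so it enters mid-procedure. Long-run usage
  fraction converges to the chain's stationary probability (tested).
- **Detector noise**: per-box misses (probe 5%, needle 25%), Gaussian
  corner jitter (2 px probe, 3 px needle), Beta confidences (means 0.88 /
  0.70), and 3% duplicate boxes at lower confidence. The needle's worse
  defaults mirror the qualitative probe/needle performance gap of 2-D
  detectors on thin tools.
- **Correlation structure**: log-normal participant random effects on
  duration (SD 0.15) and step size (SD 0.10) correlate trials within a
  participant; duration and step size shrink 5% per trial as a mild
  learning trend; the right camera's motion is scaled by 1.05–1.1 to give
  the mild inter-camera asymmetry two viewpoints produce. No fidelity is
  claimed for the asymmetry magnitude.

Everything is seeded through `numpy.random.SeedSequence` spawning, so a
study is bit-for-bit reproducible from one integer.

What the simulator does *not* capture: real tool kinematics (accelerations,
tremor spectra, deliberate repositioning), correlated detector failures
(motion blur, occlusion bursts), class confusion, perspective coupling
between the two views, and any anatomy-driven structure. Passing tests
therefore validate the *pipeline arithmetic and its statistical behavior
under the assumed effect structure*, not clinical validity of the metrics.

## Numerical and design choices

- Degenerate boxes (non-positive extent) are rejected at construction;
  simulated jitter that collapses a box is recentered to a 2 px minimum
  extent instead.
- The metrics CSV round-trips at full float precision
  (`float_precision="round_trip"` on read).
- Path-length sums are plain float64 accumulation via numpy; series with
  fewer than two visible frames have length 0 by definition.
- Trial metrics at the study scale (48 trials, two cameras, up to ~6700
  frames each) compute in well under a second; a full simulated study
  takes a couple of seconds, which keeps the 100-replicate power check in
  the test suite at a few minutes.
- The power check's conditions are the generator defaults above; the test
  asserts novice > expert group means for all seven metrics and p < 0.05
  for total procedure time in ≥ 90% of 100 seeds.
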