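# Methods

This note records the models implemented in `phasecast`, the synthetic
study conditions, and the design decisions taken where the problem left
room for choice. It states no measured result; the numbers live in the
test suite and in `scripts/acceptance.py` output.

## Task

A procedure is a per-second sequence of phase labels over a vocabulary of
C−1 operative phases plus an end-of-surgery (EOS) class. Two tasks are
posed at every query second *t*:

- **Anticipation (classification).** Predict the phase active at
  *t + n·60* s for *n* = 0…N (minutes). *n* = 0 is recognition of the
  current phase. Times past the end of the procedure take the EOS label —
  EOS is a target-only class and never appears in stored timelines.
- **Remaining time (regression).** For every class (EOS included),
  predict the minutes until its next occurrence at or after *t*: 0 if
  active now, clamped to N if it does not occur within the horizon. The
  EOS entry is the remaining procedure duration, clamped.

Coordinates are seconds, 0-based; segments are half-open `[start, end)`.
Annotations at 25 fps are decimated to 1 fps by keeping every 25th frame.

## Architecture

All trainable parts run on `phasecast.nn`, a small reverse-mode autodiff
core over dense numpy arrays (float32 by default; deterministic given
seeds; gradients are finite-difference-checked in the test suite).

**Encoder.** The last L seconds of per-second features are linearly
projected to width `d_model`, given a sinusoidal positional encoding, and
self-attended within disjoint windows of W seconds (one pre-norm
attention + feed-forward layer by default; window count = L/W, with
left-padding when W does not divide L). A linear layer compresses to
width `d`, and two pooling schemes build context tokens:

- *Key-pooling*: one elementwise max over everything older than the last
  M seconds, then a cumulative max appending each of the M most recent
  seconds — M tokens that add recent detail on top of a global summary.
- *Interval-pooling*: elementwise maxima over prefixes growing in fixed
  60-s steps from the window start — one token per elapsed minute, the
  granularity the autoregressive decoder generates at.

The positional encoding is shared over the whole window rather than reset
per attention window. This is deliberate: with piecewise-constant
observations, per-window encodings make the pooled context provably
invariant to time shifts of one window, so no elapsed-time information
survives pooling and remaining-time regression becomes ill-posed. A
window-global code with slow monotone components lets the elementwise max
retain each phase's segment-boundary offsets. For the same reason the
encoding's longest wavelength should be within an order of magnitude of
L, not the 10⁴ default used for very long token sequences.

**Recognition head.** Key-pool token m is fused with the WSA feature of
the matching recent second by an additive skip (after a learned dimension
match) and classified; row M (the current second) supplies the predicted
current phase.

**Decoders.**

- *SP*: N learned query tokens (+ sinusoidal position) cross-attend to
  the key-pooled context in one forward pass; a linear head and softmax
  give the N×C anticipation grid.
- *SP\**: identical, but query *n* is a learned linear embedding of the
  transition-prior row P(· at +n | current class), teacher-forced with
  the ground-truth current class during training and conditioned on the
  recognition head's prediction at inference.
- *AR*: a causally masked decoder consumes the interval-pooled tokens as
  a prefix and generates one token per future minute, feeding back an
  embedding of its own previous prediction. Greedy argmax feedback is the
  default (it makes rollouts deterministic and prefix-stable); temperature
  sampling is available but off by default. Training uses the same
  free-running rollout — no ground-truth label embeddings.
- *Regression*: a single query token cross-attends the context and emits
  C values; targets are scaled to [0, 1] by dividing by N during training
  (MSE conditioning) and rescaled and clamped to [0, N] at output.

**Losses.** Weighted cross-entropy over the M recognition frames plus
weighted cross-entropy (classification) or MSE (regression) over the
anticipation outputs, summed. Class weights default to inverse target
frequency normalised to mean 1 and clipped to [0.1, 10].

**R2C.** To read a phase sequence out of a remaining-time prediction:
drop classes predicted at ≥ N ("will not occur"), sort the rest by
ascending predicted time (ties by ascending class index), fill minute
bins with the current class until the first predicted occurrence, then
advance to the next sorted class once its predicted time falls below the
bin index — at most one class per bin, so every realised class occupies
at least one bin. The one-advance-per-bin rule is fixed here because it
is the unique reading consistent with both of the worked cases the
sort-and-bin description implies (a class entering mid-bin occupies the
following bins; tied classes occupy consecutive bins in index order).

## Transition priors and baselines

`estimate_transition_prior` counts, over every second of every training
timeline, the pair (class now, class at +h·60 s) for h = 1…N, with EOS
fill past the video end — the same convention as the targets — and
normalises rows with additive smoothing α (default 10⁻⁶, so classes
unseen at some horizon get a uniform row instead of an undefined one).
Counts are pooled across videos. Naive1 extends the current class over
the horizon. Naive2 draws each future minute independently from the
prior row (seeded), or takes its argmax. In evaluations here the
baselines receive the ground-truth current phase — the strongest version
of the baselines; conditioning them on a recognition model's output is a
one-line change.

## Synthetic workflows

The simulator is a semi-Markov chain over 7 phases: from phase *i* the
workflow moves forward to *i*+1, repeats *i* (an extra bout, probability
0.05 by default), or skips to *i*+2 (probability 0.05); after the last
phase the procedure ends. Holding times are log-normal per phase
(medians 120–720 s, σ = 0.35, truncated below at 30 s), tuned so the
expected procedure length is about 38 minutes. Observations at second
*t* are the active phase's orthonormal prototype vector in D dimensions
plus isotropic Gaussian noise (σ = 0.6 by default — hard enough that
context helps, easy enough that recognition is reliable).

What the simulator reproduces: ordered workflows with rare deviations,
right-skewed minute-scale phase durations, EOS-dominated long horizons,
and per-second features whose informativeness is controllable. What it
does not: visual appearance, instrument signals, within-phase feature
drift (features are exchangeable within a phase, so elapsed time within a
phase is observable only through phase boundaries inside the context
window), and multi-modal procedure variants. Passing tests therefore
validate the machinery and its statistical behaviour under known
conditions, not clinical performance on video.

## Study conditions (`phasecast.experiments`)

Desk-scale geometry used by all benchmarks: D = 16, `d_model` = 16,
d = 32, L = 360 s, W = 20, M = 12 key tokens, 60-s intervals, N = 15 min,
2 decoder layers of width 32, 2 heads. Chosen as the smallest geometry at
which the studies below are stable — the compression width d matters most,
since the pooled context must carry a boundary-offset readout per phase
for the remaining-time task. Full-scale values (L = 1440, W = 20, d = 32,
M = 24, D = 768) are reachable through the same configuration fields.

- **Prior recovery.** 200 training procedures vs a 2000-procedure
  reference corpus from the same generator (the semi-Markov conditional
  has no convenient closed form; a 10× corpus is the reference). Compared
  by total-variation distance per (class, horizon) row with ≥ 50
  supporting seconds.
- **Deterministic exactness.** One workflow with fixed durations
  (60, 240, 360, 240, 300, 240, 240 s), no skips/repeats, noiseless
  observations. All durations are multiples of 60 s, so anticipation
  targets are constant within each elapsed minute; none exceeds L, so the
  most recent boundary is always inside the window; the first phase lasts
  exactly one minute, so the cold-start ambiguity (windows fully inside
  the first phase are identical up to padding) never spans a target
  change. Probes sit mid-minute (t = 60k+30 for classification,
  t = 60k+15 for the held-out regression grid) so a probe never coincides
  with an annotation boundary. SP trains in 200-step rounds with a
  stepped learning-rate decay (3·10⁻³ → 10⁻⁴) until its greedy sequences
  match ground truth (budget 16 rounds; at a constant rate Adam orbits
  the memorisation optimum without landing on it). Regression uses a
  fixed annealing schedule (lr 3·10⁻³ → 3·10⁻⁵ with batch growth
  16 → 64) followed by averaging the last three round checkpoints,
  because its accuracy is limited by the SGD noise floor rather than by
  representational capacity.
- **Ordering.** 3 repetitions; per repetition 200 training and 50 test
  procedures (skip/repeat 0.05, noise 0.6), SP and SP* trained 300 steps
  at batch 16, probes every 120 s, 15-minute horizon, EOS cap 4 per
  sequence, mean weighted F1 averaged over repetitions. The expected
  picture: SP* ≥ SP (the prior row injects the conditional structure SP
  must learn from scratch), SP* > Naive1 (phases last a few minutes, so
  continuation decays), and Naive2's independent per-minute draws
  fragment sequences (more label changes than ground truth) while Naive1
  never changes label.

## Evaluation conventions

- **Weighted F1** per horizon step (class importance ∝ target support,
  via scikit-learn), averaged over steps for the horizon mean. At most
  `cap` EOS steps per target sequence (the earliest) are scored — cap 4
  by default, 8 for AutoLaparo-like settings — so EOS does not dominate
  long horizons.
- **SegF1**: greedy best-IoU matching of same-phase segments at a 0.5
  IoU threshold (configurable); unmatched predictions are false
  positives, unmatched ground-truth segments false negatives. Greedy
  best-IoU is fixed and documented since finer matching details are
  underdetermined; it penalises oversegmentation as intended.
- **in/out/wMAE**: per class, inMAE averages samples whose target lies
  strictly inside (0, horizon), outMAE those clamped at the horizon;
  wMAE is the unweighted mean of the two per class, then averaged over
  classes (the convention of the next-occurrence-regression literature).
  Empty sample sets are NaN-flagged, never silently zero.
- **RSD**: MAE over all seconds and restricted to true remaining
  duration ≤ 5 / ≤ 30 min (the usual late-surgery subsets), mean ± SD
  across videos.
- **Model selection**: highest mean weighted F1 (classification) or
  lowest wMAE (regression); ties to the earliest checkpoint.
- A single model trained at horizon N is evaluated at any h ≤ N by
  truncating its prediction — no retraining per horizon.

## Numerical and reproducibility notes

- One global seed fans out through SHA-256-derived named streams; every
  artefact records the configuration hash and seed that produced it;
  re-running any command is byte-identical (single-threaded numpy).
- Max-pooling gradients flow to the first argmax; elementwise-max ties
  route to the left operand. R2C tie-breaks are ascending class index.
- Softmax rows are computed in float64 for exact normalisation checks;
  CE uses the log-sum-exp form.
- Degenerate inputs fail loudly: empty timelines, EOS in annotations,
  non-monotone frame indices, vocabulary mismatches between checkpoint
  and data, NaN losses.

## Known limitations

- The AR decoder re-encodes its full prefix each step (O(N²) attention);
  fine at N ≤ 30, wasteful beyond.
- The observation model cannot express within-phase progress, which
  bounds how well remaining-time regression can do far from a phase
  boundary; the deterministic benchmark is designed so boundaries are
  always in view.
- Naive2's per-minute draws are independent by construction (a joint
  sampler is out of scope), which is exactly what the fragmentation
  statistic measures.
- No GPU path and no video/vision encoder: external per-frame features
  are consumed through the same interface as simulated observations.
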