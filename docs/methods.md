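# Methods

## Problem and model

A single IMU fixed at the sacrum (x cranial, y lateral, z posterior)
records 3-axis acceleration (g) and angular velocity (deg/s) at 280 Hz
during pool training. The task is frame-wise classification of the stream
into eight activities — the four stroke techniques plus wallpush,
underwater, turn and rest — at 0.02 s resolution, and the derivation of
typed lap times from the class transitions.

The classifier is a stacked bidirectional LSTM. Each 1.8 s window of the
preprocessed 50 Hz signal is presented with the **six channels as the
recurrent sequence axis** and the 90 frames of each channel as that step's
feature vector. This unconventional orientation is deliberate: it is the
only layout consistent with the pinned per-layer parameter counts
(first layer 2·4·64·(90+64+1) = 79,360; a frames-as-time layout is
available via `ModelConfig(layout="frames_as_time")` but yields a
different parameter budget and is rejected by the `strict_paper` build).
The stack is 64/32/16/16 units per direction with dropout 0.25 and
recurrent dropout 0.25, the last recurrent layer returning only its final
states (32 features), then dense-50 (ReLU), batch normalisation,
dropout 0.5, dense-8 softmax — 139,474 parameters in total.

Training: Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷), sparse categorical
cross-entropy, Xavier uniform initialisation with unit forget-gate bias,
batch size 64, 10 epochs, learning rate scheduled per epoch as

    α(e) = 0.001 · 800^(−e/100),

i.e. starting at 10⁻³ and declining by a factor 800^(1/100) ≈ 1.07 per
epoch. The published form of this schedule is typographically garbled;
this closed form satisfies the stated initial value and monotone decline
and is pluggable (`TrainingConfig.lr_decay_base/scale`). An optional
inverse-frequency class weighting of the loss is off by default.

The engine is pure NumPy. LSTM backpropagation-through-time, the
bidirectional wrapper, batch-norm and dense gradients are hand-derived and
checked against central finite differences (`tests/test_nn.py`); training
is bit-deterministic given the seed in single-threaded execution. Batch
normalisation keeps moving statistics (momentum 0.99, ε 10⁻³) that are
frozen at inference. Dropout masks are drawn once per sequence and shared
across time steps, with inverted scaling.

## Preprocessing

Fixed order: low-pass → resample → standardise.

* **Filter**: second-order Butterworth, 10 Hz cutoff, applied
  forward-backward (zero phase). A causal filter's group delay would shift
  every phase boundary — and hence every lap time — by a rate-dependent
  lag, so the zero-phase variant is used; the effective magnitude response
  is the square of the single-pass response (amplitude 0.5 at the cutoff).
* **Resampling** 280 → 50 Hz (non-integer factor 5.6): linear
  interpolation onto the uniform 50 Hz grid. The 10 Hz low-pass already
  guarantees band-limitation far below the 25 Hz target Nyquist, making
  interpolation error (≲10⁻⁴ of amplitude at the dominant frequencies)
  negligible against sensor noise.
* **Standardisation**: per-channel (x − mean)/sd with the sample (n−1)
  standard deviation, fitted by pooling all frames of the *training*
  subjects only and applied unchanged to validation/test subjects
  (`scaler_scope="all"` pools over everyone instead, at the cost of
  leaking test statistics into training).

Whether standardisation precedes or follows downsampling is not
observable in the result at these bandwidths; the order above is fixed for
reproducibility.

## Windowing

90-frame windows, stride 1, target = class of the median frame (0-based
index 45). Edge frames are handled by replicating the boundary frame 45
times before the start and 44 after the end, so every frame of a session
receives exactly one prediction. Training may use a larger stride purely
to thin the dataset; stride never changes semantics.

## Label filtering

Raw per-frame predictions contain short implausible blips. The filter
iteratively selects the shortest interior segment whose duration is below
its class minimum, reassigns its frames to the longer of its two
neighbours (ties to the preceding segment), merges, and repeats to
fixpoint; first/last segments of a session are exempt because a recording
may be cropped mid-phase. Each step removes at least one segment, so
termination is guaranteed; an iteration guard warns rather than loops.

Per-class minimum durations are policy, not physiology. Library defaults
(WP 0.2 s, UN 0.5 s, TU 0.6 s, RS 1.0 s, strokes 1.5 s) suit sessions at
moderate pace; the benchmark pipeline uses explicit minima set to roughly
half the shortest scheduled phase duration (notably TU 0.25 s, WP 0.10 s),
because a threshold above the shortest genuine phase — e.g. a
maximal-pace turn — erases real segments and merges laps.

## Lap timing

A session decomposes into swim blocks separated by rest. Anchors:

* block start — end of the initial wall-push segment; if none was
  detected, the first underwater frame (fallback);
* per turn, for butterfly/breaststroke — the first turn frame (the rules
  of those techniques require a wall touch, which turn onset proxies);
* per turn, for front crawl/backstroke — the end of the post-turn wall
  push when present, else the first post-turn underwater frame, else the
  turn end;
* block end — the first rest frame.

One lap per inter-anchor interval; the first of a block is START, the one
ending at rest END, others MIDDLE; a single-lap block is an END lap (it
terminates at rest). A lap's technique is the dominant stroke class among
its frames, which is robust to brief misclassifications and handles
medley blocks naturally. All indices are half-open, times are
frame/rate, so durations are exact at the sequence's resolution.

## Agreement statistics

F1 is the harmonic mean 2PR/(P+R) (0 when P+R = 0); weighted averages use
class supports. For paired lap durations: bias = mean(device − reference)
with a t-based 95% CI (n−1 df); TEM = sd(differences)/√2 with a 95% CI
obtained from the chi-squared sampling distribution of (n−1)s²/σ²;
Bland–Altman limits bias ± 1.96·sd (fixed multiplier, no
proportional-bias regression); MAPE = mean(|device−ref|/ref)·100 with the
SD of the per-pair absolute percentage errors, and a seconds form
(MAPE/100)·mean(ref). CI conventions are stated here because "typical
error" and its interval have several variants in the field.

## Synthetic data

The simulator emulates the *structure* of instrumented pool sessions, not
swimming biomechanics:

* **Grammar** — per block: WP → UN → stroke → (TU → [WP] → UN → stroke)*
  → RS; the post-turn wall push is optional (off by default).
* **Signals** — per-phase orientation baselines (the posterior-axis
  gravity component flips sign between prone strokes and backstroke, and
  rest is upright), technique-specific 1–2-harmonic oscillations (default
  base frequencies BU 0.9, BA 0.7, BR 0.55, FR 0.75 Hz with distinct
  channel weightings: roll on gx for BA/FR, surge harmonics on ax for BR,
  undulation on az/gy for BU), a half-sine 1.3 g wall-push impulse on ax,
  a 250 deg/s half-sine turn burst on gz/gx, and a decaying ~2 Hz
  underwater undulation. Additive Gaussian noise (0.05 g / 5 deg/s per
  channel) with optional AR(1) colouring and optional slow gyroscope
  drift (both off by default).
* **Variability** — four pace levels scale phase durations down
  (multipliers 1.15/1.00/0.90/0.82 relative to moderate) and stroke
  frequency/amplitude up; subjects differ by amplitude (U(0.8, 1.25)) and
  frequency (U(0.85, 1.15)) scale factors plus per-subject pace jitter.
* **Ground truth** — labels are emitted with the signal from the same
  phase schedule, and the lap table is computed from that schedule with
  the same anchor conventions the lap-timing module applies to labels, so
  the two routes are independently coded and comparable to the frame.

No phase amplitudes or stroke frequencies of the original protocol are
published, so every primitive parameter is a placeholder chosen once for
spectral plausibility and class separability, and all are overridable per
`PhaseModel`. Consequently, passing benchmarks demonstrate that the
pipeline is correct and that the architecture can learn and generalise
across subjects *under these conditions*; they do not certify performance
on real swimmers, where soft-tissue artefact, inter-stroke irregularity
and ambiguous phase boundaries make the problem harder (visible in the
original study's weaker wall-push and turn scores).

## Problem sizes and determinism

The desk-scale benchmark (tests and `scripts/acceptance.py`) uses a
6-subject cohort, one pace-ladder block per technique (4 laps each,
low → maximal pace, 20 s rests; ≈ 6 minutes of signal per subject),
training stride 4, 10 epochs, three seed replicates — sized so the full
pipeline, running on the NumPy engine with one CPU, completes a replicate
in under a minute. Larger cohorts and the full 7-block protocol
(`protocol_plan()`: 3 medleys + 4 pace ladders, ≈ 13 minutes per subject)
scale linearly.

All randomness — simulator schedules and noise, subject profiles, weight
initialisation, shuffling, dropout — flows from explicit integer seeds;
there is no global random state. Derived seeds stay below 2³¹.

## Known limitations

* The minimum-duration filter is a declared reinterpretation of the
  unpublished artefact-removal procedure the original workflow used; the
  policy object isolates the rule so alternatives can be plugged in.
* No probabilistic smoothing (HMM/Viterbi) of predictions.
* No diving starts, leg-kick phases, or classes beyond the eight.
* MAPE requires strictly positive reference durations; degenerate blocks
  (no stroke frames, no terminating rest) yield no lap records rather
  than guesses.
* The simulator's separability is by construction; see above for what
  that does and does not demonstrate.
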