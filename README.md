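# swimlap

Swimming activity recognition and lap timing from a single sacrum-worn
inertial measurement unit (IMU).

Coaches and sports scientists monitoring pool training want, per swimmer
and per session: what was swum (technique), when each lap started and
ended, how long the turns and underwater phases lasted, and how much rest
was taken — without cameras or stopwatches. `swimlap` implements a
deep-learning pipeline that extracts all of this from one 6-channel
inertial stream (3-axis accelerometer in g, 3-axis gyroscope in deg/s,
280 Hz) recorded at the sacrum:

1. **Conditioning** — second-order zero-phase Butterworth low-pass at
   10 Hz, downsampling to a 50 Hz working rate, per-channel
   standardisation `x' = (x − x̄)/σ` with statistics fitted on training
   subjects only.
2. **Windowing** — a sliding window of 90 frames (1.8 s) per prediction,
   labelled with the class of its median frame (index 45), so the model
   emits one label every 0.02 s.
3. **Classification** — a stacked bidirectional LSTM
   (64 → 32 → 16 → 16 units per direction, dropout and recurrent dropout
   0.25) followed by a dense-50 ReLU layer with batch normalisation and
   dropout 0.5 and a softmax over the 8 activity classes: wallpush (WP),
   underwater (UN), butterfly (BU), backstroke (BA), breaststroke (BR),
   front crawl (FR), turn (TU), rest (RS). Trained with Adam, sparse
   categorical cross-entropy, Xavier uniform initialisation, batch 64,
   10 epochs, learning rate α(e) = 10⁻³ · 800^(−e/100). The per-layer
   parameter counts are pinned (79,360 / 41,216 / 10,368 / 6,272 / 0 /
   1,650 / 200 / 408; bidirectional closed form 2·4u·(d+u+1)) and a
   `strict_paper` build refuses any deviation. The network and its
   training loop are implemented in NumPy with hand-derived
   backpropagation, verified against finite differences in the tests.
4. **Label filtering** — minimum-duration cleaning of the raw prediction
   sequence: the shortest interior segment violating its class minimum is
   merged into its longer neighbour, to fixpoint.
5. **Lap timing** — typed lap records (START / MIDDLE / END) from class
   transitions: wall-push end (or first underwater frame) anchors for
   front crawl and backstroke, turn-onset anchors for butterfly and
   breaststroke, first rest frame at block end.
6. **Agreement statistics** — frame-wise precision/recall/F1 and confusion
   matrix; paired lap-time bias ± 95% CI, typical error of measurement
   (TEM = sd(diff)/√2) ± 95% CI, Bland–Altman limits of agreement, and
   MAPE ± SD in percent and seconds.

Because no public recording of this protocol exists, the package ships a
**synthetic session simulator** (`swimlap.simulate`) that emits raw 280 Hz
signals, per-frame ground-truth labels and exact lap tables for
phase-structured sessions (wallpush → underwater → stroke → turn → … →
rest), with four technique-specific oscillation signatures, four pace
levels, inter-subject variability and sensor noise. Every downstream stage
is tested against it.

## Worked example

`examples/03_train_and_classify.py` simulates a 6-subject cohort
(~2 minutes of signal each), trains for 6 epochs with subject-wise splits
and scores the held-out swimmer:

```
held-out subject: S04
weighted F1 raw prediction:      0.986
weighted F1 after filtering:     0.986

per-class F1 (filtered):
  WALLPUSH     f1=0.351  support=45
  UNDERWATER   f1=0.980  support=1337
  BACKSTROKE   f1=0.997  support=1465
  BREASTSTROKE f1=0.989  support=1395
  FRONTCRAWL   f1=0.998  support=1284
  TURN         f1=0.949  support=226
  REST         f1=0.992  support=1500

lap times (9 pairs): MAPE 0.87% (0.11 s), bias +0.062 s, TEM 0.105 s
```

Stroke, underwater and rest phases are recognised almost perfectly on a
swimmer the model never saw; the sub-second wall push is the hard class
(its frames are rare and its signature overlaps the adjacent phases), and
lap boundaries land within about a tenth of a second of the ground truth.
The other examples cover simulation (`01`), signal conditioning and
windowing (`02`), and lap-time agreement statistics (`04`).

A thin CLI wires the same stages to files:

```bash
swimlap simulate --seed 1 --out-dir data/
swimlap train --data-dir data/ --out-dir run/ --strict-paper
swimlap predict --model run/model --imu data/S01_sess0_imu.csv --out pred.csv
swimlap laptimes --labels pred.csv --rate 50 --out laps.csv
swimlap evaluate --pred-laps laps.csv --ref-laps data/S01_sess0_laps.csv --out report.json
```

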