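"""Condition a raw recording and cut it into classifier windows.

Shows the fixed pipeline order — 10 Hz second-order zero-phase Butterworth,
280 -> 50 Hz resampling, per-channel standardisation — and the resulting
window tensor the network consumes.
"""

from swimlap import (
    SessionPlan,
    SubjectProfile,
    butterworth_lowpass,
    fit_scaler,
    generate_session,
    make_windows,
    medley_block,
    preprocess,
    resample_to,
)
from swimlap.pipeline import resample_labels

session = generate_session(
    SessionPlan([medley_block(rest_s=20.0)]), SubjectProfile("S01"), seed=7
)
raw = session.recording
print(f"raw:          {raw.n_frames} frames @ {raw.sample_rate:.0f} Hz")

filtered = butterworth_lowpass(raw, cutoff_hz=10.0, order=2)
down = resample_to(filtered, 50.0)
print(f"conditioned:  {down.n_frames} frames @ {down.sample_rate:.0f} Hz")

# the scaler is fitted on (conditioned) training data and applied unchanged
scaler = fit_scaler([down])
rec = preprocess(raw, scaler)
print(f"standardised: per-channel mean ~ {rec.samples.mean(axis=0).round(6)}")
print(f"              per-channel sd   ~ {rec.samples.std(axis=0, ddof=1).round(6)}")

labels50 = resample_labels(session.labels, 50.0)
batch = make_windows(rec, labels50, stride=1, pad_edges=True)
print(f"\nwindows: tensor {batch.tensor.shape}  (windows, channel steps, frame features)")
print("one window spans 90 frames = 1.8 s; its target is the class of the")
print(f"median frame (index 45). Example targets: {batch.targets[:10]}")
# With edge padding there is exactly one window per 0.02 s frame, so the
# classifier can emit a label at every time step of the session.
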