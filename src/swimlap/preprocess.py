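"""Signal conditioning for raw IMU streams.

The pipeline is fixed as: second-order Butterworth low-pass at 10 Hz
(applied forward-backward, i.e. zero phase), downsampling from the 280 Hz
sensor rate to a 50 Hz working rate, then per-channel standardisation
(x - mean) / sd with the scaler fitted on training subjects and applied
unchanged elsewhere.

Zero-phase filtering is chosen deliberately: a causal filter's group delay
would shift every detected phase boundary (and hence every lap time) by a
rate-dependent lag. The price is that the effective magnitude response is
the square of the single-pass response, so the half-power point of the
single-pass design becomes a factor 0.5 in amplitude at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .activities import CHANNELS, ImuRecording, WORKING_RATE_HZ

__all__ = [
    "ChannelScaler",
    "butterworth_lowpass",
    "resample_to",
    "fit_scaler",
    "apply_scaler",
    "preprocess",
]

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 2


@dataclass
class ChannelScaler:
    """Per-channel mean and standard deviation (ddof=1) for standardisation."""

    means: np.ndarray
    sds: np.ndarray
    fitted_on: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.sds = np.asarray(self.sds, dtype=float).ravel()
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have the same length")
        if np.any(self.sds <= 0):
            raise ValueError("scaler standard deviations must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "fitted_on": list(self.fitted_on),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScaler":
        return cls(np.asarray(d["means"]), np.asarray(d["sds"]), list(d.get("fitted_on", [])))


def butterworth_lowpass(
    rec: ImuRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> ImuRecording:
    """Zero-phase Butterworth low-pass, same shape and rate as the input."""
    nyquist = rec.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate, output="sos")
    # padlen capped for very short recordings; sosfiltfilt handles edges by
    # odd reflection which keeps DC exactly.
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.with_samples(np.ascontiguousarray(filtered))


def resample_to(rec: ImuRecording, target_rate: float = WORKING_RATE_HZ) -> ImuRecording:
    """Resample onto a uniform ``target_rate`` grid by interpolation.

    Assumes the signal is already band-limited below the target Nyquist
    (the 10 Hz low-pass guarantees this for the 50 Hz working rate), so
    plain polynomial interpolation on the dense 280 Hz grid is accurate to
    well below sensor noise. Upsampling is refused.
    """
    if target_rate > rec.sample_rate:
        raise ValueError(
            f"upsampling unsupported: target {target_rate} Hz > source {rec.sample_rate} Hz"
        )
    if target_rate == rec.sample_rate:
        return rec
    n_out = int(round(rec.n_frames * target_rate / rec.sample_rate))
    n_out = max(n_out, 1)
    t_in = rec.times()
    t_out = np.arange(n_out) / target_rate
    out = np.empty((n_out, rec.samples.shape[1]))
    for j in range(rec.samples.shape[1]):
        out[:, j] = np.interp(t_out, t_in, rec.samples[:, j])
    return rec.with_samples(out, sample_rate=float(target_rate))


def fit_scaler(recs: list[ImuRecording]) -> ChannelScaler:
    """Pool all frames of all given recordings and fit per-channel mean/sd."""
    if not recs:
        raise ValueError("need at least one recording to fit a scaler")
    pooled = np.concatenate([r.samples for r in recs], axis=0)
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [CHANNELS[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"zero-variance channel(s): {', '.join(bad)}")
    return ChannelScaler(means, sds, fitted_on=[r.subject_id for r in recs])


def apply_scaler(rec: ImuRecording, scaler: ChannelScaler) -> ImuRecording:
    """Standardise each channel: (x - mean) / sd. Marks the result preprocessed."""
    if rec.samples.shape[1] != scaler.means.size:
        raise ValueError(
            f"channel-count mismatch: recording has {rec.samples.shape[1]}, "
            f"scaler was fitted on {scaler.means.size}"
        )
    out = (rec.samples - scaler.means) / scaler.sds
    return rec.with_samples(out, preprocessed=True)


def preprocess(
    rec: ImuRecording,
    scaler: ChannelScaler | None = None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    target_rate: float = WORKING_RATE_HZ,
) -> ImuRecording:
    """Full conditioning pipeline: filter, then resample, then standardise.

    If ``scaler`` is None the filtered/resampled recording is returned
    unstandardised (used when accumulating recordings to fit a scaler on).
    """
    out = butterworth_lowpass(rec, cutoff_hz=cutoff_hz, order=order)
    out = resample_to(out, target_rate)
    if scaler is not None:
        out = apply_scaler(out, scaler)
    else:
        out = out.with_samples(out.samples, preprocessed=True)
    return out
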