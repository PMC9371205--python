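"""Shared domain types: the 8-class activity vocabulary, IMU recordings,
per-frame label sequences and their run-length (segment) encoding.

The activity vocabulary covers one pool-swimming training session recorded
by a single sacrum-mounted inertial sensor: the four stroke techniques plus
the transitional micro-phases (wall push, underwater glide, turn) and rest.
Frame indexing is 0-based throughout and segments are half-open
``[start, end)``, so durations are exactly ``(end - start) / rate`` seconds
and consecutive segments tile the frame range without gaps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ActivityClass",
    "STROKES",
    "ImuRecording",
    "LabelSequence",
    "Segment",
    "labels_to_segments",
    "segments_to_labels",
    "CHANNELS",
]

#: Canonical channel order of every recording: accelerometer (g) then
#: gyroscope (deg/s), x cranial, y lateral, z posterior.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")


class ActivityClass(enum.IntEnum):
    """The eight swimming-activity classes, with stable codes 0..7.

    Codes double as the network's target indices, so their values must
    never change across serialisation.
    """

    WALLPUSH = 0
    UNDERWATER = 1
    BUTTERFLY = 2
    BACKSTROKE = 3
    BREASTSTROKE = 4
    FRONTCRAWL = 5
    TURN = 6
    REST = 7

    @property
    def short(self) -> str:
        return _SHORT[self]

    @property
    def is_stroke(self) -> bool:
        """True for the four stroke techniques (BU, BA, BR, FR)."""
        return self in STROKES

    @classmethod
    def from_token(cls, token: str) -> "ActivityClass":
        """Parse either a full name ('FRONTCRAWL') or short code ('FR')."""
        t = str(token).strip().upper()
        if t in cls.__members__:
            return cls[t]
        if t in _FROM_SHORT:
            return _FROM_SHORT[t]
        raise ValueError(f"unknown activity class token: {token!r}")


_SHORT = {
    ActivityClass.WALLPUSH: "WP",
    ActivityClass.UNDERWATER: "UN",
    ActivityClass.BUTTERFLY: "BU",
    ActivityClass.BACKSTROKE: "BA",
    ActivityClass.BREASTSTROKE: "BR",
    ActivityClass.FRONTCRAWL: "FR",
    ActivityClass.TURN: "TU",
    ActivityClass.REST: "RS",
}
_FROM_SHORT = {v: k for k, v in _SHORT.items()}

#: The four stroke techniques, in the order they are swum in a medley.
STROKES = (
    ActivityClass.BUTTERFLY,
    ActivityClass.BACKSTROKE,
    ActivityClass.BREASTSTROKE,
    ActivityClass.FRONTCRAWL,
)

N_CLASSES = 8

RAW_RATE_HZ = 280.0
WORKING_RATE_HZ = 50.0


@dataclass
class ImuRecording:
    """A 6-channel uniformly sampled inertial time series.

    samples has shape (frames, 6) in the :data:`CHANNELS` order, with the
    accelerometer in g and the gyroscope in deg/s. ``preprocessed``
    distinguishes the raw sensor stream (280 Hz by default) from the
    filtered / resampled / standardised stream the classifier consumes
    (50 Hz by default).
    """

    samples: np.ndarray
    sample_rate: float = RAW_RATE_HZ
    subject_id: str = "S00"
    session_id: str = "sess0"
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNELS):
            raise ValueError(
                f"samples must have shape (frames, 6), got {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one frame")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate

    def times(self) -> np.ndarray:
        """Time of each frame in seconds from session start (frame k at k/rate)."""
        return np.arange(self.n_frames) / self.sample_rate

    def with_samples(self, samples: np.ndarray, **changes) -> "ImuRecording":
        return replace(self, samples=samples, **changes)


Provenance = ("ground_truth", "raw_prediction", "filtered_prediction")


@dataclass
class LabelSequence:
    """Per-frame activity classes aligned to a recording."""

    labels: np.ndarray
    sample_rate: float = WORKING_RATE_HZ
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.labels.size == 0:
            raise ValueError("label sequence has no frames")
        if self.labels.min() < 0 or self.labels.max() >= N_CLASSES:
            raise ValueError("label codes must lie in 0..7")
        if self.provenance not in Provenance:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def classes(self) -> list[ActivityClass]:
        return [ActivityClass(c) for c in self.labels]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelSequence):
            return NotImplemented
        return (
            self.sample_rate == other.sample_rate
            and self.provenance == other.provenance
            and np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class Segment:
    """One maximal run of a single class, half-open [start_frame, end_frame)."""

    activity: ActivityClass
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError(
                f"segment must satisfy start < end, got [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_s(self, rate: float) -> float:
        return self.n_frames / rate


def labels_to_segments(seq: LabelSequence) -> list[Segment]:
    """Run-length encode a label sequence into maximal single-class segments."""
    lab = seq.labels
    if lab.size == 0:
        raise ValueError("cannot segment an empty label sequence")
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lab.size]))
    return [
        Segment(ActivityClass(int(lab[s])), int(s), int(e))
        for s, e in zip(starts, ends)
    ]


def segments_to_labels(
    segs: Sequence[Segment],
    rate: float = WORKING_RATE_HZ,
    provenance: str = "ground_truth",
) -> LabelSequence:
    """Inverse of :func:`labels_to_segments`.

    Segments must tile a contiguous range starting at frame 0; any gap or
    overlap is an error.
    """
    if not segs:
        raise ValueError("no segments given")
    expected = 0
    for s in segs:
        if s.start_frame != expected:
            raise ValueError(
                f"segments must tile contiguously from 0: expected start "
                f"{expected}, got {s.start_frame}"
            )
        expected = s.end_frame
    labels = np.empty(expected, dtype=np.int64)
    for s in segs:
        labels[s.start_frame : s.end_frame] = int(s.activity)
    return LabelSequence(labels, sample_rate=rate, provenance=provenance)
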