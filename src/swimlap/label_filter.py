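"""Post-prediction cleaning of raw per-frame activity sequences.

A frame-wise classifier occasionally emits physically implausible blips —
a three-frame turn in the middle of a front-crawl lap, say. This module
removes them with a minimum-duration rule: iteratively locate the shortest
interior segment lasting less than its class minimum, hand its frames to
the longer of its two neighbours (ties go to the preceding segment), merge,
and repeat until no interior segment violates its minimum. The first and
last segments of a session are exempt, since a recording may legitimately
begin or end mid-phase after cropping.

The per-class minimum durations are tunable policy, not physiology carved
in stone; the defaults reflect rough phase durations in 25 m pool swimming
(a wall push is a fraction of a second, a stroke bout many seconds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .activities import (
    ActivityClass,
    LabelSequence,
    Segment,
    labels_to_segments,
    segments_to_labels,
)

__all__ = ["FilterPolicy", "filter_predictions", "DEFAULT_MIN_DURATIONS_S"]

DEFAULT_MIN_DURATIONS_S: dict[ActivityClass, float] = {
    ActivityClass.WALLPUSH: 0.2,
    ActivityClass.UNDERWATER: 0.5,
    ActivityClass.TURN: 0.6,
    ActivityClass.REST: 1.0,
    ActivityClass.BUTTERFLY: 1.5,
    ActivityClass.BACKSTROKE: 1.5,
    ActivityClass.BREASTSTROKE: 1.5,
    ActivityClass.FRONTCRAWL: 1.5,
}


@dataclass
class FilterPolicy:
    """Per-class minimum segment durations (seconds) and iteration guard."""

    min_duration_s: dict[ActivityClass, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_DURATIONS_S)
    )
    max_iterations: int | None = None
    exempt_boundaries: bool = True

    def __post_init__(self) -> None:
        for cls, dur in self.min_duration_s.items():
            if dur <= 0:
                raise ValueError(f"minimum duration for {cls.name} must be > 0")

    def min_frames(self, cls: ActivityClass, rate: float) -> float:
        return self.min_duration_s.get(ActivityClass(cls), 0.0) * rate


def _violations(segs: list[Segment], policy: FilterPolicy, rate: float) -> list[int]:
    lo = 1 if policy.exempt_boundaries else 0
    hi = len(segs) - 1 if policy.exempt_boundaries else len(segs)
    return [
        k
        for k in range(lo, hi)
        if segs[k].n_frames < policy.min_frames(segs[k].activity, rate) - 1e-9
    ]


def filter_predictions(
    raw: LabelSequence, policy: FilterPolicy | None = None
) -> LabelSequence:
    """Return a cleaned copy of ``raw`` with no under-length interior segment.

    Frame count and timebase are preserved; only labels change. The result
    is a fixpoint: filtering it again is the identity.
    """
    policy = policy or FilterPolicy()
    rate = raw.sample_rate
    segs = labels_to_segments(raw)
    max_iter = policy.max_iterations or len(segs) + 1
    for _ in range(max_iter):
        bad = _violations(segs, policy, rate)
        if not bad:
            break
        # shortest violating segment first; ties broken by position
        k = min(bad, key=lambda i: (segs[i].n_frames, i))
        seg = segs[k]
        prev_seg = segs[k - 1] if k > 0 else None
        next_seg = segs[k + 1] if k + 1 < len(segs) else None
        if prev_seg is not None and (
            next_seg is None or prev_seg.n_frames >= next_seg.n_frames
        ):
            absorber, into_prev = prev_seg, True
        else:
            absorber, into_prev = next_seg, False
        if into_prev:
            merged = Segment(absorber.activity, absorber.start_frame, seg.end_frame)
            segs[k - 1 : k + 1] = [merged]
        else:
            merged = Segment(absorber.activity, seg.start_frame, absorber.end_frame)
            segs[k : k + 2] = [merged]
        segs = _coalesce(segs)
    else:
        warnings.warn(
            "label filter hit its iteration guard before reaching a fixpoint",
            RuntimeWarning,
            stacklevel=2,
        )
    out = segments_to_labels(segs, rate=rate, provenance="filtered_prediction")
    return out


def _coalesce(segs: list[Segment]) -> list[Segment]:
    """Merge adjacent segments that ended up with the same class."""
    out = [segs[0]]
    for s in segs[1:]:
        if s.activity == out[-1].activity:
            out[-1] = Segment(out[-1].activity, out[-1].start_frame, s.end_frame)
        else:
            out.append(s)
    return out
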