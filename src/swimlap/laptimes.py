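"""Typed lap times derived from class transitions of a label sequence.

A session decomposes into swim blocks separated by rest. Within a block,
lap boundaries are anchored on class transitions:

* block start — the end of the initial wall push (last wall-push frame);
  if no wall-push segment was detected, the first underwater frame.
* intermediate boundaries — one per turn. For butterfly and breaststroke
  the anchor is the first turn frame (the rules of those techniques require
  a hand touch at the wall, which the turn onset proxies). For front crawl
  and backstroke the anchor is the end of the post-turn wall push when one
  exists, else the first post-turn underwater frame, else the turn end.
* block end — the first rest frame.

One lap record is emitted per inter-anchor interval: the first of a block
is typed START, the one terminating at rest END, the others MIDDLE; a
single-lap block is typed END (it terminates at rest). The technique of a
lap is the dominant stroke class among its frames, which is robust to brief
misclassified stroke frames and naturally handles medley blocks where each
lap is swum in a different technique.

All frame indices are half-open and timed as frame/rate seconds, so a lap
duration is exact at the sequence's temporal resolution (0.02 s at the
50 Hz working rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import (
    ActivityClass,
    LabelSequence,
    Segment,
    STROKES,
    labels_to_segments,
)

__all__ = [
    "LapRecord",
    "BoundaryEvent",
    "PairedLaps",
    "detect_boundaries",
    "compute_lap_times",
    "pair_lap_tables",
]

LAP_TYPES = ("START", "MIDDLE", "END")


@dataclass
class LapRecord:
    technique: ActivityClass
    lap_type: str
    start_frame: int
    end_frame: int
    sample_rate: float
    block_index: int = 0
    lap_index: int = 0
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.lap_type not in LAP_TYPES:
            raise ValueError(f"lap_type must be one of {LAP_TYPES}")
        if self.end_frame <= self.start_frame:
            raise ValueError("lap must have positive duration")
        self.technique = ActivityClass(self.technique)

    @property
    def start_s(self) -> float:
        return self.start_frame / self.sample_rate

    @property
    def end_s(self) -> float:
        return self.end_frame / self.sample_rate

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.sample_rate


@dataclass(frozen=True)
class BoundaryEvent:
    frame: int
    kind: str  # wallpush_end | underwater_start | turn_start | turn_end | rest_start
    block_index: int = 0


def _blocks(segs: list[Segment]) -> list[list[Segment]]:
    """Split a segment list into swim blocks (runs between REST segments
    that contain at least one stroke segment)."""
    blocks: list[list[Segment]] = []
    current: list[Segment] = []
    for s in segs:
        if s.activity == ActivityClass.REST:
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(s)
    if current:
        blocks.append(current)
    return [b for b in blocks if any(s.activity.is_stroke for s in b)]


def _block_anchors(block: list[Segment], segs: list[Segment], block_index: int) -> list[BoundaryEvent]:
    """Anchor events of one block, in frame order.

    ``segs`` is the full session segmentation, used to find the rest
    segment that terminates the block.
    """
    events: list[BoundaryEvent] = []
    first_stroke = next(i for i, s in enumerate(block) if s.activity.is_stroke)
    lead = block[:first_stroke]
    wp = [s for s in lead if s.activity == ActivityClass.WALLPUSH]
    un = [s for s in lead if s.activity == ActivityClass.UNDERWATER]
    if wp:
        events.append(BoundaryEvent(wp[-1].end_frame, "wallpush_end", block_index))
    elif un:
        events.append(BoundaryEvent(un[0].start_frame, "underwater_start", block_index))
    else:
        events.append(BoundaryEvent(block[first_stroke].start_frame, "underwater_start", block_index))

    for i, s in enumerate(block):
        if s.activity != ActivityClass.TURN:
            continue
        before = [t for t in block[:i] if t.activity.is_stroke]
        if not before:
            continue
        prev_stroke = before[-1].activity
        if prev_stroke in (ActivityClass.BUTTERFLY, ActivityClass.BREASTSTROKE):
            events.append(BoundaryEvent(s.start_frame, "turn_start", block_index))
            continue
        # front crawl / backstroke: anchor after the turn
        after = block[i + 1 :]
        next_stroke_i = next(
            (j for j, t in enumerate(after) if t.activity.is_stroke), len(after)
        )
        between = after[:next_stroke_i]
        wp_after = [t for t in between if t.activity == ActivityClass.WALLPUSH]
        un_after = [t for t in between if t.activity == ActivityClass.UNDERWATER]
        if wp_after:
            events.append(BoundaryEvent(wp_after[-1].end_frame, "wallpush_end", block_index))
        elif un_after:
            events.append(BoundaryEvent(un_after[0].start_frame, "underwater_start", block_index))
        else:
            events.append(BoundaryEvent(s.end_frame, "turn_end", block_index))

    # terminating rest: first REST frame after the block's last segment
    last_end = block[-1].end_frame
    rest = next(
        (s for s in segs if s.activity == ActivityClass.REST and s.start_frame >= last_end),
        None,
    )
    if rest is not None:
        events.append(BoundaryEvent(rest.start_frame, "rest_start", block_index))
    return events


def detect_boundaries(
    seq: LabelSequence, technique: ActivityClass | None = None
) -> list[BoundaryEvent]:
    """All lap-boundary anchor events, optionally restricted to blocks that
    contain the given stroke technique."""
    if technique is not None and not ActivityClass(technique).is_stroke:
        raise ValueError("technique must be a stroke class")
    segs = labels_to_segments(seq)
    events: list[BoundaryEvent] = []
    for bi, block in enumerate(_blocks(segs)):
        if technique is not None and not any(
            s.activity == technique for s in block
        ):
            continue
        events.extend(_block_anchors(block, segs, bi))
    return events


def _dominant_stroke(seq: LabelSequence, start: int, end: int) -> ActivityClass | None:
    counts = np.bincount(seq.labels[start:end], minlength=8)
    stroke_counts = {c: counts[int(c)] for c in STROKES}
    best = max(stroke_counts, key=lambda c: stroke_counts[c])
    if stroke_counts[best] == 0:
        return None
    return best


def compute_lap_times(
    seq: LabelSequence,
    subject_id: str = "",
    session_id: str = "",
) -> list[LapRecord]:
    """Derive the session's typed lap table from a (filtered or ground-truth)
    label sequence. Degenerate blocks with no complete inter-anchor interval
    yield no records."""
    segs = labels_to_segments(seq)
    laps: list[LapRecord] = []
    lap_index = 0
    for bi, block in enumerate(_blocks(segs)):
        anchors = _block_anchors(block, segs, bi)
        if len(anchors) < 2:
            continue
        n_laps = len(anchors) - 1
        for k in range(n_laps):
            a, b = anchors[k].frame, anchors[k + 1].frame
            if b <= a:
                continue
            technique = _dominant_stroke(seq, a, b)
            if technique is None:
                continue
            if k == n_laps - 1 and anchors[k + 1].kind == "rest_start":
                lap_type = "END"
            elif k == 0:
                lap_type = "START"
            else:
                lap_type = "MIDDLE"
            laps.append(
                LapRecord(
                    technique=technique,
                    lap_type=lap_type,
                    start_frame=a,
                    end_frame=b,
                    sample_rate=seq.sample_rate,
                    block_index=bi,
                    lap_index=lap_index,
                    subject_id=subject_id,
                    session_id=session_id,
                )
            )
            lap_index += 1
    return laps


@dataclass
class PairedLaps:
    """Order-preserving pairing of two lap tables from the same session."""

    pred_s: np.ndarray
    ref_s: np.ndarray
    pairs: list[tuple[LapRecord, LapRecord]] = field(default_factory=list)
    unmatched_pred: list[LapRecord] = field(default_factory=list)
    unmatched_ref: list[LapRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.pairs)


def pair_lap_tables(pred: list[LapRecord], ref: list[LapRecord]) -> PairedLaps:
    """Match laps by block order and within-block index; leftovers are
    reported unmatched and excluded from the paired vectors."""
    def by_block(laps):
        out: dict[int, list[LapRecord]] = {}
        for lap in laps:
            out.setdefault(lap.block_index, []).append(lap)
        return out

    pb, rb = by_block(pred), by_block(ref)
    pairs: list[tuple[LapRecord, LapRecord]] = []
    unmatched_pred: list[LapRecord] = []
    unmatched_ref: list[LapRecord] = []
    for block in sorted(set(pb) | set(rb)):
        p = pb.get(block, [])
        r = rb.get(block, [])
        m = min(len(p), len(r))
        pairs.extend(zip(p[:m], r[:m]))
        unmatched_pred.extend(p[m:])
        unmatched_ref.extend(r[m:])
    return PairedLaps(
        pred_s=np.array([a.duration_s for a, _ in pairs]),
        ref_s=np.array([b.duration_s for _, b in pairs]),
        pairs=pairs,
        unmatched_pred=unmatched_pred,
        unmatched_ref=unmatched_ref,
    )
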