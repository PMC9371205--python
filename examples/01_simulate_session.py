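"""Generate one synthetic swimming session and inspect its structure.

Builds a session with one moderate-pace medley block (butterfly,
backstroke, breaststroke, front crawl) followed by a pace-ladder front
crawl block, prints the phase segmentation and the ground-truth lap table.
"""

import numpy as np

from swimlap import (
    ActivityClass,
    SessionPlan,
    SubjectProfile,
    generate_session,
    labels_to_segments,
    medley_block,
    pace_ladder_block,
)

plan = SessionPlan([
    medley_block(rest_s=30.0),
    pace_ladder_block(ActivityClass.FRONTCRAWL, rest_s=30.0),
])
profile = SubjectProfile("S01", amplitude_scale=1.1, frequency_scale=0.95)
session = generate_session(plan, profile, seed=42)

rec, labels = session.recording, session.labels
print(f"recording: {rec.n_frames} frames at {rec.sample_rate:.0f} Hz "
      f"({rec.duration_s:.1f} s), channels (ax ay az gx gy gz)")

counts = np.bincount(labels.labels, minlength=8)
print("\nframes per class:")
for c in ActivityClass:
    print(f"  {c.short}: {counts[int(c)]:7d}  ({counts[int(c)] / rec.sample_rate:6.1f} s)")

print("\nphase segments (first block):")
for seg in labels_to_segments(labels)[:10]:
    print(f"  {seg.activity.short}  {seg.start_frame / rec.sample_rate:7.2f} -> "
          f"{seg.end_frame / rec.sample_rate:7.2f} s")

print("\nground-truth lap table (technique, type, duration):")
for lap in session.lap_table:
    print(f"  block {lap.block_index}  {lap.technique.short}  {lap.lap_type:6s}  "
          f"{lap.duration_s:6.2f} s")
# Each lap runs from one boundary anchor to the next (wall-push end or
# first underwater frame for crawl/backstroke, turn onset for fly/breast,
# first rest frame at block end), so durations are exact at 1/280 s.
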