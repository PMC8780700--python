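"""Generate a synthetic head-movement session and segment it.

The session emulates a user operating a scanning keyboard with lateral head
reaches: 8 valid reaches (each triggering the mechanical switch at peak
displacement) plus 6 distractor movements, with tracking-grade measurement
jitter.  Segmentation cuts the speed magnitude at zero-velocity crossings.
"""

import numpy as np

from headgest import segmentation, synth

cfg = synth.SessionConfig(n_valid_reaches=8, n_invalid_movements=6, seed=42)
session = synth.gen_session(cfg)
print(f"session: {len(session.observed)} samples at {cfg.frame_rate:.0f} Hz, "
      f"{len(session.truth_times)} switch events")

segments = segmentation.segment_trajectory(session.observed)
print(f"segmentation found {len(segments)} movement episodes:")
for i, seg in enumerate(segments):
    eps = np.hypot(seg.vx, seg.vy)
    print(f"  segment {i}: t=[{seg.start_t:6.2f}, {seg.end_t:6.2f}] s, "
          f"n_s={seg.n_s:3d}, peak speed {eps.max():6.1f} px/s")

# Every switch event should fall inside one segment: those are the reaches
# the classifiers must separate from the distractors.
inside = sum(
    any(s.start_t <= ts <= s.end_t for s in segments) for ts in session.truth_times
)
print(f"{inside}/{len(session.truth_times)} switch events covered by a segment")
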