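"""Calibrate the position-threshold classifier and detect activations.

The threshold x_t mimics a mechanical head switch: it is placed 20 px
closer to the rest position than the average maximum displacement of the
calibration reaches, and an activation fires whenever the head crosses it
(one event per excursion).
"""

from headgest import segmentation, synth, threshold

# calibration phase: the user performs reaching movements only
calib = synth.gen_session(synth.SessionConfig(n_valid_reaches=10, seed=1))
calib_segments = segmentation.segment_trajectory(calib.observed)
model = threshold.calibrate_threshold(calib_segments, x_h0=0.0)
print(f"calibrated from {len(calib_segments)} reaches: direction {model.direction:+d}, "
      f"x_t = {model.x_t:.1f} px (margin {model.margin_px:.0f} px)")

# operating phase: valid reaches mixed with half-amplitude distractors
session = synth.gen_session(
    synth.SessionConfig(n_valid_reaches=6, n_invalid_movements=6,
                        invalid_kind="half_amplitude", seed=2)
)
events = threshold.classify_threshold_stream(session.observed, model)
print(f"stream detector fired {len(events)} times; "
      f"ground truth has {len(session.truth_times)} switch events")

segments = segmentation.segment_trajectory(session.observed)
for i, seg in enumerate(segments):
    score = threshold.threshold_score(seg, model)
    decision = threshold.threshold_decision(seg, model)
    print(f"  segment {i}: excursion {score:6.1f} px -> {'VALID' if decision else 'invalid'}")
# Scores near the full reach amplitude are accepted; the half-amplitude
# distractors stay below the calibrated level and are rejected.
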