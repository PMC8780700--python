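"""Train the four-state HMM classifier and score segments with psi.

A reach is modelled as a left-to-right sequence of movement stages with
Gaussian emissions over position+velocity (PV) features.  New segments are
scored by the Mahalanobis distance of psi = [log-likelihood, length] under
a bivariate normal null fitted on the valid training segments; the decision
uses the chi-square(2) quantile at 95% confidence.
"""

import numpy as np

from headgest import evaluation, hmm, segmentation, synth

session = synth.gen_session(
    synth.SessionConfig(n_valid_reaches=14, n_invalid_movements=10,
                        invalid_kind="slow_matched", seed=3)
)
segments = segmentation.segment_trajectory(session.observed)
labels, _ = evaluation.label_segments(segments, session.truth_times)
valid = [s for s, lab in zip(segments, labels) if lab]
print(f"{len(segments)} segments, {len(valid)} valid (matched to switch events)")

clf, history = hmm.train_hmm_classifier(valid, feature_kind="PV", seed=0)
print(f"Baum-Welch: {len(history)} iterations, "
      f"log-likelihood {history[0]:.1f} -> {history[-1]:.1f}")
print("transition matrix (left-to-right):")
print(np.array_str(clf.model.transmat, precision=2, suppress_small=True))

print("psi null: mu =", np.round(clf.null.mu, 1), " decisions at 95% confidence:")
for i, (seg, lab) in enumerate(zip(segments, labels)):
    score, decision = hmm.classify_segment(seg, clf.model, clf.null)
    marker = "VALID  " if decision else "invalid"
    print(f"  segment {i}: score {score:8.2f} -> {marker} (truth: {'reach' if lab else 'distractor'})")
# The distractors match the reach amplitude but are 3x slower, so their
# velocity structure (and length) pushes psi far from the null.
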