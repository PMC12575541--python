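"""Remaining-time targets, the R2C mapping, and the regression metrics.

Shows how per-class remaining-time predictions become a minute-binned
phase sequence (sort-and-bin), and how in/out/wMAE score such predictions.
"""

import numpy as np

from phasecast import (PhaseVocabulary, RemainingTimePrediction,
                       anticipation_mae, r2c, remaining_time_target)
from phasecast import PhaseTimeline

voc = PhaseVocabulary.default()
# a toy ground truth: P1 for 2 min, P2 for 2 min, done
labels = np.concatenate([np.zeros(120, int), np.ones(120, int)])
tl = PhaseTimeline("toy", labels, voc)
target = remaining_time_target(tl, t=30, horizon_minutes=5)
print("targets at t=30 s (minutes until next occurrence, 5 = never):")
print({voc.names[c]: round(float(m), 2)
       for c, m in enumerate(target.minutes)})

# a slightly wrong prediction and its sort-and-bin phase sequence
pred = RemainingTimePrediction(
    minutes=np.array([0.0, 1.4, 5, 5, 5, 5, 5, 3.0]), horizon_minutes=5)
seq = r2c(pred, current_class=0, horizon_minutes=5)
print("R2C sequence:", [voc.names[c] for c in seq])
# the current phase fills bins until the first predicted occurrence
# (P2 at 1.4 min), then EOS at 3.0 min takes over

report = anticipation_mae(pred.minutes[None, :], target.minutes[None, :],
                          horizon=5)
print(f"wMAE {report.wmae:.3f}  inMAE {report.inmae:.3f}  "
      f"outMAE {report.outmae:.3f} (minutes)")
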