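"""Render the anticipation-timeline figure for one simulated procedure.

Columns are probe times, rows the anticipated future minutes; colours are
phases, grey is end-of-surgery.  Here the "model" is the Naive1
continuation baseline, which produces the characteristic solid diagonal
bands: whatever is happening now is predicted to continue.
"""

import numpy as np

from phasecast import (PhaseVocabulary, default_cholec_like_model,
                       naive1_predict, sample_workflow)
from phasecast.render import render_anticipation_timeline

voc = PhaseVocabulary.default()
tl = sample_workflow(default_cholec_like_model(voc), seed=8)
times = list(range(0, len(tl), 60))
grid = np.stack([naive1_predict(int(tl.labels[t]), 15) for t in times])
path = render_anticipation_timeline(grid, times, tl,
                                    "anticipation_timeline.png")
print(f"wrote {path} ({len(times)} probe columns, 15-minute horizon)")
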