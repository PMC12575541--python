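"""Simulate a surgical workflow and inspect its phase structure.

Samples one procedure from the cholecystectomy-like semi-Markov model,
prints its phase segments, and shows the per-second observation features
that stand in for a vision encoder's frame embeddings.
"""

import numpy as np

from phasecast import (PhaseVocabulary, default_cholec_like_model,
                       sample_observations, sample_workflow,
                       timeline_to_segments)

voc = PhaseVocabulary.default()
model = default_cholec_like_model(voc)
timeline = sample_workflow(model, seed=4)
obs = sample_observations(timeline, d_obs=16, noise_level=0.6, seed=5)

print(f"procedure {timeline.video_id}: {len(timeline) / 60:.1f} minutes")
for seg in timeline_to_segments(timeline):
    print(f"  {seg.start_s / 60:6.1f}-{seg.end_s / 60:6.1f} min  "
          f"{voc.names[seg.phase]}")
print(f"observations: {obs.features.shape[0]} seconds x "
      f"{obs.features.shape[1]} dims, noise level {obs.noise_level}")
# Each row is the active phase's prototype vector plus Gaussian noise, so
# a noiseless run is perfectly classifiable and heavy noise approaches
# chance - the knob that controls how hard recognition is downstream.
print("first feature row:", np.round(obs.features[0, :8], 2))
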