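"""Shared fixtures: vocabularies, toy timelines and simulated corpora."""

import numpy as np
import pytest

from phasecast import (PhaseTimeline, PhaseVocabulary,
                       default_cholec_like_model, sample_dataset)


@pytest.fixture(scope="session")
def vocab() -> PhaseVocabulary:
    return PhaseVocabulary.default()


@pytest.fixture()
def toy_timeline(vocab) -> PhaseTimeline:
    """Two minutes of phase 0, two of phase 1 (the scan-oracle example)."""
    labels = np.concatenate([np.zeros(120, int), np.ones(120, int)])
    return PhaseTimeline(video_id="toy", labels=labels, vocabulary=vocab)


@pytest.fixture(scope="session")
def small_corpus(vocab):
    """Twenty stochastic simulated procedures with noisy observations."""
    model = default_cholec_like_model(vocab)
    return sample_dataset(model, 20, d_obs=16, noise_level=0.6, seed=42)


@pytest.fixture(scope="session")
def structured_corpus(vocab):
    """Strictly ordered workflows (no skips or repeats)."""
    model = default_cholec_like_model(vocab, skip_prob=0.0, repeat_prob=0.0)
    return sample_dataset(model, 30, d_obs=16, noise_level=0.4, seed=7)
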