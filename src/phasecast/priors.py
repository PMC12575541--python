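"""Conditional future-class transition priors and the naive baselines.

The prior captures, for every observed phase ``i`` and horizon step ``h``
(minutes), the training-set probability that the phase active ``h*60``
seconds later is ``j`` — with times past the end of a procedure counted as
the end-of-surgery class.  It is the knowledge injected into the
prior-initialised single-pass decoder and the sampling distribution of the
Naive2 baseline.

Counting pools (video, t) pairs across all training timelines with every
second as a query time, mirroring how anticipation targets are built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .timelines import PhaseTimeline, PhaseVocabulary

__all__ = [
    "TransitionPrior",
    "estimate_transition_prior",
    "prior_lookup",
    "naive1_predict",
    "naive2_predict",
]


@dataclass(frozen=True)
class TransitionPrior:
    """P(future class j at +h min | current class i), h = 1..N.

    ``probs[i, j, h-1]`` with i over the non-EOS phases, j over all classes
    including EOS.  ``counts`` holds the raw pooled counts; rows are
    normalised with additive smoothing ``(counts + alpha) / row_total``.
    """

    vocabulary: PhaseVocabulary
    probs: np.ndarray   # (C-1, C, N)
    counts: np.ndarray  # (C-1, C, N) integer
    horizon_minutes: int
    interval_s: int = 60
    smoothing_alpha: float = 1e-6

    def __post_init__(self):
        c = self.vocabulary.size
        shape = (c - 1, c, self.horizon_minutes)
        if self.probs.shape != shape or self.counts.shape != shape:
            raise ValueError(f"prior tensors must have shape {shape}")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        mass = (self.counts.sum(axis=1) > 0) | (self.smoothing_alpha > 0)
        if np.any(np.abs(sums[mass] - 1.0) > 1e-9):
            raise ValueError("rows with mass must sum to 1")

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "vocabulary": list(self.vocabulary.names),
            "horizon_minutes": self.horizon_minutes,
            "interval_s": self.interval_s,
            "smoothing_alpha": self.smoothing_alpha,
            "counts": self.counts.tolist(),
            "probs": self.probs.tolist(),
        }, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TransitionPrior":
        obj = json.loads(text)
        return cls(vocabulary=PhaseVocabulary(tuple(obj["vocabulary"])),
                   probs=np.asarray(obj["probs"], dtype=np.float64),
                   counts=np.asarray(obj["counts"], dtype=np.int64),
                   horizon_minutes=int(obj["horizon_minutes"]),
                   interval_s=int(obj["interval_s"]),
                   smoothing_alpha=float(obj["smoothing_alpha"]))

    @classmethod
    def load(cls, path: str | Path) -> "TransitionPrior":
        return cls.from_json(Path(path).read_text())


def estimate_transition_prior(timelines: Sequence[PhaseTimeline],
                              horizon_minutes: int,
                              interval_s: int = 60,
                              smoothing_alpha: float = 1e-6,
                              ) -> TransitionPrior:
    """Count (current, future) class pairs over every second of every video.

    For each timeline, each query second t and each step h, the pair
    ``(label[t], label[t + h*interval_s])`` is counted, with the future
    label replaced by EOS when ``t + h*interval_s`` falls past the end of
    the video.  Probabilities are row-normalised with additive smoothing.
    """
    timelines = list(timelines)
    if not timelines:
        raise ValueError("need at least one timeline")
    if horizon_minutes < 1:
        raise ValueError("horizon must be >= 1")
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be >= 0")
    voc = timelines[0].vocabulary
    c = voc.size
    counts = np.zeros((c - 1, c, horizon_minutes), dtype=np.int64)
    for tl in timelines:
        if tl.vocabulary != voc:
            raise ValueError("timelines must share one vocabulary")
        labels = tl.labels
        t_len = labels.size
        for h in range(1, horizon_minutes + 1):
            shift = h * interval_s
            future = np.full(t_len, voc.eos_index, dtype=np.int64)
            if shift < t_len:
                future[: t_len - shift] = labels[shift:]
            pair = labels * c + future
            binc = np.bincount(pair, minlength=(c - 1) * c)
            counts[:, :, h - 1] += binc.reshape(c - 1, c)
    smoothed = counts + smoothing_alpha
    totals = smoothed.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, smoothed / totals, 0.0)
    return TransitionPrior(vocabulary=voc, probs=probs, counts=counts,
                           horizon_minutes=horizon_minutes,
                           interval_s=interval_s,
                           smoothing_alpha=smoothing_alpha)


def prior_lookup(prior: TransitionPrior, current_class: int,
                 h: int) -> np.ndarray:
    """The probability row over future classes for (current_class, step h)."""
    if not 0 <= current_class < prior.vocabulary.eos_index:
        raise ValueError(
            f"current_class must be a non-EOS phase index, got {current_class}")
    if not 1 <= h <= prior.horizon_minutes:
        raise ValueError(f"step h={h} outside 1..{prior.horizon_minutes}")
    return prior.probs[current_class, :, h - 1].copy()


def naive1_predict(current_class: int, horizon_minutes: int) -> np.ndarray:
    """Continuation baseline: the current class extended over the horizon."""
    if horizon_minutes < 1:
        raise ValueError("horizon must be >= 1")
    return np.full(horizon_minutes, current_class, dtype=np.int64)


def naive2_predict(prior: TransitionPrior, current_class: int,
                   horizon_minutes: int, mode: str = "sample",
                   seed: int = 0) -> np.ndarray:
    """Conditional baseline: per-minute draw from the transition prior.

    Each future minute is predicted independently from the prior row of
    (current_class, h) — by seeded sampling (``mode="sample"``) or by its
    argmax (``mode="argmax"``, ties to the lowest class index).
    """
    if horizon_minutes > prior.horizon_minutes:
        raise ValueError("prior does not cover the requested horizon")
    if mode not in ("sample", "argmax"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = np.empty(horizon_minutes, dtype=np.int64)
    for h in range(1, horizon_minutes + 1):
        row = prior_lookup(prior, current_class, h)
        if mode == "argmax":
            out[h - 1] = int(np.argmax(row))
        else:
            p = row / row.sum()
            out[h - 1] = int(rng.choice(row.size, p=p))
    return out
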