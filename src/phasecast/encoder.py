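"""Context encoding: windowed self-attention, compression and pooling.

The recognition branch turns the last ``L`` seconds of per-frame features
into a compact context: features are projected to the model width, given a
sinusoidal positional encoding over the window, self-attended within
disjoint ``W``-second windows (WSA), linearly compressed to a small latent
width ``d`` and then pooled into ``M`` context tokens.

Two pooling schemes are provided.  *Key-pooling* computes a single
elementwise max over everything older than the last ``M`` seconds and then
a cumulative max as each of the ``M`` most recent seconds is appended, so
the tokens progressively incorporate recent detail on top of a global
summary.  *Interval-pooling* computes elementwise maxima over growing
prefixes aligned to fixed 60-second intervals, so token ``m`` summarises
the first ``m`` minutes of the window — the temporal granularity the
autoregressive decoder generates at.

The positional encoding is shared across the whole window rather than reset
per attention window: its slowest components are monotone over the window,
so max-pooled context retains the offsets of phase boundaries, which is
what lets a remaining-time head estimate elapsed time within a phase from
otherwise piecewise-constant features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "FeatureSequence",
    "ContextTokens",
    "RecognitionOutput",
    "WSAEncoder",
    "RecognitionHead",
    "windowed_self_attention",
    "compress",
    "key_pool",
    "interval_pool",
    "recognition_head",
    "feature_window",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters for the encoder/decoder stack.

    Defaults are the desk-scale configuration used on synthetic workflows;
    the full-scale values from the video setting (L=1440, W=20, d=32, M=24,
    D=768) are all expressible through the same fields.
    """

    n_classes: int            # C, including EOS
    d_obs: int = 16           # input feature dimension D
    d_model: int = 16         # width after input projection
    d_compress: int = 8       # latent width d fed to pooling
    seq_len: int = 360        # L, seconds of context
    window: int = 20          # W, self-attention window
    n_tokens: int = 12        # M, context tokens from key-pooling
    interval_s: int = 60      # interval-pooling granularity
    horizon_minutes: int = 15  # N
    d_dec: int = 16           # decoder width
    n_heads: int = 2
    n_wsa_layers: int = 1
    n_dec_layers: int = 1

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window W must be positive")
        if not 1 <= self.n_tokens <= self.seq_len:
            raise ValueError("need 1 <= M <= L")
        if not 1 <= self.interval_s <= self.seq_len:
            raise ValueError("need 1 <= interval_s <= L")
        if self.horizon_minutes < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class FeatureSequence:
    """A fixed-length window of per-second feature vectors ending at ``t``."""

    vectors: np.ndarray  # (L, D), most recent last
    t: int = 0

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 2:
            raise ValueError("vectors must be (L, D)")
        if not np.all(np.isfinite(v)):
            raise ValueError("vectors must be finite")

    @property
    def length(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class ContextTokens:
    """M pooled context embeddings, tagged with the pooling scheme."""

    tokens: np.ndarray  # (M, d)
    scheme: str         # "key_pool" | "interval_pool"
    interval_s: int | None = None

    def __post_init__(self):
        tok = np.asarray(self.tokens, dtype=np.float64)
        object.__setattr__(self, "tokens", tok)
        if tok.ndim != 2 or tok.shape[0] < 1:
            raise ValueError("tokens must be a non-empty (M, d) matrix")
        if self.scheme not in ("key_pool", "interval_pool"):
            raise ValueError(f"unknown pooling scheme {self.scheme!r}")


@dataclass(frozen=True)
class RecognitionOutput:
    """Per-token class probabilities; the last row is the current second."""

    probs: np.ndarray  # (M, C)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("rows must sum to 1")

    @property
    def predicted_current(self) -> int:
        return int(np.argmax(self.probs[-1]))


def feature_window(features: np.ndarray, t: int, seq_len: int) -> np.ndarray:
    """The ``seq_len`` rows ending at ``t`` inclusive, left-padded.

    When fewer than ``seq_len`` seconds have elapsed the window is padded on
    the left by repeating the earliest available vector, keeping shapes
    fixed during the cold start of a procedure.
    """
    features = np.asarray(features)
    if not 0 <= t < features.shape[0]:
        raise ValueError(f"t={t} outside feature range")
    start = t + 1 - seq_len
    if start >= 0:
        return features[start: t + 1]
    pad = np.repeat(features[:1], -start, axis=0)
    return np.concatenate([pad, features[: t + 1]], axis=0)


# -- Tensor-level primitives (shared by the functional API and the model) --

def key_pool_tensor(x: Tensor, m: int) -> Tensor:
    """Cumulative max-pooling of (..., L, d) into (..., M, d) tokens."""
    length = x.shape[-2]
    if not 1 <= m <= length:
        raise ValueError(f"need 1 <= M <= L, got M={m}, L={length}")
    tokens = []
    if m < length:
        running = x[..., : length - m, :].max(axis=-2)
    else:
        running = x[..., 0, :]
        tokens.append(running)
    start = length - m if m < length else 1
    for i in range(start, length):
        running = running.maximum(x[..., i, :])
        tokens.append(running)
    # stack along a new token axis
    expanded = [tok.reshape(*tok.shape[:-1], 1, tok.shape[-1])
                for tok in tokens]
    return nn.cat(expanded, axis=-2)


def interval_pool_tensor(x: Tensor, interval_s: int) -> Tensor:
    """Prefix max-pooling of (..., L, d) at a fixed interval into M tokens."""
    length = x.shape[-2]
    if not 1 <= interval_s <= length:
        raise ValueError("need 1 <= interval_s <= L")
    m = length // interval_s
    tokens = []
    running = None
    for i in range(m):
        hi = (i + 1) * interval_s if i < m - 1 else length  # absorb remainder
        lo = i * interval_s
        chunk = x[..., lo:hi, :].max(axis=-2)
        running = chunk if running is None else running.maximum(chunk)
        tokens.append(running)
    expanded = [tok.reshape(*tok.shape[:-1], 1, tok.shape[-1])
                for tok in tokens]
    return nn.cat(expanded, axis=-2)


# -- learned modules -------------------------------------------------------

class WSAEncoder(nn.Module):
    """Input projection + positional encoding + windowed self-attention.

    Attention is computed independently within disjoint windows of ``W``
    consecutive seconds; output length and width match the input.  If the
    window length does not divide ``L`` the sequence is left-padded (by
    repeating the earliest vector) to the next multiple and trimmed back.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_proj = nn.Linear(cfg.d_obs, cfg.d_model, rng)
        # slim FFN (d_ff = d_model): the window encoder is the hot path
        self.layers = [nn.TransformerLayer(cfg.d_model, cfg.n_heads, rng,
                                           d_ff=cfg.d_model)
                       for _ in range(cfg.n_wsa_layers)]
        self.pos = nn.sinusoidal_encoding(
            cfg.seq_len + cfg.window, cfg.d_model)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (..., L, D_obs) -> (..., L, d_model)."""
        cfg = self.cfg
        length = x.shape[-2]
        w = cfg.window
        pad = (-length) % w
        h = self.in_proj(x)
        h = h + Tensor(self.pos[pad: pad + length])
        if pad:
            logger.debug("WSA: padding window of length %d by %d to a "
                         "multiple of W=%d", length, pad, w)
            first = h[..., :1, :]
            pads = nn.cat([first] * pad, axis=-2)
            h = nn.cat([pads, h], axis=-2)
        n_win = h.shape[-2] // w
        batch = h.shape[:-2]
        h = h.reshape(*batch, n_win, w, cfg.d_model)
        for layer in self.layers:
            h = layer(h)
        h = h.reshape(*batch, n_win * w, cfg.d_model)
        if pad:
            h = h[..., pad:, :]
        return h


class RecognitionHead(nn.Module):
    """Fuse key-pooled tokens with recent WSA features; classify each."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.skip_proj = nn.Linear(cfg.d_model, cfg.d_compress, rng)
        self.classifier = nn.Linear(cfg.d_compress, cfg.n_classes, rng)

    def logits(self, wsa_feats: Tensor, key_tokens: Tensor) -> Tensor:
        """(..., L, d_model) x (..., M, d) -> (..., M, C) logits."""
        m = key_tokens.shape[-2]
        recent = wsa_feats[..., wsa_feats.shape[-2] - m:, :]
        fused = key_tokens + self.skip_proj(recent)  # additive skip
        return self.classifier(fused)


# -- functional API ---------------------------------------------------------

def windowed_self_attention(features: FeatureSequence, window: int,
                            weights: WSAEncoder) -> FeatureSequence:
    """Apply the windowed self-attention encoder to one feature window."""
    if window <= 0:
        raise ValueError("window W must be positive")
    if window != weights.cfg.window:
        raise ValueError("window does not match the encoder weights")
    with nn.no_grad():
        out = weights(Tensor(features.vectors))
    return FeatureSequence(vectors=out.data, t=features.t)


def compress(features: FeatureSequence, d: int,
             weights: nn.Linear) -> FeatureSequence:
    """Linear projection of every position into a d-dimensional latent."""
    if d <= 0:
        raise ValueError("d must be positive")
    if weights.weight.shape[1] != d:
        raise ValueError("projection weights do not produce dimension d")
    with nn.no_grad():
        out = weights(Tensor(features.vectors))
    return FeatureSequence(vectors=out.data, t=features.t)


def key_pool(compressed: FeatureSequence, m: int) -> ContextTokens:
    """Cumulative max-pooling into M tokens (global summary + recent detail)."""
    out = key_pool_tensor(Tensor(compressed.vectors), m)
    return ContextTokens(tokens=out.data, scheme="key_pool")


def interval_pool(compressed: FeatureSequence,
                  interval_s: int) -> ContextTokens:
    """Prefix max-pooling over consecutive fixed-length intervals."""
    out = interval_pool_tensor(Tensor(compressed.vectors), interval_s)
    return ContextTokens(tokens=out.data, scheme="interval_pool",
                         interval_s=interval_s)


def recognition_head(wsa_features: FeatureSequence,
                     key_tokens: ContextTokens,
                     weights: RecognitionHead) -> RecognitionOutput:
    """Class probabilities for each of the M most recent seconds."""
    if key_tokens.scheme != "key_pool":
        raise ValueError("recognition head requires key-pooled tokens")
    with nn.no_grad():
        logits = weights.logits(Tensor(wsa_features.vectors),
                                Tensor(key_tokens.tokens))
    return RecognitionOutput(probs=nn.stable_softmax(logits.data))
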