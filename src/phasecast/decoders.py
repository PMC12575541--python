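"""Generative anticipation heads: single-pass, autoregressive, regression.

Three decoding routes turn pooled context tokens into future-phase
predictions over an ``N``-minute horizon:

* **SP** — a cross-attending decoder emits all ``N`` future-phase
  distributions in one forward pass from ``N`` query tokens (learned
  per-position embeddings plus sinusoidal positions).
* **SP\\*** — identical, but each query token is initialised from the
  conditional transition-probability row for that horizon step given the
  current phase (ground truth while training — teacher forcing — and the
  recognition head's prediction at inference).
* **AR** — a causally masked decoder over interval-pooled context generates
  one future token at a time, feeding back an embedding of its own previous
  prediction (greedy argmax by default, temperature sampling optional).

A fourth head regresses the remaining time until each class's next
occurrence from a single query token; :func:`r2c` converts such a
prediction into a minute-binned phase sequence by sorting and binning.

All decoders share the recognition branch (windowed self-attention +
key-pooling) and are trained jointly with it: weighted cross-entropy on the
``M`` recognition frames plus weighted cross-entropy (classification) or
MSE (regression, targets scaled to [0, 1]) on the anticipation outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoder import (ModelConfig, feature_window, interval_pool_tensor,
                      key_pool_tensor, RecognitionHead, WSAEncoder)
from .nn import Tensor
from .priors import TransitionPrior, prior_lookup
from .simulate import ObservationSequence
from .timelines import (PhaseTimeline, PhaseVocabulary, anticipation_target,
                        remaining_time_target)

__all__ = [
    "QueryTokens",
    "AnticipationGrid",
    "RemainingTimePrediction",
    "TrainConfig",
    "AnticipationModel",
    "build_query_tokens",
    "sp_decode",
    "ar_decode",
    "regress_remaining_time",
    "teacher_forced_training_step",
    "train_model",
    "r2c",
    "compute_class_weights",
    "save_checkpoint",
    "load_checkpoint",
]

DECODER_KINDS = ("sp", "sp_star", "ar", "regression")


@dataclass(frozen=True)
class QueryTokens:
    """The N decoder input tokens and how they were built."""

    tokens: np.ndarray          # (N, d_dec)
    built_from: str             # "learned" | "prior"
    conditioning_class: int | None = None

    def __post_init__(self):
        if self.built_from not in ("learned", "prior"):
            raise ValueError(f"unknown query source {self.built_from!r}")


@dataclass(frozen=True)
class AnticipationGrid:
    """N x C matrix; row n is the distribution of the phase at t + n*60 s."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2:
            raise ValueError("grid must be N x C")
        if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("grid rows must sum to 1")

    @property
    def argmax_sequence(self) -> np.ndarray:
        return np.argmax(self.probs, axis=-1)


@dataclass(frozen=True)
class RemainingTimePrediction:
    """Predicted minutes until each class's next occurrence, EOS included."""

    minutes: np.ndarray  # (C,), clamped to [0, N]
    horizon_minutes: int

    def __post_init__(self):
        m = np.asarray(self.minutes, dtype=np.float64)
        object.__setattr__(self, "minutes", m)
        if m.min() < 0 or m.max() > self.horizon_minutes:
            raise ValueError("predictions must be clamped to [0, N]")


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale optimisation settings for one training run."""

    decoder_kind: str = "sp"
    steps: int = 300
    batch_size: int = 16
    learning_rate: float = 3e-3
    seed: int = 0
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.decoder_kind not in DECODER_KINDS:
            raise ValueError(f"decoder_kind must be one of {DECODER_KINDS}")
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be positive")


class AnticipationModel(nn.Module):
    """Shared recognition encoder plus one of the anticipation heads.

    ``kind`` selects the decoding route; an SP* model additionally holds
    the (frozen) transition prior used to build its query tokens.
    """

    def __init__(self, cfg: ModelConfig, kind: str, seed: int,
                 prior: TransitionPrior | None = None):
        if kind not in DECODER_KINDS:
            raise ValueError(f"kind must be one of {DECODER_KINDS}")
        if kind == "sp_star" and prior is None:
            raise ValueError("an sp_star model requires a transition prior")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.kind = kind
        self.prior = prior if kind == "sp_star" else None
        self.wsa = WSAEncoder(cfg, rng)
        self.compressor = nn.Linear(cfg.d_model, cfg.d_compress, rng)
        self.recognition = RecognitionHead(cfg, rng)
        self.ctx_proj = nn.Linear(cfg.d_compress, cfg.d_dec, rng)
        n, c = cfg.horizon_minutes, cfg.n_classes
        self.query_pos = nn.sinusoidal_encoding(
            n + cfg.seq_len // cfg.interval_s + 1, cfg.d_dec)
        if kind == "sp":
            self.query_table = nn.Parameter(
                0.1 * rng.standard_normal((n, cfg.d_dec)))
        elif kind == "sp_star":
            self.prior_embed = nn.Linear(c, cfg.d_dec, rng)
        elif kind == "regression":
            self.reg_query = nn.Parameter(
                0.1 * rng.standard_normal((1, cfg.d_dec)))
        if kind == "ar":
            self.feedback_embed = nn.Linear(c, cfg.d_dec, rng)
            self.dec_layers = [
                nn.TransformerLayer(cfg.d_dec, cfg.n_heads, rng,
                                    d_ff=2 * cfg.d_dec)
                for _ in range(cfg.n_dec_layers)]
        else:
            self.dec_layers = [
                nn.TransformerLayer(cfg.d_dec, cfg.n_heads, rng,
                                    d_kv=cfg.d_dec, d_ff=2 * cfg.d_dec)
                for _ in range(cfg.n_dec_layers)]
        self.out_head = nn.Linear(cfg.d_dec, c, rng)

    # -- encoder ----------------------------------------------------------
    def encode(self, x: Tensor) -> dict[str, Tensor]:
        """x: (..., L, D_obs) -> WSA features, pooled contexts, recognition."""
        cfg = self.cfg
        wsa = self.wsa(x)
        comp = self.compressor(wsa)
        keys = key_pool_tensor(comp, cfg.n_tokens)
        recog_logits = self.recognition.logits(wsa, keys)
        return {"wsa": wsa, "compressed": comp, "keys": keys,
                "recognition_logits": recog_logits}

    # -- queries ----------------------------------------------------------
    def query_tensor(self, prior_rows: np.ndarray | None,
                     batch_shape: tuple[int, ...]) -> Tensor:
        """Build the (…, N, d_dec) decoder inputs for sp / sp_star / reg."""
        n = self.cfg.horizon_minutes
        pos = Tensor(self.query_pos[1: n + 1])
        if self.kind == "sp":
            q = self.query_table + pos
            return _tile(q, batch_shape)
        if self.kind == "sp_star":
            if prior_rows is None:
                raise ValueError("sp_star queries need prior probability rows")
            return self.prior_embed(Tensor(prior_rows)) + pos
        if self.kind == "regression":
            q = self.reg_query + Tensor(self.query_pos[:1])
            return _tile(q, batch_shape)
        raise ValueError("AR models build queries step by step")

    # -- decoding ---------------------------------------------------------
    def decode_cross(self, queries: Tensor, keys: Tensor) -> Tensor:
        """Single-pass cross-attention decode -> (…, N, C) logits."""
        ctx = self.ctx_proj(keys)
        h = queries
        for layer in self.dec_layers:
            h = layer(h, kv=ctx)
        return self.out_head(h)

    def decode_ar(self, intervals: Tensor, n_steps: int,
                  mode: str = "greedy", temperature: float = 1.0,
                  seed: int = 0) -> Tensor:
        """Iterative causally-masked decode -> (…, N, C) logits.

        The model consumes the interval-pooled context tokens as a prefix
        and then generates one token per future minute, embedding its own
        previous prediction (argmax one-hot by default) as the next input.
        """
        if mode not in ("greedy", "sample"):
            raise ValueError(f"unknown AR mode {mode!r}")
        rng = np.random.default_rng(seed)
        m = intervals.shape[-2]
        batch_shape = intervals.shape[:-2]
        seq = self.ctx_proj(intervals) + Tensor(self.query_pos[:m])
        logits_steps: list[Tensor] = []
        for step in range(n_steps):
            s = seq.shape[-2]
            mask = np.triu(np.full((s, s), -1e30), k=1)
            h = seq
            for layer in self.dec_layers:
                h = layer(h, mask=mask)
            logit = self.out_head(h[..., s - 1, :])  # (…, C)
            logits_steps.append(
                logit.reshape(*batch_shape, 1, self.cfg.n_classes))
            if step + 1 < n_steps:
                probs = _stable_softmax(logit.data / temperature)
                if mode == "greedy":
                    choice = np.argmax(probs, axis=-1)
                else:
                    choice = _sample_rows(probs, rng)
                onehot = np.zeros_like(probs)
                np.put_along_axis(onehot, choice[..., None], 1.0, axis=-1)
                nxt = (self.feedback_embed(Tensor(onehot))
                       + Tensor(self.query_pos[m + step]))
                seq = nn.cat(
                    [seq, nxt.reshape(*batch_shape, 1, self.cfg.d_dec)],
                    axis=-2)
        return nn.cat(logits_steps, axis=-2)

    # -- end-to-end forward ------------------------------------------------
    def forward(self, x: Tensor,
                conditioning: np.ndarray | None = None) -> dict[str, Tensor]:
        """Full forward pass on a (..., L, D_obs) batch.

        ``conditioning`` supplies the current class per sample for SP*
        (teacher forcing); when None, the recognition head's prediction is
        used.  Returns recognition logits plus either anticipation logits
        (classification kinds) or normalised remaining-time outputs.
        """
        enc = self.encode(x)
        out: dict[str, Tensor] = {
            "recognition_logits": enc["recognition_logits"]}
        if self.kind in ("sp", "sp_star", "regression"):
            prior_rows = None
            if self.kind == "sp_star":
                cond = conditioning
                if cond is None:
                    cond = np.argmax(
                        enc["recognition_logits"].data[..., -1, :], axis=-1)
                prior_rows = self._prior_rows(np.asarray(cond))
            queries = self.query_tensor(prior_rows, x.shape[:-2])
            dec = self.decode_cross(queries, enc["keys"])
            if self.kind == "regression":
                out["remaining_raw"] = dec[..., 0, :]
            else:
                out["anticipation_logits"] = dec
        else:  # ar
            intervals = interval_pool_tensor(enc["compressed"],
                                             self.cfg.interval_s)
            out["anticipation_logits"] = self.decode_ar(
                intervals, self.cfg.horizon_minutes)
        return out

    def _prior_rows(self, classes: np.ndarray) -> np.ndarray:
        """(B,) current classes -> (B, N, C) prior probability rows."""
        probs = self.prior.probs  # (C-1, C, N)
        flat = np.atleast_1d(classes)
        rows = probs[flat].transpose(0, 2, 1)  # (B, N, C)
        return rows if classes.ndim else rows[0]


def _tile(t: Tensor, batch_shape: tuple[int, ...]) -> Tensor:
    for _ in batch_shape:
        t = t.reshape(1, *t.shape)
    if batch_shape:
        t = t + Tensor(np.zeros(batch_shape + (1, 1)))
    return t


_stable_softmax = nn.stable_softmax


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flat = probs.reshape(-1, probs.shape[-1])
    cum = np.cumsum(flat, axis=-1)
    u = rng.random(flat.shape[0])[:, None] * cum[:, -1:]
    idx = (u > cum).sum(axis=-1)
    return idx.reshape(probs.shape[:-1])


# -- functional API ---------------------------------------------------------

def build_query_tokens(prior: TransitionPrior | None, conditioning_class: int,
                       horizon_minutes: int, weights: AnticipationModel,
                       ) -> QueryTokens:
    """The decoder's N input tokens for one query time.

    With a prior, token n embeds the probability row for (conditioning
    class, step n) plus its sinusoidal position; without one, the learned
    per-position embeddings (plain SP) are returned.
    """
    n = horizon_minutes
    if n != weights.cfg.horizon_minutes:
        raise ValueError("horizon does not match the model configuration")
    if prior is not None:
        if n > prior.horizon_minutes:
            raise ValueError("N exceeds the prior horizon")
        rows = np.stack([prior_lookup(prior, conditioning_class, h)
                         for h in range(1, n + 1)])
        tokens = (weights.prior_embed(Tensor(rows))
                  + Tensor(weights.query_pos[1: n + 1]))
        return QueryTokens(tokens=tokens.data, built_from="prior",
                           conditioning_class=conditioning_class)
    tokens = weights.query_table + Tensor(weights.query_pos[1: n + 1])
    return QueryTokens(tokens=tokens.data, built_from="learned")


def sp_decode(queries: QueryTokens, context, weights: AnticipationModel,
              ) -> AnticipationGrid:
    """One cross-attention forward pass over key-pooled context tokens."""
    from .encoder import ContextTokens
    if isinstance(context, ContextTokens) and context.scheme != "key_pool":
        raise ValueError("single-pass decoding uses key-pooled context")
    tokens = context.tokens if hasattr(context, "tokens") else context
    if np.asarray(tokens).shape[0] < 1:
        raise ValueError("context is empty")
    with nn.no_grad():
        logits = weights.decode_cross(Tensor(queries.tokens), Tensor(tokens))
    return AnticipationGrid(probs=_stable_softmax(logits.data))


def ar_decode(context, horizon_minutes: int, weights: AnticipationModel,
              mode: str = "greedy", temperature: float = 1.0,
              seed: int = 0) -> AnticipationGrid:
    """Greedy (default) or sampled autoregressive rollout of N tokens."""
    from .encoder import ContextTokens
    if isinstance(context, ContextTokens) and context.scheme != "interval_pool":
        raise ValueError("autoregressive decoding uses interval-pooled context")
    tokens = context.tokens if hasattr(context, "tokens") else context
    if np.asarray(tokens).shape[0] < 1:
        raise ValueError("context is empty")
    with nn.no_grad():
        logits = weights.decode_ar(Tensor(tokens), horizon_minutes,
                                   mode=mode, temperature=temperature,
                                   seed=seed)
    return AnticipationGrid(probs=_stable_softmax(logits.data))


def regress_remaining_time(context, weights: AnticipationModel,
                           ) -> RemainingTimePrediction:
    """Per-class remaining minutes from a single decoder query token."""
    tokens = context.tokens if hasattr(context, "tokens") else context
    with nn.no_grad():
        q = weights.query_tensor(None, ())
        raw = weights.decode_cross(q, Tensor(np.asarray(tokens)))
    n = weights.cfg.horizon_minutes
    minutes = np.clip(raw.data[0], 0.0, 1.0) * n
    return RemainingTimePrediction(minutes=minutes, horizon_minutes=n)


# -- regression-to-classification ------------------------------------------

def r2c(prediction: RemainingTimePrediction, current_class: int,
        horizon_minutes: int) -> np.ndarray:
    """Sort-and-bin a remaining-time prediction into a phase sequence.

    Classes predicted at or beyond the horizon are excluded ("will not
    occur"); the rest are sorted by ascending predicted time (ties by
    ascending class index).  Minute bins are filled with the current class
    until the first predicted occurrence; thereafter the active class
    advances to the next sorted class once its predicted time falls below
    the bin index, at most one class per bin so that every realised class
    occupies at least one bin.
    """
    n = horizon_minutes
    times = prediction.minutes
    order = sorted((float(times[c]), c) for c in range(times.size)
                   if c != current_class and times[c] < n)
    seq = np.empty(n, dtype=np.int64)
    ptr = -1
    active = current_class
    for b in range(1, n + 1):
        if ptr + 1 < len(order) and order[ptr + 1][0] < b:
            ptr += 1
            active = order[ptr][1]
        seq[b - 1] = active
    return seq


# -- training ---------------------------------------------------------------

def compute_class_weights(timelines: Sequence[PhaseTimeline],
                          horizon_minutes: int) -> np.ndarray:
    """Inverse-frequency class weights over anticipation targets (EOS incl.).

    Frequencies are counted over all (t, h) target cells with the EOS-fill
    convention; weights are normalised to mean 1 and clipped to [0.1, 10]
    to keep the loss well-conditioned under extreme imbalance.
    """
    voc = timelines[0].vocabulary
    counts = np.zeros(voc.size)
    for tl in timelines:
        t_len = len(tl)
        binc = np.bincount(tl.labels, minlength=voc.size).astype(float)
        counts += binc * horizon_minutes  # in-video cells, aggregate approx.
        counts[voc.eos_index] += 60.0 * (horizon_minutes *
                                         (horizon_minutes + 1)) / 2.0
    freqs = counts / counts.sum()
    with np.errstate(divide="ignore"):
        w = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-12), 0.0)
    w = w / w[w > 0].mean()
    return np.clip(w, 0.1, 10.0)


def _batch_arrays(model: AnticipationModel,
                  batch: Sequence[tuple], horizon_minutes: int):
    """Stack (features-window, timeline, t) triples into training arrays."""
    cfg = model.cfg
    xs, recog_t, antic_t, reg_t, cond = [], [], [], [], []
    for feats, tl, t in batch:
        window = feats.vectors if hasattr(feats, "vectors") else feats
        window = np.asarray(window)
        if window.shape[0] != cfg.seq_len:
            raise ValueError("feature window length must equal cfg.seq_len")
        xs.append(window)
        lo = t - cfg.n_tokens + 1
        idx = np.clip(np.arange(lo, t + 1), 0, len(tl) - 1)
        recog_t.append(tl.labels[np.maximum(idx, 0)])
        antic_t.append(anticipation_target(tl, t, horizon_minutes).future)
        reg_t.append(remaining_time_target(tl, t, horizon_minutes).minutes
                     / horizon_minutes)
        cond.append(int(tl.labels[t]))
    return (np.stack(xs), np.stack(recog_t), np.stack(antic_t),
            np.stack(reg_t), np.array(cond))


def teacher_forced_training_step(model: AnticipationModel, batch: Sequence[tuple],
                                 config: TrainConfig) -> dict[str, float]:
    """One gradient accumulation over a batch of (features, timeline, t).

    Computes the joint loss — weighted cross-entropy on the M recognition
    frames plus the anticipation loss of the model's kind — runs the
    backward pass, and returns the scalar loss components.  The optimiser
    step is the caller's responsibility.
    """
    n = model.cfg.horizon_minutes
    x, recog_t, antic_t, reg_t, cond = _batch_arrays(model, batch, n)
    weights = (np.asarray(config.class_weights)
               if config.class_weights is not None else None)
    out = model.forward(Tensor(x), conditioning=cond)
    loss_rec = nn.cross_entropy(out["recognition_logits"], recog_t, weights)
    if model.kind == "regression":
        loss_ant = nn.mse_loss(out["remaining_raw"], reg_t)
    else:
        loss_ant = nn.cross_entropy(out["anticipation_logits"], antic_t,
                                    weights)
    total = loss_rec + loss_ant
    if not np.isfinite(total.data):
        raise RuntimeError(
            f"non-finite loss (recognition={loss_rec.data}, "
            f"anticipation={loss_ant.data}); check inputs and learning rate")
    total.backward()
    return {"recognition": float(loss_rec.data),
            "anticipation": float(loss_ant.data),
            "total": float(total.data)}


def train_model(model: AnticipationModel,
                dataset: Sequence[tuple[PhaseTimeline, ObservationSequence]],
                config: TrainConfig) -> list[dict[str, float]]:
    """Desk-scale training loop: seeded probe sampling + Adam.

    Each step draws ``batch_size`` random (video, t) probes, builds their
    feature windows and targets, and takes one Adam step on the joint
    loss.  Returns the per-step loss history.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    lengths = np.array([len(tl) for tl, _ in dataset])
    history: list[dict[str, float]] = []
    for _ in range(config.steps):
        vids = rng.integers(0, len(dataset), size=config.batch_size)
        batch = []
        for v in vids:
            tl, obs = dataset[int(v)]
            t = int(rng.integers(0, lengths[int(v)]))
            window = feature_window(obs.features, t, model.cfg.seq_len)
            batch.append((window, tl, t))
        opt.zero_grad()
        losses = teacher_forced_training_step(model, batch, config)
        opt.step()
        history.append(losses)
    return history


# -- batched inference ------------------------------------------------------

def predict_batch(model: AnticipationModel, windows: np.ndarray,
                  conditioning: np.ndarray | None = None) -> dict:
    """Forward a (B, L, D) stack of feature windows without gradients.

    Returns recognition probabilities, the predicted current class, and
    either anticipation grids (B, N, C) or remaining-minutes (B, C)
    depending on the model kind.  SP* conditions on the recognition
    prediction unless ``conditioning`` (ground-truth classes) is given.
    """
    with nn.no_grad():
        out = model.forward(Tensor(np.asarray(windows)),
                            conditioning=conditioning)
    rec = _stable_softmax(out["recognition_logits"].data)
    result = {"recognition_probs": rec,
              "current_class": np.argmax(rec[..., -1, :], axis=-1)}
    if model.kind == "regression":
        n = model.cfg.horizon_minutes
        result["remaining_minutes"] = np.clip(
            out["remaining_raw"].data, 0.0, 1.0) * n
    else:
        result["grids"] = _stable_softmax(out["anticipation_logits"].data)
    return result


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model: AnticipationModel, train_config: TrainConfig,
                    vocabulary: PhaseVocabulary, path: str | Path) -> None:
    """Write weights + configs + (for SP*) the prior to one .npz container."""
    from .config import config_hash
    meta = {
        "model_config": asdict(model.cfg),
        "train_config": asdict(train_config),
        "kind": model.kind,
        "vocabulary": list(vocabulary.names),
        "prior": model.prior.to_json() if model.prior is not None else None,
    }
    meta["config_hash"] = config_hash(
        {"model": meta["model_config"], "train": meta["train_config"]})
    state = model.state_dict()
    buf = {f"param::{k}": v for k, v in state.items()}
    buf["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(Path(path), **buf)


def load_checkpoint(path: str | Path,
                    ) -> tuple[AnticipationModel, TrainConfig, PhaseVocabulary]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    cfg = ModelConfig(**meta["model_config"])
    tc = TrainConfig(**{**meta["train_config"],
                        "class_weights":
                        tuple(meta["train_config"]["class_weights"])
                        if meta["train_config"]["class_weights"] else None})
    prior = (TransitionPrior.from_json(meta["prior"])
             if meta["prior"] else None)
    model = AnticipationModel(cfg, meta["kind"], seed=0, prior=prior)
    model.load_state_dict(state)
    voc = PhaseVocabulary(tuple(meta["vocabulary"]))
    return model, tc, voc
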