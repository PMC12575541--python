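"""Reproducible desk-scale study benchmarks.

These routines package the three simulation studies the project uses to
validate the anticipation models end to end, with all study conditions
(simulator parameters, corpus sizes, probe protocols, training schedules)
fixed here so that the command-line runs, the test suite and the
reproduction script all execute the identical experiment:

* :func:`prior_recovery` — how close a transition prior estimated from a
  200-procedure corpus comes to the generator's own conditional
  distribution (approximated from a much larger reference corpus).
* :func:`deterministic_benchmark` — on a fully deterministic workflow
  (fixed durations, rigid order, noiseless observations) the future is a
  function of elapsed time, so a single-pass decoder should reproduce it
  exactly and the remaining-time head should be accurate to a few seconds.
* :func:`ordering_benchmark` — on stochastic workflows, the qualitative
  ordering the anticipation literature reports: prior-initialised
  single-pass decoding (SP*) at least matches plain SP and beats the
  continuation baseline, while per-minute conditional sampling (Naive2)
  produces visibly over-fragmented sequences.

Every routine takes one integer seed and derives all internal randomness
from it through named streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import derive_seed
from .decoders import (AnticipationModel, TrainConfig, predict_batch, train_model)
from .encoder import ModelConfig, feature_window
from .metrics import horizon_scores
from .priors import (estimate_transition_prior, naive1_predict,
                     naive2_predict)
from .simulate import (default_cholec_like_model, deterministic_model,
                       sample_dataset, sample_observations, sample_workflow)
from .timelines import (PhaseVocabulary, anticipation_target,
                        remaining_time_target)

__all__ = [
    "prior_recovery",
    "deterministic_benchmark",
    "ordering_benchmark",
    "DETERMINISTIC_DURATIONS_S",
]

#: fixed per-phase durations (s) of the deterministic benchmark workflow.
#: All are multiples of 60 s so that anticipation targets are constant
#: within each elapsed minute, and none exceeds the context window, so the
#: most recent phase boundary is always visible to the encoder.
DETERMINISTIC_DURATIONS_S = (60, 240, 360, 240, 300, 240, 240)

#: desk-scale context/decoder geometry shared by the benchmarks.  The wide
#: compression latent (d = 32) matters for remaining-time precision: the
#: pooled context must carry one boundary-offset readout per phase.
_BENCH_CONFIG = dict(seq_len=360, window=20, n_tokens=12, interval_s=60,
                     d_obs=16, d_model=16, d_compress=32, d_dec=32,
                     n_dec_layers=2, horizon_minutes=15)

#: training schedule (learning rate, batch size, steps) for the
#: deterministic regression benchmark: larger batches and smaller learning
#: rates late, to squeeze the gradient noise floor once the task is nearly
#: fit; the final model averages the last few round checkpoints.
_DET_SCHEDULE = ([(3e-3, 16, 200)] + [(1e-3, 32, 200)] * 2
                 + [(3e-4, 64, 150)] * 2 + [(1e-4, 64, 150)] * 2
                 + [(3e-5, 64, 150)] * 2)
_DET_AVERAGE_LAST = 3

#: training schedule for the stochastic ordering benchmark
_ORDER_STEPS = 300
_ORDER_BATCH = 16
_ORDER_LR = 3e-3


def _tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def prior_recovery(seed: int, n_train: int = 200, n_reference: int = 2000,
                   horizon_minutes: int = 10, min_support: int = 50) -> dict:
    """Total-variation gap between estimated and generator-implied priors.

    The generator-implied conditional P(class at +h | class now) has no
    convenient closed form under log-normal semi-Markov holding times, so
    it is approximated by estimating the same tensor from a reference
    corpus an order of magnitude larger.  Returns the maximum and mean TV
    distance over all (current class, horizon) rows whose training-corpus
    support reaches ``min_support`` query seconds.
    """
    voc = PhaseVocabulary.default()
    model = default_cholec_like_model(voc)
    train_tls = [sample_workflow(model, derive_seed(seed, f"prior-train/{i}"))
                 for i in range(n_train)]
    ref_tls = [sample_workflow(model, derive_seed(seed, f"prior-ref/{i}"))
               for i in range(n_reference)]
    est = estimate_transition_prior(train_tls, horizon_minutes,
                                    smoothing_alpha=0.0)
    ref = estimate_transition_prior(ref_tls, horizon_minutes,
                                    smoothing_alpha=0.0)
    tvs = []
    for i in range(voc.eos_index):
        for h in range(horizon_minutes):
            support = est.counts[i, :, h].sum()
            if support < min_support:
                continue
            tvs.append(_tv_distance(est.probs[i, :, h], ref.probs[i, :, h]))
    return {"max_tv": float(np.max(tvs)), "mean_tv": float(np.mean(tvs)),
            "n_rows": len(tvs), "n_train": n_train}


@dataclass(frozen=True)
class DeterministicResult:
    sp_sequence_accuracy: float
    regression_next_phase_mae: float
    n_probes: int
    sp_rounds: int


def _next_phase_errors(pred_minutes: np.ndarray,
                       target_minutes: np.ndarray) -> np.ndarray:
    """|error| of the entry for the class that occurs next (smallest
    strictly positive target time; ties to the lowest class index)."""
    errs = np.empty(len(target_minutes))
    for i, tgt in enumerate(target_minutes):
        candidates = np.flatnonzero(tgt > 0)
        c = candidates[np.argmin(tgt[candidates])]
        errs[i] = abs(pred_minutes[i][c] - tgt[c])
    return errs


#: per-round learning rates for the deterministic SP run; the decay steps
#: matter — at a constant rate Adam orbits the memorisation optimum
_DET_SP_LRS = [3e-3] * 4 + [1e-3] * 4 + [3e-4] * 4 + [1e-4] * 4


def deterministic_benchmark(seed: int, max_sp_rounds: int = 16,
                            ) -> DeterministicResult:
    """Exactness probe on the fully deterministic workflow.

    A single procedure (identical under the generator) is observed without
    noise.  The SP decoder is trained in 200-step rounds until its greedy
    sequences match the ground truth at every probe time (or the round
    budget runs out); the regression head is trained on the fixed
    annealing schedule.  Probes are placed mid-minute (one per elapsed
    minute, at :math:`t = 60k+30` for classification and :math:`60k+15`
    for the held-out regression grid) so that a probe never coincides with
    an annotation boundary.
    """
    voc = PhaseVocabulary.default()
    wf = deterministic_model(voc, DETERMINISTIC_DURATIONS_S)
    tl = sample_workflow(wf, derive_seed(seed, "det-timeline"))
    obs = sample_observations(tl, _BENCH_CONFIG["d_obs"], 0.0,
                              derive_seed(seed, "det-obs"))
    dataset = [(tl, obs)]
    cfg = ModelConfig(n_classes=voc.size, **_BENCH_CONFIG)

    # classification: train until the probe grid is reproduced exactly
    sp = AnticipationModel(cfg, "sp", seed=derive_seed(seed, "det-sp-init"))
    probes = list(range(30, len(tl), 60))
    windows = np.stack([feature_window(obs.features, t, cfg.seq_len)
                        for t in probes])
    targets = np.stack([anticipation_target(tl, t, cfg.horizon_minutes).future
                        for t in probes])
    acc = 0.0
    rounds = 0
    for rounds in range(1, min(max_sp_rounds, len(_DET_SP_LRS)) + 1):
        tc = TrainConfig(decoder_kind="sp", steps=200, batch_size=16,
                         learning_rate=_DET_SP_LRS[rounds - 1],
                         seed=derive_seed(seed, f"det-sp-round/{rounds}"))
        train_model(sp, dataset, tc)
        seqs = np.argmax(predict_batch(sp, windows)["grids"], axis=-1)
        acc = float(np.mean(np.all(seqs == targets, axis=1)))
        if acc == 1.0:
            break

    # regression: fixed annealing schedule, then checkpoint averaging over
    # the final rounds (the accuracy floor is SGD noise, which averaging
    # cancels), evaluated on a held-out probe grid
    reg = AnticipationModel(cfg, "regression", seed=derive_seed(seed, "det-reg-init"))
    snapshots = []
    for rnd, (lr, batch, steps) in enumerate(_DET_SCHEDULE):
        tc = TrainConfig(decoder_kind="regression", steps=steps,
                         batch_size=batch, learning_rate=lr,
                         seed=derive_seed(seed, f"det-reg-round/{rnd}"))
        train_model(reg, dataset, tc)
        if rnd >= len(_DET_SCHEDULE) - _DET_AVERAGE_LAST:
            snapshots.append(reg.state_dict())
    reg.load_state_dict({k: np.mean([s[k] for s in snapshots], axis=0)
                         for k in snapshots[0]})
    held = list(range(15, len(tl), 60))
    hw = np.stack([feature_window(obs.features, t, cfg.seq_len)
                   for t in held])
    ht = np.stack([remaining_time_target(tl, t, cfg.horizon_minutes).minutes
                   for t in held])
    pred = predict_batch(reg, hw)["remaining_minutes"]
    mae = float(np.mean(_next_phase_errors(pred, ht)))
    return DeterministicResult(sp_sequence_accuracy=acc,
                               regression_next_phase_mae=mae,
                               n_probes=len(probes), sp_rounds=rounds)


@dataclass(frozen=True)
class OrderingResult:
    f1_sp_star: float
    f1_sp: float
    f1_naive1: float
    f1_naive2: float
    per_seed: dict
    naive2_changes_per_seq: float
    gt_changes_per_seq: float
    naive1_changes_per_seq: float


def _eval_probe_arrays(test_set, cfg, stride_s: int = 120):
    windows, targets, currents, owners = [], [], [], []
    for tl, obs in test_set:
        for t in range(0, len(tl), stride_s):
            windows.append(feature_window(obs.features, t, cfg.seq_len))
            targets.append(
                anticipation_target(tl, t, cfg.horizon_minutes).future)
            currents.append(int(tl.labels[t]))
            owners.append(tl.video_id)
    return (np.stack(windows), np.stack(targets), np.array(currents),
            owners)


def _model_sequences(model: AnticipationModel, windows: np.ndarray,
                     batch: int = 64) -> np.ndarray:
    seqs = []
    for lo in range(0, len(windows), batch):
        out = predict_batch(model, windows[lo: lo + batch])
        seqs.append(np.argmax(out["grids"], axis=-1))
    return np.concatenate(seqs)


def ordering_benchmark(seed: int, n_seeds: int = 3, n_train: int = 200,
                       n_test: int = 50, noise_level: float = 0.6,
                       skip_prob: float = 0.05, repeat_prob: float = 0.05,
                       eos_cap: int = 4) -> OrderingResult:
    """SP* vs SP vs the naive baselines on stochastic workflows.

    For each repetition seed: simulate a training and a test corpus, fit
    the transition prior on the training timelines, train SP and SP*
    decoders, and score every method's 15-minute horizon sequences with
    EOS-capped mean weighted F1 at probes every two minutes.  The naive
    baselines are conditioned on the ground-truth current phase (the
    strongest version of those baselines).  Also counts label changes per
    predicted sequence, the over-fragmentation signature of independent
    per-minute sampling.
    """
    voc = PhaseVocabulary.default()
    wf = default_cholec_like_model(voc, skip_prob=skip_prob,
                                   repeat_prob=repeat_prob)
    cfg = ModelConfig(n_classes=voc.size, **_BENCH_CONFIG)
    n = cfg.horizon_minutes
    per_seed: dict[int, dict[str, float]] = {}
    n2_changes, gt_changes, n1_changes = [], [], []
    for rep in range(n_seeds):
        rs = derive_seed(seed, f"ordering/{rep}")
        train_set = sample_dataset(wf, n_train, cfg.d_obs, noise_level,
                                   derive_seed(rs, "train-corpus"))
        test_set = sample_dataset(wf, n_test, cfg.d_obs, noise_level,
                                  derive_seed(rs, "test-corpus"))
        prior = estimate_transition_prior([tl for tl, _ in train_set], n)
        windows, targets, currents, _ = _eval_probe_arrays(test_set, cfg)
        scores: dict[str, float] = {}

        for kind in ("sp", "sp_star"):
            model = AnticipationModel(cfg, kind, seed=derive_seed(rs, f"{kind}-init"),
                              prior=prior if kind == "sp_star" else None)
            tc = TrainConfig(decoder_kind=kind, steps=_ORDER_STEPS,
                             batch_size=_ORDER_BATCH,
                             learning_rate=_ORDER_LR,
                             seed=derive_seed(rs, f"{kind}-train"))
            train_model(model, train_set, tc)
            seqs = _model_sequences(model, windows)
            scores[kind] = horizon_scores(seqs, targets, voc.eos_index,
                                          eos_cap).mean_f1

        n1 = np.stack([naive1_predict(c, n) for c in currents])
        scores["naive1"] = horizon_scores(n1, targets, voc.eos_index,
                                          eos_cap).mean_f1
        n2 = np.stack([
            naive2_predict(prior, c, n, mode="sample",
                           seed=derive_seed(rs, f"naive2/{k}"))
            for k, c in enumerate(currents)])
        scores["naive2"] = horizon_scores(n2, targets, voc.eos_index,
                                          eos_cap).mean_f1
        per_seed[rep] = scores
        n2_changes.extend(np.sum(np.diff(n2, axis=1) != 0, axis=1))
        gt_changes.extend(np.sum(np.diff(targets, axis=1) != 0, axis=1))
        n1_changes.extend(np.sum(np.diff(n1, axis=1) != 0, axis=1))

    mean = {k: float(np.mean([per_seed[r][k] for r in per_seed]))
            for k in ("sp_star", "sp", "naive1", "naive2")}
    return OrderingResult(
        f1_sp_star=mean["sp_star"], f1_sp=mean["sp"],
        f1_naive1=mean["naive1"], f1_naive2=mean["naive2"],
        per_seed=per_seed,
        naive2_changes_per_seq=float(np.mean(n2_changes)),
        gt_changes_per_seq=float(np.mean(gt_changes)),
        naive1_changes_per_seq=float(np.mean(n1_changes)))
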