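"""Evaluation metrics for phase recognition and anticipation.

Frame-level scores use support-weighted F1 (class importance proportional
to its frequency in the targets), computed per horizon step and averaged
over the horizon.  Because the end-of-surgery class would otherwise
dominate long horizons — every step past the end of a procedure is EOS —
at most ``cap`` EOS steps per target sequence are retained for scoring
(the earliest ones), mirroring the 4-minute (Cholec80-like) and 8-minute
(AutoLaparo-like) caps used with real data.

Segment-level quality is scored with SegF1: predicted segments are matched
to same-phase ground-truth segments by greedy best-IoU matching at a
threshold (default 0.5); unmatched predictions are false positives (so
oversegmentation is penalised) and unmatched ground-truth segments false
negatives.

Remaining-time predictions are scored with inMAE (samples whose true next
occurrence falls inside the horizon), outMAE (samples clamped at the
horizon: the class does not occur) and wMAE (per class, the unweighted
mean of the two, then averaged over classes — the convention of the
next-occurrence-regression literature).  Remaining-surgery-duration (RSD)
errors are reported as MAE-5 / MAE-30 / MAE-ALL over the late-surgery
subsets defined by ground-truth RSD thresholds, mean ± SD across videos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .timelines import PhaseTimeline, SegmentList, labels_to_segments

__all__ = [
    "HorizonScores",
    "MAEReport",
    "RSDReport",
    "weighted_f1",
    "cap_eos",
    "seg_f1",
    "horizon_scores",
    "horizon_seg_f1",
    "anticipation_mae",
    "rsd_mae",
    "select_model",
]


@dataclass(frozen=True)
class HorizonScores:
    """Per-horizon and aggregate classification scores (all in [0, 1])."""

    per_horizon_f1: dict[int, float]
    mean_f1: float
    per_horizon_acc: dict[int, float]
    acc_up_to: dict[int, float]


@dataclass(frozen=True)
class MAEReport:
    """Remaining-time MAEs in minutes; NaN marks an empty sample set."""

    wmae: float
    inmae: float
    outmae: float
    per_class_inmae: np.ndarray
    per_class_outmae: np.ndarray
    horizon: float


@dataclass(frozen=True)
class RSDReport:
    """Remaining-surgery-duration MAEs: (mean, SD) across videos."""

    mae_5: tuple[float, float]
    mae_30: tuple[float, float]
    mae_all: tuple[float, float]
    per_video: dict[str, tuple[float, float, float]]


def weighted_f1(preds: Sequence[int], targets: Sequence[int],
                labels: Sequence[int] | None = None) -> float:
    """Support-weighted F1 over one set of label pairs."""
    preds = np.asarray(preds)
    targets = np.asarray(targets)
    if preds.shape != targets.shape:
        raise ValueError("predictions and targets must align")
    if preds.size == 0:
        raise ValueError("empty evaluation set")
    return float(f1_score(targets, preds, average="weighted",
                          labels=None if labels is None else list(labels),
                          zero_division=0))


def cap_eos(target_seqs: np.ndarray, cap_minutes: int,
            eos_index: int) -> np.ndarray:
    """Boolean keep-mask: at most ``cap`` EOS steps per sequence (earliest).

    ``target_seqs`` is (S, N) ground-truth horizon labels; masked-out cells
    are excluded from scoring entirely.
    """
    if cap_minutes < 0:
        raise ValueError("EOS cap must be >= 0")
    targets = np.asarray(target_seqs)
    is_eos = targets == eos_index
    rank = np.cumsum(is_eos, axis=-1)  # 1-based rank of each EOS cell
    return ~(is_eos & (rank > cap_minutes))


def seg_f1(pred_segments: SegmentList, gt_segments: SegmentList,
           iou_threshold: float = 0.5) -> float:
    """Segment F1 under greedy best-IoU, same-phase matching.

    Candidate pairs with equal phase and IoU >= threshold are matched in
    descending IoU order (ties by segment order); each segment matches at
    most once.  F1 = 2TP / (2TP + FP + FN).
    """
    preds = list(pred_segments)
    gts = list(gt_segments)
    if not gts and not preds:
        return 1.0
    if not preds or not gts:
        return 0.0
    cands = []
    for pi, p in enumerate(preds):
        for gi, g in enumerate(gts):
            if p.phase != g.phase:
                continue
            inter = min(p.end_s, g.end_s) - max(p.start_s, g.start_s)
            if inter <= 0:
                continue
            union = max(p.end_s, g.end_s) - min(p.start_s, g.start_s)
            iou = inter / union
            if iou >= iou_threshold:
                cands.append((-iou, pi, gi))
    cands.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, pi, gi in cands:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        tp += 1
    fp = len(preds) - tp
    fn = len(gts) - tp
    return 2.0 * tp / (2.0 * tp + fp + fn) if tp else 0.0


def horizon_scores(pred_seqs: np.ndarray, target_seqs: np.ndarray,
                   eos_index: int, eos_cap: int | None = None,
                   ) -> HorizonScores:
    """Weighted F1 and accuracy per horizon step, with EOS capping.

    ``pred_seqs`` / ``target_seqs`` are (S, N) label matrices, column n
    being the prediction/target for minute n+1.  The mean F1 averages the
    per-minute scores over the horizon.
    """
    preds = np.asarray(pred_seqs)
    targets = np.asarray(target_seqs)
    if preds.shape != targets.shape or preds.ndim != 2:
        raise ValueError("need matching (S, N) prediction/target matrices")
    n = preds.shape[1]
    keep = (cap_eos(targets, eos_cap, eos_index) if eos_cap is not None
            else np.ones_like(targets, dtype=bool))
    f1s: dict[int, float] = {}
    accs: dict[int, float] = {}
    for h in range(1, n + 1):
        m = keep[:, h - 1]
        if not m.any():
            continue
        f1s[h] = weighted_f1(preds[m, h - 1], targets[m, h - 1])
        accs[h] = float(np.mean(preds[m, h - 1] == targets[m, h - 1]))
    acc_up_to = {h: float(np.mean([accs[k] for k in accs if k <= h]))
                 for h in accs}
    return HorizonScores(per_horizon_f1=f1s,
                         mean_f1=float(np.mean(list(f1s.values()))),
                         per_horizon_acc=accs, acc_up_to=acc_up_to)


def horizon_seg_f1(pred_seq: Sequence[int], target_seq: Sequence[int],
                   eos_index: int, eos_cap: int | None = None,
                   iou_threshold: float = 0.5) -> float:
    """SegF1 of one predicted horizon sequence against its target.

    EOS capping is applied first: steps beyond the allowed EOS budget of
    the target are dropped from both sequences (they are trailing by
    construction), then both are run-length encoded and matched.
    """
    pred = np.asarray(pred_seq)
    target = np.asarray(target_seq)
    if eos_cap is not None:
        keep = cap_eos(target[None, :], eos_cap, eos_index)[0]
        pred, target = pred[keep], target[keep]
    if target.size == 0:
        return 1.0
    return seg_f1(labels_to_segments(pred), labels_to_segments(target),
                  iou_threshold)


def anticipation_mae(preds: np.ndarray, targets: np.ndarray,
                     horizon: float) -> MAEReport:
    """inMAE / outMAE / wMAE of remaining-time predictions, per class.

    ``preds`` and ``targets`` are (S, C) matrices of minutes; both are
    clamped to [0, horizon].  Per class: inMAE averages samples with
    0 < target < horizon, outMAE those with target = horizon ("will not
    occur"); empty sets are NaN and excluded from the class averages.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    preds = np.clip(np.atleast_2d(np.asarray(preds, dtype=float)),
                    0.0, horizon)
    targets = np.clip(np.atleast_2d(np.asarray(targets, dtype=float)),
                      0.0, horizon)
    if preds.shape != targets.shape:
        raise ValueError("predictions and targets must align")
    err = np.abs(preds - targets)
    in_mask = (targets > 0) & (targets < horizon)
    out_mask = targets == horizon
    n_classes = preds.shape[1]
    in_c = np.full(n_classes, np.nan)
    out_c = np.full(n_classes, np.nan)
    for c in range(n_classes):
        if in_mask[:, c].any():
            in_c[c] = err[in_mask[:, c], c].mean()
        if out_mask[:, c].any():
            out_c[c] = err[out_mask[:, c], c].mean()
    def nanmean(arr: np.ndarray) -> float:
        finite = arr[np.isfinite(arr)]
        return float(finite.mean()) if finite.size else float("nan")

    w_c = np.array([nanmean(np.array([in_c[c], out_c[c]]))
                    for c in range(n_classes)])
    return MAEReport(
        wmae=nanmean(w_c), inmae=nanmean(in_c), outmae=nanmean(out_c),
        per_class_inmae=in_c, per_class_outmae=out_c, horizon=float(horizon))


def rsd_mae(preds: Sequence[np.ndarray],
            timelines: Sequence[PhaseTimeline]) -> RSDReport:
    """Remaining-surgery-duration MAEs per video, mean ± SD across videos.

    ``preds[v][t]`` is the predicted remaining duration (minutes) of video
    v at second t; ground truth is ``(length - t) / 60``.  MAE-5 / MAE-30
    restrict to seconds whose true RSD is at most 5 / 30 minutes.
    """
    if len(preds) != len(timelines) or not timelines:
        raise ValueError("need one prediction series per video")
    per_video: dict[str, tuple[float, float, float]] = {}
    rows = []
    for series, tl in zip(preds, timelines):
        series = np.asarray(series, dtype=float)
        if series.size == 0:
            raise ValueError(f"empty prediction series for {tl.video_id}")
        if series.size != len(tl):
            raise ValueError(
                f"{tl.video_id}: series length {series.size} != {len(tl)}")
        t = np.arange(len(tl))
        rsd = (len(tl) - t) / 60.0
        err = np.abs(series - rsd)
        vals = (float(err[rsd <= 5].mean()),
                float(err[rsd <= 30].mean()),
                float(err.mean()))
        per_video[tl.video_id] = vals
        rows.append(vals)
    arr = np.array(rows)
    agg = [(float(arr[:, i].mean()), float(arr[:, i].std())) for i in range(3)]
    return RSDReport(mae_5=agg[0], mae_30=agg[1], mae_all=agg[2],
                     per_video=per_video)


def select_model(candidates: Sequence[tuple[object, float]],
                 task: str) -> object:
    """Pick the best candidate by validation score.

    ``candidates`` are (candidate, score) pairs in checkpoint order.
    Classification selects the highest mean weighted F1; regression the
    lowest wMAE.  Ties go to the earliest candidate.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    scores = [s for _, s in candidates]
    if task == "classification":
        best = max(range(len(scores)), key=lambda i: (scores[i], -i))
    else:
        best = min(range(len(scores)), key=lambda i: (scores[i], i))
    return candidates[best][0]
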