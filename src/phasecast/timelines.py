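"""Phase timelines: data model, annotation-file I/O and target construction.

A surgical procedure is represented as a per-second sequence of phase
labels (a :class:`PhaseTimeline`).  The phase vocabulary holds the C-1
operative phases plus a final end-of-surgery (EOS) class; EOS never appears
in timeline labels and is introduced only when building anticipation or
remaining-time targets, where it marks time past the end of the procedure.

Coordinates are seconds, 0-based; segments are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PhaseVocabulary",
    "PhaseTimeline",
    "Segment",
    "SegmentList",
    "AnticipationTarget",
    "RemainingTimeTarget",
    "read_phase_annotations",
    "resample_to_1fps",
    "timeline_to_segments",
    "segments_to_timeline",
    "anticipation_target",
    "remaining_time_target",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation files (a user-input error)."""


@dataclass(frozen=True)
class PhaseVocabulary:
    """Ordered phase names; the last entry is the end-of-surgery class."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("phase names must be unique")
        if len(self.names) < 2:
            raise ValueError("need at least one phase plus EOS")
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def size(self) -> int:
        """C = number of surgical phases + 1 (EOS)."""
        return len(self.names)

    @property
    def eos_index(self) -> int:
        return len(self.names) - 1

    @property
    def eos_name(self) -> str:
        return self.names[-1]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown phase name: {name!r}") from None

    @classmethod
    def default(cls, n_phases: int = 7) -> "PhaseVocabulary":
        """Generic vocabulary: P1..Pn plus EOS."""
        return cls(tuple(f"P{i + 1}" for i in range(n_phases)) + ("EOS",))

    @classmethod
    def cholec80(cls) -> "PhaseVocabulary":
        """The seven cholecystectomy phases of the Cholec80 annotation set."""
        return cls((
            "Preparation",
            "CalotTriangleDissection",
            "ClippingCutting",
            "GallbladderDissection",
            "GallbladderPackaging",
            "CleaningCoagulation",
            "GallbladderRetraction",
            "EOS",
        ))


@dataclass(frozen=True)
class PhaseTimeline:
    """Per-second (or per-frame) ground-truth phase labels for one procedure."""

    video_id: str
    labels: np.ndarray
    vocabulary: PhaseVocabulary
    fps_original: int = 1

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if labels.min() < 0 or labels.max() >= self.vocabulary.eos_index:
            raise ValueError(
                "labels must be valid non-EOS vocabulary indices")
        if self.fps_original < 1:
            raise ValueError("fps_original must be >= 1")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> int:
        """Length in seconds (valid for 1 fps timelines)."""
        return len(self)


@dataclass(frozen=True)
class Segment:
    start_s: int
    end_s: int  # half-open
    phase: int

    @property
    def length(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SegmentList:
    """Sorted, non-overlapping, exactly tiling segments of one timeline."""

    segments: tuple[Segment, ...]

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        pos = None
        for s in segs:
            if s.end_s <= s.start_s:
                raise ValueError(f"empty or inverted segment: {s}")
            if pos is not None and s.start_s != pos:
                raise ValueError("segments must tile contiguously")
            pos = s.end_s

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class AnticipationTarget:
    """Ground-truth phase at the current minute and each future minute.

    ``labels[n]`` is the phase active at second ``t + n*60`` (n = 0..N);
    entries at times past the end of the video are the EOS class.
    """

    t: int
    horizon_minutes: int
    labels: np.ndarray  # length N+1, entry 0 = current phase

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.size != self.horizon_minutes + 1:
            raise ValueError("need N+1 labels (h_0..h_N)")

    @property
    def future(self) -> np.ndarray:
        """The N future entries h_1..h_N (excluding the current phase)."""
        return self.labels[1:]

    def to_dict(self) -> dict:
        return {"t": self.t, "horizon_minutes": self.horizon_minutes,
                "labels": self.labels.tolist()}


@dataclass(frozen=True)
class RemainingTimeTarget:
    """Minutes until each class next occurs, clamped to the horizon N.

    0 means the class is active at t; N means it does not occur within the
    horizon.  The EOS entry is the remaining procedure duration (clamped).
    """

    t: int
    horizon_minutes: int
    minutes: np.ndarray  # length C, EOS last

    def __post_init__(self):
        minutes = np.asarray(self.minutes, dtype=np.float64)
        object.__setattr__(self, "minutes", minutes)
        if minutes.min() < 0 or minutes.max() > self.horizon_minutes:
            raise ValueError("remaining times must lie in [0, N]")

    def to_dict(self) -> dict:
        return {"t": self.t, "horizon_minutes": self.horizon_minutes,
                "minutes": self.minutes.tolist()}


# -- annotation file I/O ---------------------------------------------------

_DIALECTS = {
    # name -> (separator, has_header, fps, labels_are_names)
    "cholec80": ("\t", True, 25, True),
    "autolaparo": ("\t", False, 1, True),
    "generic_tsv": (None, False, 1, True),
}


def read_phase_annotations(path: str | Path,
                           dialect: str,
                           vocabulary: PhaseVocabulary,
                           fps: int | None = None) -> PhaseTimeline:
    """Read a plain-text phase annotation file into a :class:`PhaseTimeline`.

    Dialects: ``cholec80`` — header line then tab-separated
    ``frame<TAB>PhaseName`` at 25 fps; ``autolaparo`` — per-second
    ``frame<TAB>PhaseName`` without header at 1 fps; ``generic_tsv`` —
    whitespace-separated ``index label`` at 1 fps (``fps`` overrides).
    Labels may be phase names or integer indices.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; "
                         f"expected one of {sorted(_DIALECTS)}")
    sep, has_header, dialect_fps, _ = _DIALECTS[dialect]
    fps = dialect_fps if fps is None else fps
    path = Path(path)
    labels: list[int] = []
    prev_frame = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if has_header and lineno == 1:
                continue
            parts = line.split(sep) if sep else line.split()
            if len(parts) < 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 'frame label', got {raw!r}")
            try:
                frame = int(parts[0])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer frame index {parts[0]!r}")
            if prev_frame is not None and frame <= prev_frame:
                raise AnnotationError(
                    f"{path}:{lineno}: non-monotone frame index {frame}")
            prev_frame = frame
            token = parts[1]
            if token.lstrip("-").isdigit():
                idx = int(token)
                if not 0 <= idx < vocabulary.eos_index:
                    raise AnnotationError(
                        f"{path}:{lineno}: phase index {idx} out of range")
            else:
                try:
                    idx = vocabulary.index(token)
                except KeyError:
                    raise AnnotationError(
                        f"{path}:{lineno}: unknown phase name {token!r}")
                if idx == vocabulary.eos_index:
                    raise AnnotationError(
                        f"{path}:{lineno}: EOS may not appear in annotations")
            labels.append(idx)
    if not labels:
        raise AnnotationError(f"{path}: no annotation lines")
    return PhaseTimeline(video_id=path.stem, labels=np.array(labels),
                         vocabulary=vocabulary, fps_original=fps)


def write_phase_annotations(tl: PhaseTimeline, path: str | Path) -> None:
    """Write a timeline in the generic_tsv dialect (index, phase name)."""
    path = Path(path)
    with path.open("w") as fh:
        for i, lab in enumerate(tl.labels):
            fh.write(f"{i}\t{tl.vocabulary.names[int(lab)]}\n")


def resample_to_1fps(tl: PhaseTimeline) -> PhaseTimeline:
    """Decimate to 1 fps, keeping every ``fps_original``-th label from 0."""
    if tl.fps_original == 1:
        return tl
    if tl.fps_original < 1 or int(tl.fps_original) != tl.fps_original:
        raise ValueError("fps_original must be a positive integer")
    return PhaseTimeline(video_id=tl.video_id,
                         labels=tl.labels[:: tl.fps_original],
                         vocabulary=tl.vocabulary, fps_original=1)


# -- segments --------------------------------------------------------------

def timeline_to_segments(tl: PhaseTimeline) -> SegmentList:
    """Run-length encode a 1 fps timeline into phase segments."""
    labels = tl.labels
    if labels.size == 0:
        raise ValueError("empty timeline")
    return labels_to_segments(labels)


def labels_to_segments(labels: Sequence[int]) -> SegmentList:
    """Run-length encode any 1-D label sequence into segments."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return SegmentList(tuple(
        Segment(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)))


def segments_to_timeline(segments: SegmentList, video_id: str,
                         vocabulary: PhaseVocabulary) -> PhaseTimeline:
    """Inverse of :func:`timeline_to_segments`."""
    labels = np.concatenate([
        np.full(seg.length, seg.phase, dtype=np.int64) for seg in segments])
    return PhaseTimeline(video_id=video_id, labels=labels,
                         vocabulary=vocabulary, fps_original=1)


# -- targets ---------------------------------------------------------------

def _check_query(tl: PhaseTimeline, t: int, horizon_minutes: int) -> None:
    if not 0 <= t < len(tl):
        raise ValueError(f"query second t={t} outside [0, {len(tl)})")
    if horizon_minutes < 1:
        raise ValueError("horizon must be >= 1 minute")
    if tl.fps_original != 1:
        raise ValueError("targets require a 1 fps timeline")


def anticipation_target(tl: PhaseTimeline, t: int,
                        horizon_minutes: int) -> AnticipationTarget:
    """Phase at t and at each of the next N minutes; EOS past the end."""
    _check_query(tl, t, horizon_minutes)
    eos = tl.vocabulary.eos_index
    times = t + 60 * np.arange(horizon_minutes + 1)
    labels = np.where(times < len(tl),
                      tl.labels[np.minimum(times, len(tl) - 1)], eos)
    return AnticipationTarget(t=t, horizon_minutes=horizon_minutes,
                              labels=labels)


def remaining_time_target(tl: PhaseTimeline, t: int,
                          horizon_minutes: int) -> RemainingTimeTarget:
    """Minutes until each class's next occurrence at or after t, clamped.

    A class active at t gets 0; a class not occurring within the horizon
    gets N; the EOS entry is ``(length - t) / 60`` clamped to N.
    """
    _check_query(tl, t, horizon_minutes)
    voc = tl.vocabulary
    minutes = np.full(voc.size, float(horizon_minutes))
    future = tl.labels[t:]
    for c in range(voc.eos_index):
        hits = np.flatnonzero(future == c)
        if hits.size:
            minutes[c] = min(hits[0] / 60.0, float(horizon_minutes))
    minutes[voc.eos_index] = min((len(tl) - t) / 60.0, float(horizon_minutes))
    return RemainingTimeTarget(t=t, horizon_minutes=horizon_minutes,
                               minutes=minutes)
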