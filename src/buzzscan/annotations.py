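"""Audacity label-track annotations and interval-to-frame truth conversion.

Annotations are time-stamped intervals with a base label (e.g. ``ins_buzz``)
plus optional dot-suffixed tags encoding volume (``quiet``/``loud``), a
whole-period ``background`` condition, and a buzz pitch class.  The central
operation is :func:`frame_truth`, which converts interval annotations into
a per-frame boolean truth vector using the matching rule applied throughout
evaluation: a frame is positive for a label if at least 10% of the frame
(0.096 s at default geometry) overlaps an annotation of that label, or if
an entire annotated event is contained within the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .audio_io import Frame, FrameSpec

__all__ = [
    "DEFAULT_LABELS",
    "LabelVocabulary",
    "LabelEvent",
    "MatchPolicy",
    "LabelTrackParseError",
    "read_label_track",
    "write_label_track",
    "merge_events",
    "frame_truth",
]

# the 13 annotation labels of the training vocabulary, most-to-least data
DEFAULT_LABELS = (
    "ambient_background",
    "mech_auto",
    "mech_plane",
    "ins_buzz",
    "ins_trill",
    "ambient_noise",
    "mech_hum",
    "ambient_rain",
    "human",
    "frog",
    "mech_siren",
    "mech_train",
    "bird_goose",
)

_TAGS = frozenset({"quiet", "loud", "background"})
_PITCH_CLASSES = frozenset({"low", "medium", "high"})
_EPS = 1e-9  # boundary-equality tolerance on seconds


class LabelTrackParseError(ValueError):
    """Malformed label-track line; carries the file path and line number."""


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered label names plus an optional raw-label collapse map.

    ``collapse_map`` rewrites raw annotation labels to vocabulary members,
    supporting coarser neuron groupings than the annotation scheme.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    collapse_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels) or any(not x for x in labels):
            raise ValueError("labels must be unique and non-empty")
        bad = [v for v in self.collapse_map.values() if v not in labels]
        if bad:
            raise ValueError(f"collapse_map targets not in vocabulary: {bad}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def resolve(self, raw: str) -> str:
        """Map a raw label through the collapse map; raise if unknown."""
        label = self.collapse_map.get(raw, raw)
        if label not in self.labels:
            raise KeyError(f"unknown label {raw!r} (not in vocabulary or collapse_map)")
        return label

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class LabelEvent:
    """One annotated interval: [start_s, end_s) with base label and tags."""

    start_s: float
    end_s: float
    label: str
    tags: frozenset[str] = frozenset()
    pitch_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_s <= self.end_s):
            raise ValueError(f"require 0 <= start <= end, got [{self.start_s}, {self.end_s}]")
        object.__setattr__(self, "tags", frozenset(self.tags))
        unknown = self.tags - _TAGS
        if unknown:
            raise ValueError(f"unknown tags {sorted(unknown)}; allowed: {sorted(_TAGS)}")
        if self.pitch_class is not None and self.pitch_class not in _PITCH_CLASSES:
            raise ValueError(f"unknown pitch class {self.pitch_class!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, start: float, end: float) -> float:
        """Seconds of overlap between this event and the interval [start, end)."""
        return max(0.0, min(self.end_s, end) - max(self.start_s, start))


@dataclass(frozen=True)
class MatchPolicy:
    """Rule deciding when a frame counts as positive for an event label.

    A frame is positive if its overlap with annotations of the target label
    reaches ``min_overlap_fraction`` of the frame length, or (when
    ``full_containment_positive``) if a whole event lies inside the frame —
    so a very short buzz entirely within a frame still marks it positive.
    Whole-period ``background`` events are excluded from truth by default,
    mirroring the choice not to annotate a faint background hum of activity;
    they may instead be counted positive or negative.
    """

    min_overlap_fraction: float = 0.10
    full_containment_positive: bool = True
    background_policy: Literal["exclude", "positive", "negative"] = "exclude"

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")

    def min_overlap_s(self, frame_length_s: float) -> float:
        return self.min_overlap_fraction * frame_length_s


def _split_label(raw: str, vocab: LabelVocabulary) -> tuple[str, frozenset[str], str | None]:
    parts = raw.split(".")
    base, suffixes = parts[0], parts[1:]
    tags = frozenset(s for s in suffixes if s in _TAGS)
    pitch = next((s for s in suffixes if s in _PITCH_CLASSES), None)
    unknown = [s for s in suffixes if s not in _TAGS and s not in _PITCH_CLASSES]
    if unknown:
        raise KeyError(f"unknown label suffixes {unknown} in {raw!r}")
    return vocab.resolve(base), tags, pitch


def read_label_track(path: str | Path, vocab: LabelVocabulary | None = None) -> list[LabelEvent]:
    """Parse an Audacity label track (tab-separated start/end/label lines).

    Tags and pitch classes ride on the label text as dot suffixes
    (``ins_buzz.quiet``).  Audacity frequency-range continuation lines
    (leading backslash) are ignored.  Events are returned sorted by start.
    """
    vocab = vocab or LabelVocabulary()
    path = Path(path)
    events: list[LabelEvent] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("\\"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LabelTrackParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise LabelTrackParseError(f"{path}:{lineno}: non-numeric time: {exc}") from exc
            if end < start:
                raise LabelTrackParseError(f"{path}:{lineno}: end {end} < start {start}")
            try:
                base, tags, pitch = _split_label(fields[2].strip(), vocab)
            except KeyError as exc:
                raise LabelTrackParseError(f"{path}:{lineno}: {exc.args[0]}") from exc
            events.append(LabelEvent(start, end, base, tags, pitch))
    events.sort(key=lambda e: (e.start_s, e.end_s, e.label))
    return events


def write_label_track(events: Sequence[LabelEvent], path: str | Path) -> None:
    """Write events as an Audacity-compatible label track.

    Times use millisecond precision; tags and pitch class are re-encoded as
    dot suffixes, so the file round-trips through :func:`read_label_track`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for ev in sorted(events, key=lambda e: (e.start_s, e.end_s, e.label)):
        label = ev.label
        for tag in sorted(ev.tags):
            label += f".{tag}"
        if ev.pitch_class is not None:
            label += f".{ev.pitch_class}"
        lines.append(f"{ev.start_s:.3f}\t{ev.end_s:.3f}\t{label}")
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def merge_events(events: Sequence[LabelEvent], gap_tol_s: float = 0.0) -> list[LabelEvent]:
    """Fuse overlapping or near-abutting fragments of one base label.

    Annotators split a single buzz into ``quiet``/``loud`` sections; per-buzz
    analyses need the whole event back, so fragments whose gap is at most
    ``gap_tol_s`` are merged, unioning tags.  Idempotent and order-invariant.
    """
    if not events:
        return []
    labels = {e.label for e in events}
    if len(labels) > 1:
        raise ValueError(f"merge_events requires a single base label, got {sorted(labels)}")
    ordered = sorted(events, key=lambda e: (e.start_s, e.end_s))
    merged = [ordered[0]]
    for ev in ordered[1:]:
        last = merged[-1]
        if ev.start_s - last.end_s <= gap_tol_s + _EPS:
            merged[-1] = replace(
                last,
                end_s=max(last.end_s, ev.end_s),
                tags=last.tags | ev.tags,
                pitch_class=last.pitch_class or ev.pitch_class,
            )
        else:
            merged.append(ev)
    return merged


def frame_truth(
    events: Sequence[LabelEvent],
    frames: Sequence[Frame],
    policy: MatchPolicy,
    target_label: str,
    frame_length_s: float = FrameSpec().frame_length_s,
) -> np.ndarray:
    """Per-frame boolean truth for one target label.

    A frame is positive iff its summed overlap with (merged) target-label
    events reaches the policy minimum, or a whole event sits inside the
    frame.  Overlap is summed across same-label events after merging, so a
    buzz split into fragments is judged as one interval.  Returns a mask of
    length ``len(frames)``; the matching ``background``-tagged whole-period
    events follow ``policy.background_policy`` (excluded frames are returned
    in the companion mask from :func:`background_mask`).
    """
    mask = np.zeros(len(frames), dtype=bool)
    target = [e for e in events if e.label == target_label and "background" not in e.tags]
    merged = merge_events(target) if target else []
    min_overlap = policy.min_overlap_s(frame_length_s)
    for i, frame in enumerate(frames):
        f0, f1 = frame.start_s, frame.start_s + frame_length_s
        total = 0.0
        positive = False
        for ev in merged:
            ov = ev.overlap_s(f0, f1)
            if ov <= 0:
                continue
            total += ov
            if (
                policy.full_containment_positive
                and ev.start_s >= f0 - _EPS
                and ev.end_s <= f1 + _EPS
            ):
                positive = True
        if positive or total >= min_overlap - _EPS:
            mask[i] = True
    if policy.background_policy == "positive":
        mask |= background_mask(events, frames, target_label, frame_length_s)
    return mask


_EMPTY_WAVEFORM = np.empty(0)


def frames_from_starts(starts: Iterable[float]) -> list[Frame]:
    """Waveform-less frames for truth computation from start times alone."""
    return [Frame(index=i, start_s=float(s), waveform=_EMPTY_WAVEFORM) for i, s in enumerate(starts)]


def background_mask(
    events: Sequence[LabelEvent],
    frames: Sequence[Frame],
    target_label: str,
    frame_length_s: float = FrameSpec().frame_length_s,
) -> np.ndarray:
    """Frames touched by a ``background``-tagged whole-period event.

    Used to drop ambiguous constant-hum periods from evaluation when the
    policy excludes them.
    """
    mask = np.zeros(len(frames), dtype=bool)
    bg = [e for e in events if e.label == target_label and "background" in e.tags]
    for i, frame in enumerate(frames):
        f0, f1 = frame.start_s, frame.start_s + frame_length_s
        if any(ev.overlap_s(f0, f1) > _EPS for ev in bg):
            mask[i] = True
    return mask


def excluded_frames(
    events: Sequence[LabelEvent],
    frames: Sequence[Frame],
    policy: MatchPolicy,
    target_label: str,
    frame_length_s: float = FrameSpec().frame_length_s,
) -> np.ndarray:
    """Mask of frames to drop from evaluation under the background policy."""
    if policy.background_policy != "exclude":
        return np.zeros(len(frames), dtype=bool)
    bg = background_mask(events, frames, target_label, frame_length_s)
    # frames already positive from explicit annotations stay in
    truth = frame_truth(events, frames, policy, target_label, frame_length_s)
    return bg & ~truth
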