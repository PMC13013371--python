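"""Step annotations, the step→phase ontology, and per-frame weak label tracks.

Surgical workflow annotations come as step segments: time intervals within a
video, each carrying a fine-grained, procedure-specific step label. Steps map
many-to-one onto coarser surgical phases. From the step segments this module
derives three per-frame label tracks at a fixed sampling rate:

* ``step``  — the annotated step, ``UNLABELED`` outside any segment;
* ``phase`` — the mapped phase, with gaps between successive steps closed
  (phases by definition tile the annotated span without gaps): a gap between
  two steps of the same phase takes that phase, a gap between steps of
  different phases takes the phase of the earlier step;
* ``time``  — the index of the frame's equal-duration temporal bin (10 by
  default), a free weak label that proxies monotone case progression.

Frame ``t`` covers the half-open interval ``[t/fps, (t+1)/fps)``; a segment
``[a, b)`` claims frame ``t`` iff ``a <= t/fps < b``. Frames before the first
segment's start and after the last segment's end stay ``UNLABELED`` in the
step and phase tracks and are excluded from training and scoring downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

#: Reserved token for frames carrying no label of the track's type.
UNLABELED = "__UNLABELED__"

TRACK_TYPES = ("step", "phase", "time")


class AnnotationError(ValueError):
    """Raised for invalid segments, ontologies, or malformed files."""


@dataclass(frozen=True)
class StepSegment:
    """One annotated step interval ``[start_s, end_s)`` within a video."""

    video_id: str
    start_s: float
    end_s: float
    step_label: str

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise AnnotationError(
                f"{self.video_id}: segment start {self.start_s} < 0"
            )
        if not self.start_s < self.end_s:
            raise AnnotationError(
                f"{self.video_id}: segment [{self.start_s}, {self.end_s}) "
                f"for step {self.step_label!r} has start >= end"
            )


@dataclass
class Ontology:
    """Per-procedure step vocabularies and the many-to-one step→phase map.

    ``steps[proc]`` lists the step vocabulary of a procedure in canonical
    order; ``step_to_phase[proc]`` maps every step of that procedure to
    exactly one phase. Vocabularies of different procedures may be disjoint
    or overlap; both are recorded explicitly, nothing is inferred.
    """

    steps: dict[str, list[str]] = field(default_factory=dict)
    step_to_phase: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for proc, vocab in self.steps.items():
            mapping = self.step_to_phase.get(proc, {})
            missing = [s for s in vocab if s not in mapping]
            if missing:
                raise AnnotationError(
                    f"procedure {proc!r}: steps {missing} lack a phase mapping"
                )

    @property
    def procedures(self) -> list[str]:
        return list(self.steps)

    def phases(self, procedure: str) -> list[str]:
        """Phase vocabulary of a procedure, in first-appearance order."""
        seen: dict[str, None] = {}
        for step in self.steps[procedure]:
            seen.setdefault(self.step_to_phase[procedure][step], None)
        return list(seen)

    def phase_of(self, procedure: str, step_label: str) -> str:
        try:
            return self.step_to_phase[procedure][step_label]
        except KeyError:
            raise AnnotationError(
                f"step {step_label!r} is not in the ontology of "
                f"procedure {procedure!r}"
            ) from None


@dataclass
class FrameLabelTrack:
    """Per-frame labels of one type for one video at a fixed sampling rate."""

    video_id: str
    label_type: str
    fps: float
    labels: list[str]

    def __post_init__(self) -> None:
        if self.label_type not in TRACK_TYPES:
            raise AnnotationError(f"unknown label_type {self.label_type!r}")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def labeled_mask(self) -> list[bool]:
        return [lab != UNLABELED for lab in self.labels]


def n_frames_for(duration_s: float, fps: float) -> int:
    """Frame count of a video: floor(duration * fps)."""
    return int(duration_s * fps)


def _sorted_validated(
    segments: Sequence[StepSegment], duration_s: float
) -> list[StepSegment]:
    segs = sorted(segments, key=lambda s: (s.start_s, s.end_s))
    for prev, cur in zip(segs, segs[1:]):
        # shared boundary (prev.end == cur.start) is not an overlap
        if cur.start_s < prev.end_s:
            raise AnnotationError(
                f"{cur.video_id}: overlapping segments "
                f"[{prev.start_s}, {prev.end_s}) ({prev.step_label!r}) and "
                f"[{cur.start_s}, {cur.end_s}) ({cur.step_label!r})"
            )
    for seg in segs:
        if seg.end_s > duration_s + 1e-9:
            raise AnnotationError(
                f"{seg.video_id}: segment end {seg.end_s} exceeds video "
                f"duration {duration_s}"
            )
    return segs


def derive_step_track(
    segments: Sequence[StepSegment],
    duration_s: float,
    fps: float = 1.0,
    video_id: str | None = None,
) -> FrameLabelTrack:
    """Per-frame step labels; frames inside no segment get ``UNLABELED``."""
    if duration_s <= 0:
        raise AnnotationError(f"non-positive duration {duration_s}")
    segs = _sorted_validated(segments, duration_s)
    if video_id is None:
        video_id = segs[0].video_id if segs else "<empty>"
    n = n_frames_for(duration_s, fps)
    labels = [UNLABELED] * n
    for seg in segs:
        # frame t is claimed iff start <= t/fps < end
        first = max(0, int(-(-seg.start_s * fps // 1)))  # ceil(start*fps)
        for t in range(first, n):
            time = t / fps
            if time >= seg.end_s:
                break
            if time >= seg.start_s:
                labels[t] = seg.step_label
    return FrameLabelTrack(video_id, "step", fps, labels)


def derive_phase_track(
    segments: Sequence[StepSegment],
    ontology: Ontology,
    procedure: str,
    duration_s: float,
    fps: float = 1.0,
    video_id: str | None = None,
) -> FrameLabelTrack:
    """Per-frame phase labels with the gap-closure rules applied.

    Within a segment a frame gets the segment step's mapped phase. A gap
    between successive steps of the same phase takes that phase; a gap
    between steps of different phases takes the earlier step's phase
    (back-fill). Frames before the first segment and after the last stay
    ``UNLABELED``: phases tile only the annotated span.
    """
    if duration_s <= 0:
        raise AnnotationError(f"non-positive duration {duration_s}")
    segs = _sorted_validated(segments, duration_s)
    for seg in segs:
        ontology.phase_of(procedure, seg.step_label)  # raises if missing
    if video_id is None:
        video_id = segs[0].video_id if segs else "<empty>"
    n = n_frames_for(duration_s, fps)
    labels = [UNLABELED] * n
    if not segs:
        return FrameLabelTrack(video_id, "phase", fps, labels)
    # Extend each segment's phase forward to the start of the next segment:
    # this realizes both gap rules at once (same phase -> that phase;
    # different phase -> the earlier step's phase).
    bounds = [seg.start_s for seg in segs[1:]] + [segs[-1].end_s]
    for seg, until in zip(segs, bounds):
        phase = ontology.phase_of(procedure, seg.step_label)
        for t in range(n):
            time = t / fps
            if seg.start_s <= time < until:
                labels[t] = phase
    return FrameLabelTrack(video_id, "phase", fps, labels)


def derive_time_track(
    duration_s: float,
    fps: float = 1.0,
    n_bins: int = 10,
    video_id: str = "<unnamed>",
) -> FrameLabelTrack:
    """Elapsed-time bin labels: frame at time t gets floor(n_bins*t/duration).

    The bin index is clamped to ``n_bins - 1`` so the exact endpoint never
    creates a phantom bin. Every frame is labeled; bins are contiguous and
    non-decreasing over frames.
    """
    if duration_s <= 0:
        raise AnnotationError(f"non-positive duration {duration_s}")
    if n_bins < 1:
        raise AnnotationError(f"n_bins must be >= 1, got {n_bins}")
    n = n_frames_for(duration_s, fps)
    labels = []
    for t in range(n):
        b = int(n_bins * (t / fps) / duration_s)
        labels.append(str(min(b, n_bins - 1)))
    return FrameLabelTrack(video_id, "time", fps, labels)


# ---------------------------------------------------------------------------
# File I/O: annotations CSV, ontology YAML, track CSV
# ---------------------------------------------------------------------------

ANNOTATION_HEADER = ["video_id", "procedure", "start_s", "end_s", "step"]


@dataclass
class VideoAnnotation:
    video_id: str
    procedure: str
    segments: list[StepSegment]


def read_annotations(path) -> dict[str, VideoAnnotation]:
    """Read a step-annotation CSV, grouping segments by video.

    Expected header: ``video_id,procedure,start_s,end_s,step``. Malformed
    rows are reported with their line number.
    """
    videos: dict[str, VideoAnnotation] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return videos
        if list(reader.fieldnames) != ANNOTATION_HEADER:
            raise AnnotationError(
                f"{path}: expected header {ANNOTATION_HEADER}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            lineno = reader.line_num
            try:
                seg = StepSegment(
                    video_id=row["video_id"],
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    step_label=row["step"],
                )
            except (TypeError, ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            va = videos.setdefault(
                seg.video_id, VideoAnnotation(seg.video_id, row["procedure"], [])
            )
            if va.procedure != row["procedure"]:
                raise AnnotationError(
                    f"{path}:{lineno}: video {seg.video_id!r} appears with "
                    f"two procedures ({va.procedure!r}, {row['procedure']!r})"
                )
            va.segments.append(seg)
    for va in videos.values():
        va.segments.sort(key=lambda s: (s.start_s, s.end_s))
    return videos


def write_annotations(videos: Iterable[VideoAnnotation], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for va in videos:
            for seg in sorted(va.segments, key=lambda s: (s.start_s, s.end_s)):
                writer.writerow(
                    [va.video_id, va.procedure,
                     repr(seg.start_s), repr(seg.end_s), seg.step_label]
                )


def read_ontology(path) -> Ontology:
    """Read an ontology YAML: per-procedure ``steps`` and ``step_to_phase``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    steps: dict[str, list[str]] = {}
    mapping: dict[str, dict[str, str]] = {}
    for proc, entry in raw.items():
        if not isinstance(entry, Mapping) or "steps" not in entry:
            raise AnnotationError(
                f"{path}: procedure {proc!r} must define a 'steps' list"
            )
        steps[proc] = [str(s) for s in entry["steps"]]
        mapping[proc] = {
            str(k): str(v) for k, v in (entry.get("step_to_phase") or {}).items()
        }
    return Ontology(steps=steps, step_to_phase=mapping)


def write_ontology(ontology: Ontology, path) -> None:
    doc = {
        proc: {
            "steps": list(ontology.steps[proc]),
            "step_to_phase": dict(ontology.step_to_phase[proc]),
        }
        for proc in ontology.procedures
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_track(track: FrameLabelTrack, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "frame_index", "label"])
        for t, lab in enumerate(track.labels):
            writer.writerow([track.video_id, t, lab])


def read_track(path, label_type: str, fps: float = 1.0) -> FrameLabelTrack:
    labels: list[str] = []
    video_id = "<empty>"
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            lineno = reader.line_num
            try:
                idx = int(row["frame_index"])
            except (TypeError, ValueError, KeyError):
                raise AnnotationError(f"{path}:{lineno}: bad frame_index") from None
            if idx != len(labels):
                raise AnnotationError(
                    f"{path}:{lineno}: frame indices must be 0..n-1 in order"
                )
            video_id = row["video_id"]
            labels.append(row["label"])
    return FrameLabelTrack(video_id, label_type, fps, labels)
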