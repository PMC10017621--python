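"""Per-video temporal annotations at phase and step level.

Times are integer milliseconds and intervals are half-open ``[start, end)``,
so adjacent intervals never double-count a boundary millisecond.  A track is
*totalized* by filling un-annotated time with the ontology's idle label; all
metrics operate on totalized tracks, which tile ``[0, duration_ms)`` exactly.

Annotation files are plain CSV with columns
``video_id,rater_id,level,label,start_ms,end_ms`` and an optional
``#duration_ms=<int>`` comment header; one file holds one video/rater pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .ontology import Ontology, Level

__all__ = [
    "Interval",
    "AnnotationTrack",
    "VideoAnnotation",
    "AnnotationError",
    "read_annotation_file",
    "write_annotation_file",
    "totalize",
    "validate_hierarchy",
]

_COLUMNS = ["video_id", "rater_id", "level", "label", "start_ms", "end_ms"]


class AnnotationError(ValueError):
    """Raised when an annotation file or track violates its invariants."""


@dataclass(frozen=True)
class Interval:
    """A labeled half-open interval ``[start_ms, end_ms)``."""

    label: str
    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise AnnotationError(
                f"interval {self.label!r}: end_ms {self.end_ms} must exceed "
                f"start_ms {self.start_ms}"
            )
        if self.start_ms < 0:
            raise AnnotationError(f"interval {self.label!r}: negative start_ms")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class AnnotationTrack:
    """One rater's ordered, non-overlapping intervals at one level."""

    video_id: str
    level: Level
    intervals: tuple[Interval, ...]
    duration_ms: int

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in self.intervals:
            if iv.start_ms < prev_end:
                raise AnnotationError(
                    f"{self.video_id}/{self.level}: interval {iv.label!r} at "
                    f"{iv.start_ms} overlaps or precedes previous end {prev_end}"
                )
            prev_end = iv.end_ms
        if self.intervals and self.intervals[-1].end_ms > self.duration_ms:
            raise AnnotationError(
                f"{self.video_id}/{self.level}: intervals extend past "
                f"duration_ms={self.duration_ms}"
            )

    @property
    def labels_used(self) -> list[str]:
        out: list[str] = []
        for iv in self.intervals:
            if iv.label not in out:
                out.append(iv.label)
        return out

    def with_duration(self, duration_ms: int) -> "AnnotationTrack":
        """Same intervals on a (longer) timeline."""
        return replace(self, duration_ms=duration_ms)


@dataclass(frozen=True)
class VideoAnnotation:
    """One rater's complete annotation of one video: phase + step tracks."""

    video_id: str
    rater_id: str
    phase_track: AnnotationTrack
    step_track: AnnotationTrack

    def __post_init__(self) -> None:
        for tr in (self.phase_track, self.step_track):
            if tr.video_id != self.video_id:
                raise AnnotationError(
                    f"track video_id {tr.video_id!r} != {self.video_id!r}"
                )
        if self.phase_track.duration_ms != self.step_track.duration_ms:
            raise AnnotationError(
                f"{self.video_id}: phase and step tracks disagree on duration "
                f"({self.phase_track.duration_ms} vs {self.step_track.duration_ms})"
            )

    @property
    def duration_ms(self) -> int:
        return self.phase_track.duration_ms

    def track(self, level: Level) -> AnnotationTrack:
        return self.phase_track if level == "phase" else self.step_track


def totalize(track: AnnotationTrack, idle_label: str = "idle") -> AnnotationTrack:
    """Fill gaps with idle intervals so the track tiles ``[0, duration_ms)``.

    Idempotent; the sum of interval lengths afterwards equals ``duration_ms``
    exactly.  An empty track becomes a single idle interval.
    """
    out: list[Interval] = []
    cursor = 0
    for iv in track.intervals:
        if iv.start_ms > cursor:
            out.append(Interval(idle_label, cursor, iv.start_ms))
        out.append(iv)
        cursor = iv.end_ms
    if cursor < track.duration_ms:
        out.append(Interval(idle_label, cursor, track.duration_ms))
    return replace(track, intervals=tuple(out))


def _validate_labels(track: AnnotationTrack, o: Ontology) -> None:
    valid = set(o.labels(track.level)) | {o.idle_label}
    for iv in track.intervals:
        if iv.label not in valid:
            raise AnnotationError(
                f"{track.video_id}/{track.level}: label {iv.label!r} is not a "
                f"{track.level} label of ontology {o.name!r}"
            )


def read_annotation_file(path: str | Path, o: Ontology) -> VideoAnnotation:
    """Read one video/rater annotation CSV and validate it against ``o``.

    ``duration_ms`` comes from a ``#duration_ms=`` header comment when
    present, else from the maximum ``end_ms`` over both levels.
    """
    path = Path(path)
    declared_duration: int | None = None
    body_lines: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("duration_ms="):
                declared_duration = int(stripped.split("=", 1)[1])
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), dtype={"label": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise AnnotationError(f"{path}: no annotation rows")
    vids = df["video_id"].unique()
    raters = df["rater_id"].unique()
    if len(vids) != 1 or len(raters) != 1:
        raise AnnotationError(
            f"{path}: one file must hold exactly one video/rater "
            f"(got videos {list(vids)}, raters {list(raters)})"
        )
    duration = declared_duration or int(df["end_ms"].max())

    tracks: dict[str, AnnotationTrack] = {}
    for level in ("phase", "step"):
        sub = df[df["level"] == level].sort_values("start_ms")
        intervals = tuple(
            Interval(str(r.label), int(r.start_ms), int(r.end_ms))
            for r in sub.itertuples()
        )
        track = AnnotationTrack(
            video_id=str(vids[0]), level=level,  # type: ignore[arg-type]
            intervals=intervals, duration_ms=duration,
        )
        _validate_labels(track, o)
        tracks[level] = track
    bad_levels = set(df["level"].unique()) - {"phase", "step"}
    if bad_levels:
        raise AnnotationError(f"{path}: unknown level values {sorted(bad_levels)}")
    return VideoAnnotation(
        video_id=str(vids[0]),
        rater_id=str(raters[0]),
        phase_track=tracks["phase"],
        step_track=tracks["step"],
    )


def write_annotation_file(va: VideoAnnotation, path: str | Path) -> None:
    """Write the canonical annotation CSV (inverse of :func:`read_annotation_file`)."""
    rows = []
    for level in ("phase", "step"):
        for iv in va.track(level).intervals:  # type: ignore[arg-type]
            rows.append(
                (va.video_id, va.rater_id, level, iv.label, iv.start_ms, iv.end_ms)
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#duration_ms={va.duration_ms}\n")
        df.to_csv(fh, index=False)


def validate_hierarchy(va: VideoAnnotation, o: Ontology) -> list[str]:
    """Warn where step time is not nested under the step's parent phase.

    One warning per maximal millisecond span where a step interval overlaps
    phase time that is not its parent phase (idle phase time included).
    Warnings only — the agreement metrics treat the two levels independently.
    """
    warnings: list[str] = []
    phase_runs = totalize(va.phase_track, o.idle_label).intervals
    for step_iv in va.step_track.intervals:
        try:
            parent = o.parent_phase_of_step(step_iv.label).name
        except KeyError:
            continue  # idle or foreign labels have no parent to check
        for ph_iv in phase_runs:
            lo = max(step_iv.start_ms, ph_iv.start_ms)
            hi = min(step_iv.end_ms, ph_iv.end_ms)
            if hi > lo and ph_iv.label != parent:
                warnings.append(
                    f"{va.video_id}: step {step_iv.label!r} overlaps phase "
                    f"{ph_iv.label!r} (expected {parent!r}) on [{lo}, {hi})"
                )
    return warnings
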