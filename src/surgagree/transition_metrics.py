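"""Application-dependent (AD) metrics around phase/step transitions.

Every label change on a totalized timeline is a *transitional moment*.
Comparing a rater's transitions with the reference yields:

* **average transitional delay (ATD)** — mean (signed or absolute) offset
  between matched annotated and real transitions, in seconds;
* **coefficient of transitional moments (C_TM)** — annotated transition
  count as a percentage of the real transition count;
* **noise level (NL)** — percentage of annotated segments with zero
  temporal overlap with any real segment of the same label;
* **delta-relaxed classical metrics** — accuracy/precision/recall/F1
  recomputed after forgiving disagreement within ``delta_ms`` of a real
  transition, provided the annotated label matches the reference label on
  either side of that transition.  The default tolerance is 5 s.

Transition matching is signature-first greedy nearest-neighbour (pairs
sharing the same ``from -> to`` labels matched by smallest absolute delay),
then signature-free greedy for the remainder; no time window is imposed at
the matching stage — the relaxation threshold only enters the relaxed
metrics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .annotations import AnnotationTrack
from .timeline_metrics import (
    Averaging,
    ConfusionMatrix,
    MetricSet,
    _average_metric_sets,
    _check_comparable,
    _runs,
    metric_set_from_confusion,
    union_labels,
)

__all__ = [
    "TransitionEvent",
    "TransitionMatch",
    "MatchResult",
    "ADConfig",
    "extract_transitions",
    "match_transitions",
    "average_transitional_delay",
    "coefficient_of_transitional_moments",
    "noise_level",
    "relaxed_confusion",
    "ad_metric_set",
    "merged_segments",
]

DelayMode = Literal["signed", "absolute"]
RelaxMode = Literal["both", "pre", "post"]


@dataclass(frozen=True)
class TransitionEvent:
    """A timestamped label change on a totalized track."""

    time_ms: int
    from_label: str
    to_label: str

    def __post_init__(self) -> None:
        if self.from_label == self.to_label:
            raise ValueError("a transition must change the label")

    @property
    def signature(self) -> tuple[str, str]:
        return (self.from_label, self.to_label)


@dataclass(frozen=True)
class TransitionMatch:
    real: TransitionEvent
    annotated: TransitionEvent

    @property
    def delay_ms(self) -> int:
        """Signed delay: positive when the annotated transition is late."""
        return self.annotated.time_ms - self.real.time_ms


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[TransitionMatch, ...]
    unmatched_real: tuple[TransitionEvent, ...]
    unmatched_annotated: tuple[TransitionEvent, ...]


@dataclass(frozen=True)
class ADConfig:
    """Conventions for the application-dependent metrics.

    delta_ms
        Acceptable transitional delay; disagreement within this distance of
        a real transition is forgiven by the relaxed metrics (default 5 s).
    delay_mode
        Whether ATD averages signed or absolute delays.
    relax_mode
        Which reference label(s) adjacent to a transition earn credit
        inside the relaxation window.
    """

    delta_ms: int = 5000
    delay_mode: DelayMode = "signed"
    relax_mode: RelaxMode = "both"

    def __post_init__(self) -> None:
        if self.delta_ms < 0:
            raise ValueError("delta_ms must be non-negative")


def merged_segments(
    track: AnnotationTrack, include_idle: bool = True, idle_label: str = "idle"
) -> list[tuple[str, int, int]]:
    """Maximal same-label runs of a totalized track."""
    merged: list[tuple[str, int, int]] = []
    for lab, s, e in _runs(track):
        if merged and merged[-1][0] == lab and merged[-1][2] == s:
            merged[-1] = (lab, merged[-1][1], e)
        else:
            merged.append((lab, s, e))
    if not include_idle:
        merged = [seg for seg in merged if seg[0] != idle_label]
    return merged


def extract_transitions(track: AnnotationTrack) -> list[TransitionEvent]:
    """All label changes, sorted by time; idle participates like any label."""
    segs = merged_segments(track)
    return [
        TransitionEvent(time_ms=b[1], from_label=a[0], to_label=b[0])
        for a, b in zip(segs, segs[1:])
    ]


def _greedy_pairs(
    real: list[TransitionEvent], annotated: list[TransitionEvent]
) -> list[tuple[TransitionEvent, TransitionEvent]]:
    """Greedy one-to-one pairing by smallest |delay| (ties: earlier events)."""
    heap: list[tuple[int, int, int, int, int]] = []
    for i, r in enumerate(real):
        for j, a in enumerate(annotated):
            heapq.heappush(
                heap, (abs(a.time_ms - r.time_ms), r.time_ms, a.time_ms, i, j)
            )
    used_r: set[int] = set()
    used_a: set[int] = set()
    out: list[tuple[TransitionEvent, TransitionEvent]] = []
    while heap and len(out) < min(len(real), len(annotated)):
        _, _, _, i, j = heapq.heappop(heap)
        if i in used_r or j in used_a:
            continue
        used_r.add(i)
        used_a.add(j)
        out.append((real[i], annotated[j]))
    return out


def match_transitions(
    real: list[TransitionEvent], annotated: list[TransitionEvent]
) -> MatchResult:
    """One-to-one matching: same-signature pairs first, then the remainder."""
    by_sig: dict[tuple[str, str], tuple[list, list]] = {}
    for r in real:
        by_sig.setdefault(r.signature, ([], []))[0].append(r)
    for a in annotated:
        by_sig.setdefault(a.signature, ([], []))[1].append(a)

    matched: list[TransitionMatch] = []
    rest_r: list[TransitionEvent] = []
    rest_a: list[TransitionEvent] = []
    for rs, ans in by_sig.values():
        pairs = _greedy_pairs(rs, ans)
        matched.extend(TransitionMatch(r, a) for r, a in pairs)
        got_r = {id(r) for r, _ in pairs}
        got_a = {id(a) for _, a in pairs}
        rest_r.extend(r for r in rs if id(r) not in got_r)
        rest_a.extend(a for a in ans if id(a) not in got_a)

    pairs = _greedy_pairs(rest_r, rest_a)
    matched.extend(TransitionMatch(r, a) for r, a in pairs)
    got_r = {id(r) for r, _ in pairs}
    got_a = {id(a) for _, a in pairs}
    matched.sort(key=lambda m: (m.real.time_ms, m.annotated.time_ms))
    return MatchResult(
        matches=tuple(matched),
        unmatched_real=tuple(r for r in rest_r if id(r) not in got_r),
        unmatched_annotated=tuple(a for a in rest_a if id(a) not in got_a),
    )


def average_transitional_delay(
    matches: MatchResult | tuple[TransitionMatch, ...] | list[TransitionMatch],
    cfg: ADConfig = ADConfig(),
) -> float | None:
    """Mean matched delay in seconds (signed by default); None if no matches."""
    ms = matches.matches if isinstance(matches, MatchResult) else tuple(matches)
    if not ms:
        return None
    delays = np.array([m.delay_ms for m in ms], dtype=float)
    if cfg.delay_mode == "absolute":
        delays = np.abs(delays)
    return float(delays.mean()) / 1000.0


def coefficient_of_transitional_moments(
    real: list[TransitionEvent], annotated: list[TransitionEvent]
) -> float | None:
    """100 x annotated / real transition counts; None when real is empty."""
    if not real:
        return None
    return 100.0 * len(annotated) / len(real)


def noise_level(
    real: AnnotationTrack, annotated: AnnotationTrack, idle_label: str = "idle"
) -> float | None:
    """Percent of annotated segments with no same-label overlap in the reference.

    Segments are maximal same-label runs; idle time is excluded from both
    numerator and denominator.  None when the annotated track has no
    non-idle segments.
    """
    _check_comparable(real, annotated)
    real_by_label: dict[str, list[tuple[int, int]]] = {}
    for lab, s, e in merged_segments(real, include_idle=False, idle_label=idle_label):
        real_by_label.setdefault(lab, []).append((s, e))
    ann = merged_segments(annotated, include_idle=False, idle_label=idle_label)
    if not ann:
        return None
    noisy = 0
    for lab, s, e in ann:
        spans = real_by_label.get(lab, [])
        if not any(min(e, re) > max(s, rs) for rs, re in spans):
            noisy += 1
    return 100.0 * noisy / len(ann)


def relaxed_confusion(
    gt: AnnotationTrack,
    pred: AnnotationTrack,
    cfg: ADConfig = ADConfig(),
    labels: list[str] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix with disagreement forgiven near real transitions.

    A millisecond ``m`` with ``gt`` label ``g`` and ``pred`` label ``p != g``
    is credited to the diagonal cell of ``g`` when some ground-truth
    transition at time ``t`` satisfies ``t - delta_ms <= m < t + delta_ms``
    and ``p`` equals the gt label adjacent to that transition (per
    ``relax_mode``).  Total duration is conserved; ``delta_ms = 0``
    reproduces the classical confusion exactly.
    """
    _check_comparable(gt, pred)
    labs = union_labels(gt, pred, labels)
    idx = {lab: i for i, lab in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=np.int64)

    # relaxation windows [t - delta, t + delta) with their creditable labels
    windows: list[tuple[int, int, frozenset[str]]] = []
    if cfg.delta_ms > 0:
        for ev in extract_transitions(gt):
            if cfg.relax_mode == "pre":
                allowed = frozenset({ev.from_label})
            elif cfg.relax_mode == "post":
                allowed = frozenset({ev.to_label})
            else:
                allowed = frozenset({ev.from_label, ev.to_label})
            windows.append(
                (max(0, ev.time_ms - cfg.delta_ms),
                 min(gt.duration_ms, ev.time_ms + cfg.delta_ms),
                 allowed)
            )

    cuts = {0, gt.duration_ms}
    for _, s, e in _runs(gt):
        cuts.add(s); cuts.add(e)
    for _, s, e in _runs(pred):
        cuts.add(s); cuts.add(e)
    for lo, hi, _ in windows:
        cuts.add(lo); cuts.add(hi)
    bounds = sorted(cuts)

    g_runs, p_runs = _runs(gt), _runs(pred)
    gi = pi = wi = 0
    for t, nt in zip(bounds, bounds[1:]):
        while g_runs[gi][2] <= t:
            gi += 1
        while p_runs[pi][2] <= t:
            pi += 1
        g, p = g_runs[gi][0], p_runs[pi][0]
        if p == g:
            counts[idx[g], idx[g]] += nt - t
            continue
        while wi < len(windows) and windows[wi][1] <= t:
            wi += 1
        forgiven = False
        for wj in range(wi, len(windows)):
            lo, hi, allowed = windows[wj]
            if lo >= nt:
                break
            if hi > t and p in allowed:
                forgiven = True
                break
        if forgiven:
            counts[idx[g], idx[g]] += nt - t
        else:
            counts[idx[g], idx[p]] += nt - t
    return ConfusionMatrix(labs, counts)


def ad_metric_set(
    a: AnnotationTrack,
    b: AnnotationTrack,
    cfg: ADConfig = ADConfig(),
    labels: list[str] | None = None,
    averaging: Averaging = "macro-present",
) -> MetricSet:
    """Symmetric delta-relaxed metric set (each track once as ground truth)."""
    labs = union_labels(a, b, labels)
    m_ab = metric_set_from_confusion(relaxed_confusion(a, b, cfg, labs), averaging)
    m_ba = metric_set_from_confusion(relaxed_confusion(b, a, cfg, labs), averaging)
    return _average_metric_sets(m_ab, m_ba)
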