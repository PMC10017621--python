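"""Synthetic two-rater annotation cohorts for a phase/step ontology.

The generator draws ground-truth surgical timelines (ordered phases with
log-normal durations, facultative phases included by Bernoulli draw, steps
tiling each phase) and simulates rater behaviour by perturbing them with
boundary jitter, label substitutions, spurious insertions and omissions.

Two shipped duration/technique profiles emulate a longer-procedure center
("strasbourg-like": ~108 min, ~10 phases, ~33 steps per video) and a
shorter-procedure center ("bern-like": ~75 min, ~8 phases, ~27 steps),
including the center-specific inclusion rates of omentum division, Petersen
space closure and mesenteric defect closure.  The noise model exists to
make every metric testable by parameter recovery; it does not model human
annotator cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .annotations import AnnotationTrack, Interval, VideoAnnotation, totalize
from .ontology import Level, Ontology
from .transition_metrics import merged_segments

__all__ = [
    "CohortProfile",
    "PerturbationConfig",
    "PerturbationLog",
    "CohortSample",
    "STRASBOURG_LIKE",
    "BERN_LIKE",
    "ZERO_NOISE",
    "INTER_RATER_NOISE",
    "INTRA_RATER_NOISE",
    "sample_ground_truth",
    "perturb_as_rater",
    "insert_spurious_segment",
    "generate_cohort",
    "profile_by_name",
]


@dataclass(frozen=True)
class CohortProfile:
    """Statistical description of one center's procedures.

    ``phase_mean_min`` maps phase id to mean duration in minutes (log-normal
    with coefficient of variation ``duration_cv``); ``phase_inclusion`` maps
    phase id to inclusion probability (phases absent from the map are always
    present); ``step_inclusion_prob`` is the probability a facultative step
    of an included phase is annotated.
    """

    name: str
    phase_mean_min: dict[int, float]
    phase_inclusion: dict[int, float]
    step_inclusion_prob: float
    duration_cv: float = 0.4
    inter_phase_gap_s: tuple[float, float] = (30.0, 15.0)  # mean, sd
    lead_in_s: tuple[float, float] = (60.0, 20.0)

    def inclusion(self, phase_id: int) -> float:
        return self.phase_inclusion.get(phase_id, 1.0)

    def expected_phase_count(self) -> float:
        return sum(self.inclusion(pid) for pid in self.phase_mean_min)


@dataclass(frozen=True)
class PerturbationConfig:
    """Rater noise model.

    boundary_jitter_mean_ms / boundary_jitter_sd_ms
        Additive Gaussian shift applied to every internal boundary of the
        totalized track (positive = late annotation); optionally clipped to
        ``jitter_max_abs_ms``.  Shifted boundaries that would invert an
        interval are clamped to keep every run at least 1 ms long.
    substitution_rate
        Per-segment probability of swapping the label for a confusable one
        (adjacent in ontology order by default).
    insertion_rate
        Expected number of spurious segments per track (Poisson); each is
        placed strictly inside a host segment with a different label, so one
        insertion adds exactly two transitional moments.
    deletion_rate
        Per-segment probability that a facultative segment is omitted
        (relabeled idle).
    """

    boundary_jitter_mean_ms: float = 0.0
    boundary_jitter_sd_ms: float = 0.0
    jitter_max_abs_ms: int | None = None
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    insertion_duration_s: tuple[float, float] = (20.0, 10.0)  # mean, sd
    deletion_rate: float = 0.0
    substitution_mode: Literal["adjacent", "uniform"] = "adjacent"
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.boundary_jitter_sd_ms < 0 or self.insertion_rate < 0:
            raise ValueError("sd and rates must be non-negative")


@dataclass
class PerturbationLog:
    """What a simulated rater actually did to one track."""

    realized_jitter_ms: list[int] = field(default_factory=list)
    n_insertions: int = 0
    n_substitutions: int = 0
    n_deletions: int = 0


ZERO_NOISE = PerturbationConfig()

#: Two independent raters annotating the same video.
INTER_RATER_NOISE = PerturbationConfig(
    boundary_jitter_mean_ms=2000, boundary_jitter_sd_ms=8000,
    substitution_rate=0.03, insertion_rate=0.5, deletion_rate=0.05,
)

#: One rater re-annotating after a wash-out period (more self-consistent).
INTRA_RATER_NOISE = PerturbationConfig(
    boundary_jitter_mean_ms=1000, boundary_jitter_sd_ms=4000,
    substitution_rate=0.01, insertion_rate=0.25, deletion_rate=0.02,
)

# Inclusion probabilities for phases 3/7/9 follow the reported per-center
# technique rates; those for phases 5/10/12 are calibrated once so the
# profile-expected phase count equals the reported per-center mean
# (10 and 8 phases respectively).
STRASBOURG_LIKE = CohortProfile(
    name="strasbourg-like",
    phase_mean_min={1: 6, 2: 26, 3: 8, 4: 18, 5: 4, 6: 6,
                    7: 4, 8: 24, 9: 4, 10: 5, 11: 3, 12: 10},
    phase_inclusion={3: 0.95, 5: 0.65, 7: 0.98, 9: 1.00, 10: 0.35, 12: 0.07},
    step_inclusion_prob=0.60,
)

BERN_LIKE = CohortProfile(
    name="bern-like",
    phase_mean_min={1: 5, 2: 15, 3: 5, 4: 16, 5: 3, 6: 5,
                    7: 3, 8: 18, 9: 3, 10: 4, 11: 2, 12: 8},
    phase_inclusion={3: 0.36, 5: 0.80, 7: 0.16, 9: 0.21, 10: 0.40, 12: 0.07},
    step_inclusion_prob=0.41,
)


def profile_by_name(name: str) -> CohortProfile:
    try:
        return {"strasbourg": STRASBOURG_LIKE, "bern": BERN_LIKE}[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r} (use 'strasbourg' or 'bern')")


def _lognormal_ms(rng: np.random.Generator, mean_s: float, cv_or_sd: float,
                  sd_is_abs: bool = True) -> int:
    """Sample a log-normal duration (seconds parameterized) as >=1 ms."""
    mean = max(mean_s, 1e-3)
    sd = cv_or_sd if sd_is_abs else cv_or_sd * mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    val = float(rng.lognormal(mu, np.sqrt(sigma2)))
    return max(1, int(round(val * 1000)))


def sample_ground_truth(
    o: Ontology,
    profile: CohortProfile,
    seed: int | np.random.SeedSequence,
    video_id: str = "video",
) -> VideoAnnotation:
    """Draw one ground-truth annotation (phases + nested steps).

    Phases appear in canonical order, separated by short idle gaps;
    included steps tile each phase exactly.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    phase_ivs: list[Interval] = []
    step_ivs: list[Interval] = []
    t = _lognormal_ms(rng, profile.lead_in_s[0], profile.lead_in_s[1])
    for phase in o.phases:
        if rng.random() >= profile.inclusion(phase.id):
            continue
        mean_min = profile.phase_mean_min.get(phase.id, 5.0)
        dur = _lognormal_ms(rng, mean_min * 60.0, profile.duration_cv * mean_min * 60.0)
        phase_ivs.append(Interval(phase.name, t, t + dur))

        steps = [
            s for s in o.steps_of_phase(phase.id)
            if not s.facultative or rng.random() < profile.step_inclusion_prob
        ]
        if not steps:  # a phase is never annotated without at least one step
            steps = [o.steps_of_phase(phase.id)[0]]
        weights = rng.lognormal(0.0, 0.5, size=len(steps))
        bounds = t + np.round(np.cumsum(weights) / weights.sum() * dur).astype(int)
        prev = t
        for s_def, b in zip(steps, bounds):
            b = max(prev + 1, min(int(b), t + dur))
            step_ivs.append(Interval(s_def.name, prev, b))
            prev = b
        # rounding guard: the last step must end exactly with the phase
        if step_ivs and step_ivs[-1].end_ms != t + dur:
            last = step_ivs.pop()
            step_ivs.append(Interval(last.label, last.start_ms, t + dur))
        t += dur
        t += _lognormal_ms(rng, profile.inter_phase_gap_s[0],
                           profile.inter_phase_gap_s[1])
    duration = t  # trailing gap after the last phase is the lead-out
    return VideoAnnotation(
        video_id=video_id,
        rater_id="truth",
        phase_track=AnnotationTrack(video_id, "phase", tuple(phase_ivs), duration),
        step_track=AnnotationTrack(video_id, "step", tuple(step_ivs), duration),
    )


def _jitter_boundaries(
    segs: list[tuple[str, int, int]],
    rng: np.random.Generator,
    pc: PerturbationConfig,
    duration_ms: int,
    log: PerturbationLog,
) -> list[tuple[str, int, int]]:
    if len(segs) < 2 or (pc.boundary_jitter_sd_ms == 0
                         and pc.boundary_jitter_mean_ms == 0):
        return list(segs)
    bounds = [s[2] for s in segs[:-1]]
    shifts = rng.normal(pc.boundary_jitter_mean_ms, pc.boundary_jitter_sd_ms,
                        size=len(bounds))
    if pc.jitter_max_abs_ms is not None:
        shifts = np.clip(shifts, -pc.jitter_max_abs_ms, pc.jitter_max_abs_ms)
    new_bounds: list[int] = []
    prev = 0
    for k, (b, sh) in enumerate(zip(bounds, shifts)):
        nb = int(round(b + sh))
        # keep >=1 ms per run and room for the remaining boundaries
        nb = max(prev + 1, min(nb, duration_ms - (len(bounds) - k)))
        new_bounds.append(nb)
        prev = nb
    log.realized_jitter_ms.extend(nb - b for nb, b in zip(new_bounds, bounds))
    edges = [0] + new_bounds + [duration_ms]
    return [(lab, s, e) for (lab, _, _), s, e in zip(segs, edges, edges[1:])]


def _perturb_track(
    track: AnnotationTrack,
    o: Ontology,
    pc: PerturbationConfig,
    rng: np.random.Generator,
) -> tuple[AnnotationTrack, PerturbationLog]:
    log = PerturbationLog()
    idle = o.idle_label
    level_labels = o.labels(track.level)
    segs = merged_segments(totalize(track, idle))
    segs = _jitter_boundaries(segs, rng, pc, track.duration_ms, log)

    out: list[tuple[str, int, int]] = []
    for lab, s, e in segs:
        if lab != idle and pc.deletion_rate > 0 and o.is_facultative(lab, track.level) \
                and rng.random() < pc.deletion_rate:
            out.append((idle, s, e))
            log.n_deletions += 1
            continue
        if lab != idle and pc.substitution_rate > 0 \
                and rng.random() < pc.substitution_rate:
            i = level_labels.index(lab)
            if pc.substitution_mode == "adjacent":
                if i == 0:
                    j = 1
                elif i == len(level_labels) - 1:
                    j = i - 1
                else:
                    j = i + (1 if rng.random() < 0.5 else -1)
            else:
                j = int(rng.integers(0, len(level_labels) - 1))
                if j >= i:
                    j += 1
            out.append((level_labels[j], s, e))
            log.n_substitutions += 1
            continue
        out.append((lab, s, e))

    n_ins = int(rng.poisson(pc.insertion_rate)) if pc.insertion_rate > 0 else 0
    inserted = [False] * len(out)
    for _ in range(n_ins):
        # hosts are original (non-spurious) segments long enough to split
        hosts = [k for k, (lab, s, e) in enumerate(out)
                 if lab != idle and e - s >= 6000 and not inserted[k]]
        if not hosts:
            break
        k = int(rng.choice(hosts))
        lab, s, e = out[k]
        dur = _lognormal_ms(rng, pc.insertion_duration_s[0],
                            pc.insertion_duration_s[1])
        dur = min(dur, (e - s) // 3)
        start = int(rng.integers(s + 1, e - dur))
        candidates = [x for x in level_labels if x != lab]
        new_lab = str(rng.choice(candidates))
        out[k:k + 1] = [(lab, s, start), (new_lab, start, start + dur),
                        (lab, start + dur, e)]
        inserted[k:k + 1] = [False, True, False]
        log.n_insertions += 1

    intervals = tuple(Interval(lab, s, e) for lab, s, e in out if lab != idle)
    return replace(track, intervals=intervals), log


def perturb_as_rater(
    truth: VideoAnnotation,
    pc: PerturbationConfig,
    o: Ontology,
    rater_id: str = "rater",
    rng: int | np.random.SeedSequence | np.random.Generator | None = None,
    with_log: bool = False,
):
    """Simulate a rater's annotation of ``truth`` under noise model ``pc``.

    With an all-zero config the output equals the input (up to rater id).
    ``rng`` overrides ``pc.seed``; pass ``with_log=True`` to also receive
    per-level :class:`PerturbationLog` records of the realized operations.
    """
    if rng is None:
        rng = np.random.default_rng(pc.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    phase_track, log_p = _perturb_track(truth.phase_track, o, pc, rng)
    step_track, log_s = _perturb_track(truth.step_track, o, pc, rng)
    va = VideoAnnotation(
        video_id=truth.video_id, rater_id=rater_id,
        phase_track=phase_track, step_track=step_track,
    )
    if with_log:
        return va, {"phase": log_p, "step": log_s}
    return va


def insert_spurious_segment(
    track: AnnotationTrack, label: str, start_ms: int, duration_ms: int
) -> AnnotationTrack:
    """Deterministically insert one spurious segment (test-fixture helper).

    The segment must fall strictly inside an existing interval with a
    different label, so it adds exactly two transitional moments.
    """
    end = start_ms + duration_ms
    for k, iv in enumerate(track.intervals):
        if iv.start_ms < start_ms and end < iv.end_ms:
            if iv.label == label:
                raise ValueError("spurious label equals host label")
            new = (
                track.intervals[:k]
                + (Interval(iv.label, iv.start_ms, start_ms),
                   Interval(label, start_ms, end),
                   Interval(iv.label, end, iv.end_ms))
                + track.intervals[k + 1:]
            )
            return replace(track, intervals=new)
    raise ValueError("segment must fall strictly inside one host interval")


@dataclass
class CohortSample:
    """A simulated paired-annotation cohort."""

    truths: list[VideoAnnotation]
    rater_a: list[VideoAnnotation]
    rater_b: list[VideoAnnotation]
    logs_a: list[dict[str, PerturbationLog]]
    logs_b: list[dict[str, PerturbationLog]]


def generate_cohort(
    o: Ontology,
    profile: CohortProfile,
    pc_a: PerturbationConfig,
    pc_b: PerturbationConfig,
    n: int,
    seed: int,
    video_prefix: str = "vid",
) -> CohortSample:
    """Draw ``n`` ground truths, each annotated by two simulated raters.

    One global seed fans out through ``numpy.random.SeedSequence.spawn`` to
    independent per-video streams (truth, rater A, rater B), so cohorts are
    byte-reproducible and extensible without stream reuse.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    sample = CohortSample([], [], [], [], [])
    for i, child in enumerate(ss.spawn(n)):
        s_truth, s_a, s_b = child.spawn(3)
        truth = sample_ground_truth(o, profile, s_truth, f"{video_prefix}{i:03d}")
        va, log_a = perturb_as_rater(truth, pc_a, o, "raterA", s_a, with_log=True)
        vb, log_b = perturb_as_rater(truth, pc_b, o, "raterB", s_b, with_log=True)
        sample.truths.append(truth)
        sample.rater_a.append(va)
        sample.rater_b.append(vb)
        sample.logs_a.append(log_a)
        sample.logs_b.append(log_b)
    return sample
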