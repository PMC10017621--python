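"""Independent brute-force oracles for the interval-algebra metrics.

Everything here works on dense 1 ms label arrays (or exhaustive assignment),
deliberately sharing no interval-sweep code with the package: tracks are
rasterized to one entry per millisecond and the metrics are computed by
direct array manipulation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from surgagree.annotations import AnnotationTrack, Interval


def dense_indices(track: AnnotationTrack, labels: list[str]) -> np.ndarray:
    """1 ms label-index array; track must tile [0, duration)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    out = np.full(track.duration_ms, -1, dtype=np.int32)
    for iv in track.intervals:
        out[iv.start_ms:iv.end_ms] = idx[iv.label]
    assert (out >= 0).all(), "track not totalized"
    return out


def dense_confusion(gt: AnnotationTrack, pred: AnnotationTrack,
                    labels: list[str]) -> np.ndarray:
    g = dense_indices(gt, labels)
    p = dense_indices(pred, labels)
    n = len(labels)
    return np.bincount(g * n + p, minlength=n * n).reshape(n, n)


def dense_transitions(track: AnnotationTrack) -> list[tuple[int, str, str]]:
    labels = sorted({iv.label for iv in track.intervals})
    arr = dense_indices(track, labels)
    times = np.nonzero(arr[1:] != arr[:-1])[0] + 1
    return [(int(t), labels[arr[t - 1]], labels[arr[t]]) for t in times]


def dense_relaxed_confusion(
    gt: AnnotationTrack, pred: AnnotationTrack, labels: list[str],
    delta_ms: int, relax_mode: str = "both",
) -> np.ndarray:
    """1 ms sampling with the transition-relaxation rule applied per ms."""
    idx = {lab: i for i, lab in enumerate(labels)}
    g = dense_indices(gt, labels)
    p = dense_indices(pred, labels)
    D = len(g)
    forgiven = np.zeros(D, dtype=bool)
    if delta_ms > 0:
        for t, pre, post in dense_transitions(gt):
            lo, hi = max(0, t - delta_ms), min(D, t + delta_ms)
            window = p[lo:hi]
            if relax_mode == "pre":
                ok = window == idx[pre]
            elif relax_mode == "post":
                ok = window == idx[post]
            else:
                ok = (window == idx[pre]) | (window == idx[post])
            forgiven[lo:hi] |= ok
    eff_pred = np.where((p == g) | forgiven, g, p)
    n = len(labels)
    return np.bincount(g * n + eff_pred, minlength=n * n).reshape(n, n)


def dense_noise_level(real: AnnotationTrack, annotated: AnnotationTrack,
                      idle: str = "idle") -> float | None:
    """Segment-count NL by per-ms same-label overlap lookup."""
    labels = sorted({iv.label for iv in real.intervals}
                    | {iv.label for iv in annotated.intervals} | {idle})
    idx = {lab: i for i, lab in enumerate(labels)}
    r = dense_indices(real, labels)
    a = dense_indices(annotated, labels)
    # maximal same-label runs of the annotated array
    edges = [0, *(np.nonzero(a[1:] != a[:-1])[0] + 1), len(a)]
    segs = [(int(a[s]), s, e) for s, e in zip(edges, edges[1:])
            if a[s] != idx[idle]]
    if not segs:
        return None
    noisy = sum(1 for li, s, e in segs if not np.any(r[s:e] == li))
    return 100.0 * noisy / len(segs)


def assignment_match(real_times: list[int], ann_times: list[int]
                     ) -> tuple[list[tuple[int, int]], float]:
    """Min-total-|delay| one-to-one assignment (exhaustive optimum)."""
    if not real_times or not ann_times:
        return [], 0.0
    cost = np.abs(np.subtract.outer(real_times, ann_times)).astype(float)
    ri, ai = linear_sum_assignment(cost)
    pairs = [(real_times[i], ann_times[j]) for i, j in zip(ri, ai)]
    return pairs, float(cost[ri, ai].sum())


def random_totalized_track(
    rng: np.random.Generator,
    labels: list[str],
    duration_ms: int,
    max_segments: int = 12,
    idle: str = "idle",
    p_idle: float = 0.2,
) -> AnnotationTrack:
    """A random fully-tiling track over <= max_segments runs."""
    k = int(rng.integers(1, max_segments))
    cuts = np.sort(rng.choice(np.arange(1, duration_ms), size=min(k, duration_ms - 1),
                              replace=False)) if duration_ms > 1 and k > 0 else np.array([], int)
    edges = [0, *map(int, cuts), duration_ms]
    ivs = []
    for s, e in zip(edges, edges[1:]):
        lab = idle if rng.random() < p_idle else str(rng.choice(labels))
        ivs.append(Interval(lab, s, e))
    return AnnotationTrack("rnd", "phase", tuple(ivs), duration_ms)
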