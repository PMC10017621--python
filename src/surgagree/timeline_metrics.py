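"""Classical time-weighted agreement metrics between two annotation tracks.

All computation is exact integer-millisecond interval algebra: the
duration-weighted confusion matrix is accumulated by a sweep over the merged
interval boundaries of both tracks, which is equivalent to dense 1 ms
sampling at any video length without the memory cost.

Because neither of two human raters is privileged, the comparison is made
symmetric: each track is treated once as ground truth and the metric sets
are averaged element-wise (Cohen's kappa is symmetric by construction).
A consequence worth knowing: symmetric-averaged macro precision equals
symmetric-averaged macro recall exactly, since transposing the confusion
matrix swaps the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .annotations import AnnotationTrack

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "Averaging",
    "time_weighted_confusion",
    "accuracy",
    "per_class_prf",
    "cohens_kappa",
    "metric_set_from_confusion",
    "symmetric_compare",
]

#: Macro over classes present in either track (default), macro over the full
#: label list, or micro (time-weighted pooling, equal to accuracy).
Averaging = Literal["macro-present", "macro-all", "micro"]


@dataclass
class ConfusionMatrix:
    """Duration-weighted confusion: rows = ground truth, columns = prediction.

    ``counts`` are milliseconds; the grand total equals the common timeline
    length of the two compared tracks.
    """

    labels: list[str]
    counts: np.ndarray  # (n_labels, n_labels) int64 milliseconds

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("confusion cells must be non-negative")

    @property
    def total_ms(self) -> int:
        return int(self.counts.sum())

    def cell(self, gt_label: str, pred_label: str) -> int:
        i = self.labels.index(gt_label)
        j = self.labels.index(pred_label)
        return int(self.counts[i, j])

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(list(self.labels), self.counts.T.copy())


@dataclass
class MetricSet:
    """Accuracy, macro P/R/F1, Cohen's kappa and per-class values.

    All fractions in [0, 1]; ``kappa`` is None when chance agreement is 1
    (both raters spent the whole video on one identical label).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float | None
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
        }


def _runs(track: AnnotationTrack) -> list[tuple[str, int, int]]:
    runs = [(iv.label, iv.start_ms, iv.end_ms) for iv in track.intervals]
    if not runs or runs[0][1] != 0 or runs[-1][2] != track.duration_ms:
        raise ValueError(
            f"track {track.video_id}/{track.level} is not totalized; "
            "call annotations.totalize first"
        )
    for (_, _, e), (_, s, _) in zip(runs, runs[1:]):
        if e != s:
            raise ValueError("track has gaps; totalize first")
    return runs


def _check_comparable(gt: AnnotationTrack, pred: AnnotationTrack) -> None:
    if gt.level != pred.level:
        raise ValueError(f"levels differ: {gt.level} vs {pred.level}")
    if gt.duration_ms != pred.duration_ms:
        raise ValueError(
            f"durations differ: {gt.duration_ms} vs {pred.duration_ms}; "
            "totalize both onto the common (maximum) duration first"
        )


def union_labels(
    gt: AnnotationTrack, pred: AnnotationTrack, labels: list[str] | None = None
) -> list[str]:
    """Ordered label union: caller-supplied order first, then first appearance."""
    out = list(labels) if labels else []
    for tr in (gt, pred):
        for lab in tr.labels_used:
            if lab not in out:
                out.append(lab)
    return out


def time_weighted_confusion(
    gt: AnnotationTrack,
    pred: AnnotationTrack,
    labels: list[str] | None = None,
) -> ConfusionMatrix:
    """Exact millisecond-level confusion by interval-boundary sweep."""
    _check_comparable(gt, pred)
    labs = union_labels(gt, pred, labels)
    idx = {lab: i for i, lab in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=np.int64)

    g_runs, p_runs = _runs(gt), _runs(pred)
    gi = pi = 0
    t = 0
    end = gt.duration_ms
    while t < end:
        while g_runs[gi][2] <= t:
            gi += 1
        while p_runs[pi][2] <= t:
            pi += 1
        nt = min(g_runs[gi][2], p_runs[pi][2])
        counts[idx[g_runs[gi][0]], idx[p_runs[pi][0]]] += nt - t
        t = nt
    return ConfusionMatrix(labs, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of time on which the two labelings agree."""
    total = cm.total_ms
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / total


def per_class_prf(
    cm: ConfusionMatrix, averaging: Averaging = "macro-present"
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Per-class precision/recall/F1 plus macro (or micro) averages.

    Zero-denominator precision or recall is 0 by convention, which penalizes
    hallucinated and omitted classes deterministically.  ``macro-present``
    averages over classes with any ground-truth or predicted time.
    """
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    diag = np.diag(cm.counts).astype(float)

    per: dict[str, dict[str, float]] = {}
    for i, lab in enumerate(cm.labels):
        p = diag[i] / col[i] if col[i] > 0 else 0.0
        r = diag[i] / row[i] if row[i] > 0 else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        per[lab] = {
            "precision": p, "recall": r, "f1": f, "support_ms": float(row[i]),
        }

    if averaging == "micro":
        acc = accuracy(cm)
        macro = {"precision": acc, "recall": acc, "f1": acc}
    else:
        if averaging == "macro-present":
            mask = (row > 0) | (col > 0)
        elif averaging == "macro-all":
            mask = np.ones(len(cm.labels), dtype=bool)
        else:
            raise ValueError(f"unknown averaging scheme {averaging!r}")
        keep = [cm.labels[i] for i in np.nonzero(mask)[0]]
        if not keep:
            raise ValueError("no classes to average over")
        macro = {
            k: float(np.mean([per[lab][k] for lab in keep]))
            for k in ("precision", "recall", "f1")
        }
    return per, macro


def cohens_kappa(cm: ConfusionMatrix) -> float | None:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed time-weighted agreement, p_e the agreement expected
    from the marginal time budgets of the two raters.  Returns None in the
    degenerate case p_e = 1 (both tracks a single identical label), where
    kappa is undefined.
    """
    total = cm.total_ms
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / total
    row = cm.counts.sum(axis=1).astype(float) / total
    col = cm.counts.sum(axis=0).astype(float) / total
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def metric_set_from_confusion(
    cm: ConfusionMatrix, averaging: Averaging = "macro-present"
) -> MetricSet:
    per, macro = per_class_prf(cm, averaging)
    return MetricSet(
        accuracy=accuracy(cm),
        precision=macro["precision"],
        recall=macro["recall"],
        f1=macro["f1"],
        kappa=cohens_kappa(cm),
        per_class=per,
    )


def _average_metric_sets(a: MetricSet, b: MetricSet) -> MetricSet:
    kappa: float | None
    if a.kappa is None or b.kappa is None:
        kappa = None
    else:
        kappa = (a.kappa + b.kappa) / 2
    per: dict[str, dict[str, float]] = {}
    for lab in set(a.per_class) | set(b.per_class):
        pa = a.per_class.get(lab)
        pb = b.per_class.get(lab)
        if pa is None or pb is None:
            per[lab] = dict(pa or pb)  # type: ignore[arg-type]
        else:
            per[lab] = {k: (pa[k] + pb[k]) / 2 for k in pa}
    return MetricSet(
        accuracy=(a.accuracy + b.accuracy) / 2,
        precision=(a.precision + b.precision) / 2,
        recall=(a.recall + b.recall) / 2,
        f1=(a.f1 + b.f1) / 2,
        kappa=kappa,
        per_class=per,
    )


def symmetric_compare(
    a: AnnotationTrack,
    b: AnnotationTrack,
    labels: list[str] | None = None,
    averaging: Averaging = "macro-present",
) -> MetricSet:
    """Treat each track once as ground truth and average the two metric sets.

    The confusion matrix with roles swapped is the transpose, so accuracy and
    kappa coincide in both directions, and averaged macro precision equals
    averaged macro recall exactly.
    """
    labs = union_labels(a, b, labels)
    cm_ab = time_weighted_confusion(a, b, labs)
    m_ab = metric_set_from_confusion(cm_ab, averaging)
    m_ba = metric_set_from_confusion(cm_ab.transpose(), averaging)
    return _average_metric_sets(m_ab, m_ba)
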