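"""Per-video evaluation, cohort aggregation (mean ± SD) and rendering.

Each video pair is evaluated independently at phase and step level on the
millisecond timeline; a cohort summary is the unweighted mean and sample SD
over videos, with undefined metric values (e.g. kappa on a degenerate
single-label video) skipped and counted.

Directional quantities (signed ATD, C_TM, NL) are computed in both
ground-truth directions and averaged, mirroring the symmetric protocol;
the per-direction values are retained for inspection — note that the signed
ATD averaged over both directions is ~0 by construction, since swapping the
roles negates every matched delay.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationTrack, VideoAnnotation, totalize
from .ontology import Level, Ontology
from .timeline_metrics import Averaging, MetricSet, symmetric_compare
from .transition_metrics import (
    ADConfig,
    ad_metric_set,
    average_transitional_delay,
    coefficient_of_transitional_moments,
    extract_transitions,
    match_transitions,
    noise_level,
)

__all__ = [
    "VideoMetricReport",
    "DatasetReport",
    "evaluate_video_pair",
    "aggregate_dataset",
    "render_table",
    "parse_table",
    "per_video_frame",
    "plot_duration_bars",
    "plot_timeline_ribbon",
    "TABLE_COLUMNS",
]

#: Report column order: chance-corrected and classical agreement, then the
#: transition metrics, then the delta-relaxed (AD) metrics.
TABLE_COLUMNS = [
    "kappa", "accuracy", "precision", "recall", "f1",
    "atd_s", "ctm_pct", "nl_pct",
    "ad_accuracy", "ad_precision", "ad_recall", "ad_f1",
]
_PERCENT_COLUMNS = {
    "kappa", "accuracy", "precision", "recall", "f1",
    "ad_accuracy", "ad_precision", "ad_recall", "ad_f1",
}


@dataclass
class VideoMetricReport:
    """All metrics for one video at one level."""

    video_id: str
    level: Level
    classical: MetricSet
    ad: MetricSet
    atd_s: float | None
    ctm_pct: float | None
    nl_pct: float | None
    #: per ground-truth direction: {"a_gt": {...}, "b_gt": {...}}
    directional: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def flat(self) -> dict[str, float | None]:
        d: dict[str, float | None] = {
            "kappa": self.classical.kappa,
            "accuracy": self.classical.accuracy,
            "precision": self.classical.precision,
            "recall": self.classical.recall,
            "f1": self.classical.f1,
            "atd_s": self.atd_s,
            "ctm_pct": self.ctm_pct,
            "nl_pct": self.nl_pct,
            "ad_accuracy": self.ad.accuracy,
            "ad_precision": self.ad.precision,
            "ad_recall": self.ad.recall,
            "ad_f1": self.ad.f1,
        }
        return d


@dataclass
class DatasetReport:
    """Cohort-level summary over per-video reports."""

    dataset_id: str
    per_video: list[VideoMetricReport]
    #: level -> metric -> {"mean": .., "sd": .., "n_defined": ..}
    summary: dict[str, dict[str, dict[str, float]]]


def _mean_opt(x: float | None, y: float | None) -> float | None:
    vals = [v for v in (x, y) if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


def evaluate_video_pair(
    a: VideoAnnotation,
    b: VideoAnnotation,
    cfg: ADConfig = ADConfig(),
    ontology: Ontology | None = None,
    averaging: Averaging = "macro-present",
) -> tuple[VideoMetricReport, VideoMetricReport]:
    """Evaluate two annotations of the same video; returns (phase, step) reports.

    Tracks are totalized onto the common (maximum) duration before
    comparison, so raters who trimmed the video differently are compared on
    one timeline with explicit idle.
    """
    if a.video_id != b.video_id:
        raise ValueError(f"video ids differ: {a.video_id!r} vs {b.video_id!r}")
    idle = ontology.idle_label if ontology is not None else "idle"
    labels_by_level = {
        "phase": ontology.labels("phase") if ontology else None,
        "step": ontology.labels("step") if ontology else None,
    }
    out = []
    for level in ("phase", "step"):
        dur = max(a.duration_ms, b.duration_ms)
        ta = totalize(a.track(level).with_duration(dur), idle)  # type: ignore[arg-type]
        tb = totalize(b.track(level).with_duration(dur), idle)  # type: ignore[arg-type]
        labels = labels_by_level[level]

        classical = symmetric_compare(ta, tb, labels, averaging)
        ad = ad_metric_set(ta, tb, cfg, labels, averaging)

        ev_a = extract_transitions(ta)
        ev_b = extract_transitions(tb)
        directional: dict[str, dict[str, float | None]] = {}
        for key, real_tr, ann_tr, real_ev, ann_ev in (
            ("a_gt", ta, tb, ev_a, ev_b),
            ("b_gt", tb, ta, ev_b, ev_a),
        ):
            mres = match_transitions(real_ev, ann_ev)
            same_sig = [m for m in mres.matches
                        if m.real.signature == m.annotated.signature]
            directional[key] = {
                "atd_s": average_transitional_delay(mres, cfg),
                # delay over corresponding (same from->to labels) pairs only;
                # robust to forced cross-signature matches under structural
                # disagreement between the raters
                "atd_same_sig_s": average_transitional_delay(same_sig, cfg),
                "ctm_pct": coefficient_of_transitional_moments(real_ev, ann_ev),
                "nl_pct": noise_level(real_tr, ann_tr, idle),
                "n_matches": float(len(mres.matches)),
                "n_unmatched_real": float(len(mres.unmatched_real)),
                "n_unmatched_annotated": float(len(mres.unmatched_annotated)),
            }
        out.append(
            VideoMetricReport(
                video_id=a.video_id,
                level=level,  # type: ignore[arg-type]
                classical=classical,
                ad=ad,
                atd_s=_mean_opt(directional["a_gt"]["atd_s"],
                                directional["b_gt"]["atd_s"]),
                ctm_pct=_mean_opt(directional["a_gt"]["ctm_pct"],
                                  directional["b_gt"]["ctm_pct"]),
                nl_pct=_mean_opt(directional["a_gt"]["nl_pct"],
                                 directional["b_gt"]["nl_pct"]),
                directional=directional,
            )
        )
    return out[0], out[1]


def aggregate_dataset(
    reports: Iterable[VideoMetricReport], dataset_id: str = "dataset"
) -> DatasetReport:
    """Unweighted mean and sample SD per metric across videos.

    Undefined (None) values are skipped; ``n_defined`` records how many
    videos contributed.  With a single defined value the SD is reported as
    0 (degenerate but explicit: ``n_defined`` flags it).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")
    summary: dict[str, dict[str, dict[str, float]]] = {}
    for level in ("phase", "step"):
        level_reports = [r for r in reports if r.level == level]
        if not level_reports:
            continue
        metrics: dict[str, dict[str, float]] = {}
        for col in TABLE_COLUMNS:
            vals = [r.flat()[col] for r in level_reports]
            defined = np.array([v for v in vals if v is not None], dtype=float)
            if defined.size == 0:
                metrics[col] = {"mean": float("nan"), "sd": float("nan"),
                                "n_defined": 0.0}
            else:
                sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
                metrics[col] = {
                    "mean": float(defined.mean()),
                    "sd": sd,
                    "n_defined": float(defined.size),
                }
        summary[level] = metrics
    return DatasetReport(dataset_id=dataset_id, per_video=reports, summary=summary)


def _fmt(col: str, mean: float, sd: float) -> str:
    scale = 100.0 if col in _PERCENT_COLUMNS else 1.0
    return f"{mean * scale:.1f} ± {sd * scale:.1f}"


def render_table(dr: DatasetReport, fmt: str = "tsv") -> str:
    """Render the cohort summary, one row per level, as TSV or aligned text.

    Percent metrics are shown as mean ± SD in percent to one decimal; ATD in
    seconds; C_TM and NL are already percentages.
    """
    header = ["dataset", "level"] + TABLE_COLUMNS
    rows = [header]
    for level in ("phase", "step"):
        if level not in dr.summary:
            continue
        row = [dr.dataset_id, level]
        for col in TABLE_COLUMNS:
            cell = dr.summary[level][col]
            row.append(_fmt(col, cell["mean"], cell["sd"]))
        rows.append(row)
    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    if fmt == "text":
        widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
        return "\n".join(
            "  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows
        ) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def parse_table(tsv: str) -> dict[tuple[str, str], dict[str, tuple[float, float]]]:
    """Parse a rendered TSV back to {(dataset, level): {metric: (mean, sd)}}."""
    df = pd.read_csv(io.StringIO(tsv), sep="\t")
    out: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    for _, row in df.iterrows():
        cells: dict[str, tuple[float, float]] = {}
        for col in TABLE_COLUMNS:
            mean_s, sd_s = str(row[col]).split("±")
            scale = 100.0 if col in _PERCENT_COLUMNS else 1.0
            cells[col] = (float(mean_s) / scale, float(sd_s) / scale)
        out[(str(row["dataset"]), str(row["level"]))] = cells
    return out


def per_video_frame(dr: DatasetReport) -> pd.DataFrame:
    """Per-video metric values as a tidy DataFrame (one row per video/level)."""
    rows = []
    for r in dr.per_video:
        d: dict[str, object] = {"video_id": r.video_id, "level": r.level}
        d.update(r.flat())
        for key, vals in r.directional.items():
            for k, v in vals.items():
                d[f"{key}_{k}"] = v
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- plotting

def _label_durations_min(
    vas: Sequence[VideoAnnotation], level: Level, labels: Sequence[str]
) -> np.ndarray:
    """Mean per-video duration (minutes) of each label across a cohort."""
    per_video = np.zeros((len(vas), len(labels)))
    idx = {lab: i for i, lab in enumerate(labels)}
    for vi, va in enumerate(vas):
        for iv in va.track(level).intervals:
            if iv.label in idx:
                per_video[vi, idx[iv.label]] += iv.duration_ms / 60000.0
    return per_video.mean(axis=0)


def plot_duration_bars(
    cohorts: Mapping[str, Sequence[VideoAnnotation]],
    level: Level,
    ontology: Ontology,
    out_path: str | Path,
) -> Path:
    """Bar chart of mean per-label durations per cohort, in ontology order.

    Labels absent from a cohort get zero-height bars.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ontology.labels(level)
    x = np.arange(len(labels))
    n = max(len(cohorts), 1)
    width = 0.8 / n
    fig, ax = plt.subplots(figsize=(max(8, 0.35 * len(labels)), 4))
    for k, (name, vas) in enumerate(cohorts.items()):
        means = _label_durations_min(vas, level, labels)
        ax.bar(x + (k - (n - 1) / 2) * width, means, width, label=name)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("mean duration (min)")
    ax.set_title(f"Average {level} duration")
    ax.legend()
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def plot_timeline_ribbon(
    a: AnnotationTrack,
    b: AnnotationTrack,
    ontology: Ontology,
    out_path: str | Path,
    names: tuple[str, str] = ("rater A", "rater B"),
) -> Path:
    """Two horizontal label ribbons on a shared time axis.

    Segment widths are proportional to durations; colors are assigned from
    ontology label order so the mapping is consistent across figures, and
    every label used by either track appears in the legend.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    level = a.level
    labels = ontology.labels(level)
    palette = plt.get_cmap("tab20")
    color_of: dict[str, object] = {
        lab: palette(i % 20) for i, lab in enumerate(labels)
    }
    color_of[ontology.idle_label] = (0.85, 0.85, 0.85, 1.0)

    fig, ax = plt.subplots(figsize=(10, 2.2))
    for y, (track, name) in enumerate(zip((a, b), names)):
        tot = totalize(track, ontology.idle_label)
        for iv in tot.intervals:
            ax.barh(
                y, iv.duration_ms / 60000.0, left=iv.start_ms / 60000.0,
                height=0.6, color=color_of.get(iv.label, "black"),
                edgecolor="none",
            )
    used = [lab for lab in labels + [ontology.idle_label]
            if lab in set(a.labels_used) | set(b.labels_used)]
    ax.legend(
        handles=[Patch(color=color_of[lab], label=lab) for lab in used],
        fontsize=5, ncol=4, loc="upper center", bbox_to_anchor=(0.5, -0.35),
    )
    ax.set_yticks([0, 1])
    ax.set_yticklabels(names)
    ax.set_xlabel("time (min)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
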