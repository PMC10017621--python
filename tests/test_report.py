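import numpy as np
import pytest

from surgagree import (
    ADConfig, AnnotationTrack, Interval, VideoAnnotation,
    aggregate_dataset, evaluate_video_pair, load_packaged_lrygb,
    parse_table, per_video_frame, plot_duration_bars, plot_timeline_ribbon,
    render_table, sample_ground_truth, perturb_as_rater,
    STRASBOURG_LIKE, INTER_RATER_NOISE,
)


@pytest.fixture(scope="module")
def lrygb_pairs():
    """Three simulated video pairs (truth vs noisy rater)."""
    o = load_packaged_lrygb()
    pairs = []
    for i in range(3):
        truth = sample_ground_truth(o, STRASBOURG_LIKE, 100 + i, f"v{i}")
        noisy = perturb_as_rater(truth, INTER_RATER_NOISE, o, "A", rng=200 + i)
        pairs.append((truth, noisy))
    return o, pairs


class TestEvaluateVideoPair:
    def test_self_comparison_is_perfect(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        truth = pairs[0][0]
        rp, rs = evaluate_video_pair(truth, truth, ADConfig(), o)
        for r in (rp, rs):
            assert r.classical.accuracy == 1.0
            assert r.classical.kappa == 1.0
            assert r.atd_s == 0.0
            assert r.nl_pct == 0.0
            assert r.ctm_pct == 100.0

    def test_video_id_mismatch_rejected(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        a, b = pairs[0][0], pairs[1][0]
        with pytest.raises(ValueError, match="video ids"):
            evaluate_video_pair(a, b, ADConfig(), o)

    def test_ad_at_least_classical(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        for truth, noisy in pairs:
            for r in evaluate_video_pair(truth, noisy, ADConfig(), o):
                assert r.ad.accuracy >= r.classical.accuracy - 1e-12
                assert r.ad.f1 >= r.classical.f1 - 1e-12

    def test_directional_values_retained(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        truth, noisy = pairs[0]
        rp, _ = evaluate_video_pair(truth, noisy, ADConfig(), o)
        assert set(rp.directional) == {"a_gt", "b_gt"}
        # swapping ground truth negates the signed ATD
        assert rp.directional["a_gt"]["atd_s"] == pytest.approx(
            -rp.directional["b_gt"]["atd_s"], abs=1e-9)

    def test_different_durations_compared_on_common_timeline(self, lrygb_pairs):
        o, _ = lrygb_pairs
        short = VideoAnnotation(
            "v", "a",
            AnnotationTrack("v", "phase", (Interval("Preparation", 0, 50_000),), 60_000),
            AnnotationTrack("v", "step", (Interval("Trocar placement", 0, 50_000),), 60_000))
        long = VideoAnnotation(
            "v", "b",
            AnnotationTrack("v", "phase", (Interval("Preparation", 0, 50_000),), 90_000),
            AnnotationTrack("v", "step", (Interval("Trocar placement", 0, 50_000),), 90_000))
        rp, _ = evaluate_video_pair(short, long, ADConfig(), o)
        assert rp.classical.accuracy == 1.0  # trailing idle agrees


class TestAggregation:
    def test_mean_and_sample_sd(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        reports = []
        for truth, noisy in pairs[:2]:
            rp, rs = evaluate_video_pair(truth, noisy, ADConfig(), o)
            reports += [rp, rs]
        dr = aggregate_dataset(reports, "toy")
        accs = [r.classical.accuracy for r in reports if r.level == "phase"]
        cell = dr.summary["phase"]["accuracy"]
        assert cell["mean"] == pytest.approx(np.mean(accs))
        assert cell["sd"] == pytest.approx(np.std(accs, ddof=1))
        assert cell["n_defined"] == 2

    def test_two_video_worked_example(self, lrygb_pairs):
        # accuracies 0.9 and 1.0 -> mean 0.95, sample SD ~0.0707
        o, pairs = lrygb_pairs
        truth = pairs[0][0]
        rp1, rs1 = evaluate_video_pair(truth, truth, ADConfig(), o)
        rp1.classical.accuracy = 0.9
        rp2, _ = evaluate_video_pair(truth, truth, ADConfig(), o)
        dr = aggregate_dataset([rp1, rp2, rs1])
        assert dr.summary["phase"]["accuracy"]["mean"] == pytest.approx(0.95)
        assert dr.summary["phase"]["accuracy"]["sd"] == pytest.approx(
            0.07071, abs=1e-4)

    def test_single_video_sd_zero(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        rp, rs = evaluate_video_pair(*pairs[0], ADConfig(), o)
        dr = aggregate_dataset([rp, rs])
        assert dr.summary["phase"]["accuracy"]["sd"] == 0.0
        assert dr.summary["phase"]["accuracy"]["n_defined"] == 1

    def test_permutation_invariance(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        reports = []
        for truth, noisy in pairs:
            reports += list(evaluate_video_pair(truth, noisy, ADConfig(), o))
        d1 = aggregate_dataset(reports)
        d2 = aggregate_dataset(list(reversed(reports)))
        for level in d1.summary:
            for col, cell in d1.summary[level].items():
                assert d2.summary[level][col] == pytest.approx(cell, abs=1e-12)


class TestRendering:
    def test_identity_cohort_row(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        truth = pairs[0][0]
        reports = list(evaluate_video_pair(truth, truth, ADConfig(), o))
        tsv = render_table(aggregate_dataset(reports, "ident"))
        parsed = parse_table(tsv)
        assert parsed[("ident", "phase")]["accuracy"] == (1.0, 0.0)
        assert parsed[("ident", "phase")]["ctm_pct"] == (100.0, 0.0)

    def test_round_trip_to_printed_precision(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        reports = []
        for truth, noisy in pairs:
            reports += list(evaluate_video_pair(truth, noisy, ADConfig(), o))
        dr = aggregate_dataset(reports, "sim")
        parsed = parse_table(render_table(dr))
        for level in ("phase", "step"):
            for col, cell in dr.summary[level].items():
                mean, sd = parsed[("sim", level)][col]
                scale = 1.0 if col in ("atd_s", "ctm_pct", "nl_pct") else 100.0
                assert mean * scale == pytest.approx(cell["mean"] * scale, abs=0.051)
                assert sd * scale == pytest.approx(cell["sd"] * scale, abs=0.051)

    def test_column_order(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        reports = list(evaluate_video_pair(*pairs[0], ADConfig(), o))
        header = render_table(aggregate_dataset(reports)).splitlines()[0].split("\t")
        assert header[2:] == [
            "kappa", "accuracy", "precision", "recall", "f1",
            "atd_s", "ctm_pct", "nl_pct",
            "ad_accuracy", "ad_precision", "ad_recall", "ad_f1"]

    def test_per_video_frame_shape(self, lrygb_pairs):
        o, pairs = lrygb_pairs
        reports = []
        for truth, noisy in pairs:
            reports += list(evaluate_video_pair(truth, noisy, ADConfig(), o))
        df = per_video_frame(aggregate_dataset(reports))
        assert len(df) == 6  # 3 videos x 2 levels
        assert {"accuracy", "kappa", "a_gt_atd_s", "b_gt_ctm_pct"} <= set(df.columns)


class TestPlots:
    def test_duration_bars_written(self, lrygb_pairs, tmp_path):
        o, pairs = lrygb_pairs
        out = plot_duration_bars(
            {"simA": [p[0] for p in pairs], "simB": [p[1] for p in pairs]},
            "phase", o, tmp_path / "bars.png")
        assert out.exists() and out.stat().st_size > 0

    def test_ribbon_written(self, lrygb_pairs, tmp_path):
        o, pairs = lrygb_pairs
        truth, noisy = pairs[0]
        out = plot_timeline_ribbon(truth.phase_track, noisy.phase_track, o,
                                   tmp_path / "ribbon.png")
        assert out.exists() and out.stat().st_size > 0
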