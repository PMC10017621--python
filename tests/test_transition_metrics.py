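import numpy as np
import pytest

from surgagree import (
    ADConfig, TransitionEvent, accuracy, ad_metric_set,
    average_transitional_delay, coefficient_of_transitional_moments,
    extract_transitions, match_transitions, noise_level, relaxed_confusion,
    symmetric_compare, time_weighted_confusion,
)
from .conftest import make_track
from .oracles import (
    assignment_match, dense_noise_level, dense_relaxed_confusion,
    dense_transitions, random_totalized_track,
)


def ev(t, a, b):
    return TransitionEvent(t, a, b)


class TestExtraction:
    def test_single_boundary(self):
        tr = make_track([("A", 0, 50), ("B", 50, 100)])
        assert extract_transitions(tr) == [ev(50, "A", "B")]

    def test_single_label_no_transitions(self):
        assert extract_transitions(make_track([("A", 0, 100)])) == []

    def test_idle_participates(self):
        tr = make_track([("A", 0, 40), ("B", 60, 100)], duration_ms=100)
        assert extract_transitions(tr) == [ev(40, "A", "idle"),
                                           ev(60, "idle", "B")]

    def test_adjacent_same_label_merged(self):
        tr = make_track([("A", 0, 40), ("A", 40, 70), ("B", 70, 100)])
        assert extract_transitions(tr) == [ev(70, "A", "B")]

    def test_matches_dense_boundary_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            tr = random_totalized_track(rng, ["A", "B", "C"],
                                        int(rng.integers(5, 3000)))
            got = [(e.time_ms, e.from_label, e.to_label)
                   for e in extract_transitions(tr)]
            assert got == dense_transitions(tr)


class TestMatching:
    def test_identical_lists_all_delay_zero(self):
        evs = [ev(50, "A", "B"), ev(90, "B", "C")]
        res = match_transitions(evs, list(evs))
        assert all(m.delay_ms == 0 for m in res.matches)
        assert not res.unmatched_real and not res.unmatched_annotated

    def test_simple_shift(self):
        res = match_transitions([ev(50, "A", "B")], [ev(58, "A", "B")])
        assert res.matches[0].delay_ms == 8

    def test_spurious_annotated_left_unmatched(self):
        res = match_transitions(
            [ev(50, "A", "B")], [ev(48, "A", "B"), ev(300, "A", "B")])
        assert res.matches[0].delay_ms == -2
        assert [e.time_ms for e in res.unmatched_annotated] == [300]
        # exhaustive assignment agrees on this instance
        pairs, _ = assignment_match([50], [48, 300])
        assert pairs == [(50, 48)]

    def test_signature_preferred_over_proximity(self):
        # the nearer annotated event has the wrong signature
        res = match_transitions(
            [ev(100, "A", "B")], [ev(101, "C", "D"), ev(140, "A", "B")])
        same_sig = [m for m in res.matches
                    if m.real.signature == m.annotated.signature]
        assert same_sig and same_sig[0].delay_ms == 40

    def test_swap_negates_delays(self):
        real = [ev(50, "A", "B"), ev(200, "B", "C")]
        ann = [ev(61, "A", "B"), ev(190, "B", "C")]
        fwd = match_transitions(real, ann)
        bwd = match_transitions(ann, real)
        assert sorted(m.delay_ms for m in fwd.matches) == sorted(
            -m.delay_ms for m in bwd.matches)

    def test_greedy_equals_assignment_on_jitter_instances(self):
        # unique signatures + moderate jitter: greedy is the exact optimum
        rng = np.random.default_rng(5)
        labels = [f"L{i}" for i in range(12)]
        for _ in range(20):
            times = np.sort(rng.choice(np.arange(100, 100_000, 100), 10,
                                       replace=False))
            real = [ev(int(t), labels[i], labels[i + 1])
                    for i, t in enumerate(times)]
            ann = [ev(max(1, int(t + rng.normal(0, 30))), e.from_label,
                      e.to_label) for t, e in zip(times, real)]
            res = match_transitions(real, ann)
            _, opt_cost = assignment_match([e.time_ms for e in real],
                                           [e.time_ms for e in ann])
            got_cost = sum(abs(m.delay_ms) for m in res.matches)
            assert got_cost == opt_cost


class TestScalarTransitionMetrics:
    def test_atd_modes(self):
        ms = match_transitions([ev(50_000, "A", "B"), ev(90_000, "B", "C")],
                               [ev(58_000, "A", "B"), ev(88_000, "B", "C")])
        assert average_transitional_delay(ms) == pytest.approx(3.0)
        assert average_transitional_delay(
            ms, ADConfig(delay_mode="absolute")) == pytest.approx(5.0)

    def test_atd_empty_is_undefined(self):
        assert average_transitional_delay(match_transitions([], [])) is None

    def test_ctm(self):
        mk = lambda n: [ev(100 * (i + 1), "A", "B") for i in range(n)]
        assert coefficient_of_transitional_moments(mk(30), mk(33)) == pytest.approx(110.0)
        assert coefficient_of_transitional_moments(mk(5), []) == 0.0
        assert coefficient_of_transitional_moments([], mk(5)) is None

    def test_noise_level_identity_zero(self):
        tr = make_track([("A", 0, 50), ("B", 50, 100)])
        assert noise_level(tr, tr) == 0.0

    def test_noise_level_insertion(self):
        real = make_track([("A", 0, 50), ("B", 50, 100)])
        ann = make_track([("A", 0, 40), ("C", 40, 45), ("A", 45, 50),
                          ("B", 50, 100)])
        # 4 annotated segments, 1 (C) with no same-label overlap
        assert noise_level(real, ann) == pytest.approx(25.0)

    def test_noise_level_total_mislabeling(self):
        real = make_track([("A", 0, 50), ("B", 50, 100)])
        ann = make_track([("B", 0, 50), ("A", 50, 100)])
        assert noise_level(real, ann) == pytest.approx(100.0)

    def test_noise_level_idle_excluded(self):
        real = make_track([("A", 0, 100)])
        ann = make_track([("A", 0, 60)], duration_ms=100)  # idle tail
        assert noise_level(real, ann) == 0.0

    def test_noise_level_matches_dense_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            dur = int(rng.integers(10, 3000))
            real = random_totalized_track(rng, ["A", "B", "C"], dur)
            ann = random_totalized_track(rng, ["A", "B", "C"], dur)
            assert noise_level(real, ann) == dense_noise_level(real, ann)


class TestRelaxedConfusion:
    def test_delta_zero_equals_classical(self):
        a = make_track([("A", 0, 50_000), ("B", 50_000, 100_000)])
        b = make_track([("A", 0, 53_000), ("B", 53_000, 100_000)])
        np.testing.assert_array_equal(
            relaxed_confusion(a, b, ADConfig(delta_ms=0)).counts,
            time_weighted_confusion(a, b).counts)

    def test_small_delay_fully_forgiven(self):
        gt = make_track([("A", 0, 50_000), ("B", 50_000, 100_000)])
        pred = make_track([("A", 0, 53_000), ("B", 53_000, 100_000)])
        cm = relaxed_confusion(gt, pred, ADConfig(delta_ms=5000))
        assert accuracy(cm) == 1.0
        assert accuracy(time_weighted_confusion(gt, pred)) < 1.0

    def test_large_delay_partially_forgiven(self):
        gt = make_track([("A", 0, 50_000), ("B", 50_000, 100_000)])
        pred = make_track([("A", 0, 58_000), ("B", 58_000, 100_000)])
        cm = relaxed_confusion(gt, pred, ADConfig(delta_ms=5000))
        # 8 s of error, 5 s inside the window -> 3 s remains off-diagonal
        assert cm.cell("B", "A") == 3000
        assert accuracy(cm) == pytest.approx(0.97)

    def test_total_duration_conserved(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            dur = int(rng.integers(50, 5000))
            a = random_totalized_track(rng, ["A", "B", "C"], dur)
            b = random_totalized_track(rng, ["A", "B", "C"], dur)
            cm = relaxed_confusion(a, b, ADConfig(delta_ms=100))
            assert cm.total_ms == dur

    @pytest.mark.parametrize("relax_mode", ["both", "pre", "post"])
    def test_matches_dense_oracle(self, relax_mode):
        rng = np.random.default_rng(31)
        labels = ["A", "B", "C", "idle"]
        for _ in range(15):
            dur = int(rng.integers(50, 4000))
            delta = int(rng.integers(0, 300))
            a = random_totalized_track(rng, labels[:3], dur)
            b = random_totalized_track(rng, labels[:3], dur)
            cm = relaxed_confusion(a, b,
                                   ADConfig(delta_ms=delta, relax_mode=relax_mode),
                                   labels)
            np.testing.assert_array_equal(
                cm.counts,
                dense_relaxed_confusion(a, b, labels, delta, relax_mode))


class TestADMetricSet:
    def test_identity_all_perfect(self):
        t = make_track([("A", 0, 50), ("B", 50, 100)])
        m = ad_metric_set(t, t)
        assert m.accuracy == m.f1 == m.kappa == 1.0

    def test_ad_never_below_classical_and_monotone_in_delta(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            dur = int(rng.integers(100, 5000))
            a = random_totalized_track(rng, ["A", "B", "C"], dur)
            b = random_totalized_track(rng, ["A", "B", "C"], dur)
            classical = symmetric_compare(a, b)
            prev = classical.accuracy
            for delta in (0, 50, 200, 1000):
                m = ad_metric_set(a, b, ADConfig(delta_ms=delta))
                assert m.accuracy >= prev - 1e-12
                prev = m.accuracy

    def test_jitter_within_delta_gives_perfect_ad(self):
        gt = make_track([("A", 0, 60_000), ("B", 60_000, 120_000),
                         ("C", 120_000, 180_000)])
        jit = make_track([("A", 0, 61_500), ("B", 61_500, 117_000),
                          ("C", 117_000, 180_000)])
        m = ad_metric_set(gt, jit, ADConfig(delta_ms=5000))
        assert m.accuracy == 1.0
        assert symmetric_compare(gt, jit).accuracy < 1.0
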