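"""Confusion metrics, calibration, per-buzz and stratified sensitivity, CIs."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from buzzscan.annotations import LabelEvent, MatchPolicy
from buzzscan.evaluation import (
    CalibrationError,
    ConfusionCounts,
    calibrate_threshold,
    confusion_at,
    metric_curve,
    per_buzz_sensitivity,
    round_half_away,
    sensitivity_ci,
    stratified_sensitivity,
)


class TestConfusion:
    def test_printed_false_positive_arithmetic(self):
        # 64 detected negatives among 20,833 negative frames -> 0.3% (one
        # decimal) and 0.31% (two decimals)
        c = ConfusionCounts(tp=0, fp=64, tn=20_833 - 64, fn=0)
        assert round_half_away(100 * c.false_positive_rate, 1) == 0.3
        assert round_half_away(100 * c.false_positive_rate, 2) == 0.31

    def test_minus_infinity_threshold_detects_everything(self, rng):
        a = rng.standard_normal(100)
        t = rng.random(100) < 0.3
        c = confusion_at(a, t, -np.inf)
        assert c.fn == c.tn == 0
        assert c.tp + c.fp == 100

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            a = rng.standard_normal(30)
            t = rng.random(30) < 0.4
            theta = float(rng.standard_normal())
            c = confusion_at(a, t, theta)
            tp = sum(1 for x, y in zip(a, t) if x > theta and y)
            fp = sum(1 for x, y in zip(a, t) if x > theta and not y)
            fn = sum(1 for x, y in zip(a, t) if x <= theta and y)
            tn = sum(1 for x, y in zip(a, t) if x <= theta and not y)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_counts_partition_frames(self, rng):
        c = confusion_at(rng.standard_normal(57), rng.random(57) < 0.5, 0.1)
        assert c.total == 57

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_at(np.zeros(3), np.zeros(4, dtype=bool), 0.0)

    def test_identities_on_hand_built_table(self):
        c = ConfusionCounts(tp=6, fp=2, tn=90, fn=14)
        assert c.sensitivity == pytest.approx(6 / 20)
        assert c.false_positive_rate == pytest.approx(2 / 92)
        assert c.precision == pytest.approx(6 / 8)

    def test_precision_undefined_without_detections(self):
        assert np.isnan(ConfusionCounts(tp=0, fp=0, tn=5, fn=5).precision)


class TestCurve:
    def test_perfect_separation_has_ideal_point(self):
        a = np.array([2.0, 3.0, -1.0, -2.0])
        t = np.array([True, True, False, False])
        curve = metric_curve(a, t)
        assert any(p.sensitivity == 1.0 and p.false_positive_rate == 0.0 for p in curve.points)

    def test_monotone_in_threshold(self, rng):
        a = rng.standard_normal(500)
        t = rng.random(500) < 0.3
        curve = metric_curve(a, t)
        sens = [p.sensitivity for p in curve.points]
        fpr = [p.false_positive_rate for p in curve.points]
        assert all(b <= a + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(fpr, fpr[1:]))

    def test_points_equal_confusion_at(self, rng):
        a = rng.standard_normal(200)
        t = rng.random(200) < 0.4
        curve = metric_curve(a, t)
        for p in curve.points[:: 20]:
            c = confusion_at(a, t, p.threshold)
            assert (p.counts.tp, p.counts.fp, p.counts.tn, p.counts.fn) == (c.tp, c.fp, c.tn, c.fn)

    def test_independent_activations_precision_tracks_prevalence(self, rng):
        # binomial oracle: with activations independent of truth, precision
        # at any threshold estimates the prevalence
        n = 10_000
        prevalence = 0.2
        a = rng.standard_normal(n)
        t = rng.random(n) < prevalence
        curve = metric_curve(a, t, thresholds=np.quantile(a, [0.1, 0.5, 0.9]))
        for p in curve.points:
            n_det = p.counts.tp + p.counts.fp
            se = np.sqrt(prevalence * (1 - prevalence) / n_det)
            assert abs(p.precision - prevalence) < 3 * se


class TestCalibration:
    def test_exhaustive_sweep_example(self):
        # positives {2, 0, -2}, negatives {-1, -3}: theta=-1 is the smallest
        # threshold with precision 1.0; sensitivity there is 2/3
        a = np.array([2.0, 0.0, -2.0, -1.0, -3.0])
        t = np.array([True, True, True, False, False])
        cal = calibrate_threshold(metric_curve(a, t), target_precision=1.0)
        assert cal.threshold == pytest.approx(-1.0)
        assert cal.achieved_precision == 1.0
        assert cal.achieved_sensitivity == pytest.approx(2 / 3)

    def test_zero_target_takes_smallest_threshold(self, rng):
        a = rng.standard_normal(50)
        t = rng.random(50) < 0.5
        curve = metric_curve(a, t)
        cal = calibrate_threshold(curve, target_precision=0.0)
        defined = [p for p in curve.points if not np.isnan(p.precision)]
        assert cal.threshold == defined[0].threshold

    def test_unachievable_target_reports_maximum(self):
        a = np.array([1.0, 1.0])
        t = np.array([True, False])
        # only mixed detections possible below the max; no point is precise
        with pytest.raises(CalibrationError, match="maximum achievable"):
            calibrate_threshold(metric_curve(a, np.array([False, True])), 1.0)

    def test_calibration_meets_target_on_calibration_data(self, rng):
        for trial in range(30):
            a = rng.standard_normal(300) + 1.5 * (rng.random(300) < 0.3)
            t = rng.random(300) < 0.3
            curve = metric_curve(a, t)
            try:
                cal = calibrate_threshold(curve, 0.8)
            except CalibrationError:
                continue
            c = confusion_at(a, t, cal.threshold)
            assert c.precision >= 0.8


class TestPerBuzz:
    POLICY = MatchPolicy()

    def test_simple_counting(self):
        events = [
            LabelEvent(0.0, 1.0, "ins_buzz"),
            LabelEvent(5.0, 6.0, "ins_buzz"),
            LabelEvent(10.0, 11.0, "ins_buzz"),
        ]
        starts = np.arange(13) * 0.96
        detected = np.zeros(13, dtype=bool)
        detected[0] = True  # hits first buzz
        detected[5] = True  # frame [4.8, 5.76) overlaps second buzz
        overall, _ = per_buzz_sensitivity(events, starts, detected, self.POLICY)
        assert overall == pytest.approx(2 / 3)

    def test_all_frames_detected_gives_one(self):
        events = [LabelEvent(1.0, 2.0, "ins_buzz"), LabelEvent(8.0, 9.5, "ins_buzz")]
        starts = np.arange(12) * 0.96
        overall, table = per_buzz_sensitivity(events, starts, np.ones(12, dtype=bool), self.POLICY)
        assert overall == 1.0
        assert sum(r["n_events"] for r in table) == 2

    def test_matches_bruteforce_event_loop(self, rng):
        for _ in range(20):
            n_ev = int(rng.integers(1, 10))
            events = [
                LabelEvent(float(s), float(s + d), "ins_buzz")
                for s, d in zip(rng.uniform(0, 30, n_ev), rng.uniform(0.2, 4, n_ev))
            ]
            starts = np.arange(40) * 0.96
            detected = rng.random(40) < 0.3
            overall, _ = per_buzz_sensitivity(events, starts, detected, self.POLICY)
            # oracle: merge intervals, then per-event frame scan
            from tests.test_annotations import bruteforce_truth

            merged = []
            for s, e in sorted((e.start_s, e.end_s) for e in events):
                if merged and s <= merged[-1][1] + 1e-9:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            hits = 0
            for s, e in merged:
                ok = False
                for i, fs in enumerate(starts):
                    if not detected[i]:
                        continue
                    ov = min(e, fs + 0.96) - max(s, fs)
                    contained = s >= fs - 1e-9 and e <= fs + 0.96 + 1e-9 and ov > 0
                    if ov >= 0.096 - 1e-9 or contained:
                        ok = True
                hits += ok
            assert overall == pytest.approx(hits / len(merged))

    def test_duration_classes_partition_events(self, rng):
        events = [
            LabelEvent(float(10 * i), float(10 * i + d), "ins_buzz")
            for i, d in enumerate(rng.uniform(0.1, 9.5, 12))
        ]
        starts = np.arange(130) * 0.96
        _, table = per_buzz_sensitivity(events, starts, np.zeros(130, dtype=bool), self.POLICY)
        assert sum(r["n_events"] for r in table) == len(events)


class TestStrata:
    def test_single_overlap_assignment(self):
        buzz = np.array([True, True, False])
        det = np.array([True, False, False])
        table = stratified_sensitivity(buzz, det, {"mech_plane": np.array([False, True, False])})
        by = {r["stratum"]: r for r in table}
        assert by["none"]["n_frames"] == 1 and by["none"]["sensitivity"] == 1.0
        assert by["mech_plane"]["n_frames"] == 1 and by["mech_plane"]["sensitivity"] == 0.0

    def test_two_overlaps_go_to_multiple(self):
        buzz = np.array([True])
        table = stratified_sensitivity(
            buzz,
            np.array([False]),
            {"ins_trill": np.array([True]), "mech_auto": np.array([True])},
        )
        assert table[0]["stratum"] == "multiple"

    def test_nonbuzz_takes_precedence_over_multibuzz(self):
        buzz = np.array([True, True])
        det = np.array([True, True])
        table = stratified_sensitivity(
            buzz,
            det,
            {"ins_trill": np.array([True, False])},
            multi_buzz=np.array([True, True]),
        )
        by = {r["stratum"]: r for r in table}
        assert by["ins_trill"]["n_frames"] == 1
        assert by["multi_buzz"]["n_frames"] == 1

    def test_strata_sizes_sum_to_buzz_frames(self, rng):
        n = 200
        buzz = rng.random(n) < 0.4
        det = rng.random(n) < 0.5
        overlaps = {
            k: rng.random(n) < 0.2 for k in ("ins_trill", "mech_auto", "mech_plane")
        }
        table = stratified_sensitivity(buzz, det, overlaps, rng.random(n) < 0.1)
        assert sum(r["n_frames"] for r in table) == int(buzz.sum())


class TestBinomialCI:
    def test_zero_successes_closed_form(self):
        ci = sensitivity_ci(0, 10, 0.95)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_closed_form(self):
        ci = sensitivity_ci(10, 10, 0.95)
        assert ci.upper == 1.0
        assert ci.lower == pytest.approx(0.025 ** (1 / 10))

    def test_300_buzzes_at_28_percent(self):
        # the design-guidance case: 84/300 gives roughly a +/-5% interval
        ci = sensitivity_ci(84, 300, 0.95)
        assert ci.lower == pytest.approx(0.2299, abs=2e-4)
        assert ci.upper == pytest.approx(0.3345, abs=2e-4)
        assert (ci.upper - ci.lower) / 2 == pytest.approx(0.0523, abs=5e-4)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 400))
            x = int(rng.integers(0, n + 1))
            ci = sensitivity_ci(x, n)
            assert ci.lower - 1e-12 <= x / n <= ci.upper + 1e-12

    def test_matches_beta_quantile_oracle(self):
        ci = sensitivity_ci(7, 40, 0.9)
        assert ci.lower == pytest.approx(beta_dist.ppf(0.05, 7, 34))
        assert ci.upper == pytest.approx(beta_dist.ppf(0.95, 8, 33))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_ci(5, 0)
        with pytest.raises(ValueError):
            sensitivity_ci(-1, 10)
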