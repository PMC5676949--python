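"""Event-level scoring: merging, matching, reports, curves, attribution."""

import numpy as np
import pytest

import ictalhr as ih
from ictalhr.detector import Alarm
from ictalhr.evaluation import (MatchResult, SeizureAnnotation, compute_report,
                                fp_coincidence, match, merge_alarms,
                                patient_average, round_half_up,
                                sensitivity_by_duration, sensitivity_fa_curve,
                                sensitivity_from_counts)


def alarms_at(*times, score=1.0):
    return [Alarm(float(t), score) for t in times]


def brute_force_match(alarms, seizures, window=(-30.0, 90.0)):
    """Exhaustive alarm x seizure pairing oracle: seizures in onset order
    claim their earliest in-window alarm."""
    seiz = sorted(seizures, key=lambda s: s.onset)
    alarms = sorted(alarms, key=lambda a: a.time)
    used = set()
    pairs = []
    for si, s in enumerate(seiz):
        best = None
        for ai, a in enumerate(alarms):
            if ai in used:
                continue
            if s.onset + window[0] <= a.time <= s.onset + window[1]:
                if best is None or a.time < alarms[best].time:
                    best = ai
        if best is not None:
            used.add(best)
        pairs.append(best)
    return pairs


class TestMerge:
    def test_sixty_second_rule(self):
        out = merge_alarms(alarms_at(0, 30, 120))
        assert [a.time for a in out] == [0, 120]

    def test_greedy_chain(self):
        out = merge_alarms(alarms_at(0, 50, 100))
        assert [a.time for a in out] == [0, 100]

    def test_empty(self):
        assert merge_alarms([]) == []

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        a = alarms_at(*np.sort(rng.uniform(0, 3600, 100)))
        once = merge_alarms(a)
        twice = merge_alarms(once)
        assert [x.time for x in once] == [x.time for x in twice]

    def test_cluster_keeps_max_score(self):
        a = [Alarm(0.0, 0.2), Alarm(30.0, 1.5), Alarm(50.0, 0.9)]
        out = merge_alarms(a)
        assert len(out) == 1
        assert out[0].time == 0.0 and out[0].score == 1.5


class TestMatch:
    def test_one_alarm_two_seizures(self):
        seiz = [SeizureAnnotation(100.0, 130.0), SeizureAnnotation(500.0)]
        m = match(alarms_at(110.0), seiz)
        assert m.tp == 1 and m.missed == 1 and m.fp == 0

    def test_window_boundary_closed(self):
        m = match(alarms_at(70.0), [SeizureAnnotation(100.0)])
        assert m.tp == 1  # exactly onset - 30 s counts

    def test_extra_alarms_are_fp(self):
        m = match(alarms_at(110.0, 400.0, 700.0), [SeizureAnnotation(100.0)])
        assert m.tp == 1 and m.fp == 2

    def test_double_window_goes_to_earlier_seizure(self):
        seiz = [SeizureAnnotation(100.0, 110.0), SeizureAnnotation(150.0)]
        m = match(alarms_at(130.0), seiz)
        assert m.detected == [True, False]

    def test_overlapping_annotations_rejected(self):
        with pytest.raises(ValueError):
            match([], [SeizureAnnotation(0.0, 50.0),
                       SeizureAnnotation(20.0, 80.0)])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            onsets = np.sort(rng.uniform(0, 3600, rng.integers(1, 8)))
            onsets = onsets[np.diff(np.concatenate([[-200], onsets])) > 150]
            seiz = [SeizureAnnotation(float(o)) for o in onsets]
            al = alarms_at(*np.sort(rng.uniform(0, 3600,
                                                rng.integers(0, 50))))
            m = match(al, seiz)
            pairs = brute_force_match(al, seiz)
            expect = [p is not None for p in pairs]
            assert m.detected == expect
            assert m.tp + m.missed == len(seiz)
            assert m.tp + m.fp == len(al)


class TestReport:
    def test_ppv(self):
        m = match(alarms_at(110.0, 400.0, 600.0, 800.0),
                  [SeizureAnnotation(100.0)])
        rep = compute_report([("p", m, 2.0)])
        assert rep.total_average()["ppv"] == pytest.approx(25.0)

    def test_fp_per_hour(self):
        m = match(alarms_at(100.0, 400.0, 800.0, 1200.0), [])
        rep = compute_report([("p", m, 2.0)])
        assert rep.total_average()["fp_per_h"] == pytest.approx(2.0)

    def test_zero_duration_rejected(self):
        m = match([], [])
        with pytest.raises(ValueError):
            compute_report([("p", m, 0.0)])

    def test_total_average_is_seizure_weighted(self):
        m1 = match(alarms_at(110.0), [SeizureAnnotation(100.0)] )
        seiz2 = [SeizureAnnotation(100.0, 130.0), SeizureAnnotation(400.0),
                 SeizureAnnotation(700.0)]
        m2 = match(alarms_at(110.0), seiz2)
        rep = compute_report([("a", m1, 1.0), ("b", m2, 1.0)])
        per = [p.se for p in rep.per_patient]
        weights = [p.n_seizures for p in rep.per_patient]
        expect = np.average(per, weights=weights)
        assert rep.total_average()["se"] == pytest.approx(expect)

    def test_published_hospital_columns_reproduced(self):
        """The printed per-patient hospital-ECG columns aggregate to the
        printed patient averages (57 % Se, 2.05 FP/h to table precision)."""
        from ictalhr import published
        col = published.PER_PATIENT["hospital_ecg"]
        se = patient_average(v[0] for v in col.values())
        fph = patient_average(v[1] for v in col.values())
        assert round_half_up(se) == 57
        assert abs(fph - 2.05) <= 0.01


class TestCurve:
    def _scored(self):
        # spacing >= 60 s, as the detector's refractory guarantees
        rng = np.random.default_rng(21)
        seiz = [SeizureAnnotation(float(o))
                for o in (500.0, 1500.0, 2500.0)]
        times = np.cumsum(rng.uniform(61.0, 200.0, 30))
        alarms = [Alarm(float(t), float(rng.normal()))
                  for t in times if t < 3600.0]
        return [(alarms, seiz, 1.0)]

    def test_low_threshold_equals_unfiltered(self):
        scored = self._scored()
        pts = sensitivity_fa_curve(scored, np.array([-10.0]))
        alarms, seiz, dur = scored[0]
        m = match(merge_alarms(alarms), seiz)
        assert pts[0][2] == pytest.approx(100.0 * m.tp / len(seiz))
        assert pts[0][1] == pytest.approx(m.fp / dur)

    def test_high_threshold_zero_point(self):
        pts = sensitivity_fa_curve(self._scored(), np.array([100.0]))
        assert pts[0][1] == 0.0 and pts[0][2] == 0.0

    def test_monotone_and_matches_brute_force(self):
        scored = self._scored()
        taus = np.linspace(-3, 3, 25)
        pts = sensitivity_fa_curve(scored, taus)
        fa = [p[1] for p in pts]
        se = [p[2] for p in pts]
        assert all(a >= b - 1e-12 for a, b in zip(fa, fa[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(se, se[1:]))
        # independent full re-evaluation per threshold
        for tau, fa_i, se_i in pts:
            alarms, seiz, dur = scored[0]
            kept = [a for a in alarms if a.score >= tau]
            m = match(merge_alarms(kept), seiz)
            assert se_i == pytest.approx(100.0 * m.tp / len(seiz))
            assert fa_i == pytest.approx(m.fp / dur)


class TestDurationBins:
    def _matches(self, durations, detected):
        seiz = [SeizureAnnotation(1000.0 * k, 1000.0 * k + d if d else None)
                for k, d in enumerate(durations)]
        alarms = alarms_at(*[1000.0 * k + 10 for k, det
                             in enumerate(detected) if det])
        return match(alarms, seiz)

    def test_boundary_half_open(self):
        m = self._matches([20.0], [True])
        bins = sensitivity_by_duration([m])
        assert bins[1]["n"] == 1 and bins[0]["n"] == 0

    def test_unknown_durations_excluded(self):
        m = self._matches([None, None], [True, False])
        bins = sensitivity_by_duration([m])
        assert all(b["n"] == 0 and b["se"] is None for b in bins)

    def test_three_bins_filled(self):
        m = self._matches([10.0, 30.0, 70.0], [True, True, True])
        bins = sensitivity_by_duration([m])
        assert [b["n"] for b in bins] == [1, 1, 0, 1]
        assert bins[0]["se"] == bins[1]["se"] == bins[3]["se"] == 100.0
        assert bins[2]["se"] is None


class TestAttribution:
    def _truth(self, events, ppg_art=()):
        return ih.GroundTruth(
            beat_times=np.empty(0), seizure_intervals=[
                (ev.onset, ev.offset) for ev in events],
            artifact_intervals={"ecg": [], "ppg": list(ppg_art)},
            programmed_hr=lambda t: np.full_like(np.asarray(t, float), 70.0),
            events=tuple(events))

    def test_decrease_attributed_hrd(self):
        ev = ih.SimSeizureEvent(200.0, 60.0, "decrease", 15.0, 20.0)
        truth = self._truth([ev])
        m = match([], [SeizureAnnotation(200.0, 260.0)])
        assert ih.attribute_missed(m, truth, "ecg") == ["HRD"]

    def test_motion_burst_wins_precedence(self):
        ev = ih.SimSeizureEvent(200.0, 60.0, "decrease", 15.0, 20.0)
        truth = self._truth([ev], ppg_art=[(180.0, 300.0, "motion_burst")])
        m = match([], [SeizureAnnotation(200.0, 260.0)])
        assert ih.attribute_missed(m, truth, "ppg") == ["MA"]

    def test_small_increase(self):
        ev = ih.SimSeizureEvent(200.0, 60.0, "increase", 10.0, 20.0)
        truth = self._truth([ev])
        m = match([], [SeizureAnnotation(200.0, 260.0)])
        assert ih.attribute_missed(m, truth, "ecg") == ["small HRI"]

    def test_interference_category_and_detected_none(self):
        evs = [ih.SimSeizureEvent(200.0, 60.0, "increase", 30.0, 20.0),
               ih.SimSeizureEvent(600.0, 60.0, "none", 0.0, 20.0)]
        truth = self._truth(evs)
        truth.artifact_intervals["ecg"] = [(150.0, 320.0, "narrowband_12hz")]
        m = match(alarms_at(610.0), [SeizureAnnotation(200.0, 260.0),
                                     SeizureAnnotation(600.0, 660.0)])
        assert ih.attribute_missed(m, truth, "ecg") == ["Interf", None]

    def test_real_data_requires_external_reasons(self):
        m = match([], [SeizureAnnotation(200.0)])
        with pytest.raises(ValueError):
            ih.attribute_missed(m, None, "ecg")


class TestFpCoincidence:
    def test_identical_lists_full_coincidence(self):
        out = fp_coincidence({"p": [10.0, 500.0]}, {"p": [10.0, 500.0]})
        assert out["per_patient"]["p"] == 100.0

    def test_disjoint_lists_zero(self):
        out = fp_coincidence({"p": [0.0, 1000.0]}, {"p": [400.0, 2000.0]})
        assert out["per_patient"]["p"] == 0.0

    def test_pairwise_scan_asymmetric(self):
        a = {"p": [0.0, 200.0]}
        b = {"p": [30.0, 500.0]}
        assert fp_coincidence(a, b)["per_patient"]["p"] == 50.0
        assert fp_coincidence(b, a)["per_patient"]["p"] == 50.0
        c = {"p": [30.0, 40.0, 500.0]}
        assert fp_coincidence(c, a)["per_patient"]["p"] \
            == pytest.approx(200.0 / 3)

    def test_empty_list_excluded_from_mean(self, caplog):
        with caplog.at_level("WARNING"):
            out = fp_coincidence({"p": [], "q": [5.0]}, {"p": [5.0],
                                                         "q": [10.0]})
        assert out["per_patient"]["p"] is None
        assert out["mean"] == 100.0


class TestDerivedCounts:
    def test_sensitivity_from_counts(self):
        assert sensitivity_from_counts(47, 20) == pytest.approx(100 * 27 / 47)
        with pytest.raises(ValueError):
            sensitivity_from_counts(10, 11)

    def test_round_half_up(self):
        assert round_half_up(56.5) == 57
        assert round_half_up(2.345, 2) == 2.35
        assert round_half_up(31.9) == 32
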