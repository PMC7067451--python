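"""Unit tests for minute-level scoring, ROC selection and confusion matrix."""

from __future__ import annotations

import numpy as np
import pytest

import csrdemod as cd
from csrdemod.evaluation import (
    NORMAL,
    OSC,
    REF_ERRATIC,
    REF_NEGATIVE,
    REF_POSITIVE,
    PerformanceReport,
    minutes_from_zones,
    roc_select_threshold,
    se_sp,
)

from _oracles import minute_labels_from_intervals


def zone(start, end, h=1.0):
    return cd.OscillationZone(start, end, h, h)


class TestMinutesFromZones:
    def test_partial_coverage_thirty_second_rule(self):
        pred = minutes_from_zones([zone(90.0, 300.0)], 6)
        assert pred == [NORMAL, OSC, OSC, OSC, OSC, NORMAL]

    def test_matches_interval_overlap_oracle(self):
        rng = np.random.default_rng(5)
        zones = []
        t = 0.0
        while t < 1700.0:
            start = t + rng.uniform(0.0, 200.0)
            end = start + rng.uniform(30.0, 400.0)
            zones.append(zone(start, end))
            t = end
        pred = minutes_from_zones(zones, 30)
        oracle = minute_labels_from_intervals(
            [(z.start_s, z.end_s) for z in zones], 30
        )
        assert pred == oracle

    def test_no_zones_all_normal(self):
        assert minutes_from_zones([], 5) == [NORMAL] * 5

    def test_exact_minute_zone(self):
        pred = minutes_from_zones([zone(60.0, 120.0)], 3)
        assert pred == [NORMAL, OSC, NORMAL]


class TestSeSp:
    def test_printed_formula_arithmetic(self):
        pred = [OSC] * 45 + [NORMAL] * 6
        ref = [REF_POSITIVE] * 40 + [REF_NEGATIVE] * 5 + [REF_POSITIVE] * 6
        rep = se_sp(pred, ref)
        assert (rep.tp, rep.fp, rep.fn) == (40, 5, 6)
        assert rep.se == pytest.approx(86.96, abs=0.01)
        assert rep.sp_as_printed == pytest.approx(88.89, abs=0.01)

    def test_perfect_prediction(self):
        pred = [OSC, NORMAL, OSC]
        ref = [REF_POSITIVE, REF_NEGATIVE, REF_POSITIVE]
        rep = se_sp(pred, ref)
        assert rep.se == 100.0
        assert rep.sp_as_printed == 100.0
        assert rep.specificity_conventional == 100.0

    def test_all_normal_prediction_zero_sensitivity(self):
        rep = se_sp([NORMAL] * 4, [REF_POSITIVE, REF_NEGATIVE] * 2)
        assert rep.se == 0.0

    def test_erratic_minutes_excluded(self):
        pred = [OSC, OSC, NORMAL]
        ref = [REF_POSITIVE, REF_ERRATIC, REF_NEGATIVE]
        rep = se_sp(pred, ref)
        assert rep.excluded == 1
        assert rep.tp == 1 and rep.fp == 0 and rep.tn == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            se_sp([OSC], [REF_POSITIVE, REF_NEGATIVE])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        pred = [OSC if rng.random() < 0.4 else NORMAL for _ in range(60)]
        ref = [REF_POSITIVE if rng.random() < 0.5 else REF_NEGATIVE for _ in range(60)]
        order = rng.permutation(60)
        a = se_sp(pred, ref)
        b = se_sp([pred[i] for i in order], [ref[i] for i in order])
        assert a == b

    def test_added_true_positive_never_decreases_se(self):
        base = se_sp([OSC, NORMAL], [REF_POSITIVE, REF_POSITIVE])
        more = se_sp([OSC, NORMAL, OSC], [REF_POSITIVE, REF_POSITIVE, REF_POSITIVE])
        assert more.se >= base.se


class TestRocSelectThreshold:
    def make_track(self, hs, f=0.015):
        ests = tuple(
            cd.WindowEstimate(
                t_center=60.0 + 24.0 * i, a_c_hat=1.0, h_hat=h, f_m_hat=f,
                phi_hat=0.0, valid=True,
            )
            for i, h in enumerate(hs)
        )
        return cd.EstimateTrack(estimates=ests, window_s=120.0, overlap=0.8)

    def test_perfect_separation_returns_smallest_optimal(self):
        # positives h_hat >= 0.4; negatives <= 0.05
        pos = self.make_track([0.4] * 70)
        neg = self.make_track([0.05] * 70)
        refs = [["csr_pb"] * 30, ["normal"] * 30]
        res = roc_select_threshold([pos, neg], refs, np.arange(0.05, 0.45, 0.05))
        # smallest grid value strictly above the negatives' h_hat
        assert res.h0 == pytest.approx(0.10)

    def test_youden_on_overlapping_grid_matches_exhaustive(self):
        rng = np.random.default_rng(8)
        tracks, refs = [], []
        for _ in range(3):
            hs = np.where(rng.random(70) < 0.5, rng.uniform(0.1, 0.4, 70),
                          rng.uniform(0.0, 0.2, 70))
            tracks.append(self.make_track(list(hs)))
            refs.append(
                ["csr_pb" if rng.random() < 0.5 else "normal" for _ in range(30)]
            )
        grid = np.array([0.05, 0.12, 0.3])
        res = roc_select_threshold(tracks, refs, grid)
        best = max(res.curve, key=lambda p: (p.youden, -p.h0))
        assert res.h0 == best.h0

    def test_single_class_reference_rejected(self):
        track = self.make_track([0.5] * 70)
        with pytest.raises(ValueError, match="single-class"):
            roc_select_threshold([track], [["csr_pb"] * 30], np.array([0.1]))


class TestConfusionMatrix:
    def test_perfect_pipeline_is_diagonal(self):
        labels = [cd.CSR_CSA] * 4 + [cd.PB] + [cd.NON_CSR] * 10
        mat = cd.confusion_matrix(labels, labels)
        assert np.array_equal(np.diag(mat.to_numpy()), [4, 1, 10])
        assert mat.to_numpy().sum() == 15

    def test_all_non_csr_prediction(self):
        ref = [cd.CSR_CSA, cd.PB, cd.NON_CSR, cd.NON_CSR]
        mat = cd.confusion_matrix([cd.NON_CSR] * 4, ref)
        assert list(mat.loc[cd.NON_CSR]) == [1, 1, 2]
        assert mat.loc[cd.CSR_CSA].sum() == 0

    def test_mixed_errors_hand_tally(self):
        pred = [cd.CSR_CSA, cd.PB, cd.PB, cd.NON_CSR, cd.CSR_CSA]
        ref = [cd.CSR_CSA, cd.CSR_CSA, cd.PB, cd.PB, cd.NON_CSR]
        mat = cd.confusion_matrix(pred, ref)
        assert mat.loc[cd.CSR_CSA, cd.CSR_CSA] == 1
        assert mat.loc[cd.PB, cd.CSR_CSA] == 1
        assert mat.loc[cd.PB, cd.PB] == 1
        assert mat.loc[cd.NON_CSR, cd.PB] == 1
        assert mat.loc[cd.CSR_CSA, cd.NON_CSR] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            cd.confusion_matrix(["bogus"], [cd.PB])


def test_report_dict_is_serializable():
    rep = PerformanceReport(tp=10, fp=2, fn=1, tn=30, excluded=3)
    d = rep.as_dict()
    assert d["TP"] == 10 and d["excluded_erratic"] == 3
    assert d["specificity_conventional"] == pytest.approx(100 * 30 / 32)
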