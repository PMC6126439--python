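import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from respimoco.grids import VoxelVolume
from respimoco.quantify import (delta_suv, detection_summary, match_marks,
                                paired_t, suv_max, suv_peak, suv_scale,
                                wilcoxon_signed_rank)


def _suv_vol(values, spacing=3.0):
    return VoxelVolume(values, (spacing,) * np.asarray(values).ndim,
                       semantics="suv")


class TestSUV:
    def test_scale_arithmetic(self):
        vol = VoxelVolume(np.full((4, 4), 10.0), (3.0, 3.0),
                          semantics="activity")
        suv = suv_scale(vol, weight_kg=70.0, dose_MBq=350.0)
        assert np.allclose(suv.values, 2.0)
        assert suv.semantics == "suv"

    def test_doubling_dose_halves_suv(self, rng):
        vol = VoxelVolume(rng.random((6, 6)), (3.0, 3.0),
                          semantics="activity")
        a = suv_scale(vol, 70.0, 350.0).values
        b = suv_scale(vol, 70.0, 700.0).values
        assert np.allclose(a, 2.0 * b)

    def test_zero_image_zero_suv(self):
        vol = VoxelVolume(np.zeros((4, 4)), (3.0, 3.0),
                          semantics="activity")
        assert np.all(suv_scale(vol, 70.0, 350.0).values == 0.0)

    def test_missing_calibration_rejected(self):
        vol = VoxelVolume(np.ones((4, 4)), (3.0, 3.0))
        with pytest.raises(ValueError):
            suv_scale(vol, 0.0, 350.0)

    def test_uniform_image_peak_equals_value(self):
        vol = _suv_vol(np.full((20, 20, 20), 3.7))
        roi = np.zeros((20, 20, 20), dtype=bool)
        roi[8:12, 8:12, 8:12] = True
        assert suv_peak(vol, roi) == pytest.approx(3.7)
        assert suv_max(vol, roi) == pytest.approx(3.7)

    def test_small_hot_lesion_peak_below_max(self):
        # 6-mm lesion, 12-mm averaging sphere: partial volume by design
        vol_arr = np.zeros((24, 24, 24))
        vol_arr[12, 12, 12] = 10.0
        vol_arr[11:14, 11:14, 11:14] += 2.0
        vol = _suv_vol(vol_arr)
        roi = np.zeros_like(vol_arr, dtype=bool)
        roi[10:15, 10:15, 10:15] = True
        assert suv_peak(vol, roi) < suv_max(vol, roi)

    def test_peak_equals_bruteforce_on_random_volumes(self, rng):
        from respimoco.experiments import _suv_peak_bruteforce
        for _ in range(5):
            n = int(rng.integers(16, 30))
            vol = _suv_vol(rng.random((n, n, n)))
            roi = np.zeros((n, n, n), dtype=bool)
            c = rng.integers(4, n - 4, size=3)
            roi[c[0]-1:c[0]+2, c[1]-1:c[1]+2, c[2]-1:c[2]+2] = True
            assert suv_peak(vol, roi) == _suv_peak_bruteforce(vol, roi, 12.0)
            flat_max = max(vol.values[tuple(i)] for i in np.argwhere(roi))
            assert suv_max(vol, roi) == flat_max

    def test_sphere_larger_than_grid_rejected(self):
        vol = _suv_vol(np.ones((4, 4, 4)))
        roi = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="sphere"):
            suv_peak(vol, roi, sphere_diameter_mm=60.0)

    def test_empty_roi_rejected(self):
        vol = _suv_vol(np.ones((6, 6)))
        with pytest.raises(ValueError, match="empty"):
            suv_peak(vol, np.zeros((6, 6), dtype=bool))


class TestDeltaSUV:
    def test_example_percentages(self):
        u = {0: {"suv_peak": 10.0, "suv_max": 10.0}}
        mc = {0: {"suv_peak": 11.24, "suv_max": 11.0}}
        tab = delta_suv(u, mc)
        assert tab.loc[0, "delta_suv_peak_pct"] == pytest.approx(12.4)
        assert tab.loc[0, "delta_suv_max_pct"] == pytest.approx(10.0)
        assert bool(tab.loc[0, "considerable"])

    def test_no_change_not_considerable(self):
        u = {0: {"suv_peak": 5.0, "suv_max": 7.0}}
        tab = delta_suv(u, u)
        assert tab.loc[0, "delta_suv_peak_pct"] == 0.0
        assert not tab.loc[0, "considerable"]

    def test_considerable_requires_both_metrics(self):
        u = {0: {"suv_peak": 10.0, "suv_max": 10.0}}
        mc = {0: {"suv_peak": 10.6, "suv_max": 10.4}}  # +6% / +4%
        tab = delta_suv(u, mc)
        assert not tab.loc[0, "considerable"]

    def test_zero_uncorrected_flagged_undefined(self):
        u = {0: {"suv_peak": 0.0, "suv_max": 0.0}}
        mc = {0: {"suv_peak": 1.0, "suv_max": 1.0}}
        tab = delta_suv(u, mc)
        assert bool(tab.loc[0, "delta_undefined"])
        assert np.isnan(tab.loc[0, "delta_suv_peak_pct"])


class TestMatchMarks:
    REF = pd.DataFrame({"lesion": [0, 1], "z_mm": [100.0, 160.0],
                        "x_mm": [100.0, 200.0]})

    def _marks(self, rows):
        return pd.DataFrame(rows, columns=["reader", "mode", "z_mm", "x_mm",
                                           "score"])

    def test_nearby_mark_is_tp(self):
        marks = self._marks([["r1", "U", 103.0, 104.0, 3]])
        tab = match_marks(marks, self.REF, tolerance_mm=15.0)
        row = tab[(tab["label"] == "TP")].iloc[0]
        assert row["lesion"] == 0 and row["score"] == 3

    def test_distant_mark_is_fp_and_miss_scored_zero(self):
        marks = self._marks([["r1", "U", 400.0, 400.0, 2]])
        tab = match_marks(marks, self.REF, tolerance_mm=15.0)
        assert (tab["label"] == "FP").sum() == 1
        fns = tab[tab["label"] == "FN"]
        assert len(fns) == 2 and np.all(fns["score"] == 0)

    def test_two_marks_near_one_lesion_nearer_wins(self):
        marks = self._marks([["r1", "U", 101.0, 100.0, 4],
                             ["r1", "U", 108.0, 100.0, 2]])
        tab = match_marks(marks, self.REF, tolerance_mm=15.0)
        tp = tab[tab["label"] == "TP"].iloc[0]
        assert tp["score"] == 4
        assert (tab["label"] == "FP").sum() == 1


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        before = np.zeros(6)
        after = np.arange(1.0, 7.0)
        w, p = wilcoxon_signed_rank(before, after, mode="exact")
        assert w == 21.0
        assert p == pytest.approx(2.0 / 64.0)

    def test_no_change_gives_p_one(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-3, 3), min_size=4, max_size=10))
    def test_exact_matches_scipy_when_no_ties(self, diffs):
        """scipy.stats.wilcoxon as the independent oracle on tie-free data
        (scipy's exact mode refuses ties)."""
        from scipy import stats
        d = np.asarray(diffs, dtype=float)
        d = d[d != 0]
        if len(d) < 4 or len(np.unique(np.abs(d))) != len(d):
            return
        _, p = wilcoxon_signed_rank(np.zeros_like(d), d, mode="exact")
        ref = stats.wilcoxon(d, mode="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_pratt_zero_handling_available(self):
        before = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        after = np.array([1.0, 3.0, 4.0, 0.0, 5.0])
        w_w, p_w = wilcoxon_signed_rank(before, after,
                                        zero_method="wilcox")
        w_p, p_p = wilcoxon_signed_rank(before, after, zero_method="pratt")
        assert w_p != w_w  # zeros shift the ranks under Pratt


class TestPairedT:
    def test_constant_differences_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([0, 0, 0, 0], [1, 1, 1, 1])

    def test_alternating_differences_give_t_zero(self):
        t, p = paired_t([0, 0, 0, 0], [1, -1, 1, -1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_to_1e10(self, rng):
        from scipy import stats
        u = rng.normal(0, 1, 20)
        mc = u + rng.normal(0.5, 1, 20)
        t, p = paired_t(u, mc)
        ref = stats.ttest_rel(mc, u)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestDetectionSummary:
    def _table(self):
        rows = []
        # 4 lesions, 2 readers; MC adds +1 where chi < 4, lesion 3 missed in U
        chi_u = {0: 3, 1: 4, 2: 2, 3: 0}
        for reader in ("r1", "r2"):
            for lesion, score in chi_u.items():
                label = "FN" if score == 0 else "TP"
                rows.append(dict(reader=reader, mode="U", lesion=lesion,
                                 score=score, label=label))
                mc = min(score + 1, 4) if score else 1
                rows.append(dict(reader=reader, mode="MC", lesion=lesion,
                                 score=mc, label="TP"))
        rows.append(dict(reader="r1", mode="U", lesion=None, score=2,
                         label="FP"))
        return pd.DataFrame(rows)

    def test_counts_match_hand_enumeration(self):
        stats_ = detection_summary(self._table())
        # per reader: 3 of 4 marked in U, 4 of 4 in MC
        assert stats_.tp_rate.loc["r1", "U"] == pytest.approx(0.75)
        assert stats_.tp_rate.loc["pooled", "MC"] == pytest.approx(1.0)
        assert stats_.fp_counts.loc["U", "n_fp"] == 1
        assert stats_.fp_counts.loc["MC", "n_fp"] == 0
        # Delta-chi_1+2: lesion 0: +1+1; lesion 1: 0; lesion 2: +1+1;
        # lesion 3: +1+1
        assert stats_.delta_chi_sum.to_dict() == {0: 2, 1: 0, 2: 2, 3: 2}
        assert stats_.agree_increase == [0, 2, 3]
        assert stats_.agree_decrease == []

    def test_uniform_scores_give_null_statistics(self):
        rows = []
        for reader in ("r1", "r2"):
            for lesion in range(4):
                for mode in ("U", "MC"):
                    rows.append(dict(reader=reader, mode=mode, lesion=lesion,
                                     score=4, label="TP"))
        with pytest.warns(UserWarning):
            stats_ = detection_summary(pd.DataFrame(rows))
        assert np.all(stats_.delta_chi["delta_chi"] == 0)
        assert stats_.wilcoxon[1] == 1.0
        assert stats_.tp_rate.loc["pooled", "U"] == 1.0

    def test_mc_improvement_detected_as_significant(self):
        stats_ = detection_summary(self._table())
        assert stats_.wilcoxon[1] < 0.05
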