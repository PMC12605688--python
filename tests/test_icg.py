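import numpy as np
import pandas as pd
import pytest

from pepflow.icg import (
    B_METHODS,
    bpoint_arbol_ic,
    bpoint_arbol_sd,
    bpoint_drost,
    bpoint_forouzanfar,
    bpoint_lozano,
    bpoint_miljkovic,
    bpoint_pale,
    bpoint_sherwood,
    bpoint_stern,
    detect_c_points,
    extract_b_points,
    lozano_b_offset_ms,
)


def _partition(start, r_peak, end, rr_prev=1000):
    return pd.DataFrame(
        {
            "start": np.atleast_1d(start),
            "r_peak": np.atleast_1d(r_peak),
            "end": np.atleast_1d(end),
            "rr_prev": np.atleast_1d(rr_prev),
        }
    )


def _cpoints(c, rc_ms=None):
    c = np.atleast_1d(np.asarray(c, dtype=float))
    return pd.DataFrame(
        {"c_point": c, "rc_ms": rc_ms if rc_ms is not None else c, "reason": ""}
    )


class TestCPoint:
    def test_single_interior_maximum(self):
        dzdt = np.array([0.0, 0.1, 0.3, 1.0, 0.2, 0.0, 0.0])
        res = detect_c_points(dzdt, _partition(0, 1, 7), fs=1000.0)
        assert res.loc[0, "c_point"] == 3.0

    def test_candidate_closest_to_preceding_rc_mean(self):
        """Two peaks at RC 150 and 260 ms; history mean 160 ms -> the 150 ms
        peak wins even though the other is taller."""
        fs = 1000.0
        n = 4000
        dzdt = np.zeros(n)
        rs = [500, 1500, 2500, 3500]
        for r in rs[:3]:
            dzdt[r + 160] = 1.0  # history beats: single peak at RC 160 ms
            dzdt[r + 159] = dzdt[r + 161] = 0.5
        r = rs[3]
        dzdt[r + 150] = 1.0
        dzdt[r + 149] = dzdt[r + 151] = 0.5
        dzdt[r + 260] = 2.0
        dzdt[r + 259] = dzdt[r + 261] = 0.5
        part = pd.DataFrame(
            {
                "start": [150, 1150, 2150, 3150],
                "r_peak": rs,
                "end": [1150, 2150, 3150, 4000],
                "rr_prev": [1000] * 4,
            }
        )
        res = detect_c_points(dzdt, part, fs)
        assert res.loc[3, "c_point"] == r + 150

    def test_monotone_segment_missing(self):
        dzdt = np.arange(100.0)
        res = detect_c_points(dzdt, _partition(0, 10, 100), fs=1000.0)
        assert np.isnan(res.loc[0, "c_point"])
        assert res.loc[0, "reason"] == "NoC"

    def test_clean_train_accuracy(self, notch_train):
        err = notch_train.cpoints["c_point"].to_numpy() - notch_train.truth_aligned[
            "c_point"
        ].to_numpy()
        assert notch_train.cpoints["c_point"].notna().all()
        assert np.max(np.abs(err)) <= 5


class TestExtremumFamily:
    def test_stern_last_local_minimum(self):
        dzdt = np.array([0.0, -1.0, 0.0, 2.0, 5.0, 9.0])
        res = bpoint_stern(dzdt, _partition(0, 0, 6), _cpoints(5))
        assert res.loc[0, "b_point"] == 1.0

    def test_stern_no_minimum_reason(self):
        res = bpoint_stern(np.arange(10.0), _partition(0, 0, 10), _cpoints(9))
        assert res.loc[0, "reason"] == "NoLocMin"

    def test_sherwood_zero_crossing(self):
        dzdt = np.array([-2.0, -1.0, 1.0, 3.0, 9.0])
        res = bpoint_sherwood(dzdt, _partition(0, 0, 5), _cpoints(4))
        assert res.loc[0, "b_point"] == 2.0

    def test_sherwood_no_crossing_reason(self):
        dzdt = np.array([1.0, 2.0, 3.0, 9.0])
        res = bpoint_sherwood(dzdt, _partition(0, 0, 4), _cpoints(3))
        assert res.loc[0, "reason"] == "NoZCross"

    def test_arbol_ic_above_mean_everywhere(self):
        # strictly increasing segment crosses its own mean exactly once; use a
        # window whose pre-C part stays above the cycle mean
        dzdt = np.array([10.0, 10.0, 10.0, 10.0, 11.0, 0.0, 0.0, 0.0])
        res = bpoint_arbol_ic(dzdt, _partition(0, 0, 8), _cpoints(4))
        assert res.loc[0, "reason"] == "NoIsoCross"

    def test_arbol_sd_window_clipped_to_invalid(self):
        # C only 100 ms into the cycle: the [C-150, C-100] window clips empty
        fs = 1000.0
        dzdt = np.linspace(0, 1, 400)
        res = bpoint_arbol_sd(dzdt, _partition(0, 0, 400), _cpoints(100), fs)
        assert res.loc[0, "reason"] == "InvBWindow"

    def test_missing_c_propagates(self):
        res = bpoint_stern(np.zeros(10), _partition(0, 0, 10), _cpoints(np.nan))
        assert res.loc[0, "reason"] == "NoC"


class TestLozano:
    def test_linear_printed_coefficients(self):
        assert lozano_b_offset_ms(100.0, "linear") == pytest.approx(59.45, abs=1e-9)
        assert lozano_b_offset_ms(0.0, "linear") == pytest.approx(4.45, abs=1e-9)

    def test_quadratic_printed_coefficients(self):
        assert lozano_b_offset_ms(100.0, "quadratic") == pytest.approx(59.71, abs=1e-9)

    def test_index_placement(self):
        fs = 1000.0
        part = _partition(0, 100, 1000)
        res = bpoint_lozano(part, _cpoints(200.0), fs, form="linear")
        assert res.loc[0, "b_point"] == 100 + 59  # round(59.45)

    def test_prediction_at_or_past_c_invalid(self):
        fs = 1000.0
        part = _partition(0, 100, 1000)
        res = bpoint_lozano(part, _cpoints(110.0), fs, form="linear")
        assert res.loc[0, "reason"] == "InvBWindow"

    def test_deterministic_pure_function(self, notch_train):
        a = bpoint_lozano(notch_train.partition, notch_train.cpoints, notch_train.fs)
        b = bpoint_lozano(notch_train.partition, notch_train.cpoints, notch_train.fs)
        assert a.equals(b)


class TestDrost:
    def test_analytic_cubic_maximum(self):
        # dzdt(k) = 10*(k/150)^3 on 1 ms sampling; chord from (0,0) to (150,10);
        # max of 10k/150 - 10(k/150)^3 at k = 150/sqrt(3) ~ 86.6 -> sample 87
        k = np.arange(151.0)
        dzdt = 10.0 * (k / 150.0) ** 3
        res = bpoint_drost(dzdt, _partition(0, 0, 151), _cpoints(150), fs=1000.0)
        assert res.loc[0, "b_point"] == 87.0

    def test_linear_window_degenerates_to_c(self):
        # slope/window chosen so the chord arithmetic is exact in binary fp
        dzdt = 150.0 * np.arange(200.0)
        res = bpoint_drost(dzdt, _partition(0, 0, 200), _cpoints(160), fs=1000.0)
        assert res.loc[0, "b_point"] == 160.0  # zero distance everywhere; latest tie

    def test_clean_notch_within_4ms(self, notch_train):
        res = bpoint_drost(
            notch_train.dzdt, notch_train.partition, notch_train.cpoints, notch_train.fs
        )
        err = res["b_point"].to_numpy() - notch_train.truth_aligned["b_point"].to_numpy()
        assert np.max(np.abs(err)) <= 4


class TestForouzanfarB:
    def test_two_runs_search_confined_to_longest(self):
        fs = 1000.0
        # run 1: 40 samples rising; dip; run 2: 120 samples rising to C
        seg1 = np.linspace(-0.5, 0.0, 40)
        dip = np.linspace(0.0, -0.4, 20)
        seg2 = np.linspace(-0.4, 1.0, 120)
        dzdt = np.concatenate([np.zeros(50), seg1, dip, seg2, np.linspace(1.0, 0.0, 30)])
        c = 50 + 40 + 20 + 119
        res = bpoint_forouzanfar(dzdt, _partition(0, 10, len(dzdt), rr_prev=600),
                                 _cpoints(float(c)), fs)
        b = res.loc[0, "b_point"]
        run2_start = 50 + 40 + 20
        assert run2_start <= b <= run2_start + 40  # first third of the 120-run

    def test_monotone_decrease_into_c_no_a_point(self):
        fs = 1000.0
        dzdt = np.concatenate([np.linspace(1.0, 0.0, 200), [2.0], np.zeros(20)])
        res = bpoint_forouzanfar(dzdt, _partition(0, 10, len(dzdt), rr_prev=600),
                                 _cpoints(200.0), fs)
        assert res.loc[0, "reason"] == "NoLocMin"

    def test_clean_notch_returns_values(self, notch_train):
        res = bpoint_forouzanfar(
            notch_train.dzdt, notch_train.partition, notch_train.cpoints, notch_train.fs
        )
        assert res["b_point"].notna().all()
        err = res["b_point"].to_numpy() - notch_train.truth_aligned["b_point"].to_numpy()
        assert np.max(np.abs(err)) <= 8


class TestPale:
    def test_notch_stage_one_local_minimum(self, notch_train):
        res = bpoint_pale(
            notch_train.dzdt, notch_train.partition, notch_train.cpoints, notch_train.fs
        )
        err = res["b_point"].to_numpy() - notch_train.truth_aligned["b_point"].to_numpy()
        assert np.max(np.abs(err)) <= 4

    def test_monotone_rise_first_suprathreshold_slope(self):
        fs = 1000.0
        # no local min in [C-150, C); slope accelerates mid-window
        k = np.arange(400.0)
        dzdt = 1e-4 * k + np.where(k > 330, (k - 330) ** 2 * 1e-3, 0.0)
        res = bpoint_pale(dzdt, _partition(0, 0, 400), _cpoints(380), fs)
        b = res.loc[0, "b_point"]
        assert 330 <= b < 380

    def test_flat_window_falls_back_to_global_minimum(self):
        fs = 1000.0
        dzdt = np.concatenate([[0.5, -0.7], np.zeros(300), [1.0, 0.0]])
        res = bpoint_pale(dzdt, _partition(0, 0, len(dzdt)), _cpoints(302.0), fs)
        assert res.loc[0, "b_point"] == 1.0  # stage 3: argmin over [start, C)


class TestMiljkovic:
    def test_clean_notch_within_6ms(self, notch_train):
        res = bpoint_miljkovic(
            notch_train.dzdt, notch_train.partition, notch_train.cpoints, notch_train.fs
        )
        err = res["b_point"].to_numpy() - notch_train.truth_aligned["b_point"].to_numpy()
        assert np.max(np.abs(err)) <= 6

    def test_unit_weight_reduces_to_stern_on_window(self, notch_train):
        fs = notch_train.fs
        flat = bpoint_miljkovic(
            notch_train.dzdt, notch_train.partition, notch_train.cpoints, fs,
            weight_fn=lambda n: np.ones(n),
        )
        stern = bpoint_stern(notch_train.dzdt, notch_train.partition, notch_train.cpoints, fs)
        # identical wherever Stern's minimum lies inside the 300 ms window
        both = flat["b_point"].notna() & stern["b_point"].notna()
        c = notch_train.cpoints["c_point"]
        inside = stern["b_point"] >= c - 300
        sel = both & inside
        assert (flat.loc[sel, "b_point"] == stern.loc[sel, "b_point"]).all()
        assert sel.sum() > 0

    def test_empty_window_invalid(self):
        dzdt = np.linspace(0, 1, 50)
        res = bpoint_miljkovic(dzdt, _partition(10, 10, 50), _cpoints(11.0), 1000.0)
        assert res.loc[0, "reason"] == "InvBWindow"


class TestCrossMethodInvariants:
    @pytest.mark.parametrize("method", B_METHODS)
    def test_b_before_c_and_reasons_exclusive(self, notch_train, method):
        res = extract_b_points(
            method, notch_train.dzdt, notch_train.partition, notch_train.cpoints,
            notch_train.fs,
        )
        present = res["b_point"].notna()
        c = notch_train.cpoints["c_point"].to_numpy(dtype=float)
        start = notch_train.partition["start"].to_numpy(dtype=float)
        assert (res.loc[present, "b_point"].to_numpy() < c[present.to_numpy()]).all()
        assert (res.loc[present, "b_point"].to_numpy() >= start[present.to_numpy()]).all()
        # reason present iff b_point missing
        assert (res.loc[present, "reason"] == "").all()
        assert (res.loc[~present, "reason"] != "").all()

    def test_featureless_stern_fails_drost_succeeds(self, featureless_train):
        ft = featureless_train
        stern = bpoint_stern(ft.dzdt, ft.partition, ft.cpoints, ft.fs)
        drost = bpoint_drost(ft.dzdt, ft.partition, ft.cpoints, ft.fs)
        assert (stern["reason"] == "NoLocMin").all()
        assert drost["b_point"].notna().all()
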