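"""Glycemic metrics: band occupancy, TIR, GRI components, zones, deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycea.cohort import generate_cgm_trace
from glycea.metrics import (
    GlucoseTrace, GlycemicProfile, classify_gri_zone, compute_gri,
    compute_tir, metric_delta, profile_from_trace, zone_grid_counts,
)


def _trace(values, step_min=5):
    ts = pd.date_range("2024-01-01", periods=len(values), freq=f"{step_min}min")
    return GlucoseTrace(ts, values)


class TestGlucoseTrace:
    def test_rejects_implausible_raw_values(self):
        with pytest.raises(ValueError, match=r"\[20, 600\]"):
            _trace([100.0, 10.0])
        with pytest.raises(ValueError):
            _trace([100.0, 650.0])

    def test_clamps_to_reporting_range(self):
        tr = _trace([25.0, 500.0, 100.0])
        assert tr.glucose.min() == 40.0 and tr.glucose.max() == 400.0

    def test_requires_increasing_timestamps(self):
        ts = pd.to_datetime(["2024-01-01 00:00", "2024-01-01 00:00"])
        with pytest.raises(ValueError, match="strictly increasing"):
            GlucoseTrace(ts, [100.0, 110.0])

    def test_csv_round_trip(self, tmp_path):
        tr = _trace([80.0, 120.0, 200.0])
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = GlucoseTrace.from_csv(path)
        np.testing.assert_allclose(back.glucose, tr.glucose)


class TestProfileFromTrace:
    def test_single_band(self):
        prof = profile_from_trace(_trace([100.0] * 12))
        assert prof.as_array().tolist() == [0, 0, 100, 0, 0]

    def test_one_reading_per_band(self):
        prof = profile_from_trace(_trace([50, 60, 100, 200, 300]))
        np.testing.assert_allclose(prof.as_array(), [20, 20, 20, 20, 20])

    def test_band_edge_convention(self):
        # 54 and 70 are closed on the left of their bands; 180/250 on the right
        prof = profile_from_trace(_trace([53.9, 54.0, 69.9, 70.0, 180.0, 180.1, 250.0, 250.1]))
        np.testing.assert_allclose(prof.as_array(), [12.5, 25, 25, 25, 12.5])

    def test_irregular_sampling_weights_capped(self):
        # one 2-hour gap among 5-minute samples must not dominate
        ts = pd.to_datetime(["2024-01-01 00:00", "2024-01-01 00:05",
                             "2024-01-01 02:05", "2024-01-01 02:10",
                             "2024-01-01 02:15"])
        tr = GlucoseTrace(ts, [100, 300, 100, 100, 100])
        prof = profile_from_trace(tr)
        # the gap reading (300) weight is capped at 2x median (10 min of 30)
        assert prof.pct_vhigh == pytest.approx(100 * 10 / 30)


class TestGri:
    @pytest.mark.parametrize("profile, hypo, hyper, gri, zone", [
        ((0, 0, 100, 0, 0), 0.0, 0.0, 0.0, "A"),
        ((2, 4, 70, 20, 4), 5.2, 14.0, 38.0, "B"),
        ((40, 20, 0, 20, 20), 56.0, 30.0, 100.0, "E"),  # 216 clipped to 100
    ])
    def test_hand_computed_values(self, profile, hypo, hyper, gri, zone):
        res = compute_gri(GlycemicProfile(*profile))
        assert res.hypo_component == pytest.approx(hypo)
        assert res.hyper_component == pytest.approx(hyper)
        assert res.gri == pytest.approx(gri)
        assert res.zone == zone

    def test_tir_is_the_in_range_band(self):
        assert compute_tir(GlycemicProfile(0, 0, 100, 0, 0)) == 100
        assert compute_tir(GlycemicProfile(2, 4, 70, 20, 4)) == 70

    @given(st.tuples(*[st.floats(0, 100) for _ in range(4)]))
    @settings(max_examples=200, deadline=None)
    def test_clipped_and_monotone(self, bands):
        vlow, low, high, vhigh = (np.array(bands) / max(1e-9, sum(bands)) * 50)
        tir = 100 - vlow - low - high - vhigh
        res = compute_gri(GlycemicProfile(vlow, low, tir, high, vhigh))
        assert 0 <= res.gri <= 100
        # monotone: adding very-low time at the expense of TIR never lowers GRI
        if vlow + 1 <= 50 and res.gri < 100:
            bumped = compute_gri(GlycemicProfile(vlow + 1, low, tir - 1, high, vhigh))
            assert bumped.gri >= res.gri

    def test_zero_iff_no_out_of_range_time(self):
        assert compute_gri(GlycemicProfile(0, 0, 100, 0, 0)).gri == 0
        assert compute_gri(GlycemicProfile(0.1, 0, 99.9, 0, 0)).gri > 0


class TestZones:
    @pytest.mark.parametrize("gri, zone", [
        (0.0, "A"), (20.0, "A"), (20.000001, "B"), (40.0, "B"),
        (56.4, "C"), (60.0, "C"), (80.0, "D"), (80.1, "E"), (100.0, "E"),
    ])
    def test_boundaries(self, gri, zone):
        assert classify_gri_zone(gri) == zone

    def test_total_on_dense_grid(self):
        grid = np.linspace(0, 100, 100001)
        zones = [classify_gri_zone(g) for g in grid]
        assert set(zones) == {"A", "B", "C", "D", "E"}
        # labels are ordered along the grid: no gaps or interleaving
        changes = [i for i in range(1, len(zones)) if zones[i] != zones[i - 1]]
        assert len(changes) == 4

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1, np.nan):
            with pytest.raises(ValueError):
                classify_gri_zone(bad)


class TestMetricDelta:
    @pytest.mark.parametrize("m0, m12, expected", [
        (52.9, 72.7, 19.8),   # intervention TIR gain
        (65.9, 71.9, 6.0),    # comparator TIR gain
        (56.4, 30.1, -26.3),  # intervention GRI reduction
        (37.8, 30.3, -7.5),   # comparator GRI reduction
        (50.0, 50.0, 0.0),
    ])
    def test_printed_longitudinal_changes(self, m0, m12, expected):
        assert metric_delta(m0, m12) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            metric_delta(-1, 50)


class TestZoneGrid:
    @staticmethod
    def _frame(gris, timepoint="M12"):
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(len(gris))],
            "timepoint": timepoint, "gri": gris,
        })

    def test_all_zone_a(self):
        res = zone_grid_counts(self._frame([0.0] * 5), "M12")
        assert res["counts"]["A"] == 5 and res["cde_fraction"] == 0

    def test_hand_enumeration(self):
        res = zone_grid_counts(self._frame([10, 30, 50, 90]), "M12")
        assert res["counts"] == {"A": 1, "B": 1, "C": 1, "D": 0, "E": 1}
        assert res["cde_count"] == 2 and res["cde_fraction"] == 0.5

    def test_missing_timepoint_lists_patients(self):
        with pytest.raises(ValueError, match="p0"):
            zone_grid_counts(self._frame([10, 20], "M0"), "M12")

    def test_high_risk_fraction_under_truncated_normal(self):
        """A cohort like the intervention baseline (mean 56.4, SD 21) puts
        roughly 79% of patients in zones C-E."""
        from glycea.cohort import CohortSpec, cohort_to_frame, generate_cohort
        spec = CohortSpec(n_intervention=4000, n_comparator=1, seed=2)
        df = cohort_to_frame(generate_cohort(spec))
        df = df[df["arm"] == spec.intervention_label]
        res = zone_grid_counts(df, "M0")
        assert res["cde_fraction"] == pytest.approx(0.79, abs=0.05)


class TestTraceRoundTrip:
    def test_single_band_target(self):
        from glycea.metrics import GlycemicProfile
        tr = generate_cgm_trace(GlycemicProfile(0, 0, 100, 0, 0), 14, 5, seed=1)
        assert len(tr) == 4032
        assert ((tr.glucose >= 70) & (tr.glucose <= 180)).all()

    def test_target_recovery(self):
        target = GlycemicProfile(2, 4, 70, 20, 4)
        tr = generate_cgm_trace(target, 14, 5, seed=9)
        back = profile_from_trace(tr)
        np.testing.assert_allclose(back.as_array(), target.as_array(),
                                   atol=100 / 4032)

    def test_determinism(self):
        target = GlycemicProfile(5, 5, 60, 20, 10)
        a = generate_cgm_trace(target, 2, 5, seed=4)
        b = generate_cgm_trace(target, 2, 5, seed=4)
        np.testing.assert_array_equal(a.glucose, b.glucose)

    @given(st.lists(st.floats(0.0, 100.0), min_size=5, max_size=5)
           .filter(lambda v: sum(v) > 1e-6))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, raw):
        pct = np.array(raw) / sum(raw) * 100
        pct[2] += 100 - pct.sum()
        if pct[2] < 0 or pct[2] > 100:
            return
        target = GlycemicProfile(*pct)
        tr = generate_cgm_trace(target, 3, 5, seed=17)
        back = profile_from_trace(tr)
        np.testing.assert_allclose(back.as_array(), target.as_array(),
                                   atol=100 / len(tr) + 1e-9)
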