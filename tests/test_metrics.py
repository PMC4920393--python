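"""Beat metrics, normalized RMSE, brachial amplification."""

import numpy as np
import pytest

from cardioage.metrics import (
    ReferenceSeries,
    apply_brachial_amplification,
    beat_metrics,
    normalized_rmse,
)
from cardioage.synthetic import fixture_beat


class TestBeatMetrics:
    def test_sinusoid_pressure_extrema_and_mean(self):
        w = fixture_beat("sinusoid", pressure_mean=90.0, pressure_amplitude=20.0)
        m = beat_metrics(w)
        assert m.Psys == pytest.approx(110.0, abs=1e-3)
        assert m.Pdia == pytest.approx(70.0, abs=1e-3)
        assert m.MAP == pytest.approx(90.0, abs=1e-3)
        assert m.pulse_pressure == pytest.approx(40.0, abs=1e-3)

    def test_square_pulse_stroke_volume_and_ejection_time(self):
        w = fixture_beat("square-pulse-flow", flow_amplitude=400.0,
                         flow_duration=0.25)
        m = beat_metrics(w)
        assert m.stroke_volume == pytest.approx(100.0, rel=1e-3)
        assert m.ejection_time == pytest.approx(0.25, abs=1e-3)
        assert m.peak_aortic_flow == pytest.approx(400.0)

    def test_zero_flow_beat(self):
        w = fixture_beat("square-pulse-flow", flow_amplitude=0.0)
        m = beat_metrics(w)
        assert m.stroke_volume == 0.0
        assert m.ejection_time == 0.0

    def test_nonperiodic_waveform_rejected(self):
        w = fixture_beat("sinusoid")
        w.lv_volume = w.lv_volume + np.linspace(0.0, 10.0, w.time.size)
        with pytest.raises(ValueError, match="periodic"):
            beat_metrics(w)

    def test_ohmic_balance_on_converged_beat(self, baseline, arterial20):
        _, rec = baseline
        m = beat_metrics(rec.waveforms, arterial20)
        assert m.MAP == pytest.approx(
            m.stroke_volume / rec.waveforms.period * arterial20.R, rel=0.02)

    def test_ejection_time_increase_combined_mode(self, combined_records):
        recs = {r.age: r for r in combined_records}
        rel = recs[80].metrics.ejection_time / recs[20].metrics.ejection_time - 1.0
        assert rel == pytest.approx(0.12, abs=0.03)


class TestNormalizedRmse:
    def test_zero_iff_identical(self):
        a = ReferenceSeries([20, 30, 40], [100, 105, 110], [76, 77, 78])
        b = ReferenceSeries([20, 30, 40], [100, 105, 110], [76, 77, 78])
        assert normalized_rmse(a, b) == 0.0

    def test_single_age_arithmetic(self):
        model = ReferenceSeries([50], [110.0], [76.0])
        ref = ReferenceSeries([50], [100.0], [76.0])
        assert normalized_rmse(model, ref) == pytest.approx(
            100.0 * np.sqrt(0.1**2 / 2), rel=1e-12)

    def test_seven_age_table_matches_hand_computation(self):
        ages = np.arange(20, 90, 10)
        ref_sys = np.array([112., 116, 120, 125, 131, 138, 145])
        ref_dia = np.array([72., 75, 77, 79, 79, 77, 74])
        mod_sys = ref_sys + np.array([2., -3, 4, -1, 0, 5, -6])
        mod_dia = ref_dia + np.array([-1., 2, 0, 3, -2, 1, -4])
        model = ReferenceSeries(ages, mod_sys, mod_dia)
        ref = ReferenceSeries(ages, ref_sys, ref_dia)
        # independent spreadsheet-style accumulation
        total = 0.0
        count = 0
        for ms, rs in zip(mod_sys, ref_sys):
            total += ((ms - rs) / rs) ** 2
            count += 1
        for md, rd in zip(mod_dia, ref_dia):
            total += ((md - rd) / rd) ** 2
            count += 1
        expected = 100.0 * (total / count) ** 0.5
        assert normalized_rmse(model, ref) == pytest.approx(expected, rel=1e-12)

    def test_small_uniform_offset_scales_linearly(self):
        ages = [20, 30, 40]
        ref = ReferenceSeries(ages, [100.0] * 3, [80.0] * 3)
        for eps in (0.01, 0.02):
            model = ReferenceSeries(ages, [100.0 * (1 + eps)] * 3,
                                    [80.0 * (1 + eps)] * 3)
            assert normalized_rmse(model, ref) == pytest.approx(100 * eps, rel=1e-9)

    def test_mismatched_grids_rejected(self):
        a = ReferenceSeries([20, 30], [100, 105], [76, 77])
        b = ReferenceSeries([20, 40], [100, 105], [76, 77])
        with pytest.raises(ValueError):
            normalized_rmse(a, b)

    def test_zero_reference_rejected(self):
        a = ReferenceSeries([20], [100], [76])
        b = ReferenceSeries([20], [0.0], [76])
        with pytest.raises(ValueError):
            normalized_rmse(a, b)


class TestBrachialAmplification:
    def test_zero_table_is_identity(self):
        s = ReferenceSeries([20, 30], [100, 105], [76, 77])
        out = apply_brachial_amplification(s, {20: 0.0, 30: 0.0})
        assert np.allclose(out.systolic, s.systolic)
        assert np.allclose(out.diastolic, s.diastolic)

    def test_uniform_offset_shifts_systolic_only(self):
        s = ReferenceSeries([20, 30], [100.0, 105.0], [76.0, 77.0])
        out = apply_brachial_amplification(s, {20: 10.0, 30: 10.0})
        assert np.allclose(out.systolic - s.systolic, 10.0)
        assert np.allclose(out.diastolic, s.diastolic)

    def test_additivity_elementwise(self):
        table = {20: 14.0, 30: 11.0, 40: 8.0}
        s = ReferenceSeries([20, 30, 40], [100.0, 105.0, 110.0], [76.0] * 3)
        out = apply_brachial_amplification(s, table)
        assert np.allclose(out.systolic - s.systolic, [14.0, 11.0, 8.0])

    def test_missing_decade_rejected(self):
        s = ReferenceSeries([20, 30], [100, 105], [76, 77])
        with pytest.raises(KeyError):
            apply_brachial_amplification(s, {20: 5.0})


class TestReferenceSeries:
    def test_csv_round_trip(self, tmp_path):
        s = ReferenceSeries([20, 30, 40], [100.5, 105.25, 110.0], [76.0, 77.5, 78.0])
        path = tmp_path / "ref.csv"
        s.to_csv(path)
        back = ReferenceSeries.from_csv(path)
        assert np.allclose(back.ages, s.ages)
        assert np.allclose(back.systolic, s.systolic)
        assert np.allclose(back.diastolic, s.diastolic)

    def test_validation(self):
        with pytest.raises(ValueError):
            ReferenceSeries([20, 20], [100, 101], [70, 71])
        with pytest.raises(ValueError):
            ReferenceSeries([20, 30], [100], [70, 71])
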