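"""Coupled beat simulation: valve logic, conservation, steady state, filling."""

import numpy as np
import pytest

from cardioage import (
    CirculationState,
    ElastanceParams,
    FillingSource,
    calibrate_filling,
    decade_arterial_params,
    simulate_to_steady_state,
    step_circulation,
    update_valves,
)
from cardioage.simulation import ValveParams

from cardioage.metrics import beat_metrics


class TestStepAndValves:
    def test_isovolumic_when_both_valves_closed(self, cardiac20, arterial20, valves):
        state = CirculationState(lv_volume=150.0, compliance_pressure=80.0,
                                 av_open=False, mv_open=False)
        # during early contraction both valves stay shut: volume frozen
        nxt = step_circulation(state, 0.05, cardiac20, arterial20, valves,
                               FillingSource(5.0), dt=2e-4)
        assert nxt.lv_volume == pytest.approx(150.0, abs=1e-12)
        assert nxt.aortic_valve_flow == 0.0 and nxt.mitral_valve_flow == 0.0

    def test_aortic_valve_opens_on_pressure_crossing(self):
        state = CirculationState(lv_volume=150.0, av_open=False, mv_open=False)
        update_valves(state, p_lv=90.0, p_ao=80.0, venous_pressure=5.0)
        assert state.av_open

    def test_open_valve_closes_and_clamps_on_flow_reversal(self):
        state = CirculationState(lv_volume=150.0, aortic_valve_flow=-0.5,
                                 av_open=True, mv_open=False)
        update_valves(state, p_lv=60.0, p_ao=80.0, venous_pressure=5.0)
        assert not state.av_open
        assert state.aortic_valve_flow == 0.0

    def test_valves_never_simultaneously_open(self, arterial_only_records,
                                              combined_records):
        for rec in [*arterial_only_records, *combined_records]:
            w = rec.waveforms
            assert not np.any(w.av_open & w.mv_open), f"age {rec.age}"


class TestConvergedBeat:
    def test_baseline_pressures(self, baseline):
        _, rec = baseline
        assert rec.metrics.Psys == pytest.approx(100.0, abs=3.0)
        assert rec.metrics.Pdia == pytest.approx(76.0, abs=3.0)

    def test_volume_conservation(self, baseline):
        _, rec = baseline
        w = rec.waveforms
        net = np.trapezoid(w.mitral_flow - w.aortic_flow, dx=w.dt)
        assert abs(net) < 0.1

    def test_no_regurgitation(self, baseline):
        _, rec = baseline
        w = rec.waveforms
        assert np.all(w.aortic_flow >= 0.0)
        assert np.all(w.mitral_flow >= 0.0)

    def test_ohmic_balance_map_equals_flow_times_r(self, baseline, arterial20):
        _, rec = baseline
        mean_flow = rec.metrics.stroke_volume / rec.waveforms.period
        assert rec.metrics.MAP == pytest.approx(mean_flow * arterial20.R, rel=0.02)

    def test_stroke_volume_consistent_with_map(self, baseline, arterial20):
        _, rec = baseline
        sv_pred = rec.metrics.MAP / arterial20.R * rec.waveforms.period
        assert rec.metrics.stroke_volume == pytest.approx(sv_pred, rel=0.02)

    def test_initialization_independence(self, cardiac20, arterial20, valves, baseline):
        base, rec = baseline
        far = CirculationState(lv_volume=80.0, compliance_pressure=40.0,
                               mv_open=True)
        w = simulate_to_steady_state(cardiac20, arterial20, valves,
                                     FillingSource(base.Pven20),
                                     initial_state=far)
        assert w.aortic_pressure.max() == pytest.approx(rec.metrics.Psys, abs=0.2)
        assert w.aortic_pressure.min() == pytest.approx(rec.metrics.Pdia, abs=0.2)

    def test_step_refinement_oracle(self, cardiac20, arterial20, valves, baseline):
        # independently converged runs at dt and dt/10 must agree closely
        base, _ = baseline
        filling = FillingSource(base.Pven20)
        coarse = simulate_to_steady_state(cardiac20, arterial20, valves, filling,
                                          dt=2e-4)
        fine = simulate_to_steady_state(cardiac20, arterial20, valves, filling,
                                        dt=2e-5)
        diff = np.abs(coarse.aortic_pressure - fine.aortic_pressure[::10])
        assert diff.max() < 0.1

    def test_nonconvergence_reports_diagnostics(self, cardiac20, arterial20, valves):
        from cardioage import SimulationError

        with pytest.raises(SimulationError, match="beats"):
            simulate_to_steady_state(cardiac20, arterial20, valves,
                                     FillingSource(5.0), max_beats=2)


class TestFillingCalibration:
    def test_ped_target_reached(self, baseline):
        _, rec = baseline
        assert rec.waveforms.end_diastolic_pressure == pytest.approx(5.0, abs=0.05)

    def test_edv_target_mode(self, cardiac20, arterial20, valves):
        src, w = calibrate_filling("edv", 195.0, cardiac20, arterial20, valves,
                                   return_waveforms=True)
        assert w.end_diastolic_volume == pytest.approx(195.0, abs=0.1)

    def test_filling_monotonicity(self, cardiac20, arterial20, valves):
        lo = simulate_to_steady_state(cardiac20, arterial20, valves,
                                      FillingSource(4.5))
        hi = simulate_to_steady_state(cardiac20, arterial20, valves,
                                      FillingSource(5.5))
        assert hi.end_diastolic_volume > lo.end_diastolic_volume

    def test_unreachable_target_raises(self, cardiac20, arterial20, valves):
        from cardioage import SimulationError

        with pytest.raises((SimulationError, ValueError)):
            calibrate_filling("edv", -5.0, cardiac20, arterial20, valves)

    def test_unknown_target_kind_rejected(self, cardiac20, arterial20, valves):
        with pytest.raises(ValueError):
            calibrate_filling("esv", 100.0, cardiac20, arterial20, valves)


class TestWaveformShape:
    def test_systolic_peak_later_in_ejection_at_old_age(self, combined_records):
        recs = {r.age: r for r in combined_records}
        t20 = recs[20].metrics.time_to_psys
        t80 = recs[80].metrics.time_to_psys
        assert t80 > t20

    def test_ejection_bracketed_by_aortic_valve(self, baseline):
        _, rec = baseline
        w = rec.waveforms
        ej = w.av_open
        assert 0.1 < np.count_nonzero(ej[:-1]) * w.dt < 0.45
        # no aortic flow outside ejection
        assert np.all(w.aortic_flow[~ej] == 0.0)
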