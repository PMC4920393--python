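"""Coupled ventricular-arterial beat simulation run to periodic steady state.

The left ventricle (time-varying elastance law) fills from a constant-pressure
venous source through the mitral valve and ejects through the aortic valve
into the four-element Windkessel.  Both valves are ideal diodes with a small
series resistance and inertance: a closed valve opens when its upstream
pressure exceeds its downstream pressure, an open valve closes when its flow
decays through zero, at which point the flow state is clamped to zero.  Only
forward flow is possible.

State vector (5 ODEs): LV volume, aortic valve flow, mitral valve flow,
Windkessel compliance pressure, Windkessel inertance flow.  Integration is
fixed-step classical RK4 with valve transitions applied at step boundaries;
the step divides the period exactly so every beat shares one phase grid.
Consecutive beats are simulated until stroke volume and systolic/diastolic
aortic pressure are beat-to-beat stable, which removes any dependence on the
initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .elastance import ElastanceParams, normalized_elastance
from .windkessel import ArterialParams

__all__ = [
    "ValveParams",
    "FillingSource",
    "CirculationState",
    "BeatWaveforms",
    "SimulationError",
    "step_circulation",
    "update_valves",
    "simulate_to_steady_state",
    "calibrate_filling",
]


class SimulationError(RuntimeError):
    """Raised on numerical failure or non-convergence; carries diagnostics."""


@dataclass(frozen=True)
class ValveParams:
    """Open-valve series resistance (mmHg·s/mL) and blood inertance (mmHg·s²/mL)."""

    resistance: float = 0.003
    inertance: float = 3e-5

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.inertance <= 0:
            raise ValueError("valve resistance and inertance must be > 0")


@dataclass(frozen=True)
class FillingSource:
    """Constant venous pressure (mmHg) feeding the mitral valve."""

    venous_pressure: float = 5.2

    def __post_init__(self) -> None:
        if self.venous_pressure <= 0:
            raise ValueError("venous_pressure must be > 0")


@dataclass
class CirculationState:
    """Instantaneous state of the coupled circulation."""

    lv_volume: float
    aortic_valve_flow: float = 0.0
    mitral_valve_flow: float = 0.0
    compliance_pressure: float = 80.0
    inertance_flow: float = 0.0
    av_open: bool = False
    mv_open: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.lv_volume,
                self.aortic_valve_flow,
                self.mitral_valve_flow,
                self.compliance_pressure,
                self.inertance_flow,
            ],
            dtype=float,
        )


@dataclass
class BeatWaveforms:
    """Time-sampled waveforms of one beat on a uniform grid spanning one period."""

    time: np.ndarray
    lv_pressure: np.ndarray
    lv_volume: np.ndarray
    aortic_pressure: np.ndarray
    aortic_flow: np.ndarray
    mitral_flow: np.ndarray
    av_open: np.ndarray
    mv_open: np.ndarray
    period: float
    dt: float
    converged: bool = True
    n_beats: int = 0
    end_diastolic_index: int = field(default=0)
    mitral_closure_index: int = field(default=-1)
    final_state: "CirculationState | None" = None

    @property
    def end_diastolic_pressure(self) -> float:
        """LV pressure (mmHg) at end diastole.

        End diastole is the cycle boundary, where the activation waveform is
        at its minimum (E = Eed); mitral closure follows within a few
        milliseconds once contraction reverses the filling gradient.
        """
        return float(self.lv_pressure[self.end_diastolic_index])

    @property
    def end_diastolic_volume(self) -> float:
        """LV volume (mL, relative to V0 when V0 = 0) at end diastole."""
        return float(self.lv_volume[self.end_diastolic_index])

    def summary(self) -> dict:
        from .metrics import beat_metrics  # local import avoids a cycle

        return beat_metrics(self).as_dict()


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs(V, qav, qmv, pc, ql, e, av_open, mv_open, V0, C, R, Zc, L, Rv, Lv, Pven):
    plv = e * (V - V0)
    pao = pc + Zc * (qav - ql)
    dV = qmv - qav
    dqav = (plv - pao - Rv * qav) / Lv if av_open else 0.0
    dqmv = (Pven - plv - Rv * qmv) / Lv if mv_open else 0.0
    dpc = (qav - pc / R) / C
    dql = Zc * (qav - ql) / L
    return dV, dqav, dqmv, dpc, dql


@njit(cache=True)
def _integrate_beat(y0, av0, mv0, e_half, dt, V0, C, R, Zc, L, Rv, Lv, Pven):
    """One beat of fixed-step RK4; returns sampled waveforms and final state.

    ``e_half`` holds elastance values on the half-step grid (2n+1 points for n
    steps).  Valve flags are frozen within a step and updated at its end;
    samples are recorded after the update so clamped flows never appear
    negative in the output.
    """
    n = (e_half.shape[0] - 1) // 2
    V, qav, qmv, pc, ql = y0[0], y0[1], y0[2], y0[3], y0[4]
    av, mv = av0, mv0

    v_out = np.empty(n + 1)
    plv_out = np.empty(n + 1)
    pao_out = np.empty(n + 1)
    qav_out = np.empty(n + 1)
    qmv_out = np.empty(n + 1)
    av_out = np.empty(n + 1, dtype=np.bool_)
    mv_out = np.empty(n + 1, dtype=np.bool_)

    v_out[0] = V
    plv_out[0] = e_half[0] * (V - V0)
    pao_out[0] = pc + Zc * (qav - ql)
    qav_out[0] = qav
    qmv_out[0] = qmv
    av_out[0] = av
    mv_out[0] = mv

    for i in range(n):
        e0 = e_half[2 * i]
        em = e_half[2 * i + 1]
        e1 = e_half[2 * i + 2]

        k1 = _rhs(V, qav, qmv, pc, ql, e0, av, mv, V0, C, R, Zc, L, Rv, Lv, Pven)
        k2 = _rhs(V + 0.5 * dt * k1[0], qav + 0.5 * dt * k1[1], qmv + 0.5 * dt * k1[2],
                  pc + 0.5 * dt * k1[3], ql + 0.5 * dt * k1[4],
                  em, av, mv, V0, C, R, Zc, L, Rv, Lv, Pven)
        k3 = _rhs(V + 0.5 * dt * k2[0], qav + 0.5 * dt * k2[1], qmv + 0.5 * dt * k2[2],
                  pc + 0.5 * dt * k2[3], ql + 0.5 * dt * k2[4],
                  em, av, mv, V0, C, R, Zc, L, Rv, Lv, Pven)
        k4 = _rhs(V + dt * k3[0], qav + dt * k3[1], qmv + dt * k3[2],
                  pc + dt * k3[3], ql + dt * k3[4],
                  e1, av, mv, V0, C, R, Zc, L, Rv, Lv, Pven)

        V += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        qav += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        qmv += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        pc += dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
        ql += dt / 6.0 * (k1[4] + 2.0 * k2[4] + 2.0 * k3[4] + k4[4])

        if not (np.isfinite(V) and np.isfinite(qav) and np.isfinite(qmv)
                and np.isfinite(pc) and np.isfinite(ql)):
            return (v_out[: i + 1], plv_out[: i + 1], pao_out[: i + 1],
                    qav_out[: i + 1], qmv_out[: i + 1], av_out[: i + 1],
                    mv_out[: i + 1],
                    np.array([V, qav, qmv, pc, ql]), av, mv, False)

        # valve transitions at the step boundary: close on reverse flow,
        # then open on a favourable pressure gradient
        if av and qav <= 0.0:
            av = False
            qav = 0.0
        if mv and qmv <= 0.0:
            mv = False
            qmv = 0.0
        plv = e1 * (V - V0)
        pao = pc + Zc * (qav - ql)
        if not av and plv > pao:
            av = True
        if not mv and Pven > plv:
            mv = True

        v_out[i + 1] = V
        plv_out[i + 1] = plv
        pao_out[i + 1] = pao
        qav_out[i + 1] = qav
        qmv_out[i + 1] = qmv
        av_out[i + 1] = av
        mv_out[i + 1] = mv

    return (v_out, plv_out, pao_out, qav_out, qmv_out, av_out, mv_out,
            np.array([V, qav, qmv, pc, ql]), av, mv, True)


# ---------------------------------------------------------------------------
# python layer
# ---------------------------------------------------------------------------

def _elastance_half_grid(p: ElastanceParams, n_steps: int, dt: float) -> np.ndarray:
    """Elastance values at 0, dt/2, dt, ..., n·dt (2n+1 points)."""
    t_frac = np.arange(2 * n_steps + 1) * (0.5 * dt) / p.period_T
    t_frac = np.mod(t_frac, 1.0)
    en = normalized_elastance(t_frac, p.shape)
    return p.Eed + (p.Ees - p.Eed) * np.asarray(en)


def update_valves(state: CirculationState, p_lv: float, p_ao: float,
                  venous_pressure: float) -> CirculationState:
    """Apply the diode valve logic to ``state`` (returns the mutated state).

    An open valve closes (flow clamped to 0) when its flow has decayed to or
    through zero; a closed valve opens when upstream pressure exceeds
    downstream pressure (LV vs aorta for the aortic valve, venous source vs
    LV for the mitral valve).
    """
    if state.av_open and state.aortic_valve_flow <= 0.0:
        state.av_open = False
        state.aortic_valve_flow = 0.0
    if state.mv_open and state.mitral_valve_flow <= 0.0:
        state.mv_open = False
        state.mitral_valve_flow = 0.0
    if not state.av_open and p_lv > p_ao:
        state.av_open = True
    if not state.mv_open and venous_pressure > p_lv:
        state.mv_open = True
    return state


def step_circulation(
    state: CirculationState,
    t: float,
    cardiac: ElastanceParams,
    arterial: ArterialParams,
    valves: ValveParams,
    filling: FillingSource,
    dt: float = 2e-4,
) -> CirculationState:
    """Advance the coupled circulation one RK4 step of size ``dt`` from time ``t``.

    Valve flags are held fixed during the step and updated at its end.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t_frac = np.mod(np.array([t, t + dt / 2, t + dt]), cardiac.period_T) / cardiac.period_T
    t_frac = np.where(t_frac >= 1.0, 0.0, t_frac)
    en = np.asarray(normalized_elastance(t_frac, cardiac.shape))
    e_half = cardiac.Eed + (cardiac.Ees - cardiac.Eed) * en
    out = _integrate_beat(
        state.as_array(), state.av_open, state.mv_open, e_half, dt,
        cardiac.V0, arterial.C, arterial.R, arterial.Zc, arterial.L,
        valves.resistance, valves.inertance, filling.venous_pressure,
    )
    y_end, av_end, mv_end, ok = out[7], out[8], out[9], out[10]
    if not ok:
        raise SimulationError(f"non-finite state after step from t={t:.6f}")
    return CirculationState(
        lv_volume=float(y_end[0]),
        aortic_valve_flow=float(y_end[1]),
        mitral_valve_flow=float(y_end[2]),
        compliance_pressure=float(y_end[3]),
        inertance_flow=float(y_end[4]),
        av_open=bool(av_end),
        mv_open=bool(mv_end),
    )


def _mitral_closure_index(mv_open: np.ndarray) -> int:
    """Sample index of mitral valve closure."""
    closures = np.flatnonzero(mv_open[:-1] & ~mv_open[1:])
    if closures.size == 0:
        raise SimulationError("mitral valve never closed during the beat")
    return int(closures[0] + 1)


def simulate_to_steady_state(
    cardiac: ElastanceParams,
    arterial: ArterialParams,
    valves: ValveParams | None = None,
    filling: FillingSource | None = None,
    *,
    dt: float = 2e-4,
    max_beats: int = 100,
    sv_tol: float = 0.1,
    pressure_tol: float = 0.1,
    initial_state: CirculationState | None = None,
) -> BeatWaveforms:
    """Simulate consecutive beats until periodic steady state; return the last beat.

    Convergence requires the beat-to-beat change in stroke volume to fall
    below ``sv_tol`` (mL) and in systolic and diastolic aortic pressure below
    ``pressure_tol`` (mmHg).  Raises :class:`SimulationError` if ``max_beats``
    is exceeded or the state becomes non-finite.
    """
    valves = valves or ValveParams()
    filling = filling or FillingSource()

    n_steps = int(round(cardiac.period_T / dt))
    if n_steps < 10:
        raise ValueError("dt too large for the cardiac period")
    dt_eff = cardiac.period_T / n_steps
    e_half = _elastance_half_grid(cardiac, n_steps, dt_eff)

    if initial_state is None:
        state = CirculationState(lv_volume=cardiac.V0 + 150.0,
                                 compliance_pressure=80.0)
        p_lv0 = cardiac.Eed * 150.0
        update_valves(state, p_lv0, state.compliance_pressure
                      - arterial.Zc * state.inertance_flow,
                      filling.venous_pressure)
    else:
        state = initial_state

    y = state.as_array()
    av, mv = state.av_open, state.mv_open
    prev = None
    time = np.arange(n_steps + 1) * dt_eff

    for beat in range(1, max_beats + 1):
        (v, plv, pao, qav, qmv, av_arr, mv_arr, y, av, mv, ok) = _integrate_beat(
            y, av, mv, e_half, dt_eff,
            cardiac.V0, arterial.C, arterial.R, arterial.Zc, arterial.L,
            valves.resistance, valves.inertance, filling.venous_pressure,
        )
        if not ok:
            raise SimulationError(
                f"non-finite state in beat {beat}; last volume {y[0]:.3g} mL"
            )
        sv = float(np.trapezoid(qav, dx=dt_eff))
        psys = float(pao.max())
        pdia = float(pao.min())
        if prev is not None:
            dsv, dps, dpd = (abs(sv - prev[0]), abs(psys - prev[1]),
                             abs(pdia - prev[2]))
            if dsv < sv_tol and dps < pressure_tol and dpd < pressure_tol:
                return BeatWaveforms(
                    time=time, lv_pressure=plv, lv_volume=v,
                    aortic_pressure=pao, aortic_flow=qav, mitral_flow=qmv,
                    av_open=av_arr, mv_open=mv_arr,
                    period=cardiac.period_T, dt=dt_eff,
                    converged=True, n_beats=beat,
                    end_diastolic_index=0,
                    mitral_closure_index=_mitral_closure_index(mv_arr),
                    final_state=CirculationState(
                        lv_volume=float(y[0]),
                        aortic_valve_flow=float(y[1]),
                        mitral_valve_flow=float(y[2]),
                        compliance_pressure=float(y[3]),
                        inertance_flow=float(y[4]),
                        av_open=bool(av),
                        mv_open=bool(mv),
                    ),
                )
        prev = (sv, psys, pdia)

    raise SimulationError(
        f"no periodic steady state within {max_beats} beats "
        f"(last beat: SV={prev[0]:.3f} mL, Psys={prev[1]:.2f}, Pdia={prev[2]:.2f} mmHg)"
    )


def calibrate_filling(
    target_kind: str,
    target_value: float,
    cardiac: ElastanceParams,
    arterial: ArterialParams,
    valves: ValveParams | None = None,
    *,
    dt: float = 2e-4,
    guess: float | None = None,
    return_waveforms: bool = False,
):
    """Find the venous pressure that realizes a filling target.

    ``target_kind`` is ``"ped"`` (end-diastolic LV pressure, mmHg, matched
    within 0.05) or ``"edv"`` (end-diastolic LV volume, mL, matched within
    0.1).  Root-finding is Brent's method on the converged-beat residual with
    automatic bracket expansion.  Returns the calibrated
    :class:`FillingSource`, or ``(FillingSource, BeatWaveforms)`` when
    ``return_waveforms`` is set.
    """
    if target_kind not in ("ped", "edv"):
        raise ValueError("target_kind must be 'ped' or 'edv'")
    valves = valves or ValveParams()

    warm: dict = {"state": None}
    cache: dict[float, BeatWaveforms] = {}

    def run(pven: float) -> BeatWaveforms:
        waves = simulate_to_steady_state(
            cardiac, arterial, valves, FillingSource(pven), dt=dt,
            initial_state=warm["state"],
        )
        warm["state"] = waves.final_state
        cache[pven] = waves
        return waves

    def residual(pven: float) -> float:
        waves = run(pven)
        if target_kind == "ped":
            return waves.end_diastolic_pressure - target_value
        return waves.end_diastolic_volume - target_value

    if target_kind == "ped":
        lo = max(0.5 * target_value, 0.2)
        hi = target_value + 1.0
    else:
        est = cardiac.Eed * (target_value - cardiac.V0)
        lo = max(0.5 * est, 0.2)
        hi = est + 1.0
    if guess is not None:
        lo = max(0.7 * guess, 0.1)
        hi = 1.3 * guess

    f_lo, f_hi = residual(lo), residual(hi)
    n_expand = 0
    while f_lo * f_hi > 0:
        n_expand += 1
        if n_expand > 40:
            raise SimulationError(
                f"filling calibration could not bracket {target_kind}="
                f"{target_value} in venous pressure range [{lo:.3g}, {hi:.3g}]"
            )
        if f_lo > 0:
            lo *= 0.7
            f_lo = residual(lo)
        else:
            hi *= 1.3
            f_hi = residual(hi)

    pven = brentq(residual, lo, hi, xtol=1e-3)
    waves = cache.get(pven) or run(pven)
    src = FillingSource(pven)
    if return_waveforms:
        return src, waves
    return src
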