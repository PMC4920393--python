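"""Aging protocol: prescribed arterial changes plus iterative cardiac adaptation.

Per decade from age 20 to 80 the arterial load follows its prescribed
schedule.  In *combined* mode the heart then adapts by two physiological
rules run to a fixed point:

1. **Compensated concentric hypertrophy.**  By Laplace's law
   (σ = P·r/2h) with constant lumen radius, restoring wall stress after a
   systolic pressure rise requires wall thickness — and with it both
   elastances — to scale with systolic pressure:
   ``Ees/Ees20 = Eed/Eed20 = Psys/Psys20`` (relative to the age-20 baseline).
2. **Preserved end-diastolic volume.**  Filling pressure is recalibrated at
   every iterate so the end-diastolic volume stays at its age-20 value; the
   resulting end-diastolic pressure Ped is an output.

A thicker wall raises systolic pressure, which demands a thicker wall again;
the loop repeats until successive iterates change systolic pressure by less
than 1 mmHg and end-diastolic volume by less than 1 mL.  In *arterial_only*
mode cardiac parameters and the filling source stay frozen at their age-20
values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .elastance import ElastanceParams
from .metrics import BeatMetrics, beat_metrics
from .simulation import (
    BeatWaveforms,
    FillingSource,
    SimulationError,
    ValveParams,
    calibrate_filling,
    simulate_to_steady_state,
)
from .windkessel import DECADE_AGES, ArterialParams, decade_arterial_params

__all__ = [
    "AgingRecord",
    "Baseline",
    "relative_wall_thickness",
    "wall_stress",
    "adapt_cardiac",
    "run_aging_study",
    "records_to_frame",
]


def wall_stress(p_lv: float, r_i: float, h: float) -> float:
    """Laplace-law wall stress σ = P·r_i/(2h) of a thick-walled sphere."""
    if h <= 0 or r_i <= 0:
        raise ValueError("radius and wall thickness must be > 0")
    return p_lv * r_i / (2.0 * h)


def relative_wall_thickness(psys: float, psys_baseline: float) -> float:
    """Wall thickness ratio h/h0 that normalizes wall stress after a pressure rise.

    With constant lumen radius (concentric remodelling), σ ∝ P/h, so
    ``h/h0 = psys/psys_baseline`` returns the stress ratio exactly to 1.
    """
    if psys_baseline <= 0:
        raise ValueError("psys_baseline must be > 0")
    return psys / psys_baseline


@dataclass(frozen=True)
class Baseline:
    """Converged age-20 operating point anchoring the adaptation rules."""

    Ees20: float
    Eed20: float
    EDV20: float
    Psys20: float
    Pven20: float
    cardiac: ElastanceParams
    valves: ValveParams


@dataclass
class AgingRecord:
    """Per-decade bundle of prescribed, adapted and derived quantities."""

    age: int
    arterial: ArterialParams
    Ees: float
    Eed: float
    Ped: float
    venous_pressure: float
    metrics: BeatMetrics
    waveforms: BeatWaveforms
    iterations: int
    converged: bool


def _metrics(waves: BeatWaveforms, arterial: ArterialParams) -> BeatMetrics:
    return beat_metrics(waves, arterial)


def compute_baseline(
    cardiac: ElastanceParams | None = None,
    valves: ValveParams | None = None,
    *,
    ped_target: float = 5.0,
    dt: float = 2e-4,
) -> tuple[Baseline, AgingRecord]:
    """Calibrate and simulate the age-20 operating point.

    Filling is calibrated so the end-diastolic LV pressure equals
    ``ped_target``; the converged beat defines EDV20 and Psys20 for the
    adaptation rules.
    """
    cardiac = cardiac or ElastanceParams()
    valves = valves or ValveParams()
    arterial = decade_arterial_params(20)
    src, waves = calibrate_filling(
        "ped", ped_target, cardiac, arterial, valves, dt=dt,
        return_waveforms=True,
    )
    m = _metrics(waves, arterial)
    base = Baseline(
        Ees20=cardiac.Ees, Eed20=cardiac.Eed,
        EDV20=waves.end_diastolic_volume, Psys20=m.Psys,
        Pven20=src.venous_pressure, cardiac=cardiac, valves=valves,
    )
    rec = AgingRecord(
        age=20, arterial=arterial, Ees=cardiac.Ees, Eed=cardiac.Eed,
        Ped=waves.end_diastolic_pressure, venous_pressure=src.venous_pressure,
        metrics=m, waveforms=waves, iterations=0, converged=True,
    )
    return base, rec


def adapt_cardiac(
    age: int,
    arterial: ArterialParams,
    baseline: Baseline,
    *,
    dt: float = 2e-4,
    start_Ees: float | None = None,
    start_pven: float | None = None,
    max_iter: int = 50,
    psys_tol: float = 1.0,
    edv_tol: float = 1.0,
) -> AgingRecord:
    """Run the hypertrophy/filling fixed-point loop at one age.

    Each iterate simulates to periodic steady state with filling calibrated
    to the age-20 end-diastolic volume, reads the systolic aortic pressure,
    and rescales both elastances relative to the age-20 baseline
    (rule 1: Ees = Ees20·Psys/Psys20, likewise Eed).  Convergence requires
    successive iterates to change Psys by < ``psys_tol`` mmHg and EDV by
    < ``edv_tol`` mL.  Raises :class:`SimulationError` with the iterate
    history if the loop does not settle within ``max_iter``.
    """
    scale = (start_Ees / baseline.Ees20) if start_Ees else 1.0
    pven = start_pven if start_pven else baseline.Pven20
    history: list[tuple[float, float, float]] = []
    prev_psys = prev_edv = None

    for it in range(1, max_iter + 1):
        cardiac = replace(baseline.cardiac,
                          Ees=baseline.Ees20 * scale,
                          Eed=baseline.Eed20 * scale)
        src, waves = calibrate_filling(
            "edv", baseline.EDV20, cardiac, arterial, baseline.valves,
            dt=dt, guess=pven, return_waveforms=True,
        )
        pven = src.venous_pressure
        m = _metrics(waves, arterial)
        history.append((scale, m.Psys, m.EDV))
        if (prev_psys is not None
                and abs(m.Psys - prev_psys) < psys_tol
                and abs(m.EDV - prev_edv) < edv_tol):
            return AgingRecord(
                age=age, arterial=arterial,
                Ees=cardiac.Ees, Eed=cardiac.Eed,
                Ped=waves.end_diastolic_pressure, venous_pressure=pven,
                metrics=m, waveforms=waves, iterations=it, converged=True,
            )
        prev_psys, prev_edv = m.Psys, m.EDV
        scale = m.Psys / baseline.Psys20
    raise SimulationError(
        f"cardiac adaptation at age {age} did not converge in {max_iter} "
        f"iterations; history (scale, Psys, EDV): {history}"
    )


def run_aging_study(
    mode: str = "combined",
    *,
    cardiac: ElastanceParams | None = None,
    valves: ValveParams | None = None,
    ped_target: float = 5.0,
    dt: float = 2e-4,
    ages: tuple[int, ...] = DECADE_AGES,
    arterial_for_age=decade_arterial_params,
) -> list[AgingRecord]:
    """Run the full per-decade study in ``arterial_only`` or ``combined`` mode.

    ``arterial_only`` freezes the cardiac parameters and the filling source
    at their calibrated age-20 values while the arterial load follows the
    prescribed schedule.  ``combined`` additionally runs the cardiac
    adaptation loop at every age, warm-starting each decade from the
    previous decade's converged parameters.
    """
    if mode not in ("arterial_only", "combined"):
        raise ValueError("mode must be 'arterial_only' or 'combined'")
    baseline, rec20 = compute_baseline(cardiac, valves,
                                       ped_target=ped_target, dt=dt)
    records = [rec20]
    ees_prev, pven_prev = baseline.Ees20, baseline.Pven20
    for age in ages:
        if age == 20:
            continue
        arterial = arterial_for_age(age)
        try:
            if mode == "arterial_only":
                waves = simulate_to_steady_state(
                    baseline.cardiac, arterial, baseline.valves,
                    FillingSource(baseline.Pven20), dt=dt,
                )
                records.append(AgingRecord(
                    age=age, arterial=arterial,
                    Ees=baseline.Ees20, Eed=baseline.Eed20,
                    Ped=waves.end_diastolic_pressure,
                    venous_pressure=baseline.Pven20,
                    metrics=_metrics(waves, arterial), waveforms=waves,
                    iterations=0, converged=True,
                ))
            else:
                rec = adapt_cardiac(
                    age, arterial, baseline, dt=dt,
                    start_Ees=ees_prev, start_pven=pven_prev,
                )
                ees_prev, pven_prev = rec.Ees, rec.venous_pressure
                records.append(rec)
        except SimulationError as exc:
            raise SimulationError(f"age {age}: {exc}") from exc
    return records


def records_to_frame(records: list[AgingRecord]) -> pd.DataFrame:
    """Tabulate a study: one row per age, prescribed + adapted + derived columns."""
    rows = []
    for r in records:
        rows.append({
            "age": r.age,
            "C": r.arterial.C, "R": r.arterial.R,
            "Zc": r.arterial.Zc, "L": r.arterial.L,
            "Ees": r.Ees, "Eed": r.Eed, "Ped": r.Ped,
            "Psys": r.metrics.Psys, "Pdia": r.metrics.Pdia,
            "MAP": r.metrics.MAP, "PP": r.metrics.pulse_pressure,
            "SV": r.metrics.stroke_volume, "EDV": r.metrics.EDV,
            "ESV": r.metrics.ESV, "CO": r.metrics.cardiac_output,
            "ejection_time": r.metrics.ejection_time,
            "peak_flow": r.metrics.peak_aortic_flow,
            "iterations": r.iterations,
        })
    return pd.DataFrame(rows)
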