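"""Scalar hemodynamic metrics and comparison against reference pressure data.

Beat-level metrics (systolic/diastolic/mean aortic pressure, stroke volume,
ejection time, ...) are derived from one converged periodic beat.  Model
pressure-vs-age trajectories are compared with reference series through a
normalized root-mean-squared error pooled over the systolic and diastolic
residuals, and central systolic pressure can be mapped to a brachial
estimate by adding a per-decade amplification offset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulation import BeatWaveforms
from .windkessel import ArterialParams

__all__ = [
    "BeatMetrics",
    "ReferenceSeries",
    "beat_metrics",
    "normalized_rmse",
    "apply_brachial_amplification",
]


@dataclass(frozen=True)
class BeatMetrics:
    """Per-beat scalar hemodynamics.

    Volumes are relative to the unstressed volume V0; cardiac output is in
    L/min, everything else in mmHg / mL / s as named.
    """

    Psys: float
    Pdia: float
    MAP: float
    pulse_pressure: float
    stroke_volume: float
    cardiac_output: float
    EDV: float
    ESV: float
    ejection_time: float
    peak_aortic_flow: float
    time_to_psys: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReferenceSeries:
    """A pressure-vs-age trajectory: matched systolic/diastolic values per age."""

    ages: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        if not (self.ages.size == self.systolic.size == self.diastolic.size):
            raise ValueError("ages, systolic and diastolic must have equal length")
        if self.ages.size and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "ReferenceSeries":
        df = pd.read_csv(path)
        return cls(df["age_years"].to_numpy(), df["sys_mmHg"].to_numpy(),
                   df["dia_mmHg"].to_numpy(), label=label or str(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "age_years": self.ages,
            "sys_mmHg": self.systolic,
            "dia_mmHg": self.diastolic,
        }).to_csv(path, index=False)


def beat_metrics(w: BeatWaveforms, arterial: ArterialParams | None = None) -> BeatMetrics:
    """Scalar metrics of one converged periodic beat.

    Psys/Pdia are the extrema of aortic pressure, MAP its time average,
    stroke volume the integral of aortic flow, EDV/ESV the LV volume
    extrema, and ejection time the duration the aortic valve is open.
    ``arterial`` is accepted for interface symmetry (no metric currently
    needs it).  Raises on a beat that is visibly non-periodic (LV volume
    mismatch between the first and last sample above 1 mL).
    """
    if abs(float(w.lv_volume[0]) - float(w.lv_volume[-1])) > 1.0:
        raise ValueError("waveform is not periodic: LV volume drifts over the beat")
    pao = np.asarray(w.aortic_pressure, dtype=float)
    qav = np.asarray(w.aortic_flow, dtype=float)
    vlv = np.asarray(w.lv_volume, dtype=float)
    psys = float(pao.max())
    pdia = float(pao.min())
    # time average over the exact period: drop the duplicated endpoint sample
    map_ = float(np.mean(pao[:-1]))
    sv = float(np.trapezoid(qav, dx=w.dt))
    edv = float(vlv.max())
    esv = float(vlv.min())
    ejection = float(np.count_nonzero(w.av_open[:-1]) * w.dt)
    return BeatMetrics(
        Psys=psys,
        Pdia=pdia,
        MAP=map_,
        pulse_pressure=psys - pdia,
        stroke_volume=sv,
        cardiac_output=sv / w.period * 60.0 / 1000.0,
        EDV=edv,
        ESV=esv,
        ejection_time=ejection,
        peak_aortic_flow=float(qav.max()),
        time_to_psys=float(w.time[int(np.argmax(pao))]),
    )


def normalized_rmse(model: ReferenceSeries, ref: ReferenceSeries) -> float:
    """Normalized RMSE (%) between model and reference pressure trajectories.

    Relative residuals (model − ref)/ref are pooled across the systolic and
    diastolic series at every age, then
    ``100 · sqrt(mean(residual²))`` is returned.
    """
    if model.ages.size != ref.ages.size or not np.allclose(model.ages, ref.ages):
        raise ValueError("model and reference age grids must match")
    ref_all = np.concatenate([ref.systolic, ref.diastolic])
    if np.any(ref_all == 0):
        raise ValueError("reference values must be non-zero")
    mod_all = np.concatenate([model.systolic, model.diastolic])
    rel = (mod_all - ref_all) / ref_all
    return float(100.0 * np.sqrt(np.mean(rel**2)))


def apply_brachial_amplification(
    aortic: ReferenceSeries, amplification_by_decade: Mapping[int, float]
) -> ReferenceSeries:
    """Add a per-decade systolic amplification (mmHg) to a central trajectory.

    Models the central-to-brachial systolic pressure amplification as a pure
    additive offset per decade; diastolic pressure passes through unchanged.
    Every age in the series must be covered by the table.
    """
    try:
        offsets = np.array([amplification_by_decade[int(a)] for a in aortic.ages],
                           dtype=float)
    except KeyError as exc:
        raise KeyError(f"amplification table missing decade {exc.args[0]}") from exc
    return ReferenceSeries(
        ages=aortic.ages.copy(),
        systolic=aortic.systolic + offsets,
        diastolic=aortic.diastolic.copy(),
        label=(aortic.label + " + brachial amplification").strip(),
    )
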