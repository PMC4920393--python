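"""Synthetic reference curves and analytic test beats.

Population blood-pressure references (e.g. longitudinal cohort trajectories)
show a monotonically rising systolic pressure, while diastolic pressure
rises to about age 55 and then declines.  :func:`synth_reference_curves`
emulates that pattern — linear systolic trend, quadratic diastolic arc
through three anchor points, optional Gaussian noise — so every comparison
code path can be exercised without external data.  :func:`fixture_beat`
builds beats with closed-form extrema, means and integrals for metric
verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ReferenceSeries
from .simulation import BeatWaveforms
from .windkessel import DECADE_AGES

__all__ = ["SyntheticReferenceSpec", "synth_reference_curves", "fixture_beat"]


@dataclass(frozen=True)
class SyntheticReferenceSpec:
    """Recipe for a synthetic pressure-vs-age reference trajectory.

    Defaults sketch a normotensive cohort (systolic 110→150 mmHg, diastolic
    72→78 peaking at age 55→74); they are illustrative, not literature
    values.
    """

    sys_start: float = 110.0
    sys_end: float = 150.0
    dia_start: float = 72.0
    dia_peak: float = 78.0
    dia_end: float = 74.0
    dia_peak_age: float = 55.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sys_end <= self.sys_start:
            raise ValueError("sys_end must exceed sys_start")
        if self.dia_peak < self.dia_start or self.dia_peak < self.dia_end:
            raise ValueError("dia_peak must be >= dia_start and dia_end")
        if not (20.0 <= self.dia_peak_age <= 80.0):
            raise ValueError("dia_peak_age must lie in [20, 80]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_reference_curves(
    spec: SyntheticReferenceSpec | None = None,
    ages: tuple[int, ...] = DECADE_AGES,
) -> ReferenceSeries:
    """Generate a reference trajectory at the given ages from ``spec``.

    Systolic pressure is linear in age; diastolic is the quadratic through
    (20, dia_start), (dia_peak_age, dia_peak) and (80, dia_end).  i.i.d.
    Gaussian noise of sd ``noise_sd`` is added to both series; the output is
    fully determined by ``spec.seed``.
    """
    spec = spec or SyntheticReferenceSpec()
    a = np.asarray(ages, dtype=float)
    sys_ = spec.sys_start + (a - 20.0) / 60.0 * (spec.sys_end - spec.sys_start)
    x = np.array([20.0, spec.dia_peak_age, 80.0])
    y = np.array([spec.dia_start, spec.dia_peak, spec.dia_end])
    if np.unique(x).size < 3:
        raise ValueError("degenerate diastolic quadratic: anchor ages coincide")
    coeffs = np.polyfit(x, y, 2)
    dia = np.polyval(coeffs, a)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sys_ = sys_ + rng.normal(0.0, spec.noise_sd, size=a.size)
        dia = dia + rng.normal(0.0, spec.noise_sd, size=a.size)
    return ReferenceSeries(ages=a, systolic=sys_, diastolic=dia,
                           label="synthetic reference")


def fixture_beat(
    kind: str = "sinusoid",
    *,
    period: float = 0.89,
    n_samples: int = 8901,
    pressure_mean: float = 90.0,
    pressure_amplitude: float = 20.0,
    flow_amplitude: float = 400.0,
    flow_duration: float = 0.25,
) -> BeatWaveforms:
    """Analytic beat with known metrics, for exercising the metrics layer.

    ``kind="sinusoid"``: aortic pressure ``mean + amplitude·sin``, zero flow —
    extrema and time average are exact.  ``kind="square-pulse-flow"``: flat
    pressure with a rectangular aortic flow pulse (``amplitude`` mL/s for
    ``flow_duration`` s), so stroke volume is amplitude×duration and
    ejection time equals the pulse duration; set ``flow_amplitude=0`` for a
    zero-flow beat.
    """
    t = np.linspace(0.0, period, n_samples)
    dt = t[1] - t[0]
    zeros = np.zeros_like(t)
    if kind == "sinusoid":
        pao = pressure_mean + pressure_amplitude * np.sin(2 * np.pi * t / period)
        qav = zeros.copy()
        av = np.zeros(t.size, dtype=bool)
    elif kind == "square-pulse-flow":
        if not (0.0 <= flow_duration <= period):
            raise ValueError("flow_duration must lie within the period")
        pao = np.full_like(t, pressure_mean)
        in_pulse = t < flow_duration
        qav = np.where(in_pulse, flow_amplitude, 0.0)
        av = in_pulse & (flow_amplitude > 0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    mv = ~av
    return BeatWaveforms(
        time=t, lv_pressure=pao.copy(), lv_volume=np.full_like(t, 120.0),
        aortic_pressure=pao, aortic_flow=qav, mitral_flow=zeros.copy(),
        av_open=av, mv_open=mv, period=period, dt=float(dt),
        converged=True, n_beats=1, end_diastolic_index=0,
    )
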