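"""Time-varying elastance model of the left ventricle.

The ventricle is described by a single pressure-volume law
``P_LV(t) = E(t) * (V - V0)`` where the elastance ``E(t)`` rises once per
cardiac cycle from its end-diastolic value ``Eed`` (diastolic stiffness) to
its end-systolic value ``Ees`` (contractility) and back.  The normalized
activation waveform is the classic "double-Hill" product of a rising and a
decaying Hill function; its shape is assumed identical at all ages and is
rescaled so that its maximum over one cycle is exactly 1, making ``Eed`` and
``Ees`` the exact extremes of ``E(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ElastanceShape",
    "ElastanceParams",
    "normalized_elastance",
    "elastance_at",
    "lv_pressure",
]

# Double-Hill shape constants, calibrated so the age-20 operating point
# (Ees=1, Eed=0.025, Ped=5, HR=67, young arterial load) reproduces the
# published 100/76 mmHg aortic pressures with physiological ejection timing
# (activation peak ~0.41 of the cycle, ejection ~0.27 s).  Overridable
# through the study config; never hard-coded downstream.
DEFAULT_RISE_EXPONENT = 1.2
DEFAULT_RISE_TIME_FRAC = 0.26
DEFAULT_DECAY_EXPONENT = 40.0
DEFAULT_DECAY_TIME_FRAC = 0.46


@dataclass(frozen=True)
class ElastanceShape:
    """Shape constants of the normalized double-Hill activation waveform.

    Timescales are expressed as fractions of the cardiac cycle, so the
    waveform is defined on normalized time ``t/T in [0, 1)``.
    """

    rise_exponent: float = DEFAULT_RISE_EXPONENT
    rise_timescale: float = DEFAULT_RISE_TIME_FRAC
    decay_exponent: float = DEFAULT_DECAY_EXPONENT
    decay_timescale: float = DEFAULT_DECAY_TIME_FRAC

    def __post_init__(self) -> None:
        for name in ("rise_exponent", "rise_timescale", "decay_exponent", "decay_timescale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ElastanceShape.{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class ElastanceParams:
    """Cardiac parameters: elastance extremes, unstressed volume, period.

    ``Ees`` and ``Eed`` are the slopes of the end-systolic and end-diastolic
    pressure-volume relationships (mmHg/mL); ``V0`` is the unstressed volume
    (mL) at which the ventricle generates zero pressure; ``period_T`` is the
    R-R interval (s).
    """

    Ees: float = 1.0
    Eed: float = 0.025
    V0: float = 0.0
    period_T: float = 0.89
    shape: ElastanceShape = field(default_factory=ElastanceShape)

    def __post_init__(self) -> None:
        if not (self.Ees > self.Eed > 0):
            raise ValueError(f"require Ees > Eed > 0, got Ees={self.Ees}, Eed={self.Eed}")
        if self.period_T <= 0:
            raise ValueError(f"period_T must be > 0, got {self.period_T}")


def _raw_double_hill(t_frac: np.ndarray | float, shape: ElastanceShape) -> np.ndarray | float:
    """Unnormalized double-Hill product on normalized time in [0, 1)."""
    x = np.asarray(t_frac, dtype=float)
    rise = (x / shape.rise_timescale) ** shape.rise_exponent
    rising = rise / (1.0 + rise)
    decaying = 1.0 / (1.0 + (x / shape.decay_timescale) ** shape.decay_exponent)
    return rising * decaying


@lru_cache(maxsize=32)
def _shape_maximum(shape: ElastanceShape) -> tuple[float, float]:
    """(argmax t_frac, max value) of the raw waveform, grid search + refine."""
    grid = np.linspace(0.0, 1.0, 4097, endpoint=False)
    vals = _raw_double_hill(grid, shape)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda x: -_raw_double_hill(x, shape), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def normalized_elastance(t_frac, shape: ElastanceShape | None = None):
    """Normalized activation waveform at cycle fraction ``t_frac`` in [0, 1).

    Returns the max-normalized double-Hill value in [0, 1].  Scalar in,
    scalar out; array in, array out.

    Raises
    ------
    ValueError
        If any ``t_frac`` lies outside [0, 1).
    """
    if shape is None:
        shape = ElastanceShape()
    x = np.asarray(t_frac, dtype=float)
    if np.any(x < 0.0) or np.any(x >= 1.0):
        raise ValueError("t_frac must lie in [0, 1)")
    _, peak = _shape_maximum(shape)
    out = _raw_double_hill(x, shape) / peak
    if np.isscalar(t_frac) or np.ndim(t_frac) == 0:
        return float(out)
    return out


def activation_peak_time(shape: ElastanceShape | None = None) -> float:
    """Cycle fraction at which the activation waveform peaks."""
    if shape is None:
        shape = ElastanceShape()
    t_peak, _ = _shape_maximum(shape)
    return t_peak


def elastance_at(t, p: ElastanceParams):
    """Elastance E(t) in mmHg/mL at time ``t`` (s), periodically extended.

    ``E(t) = Eed + (Ees - Eed) * e_n((t mod T)/T)`` so the minimum over a
    cycle is ``Eed`` and the maximum ``Ees``.
    """
    t_frac = np.mod(np.asarray(t, dtype=float), p.period_T) / p.period_T
    # mod can return exactly 1.0 for tiny negative arguments; fold back
    t_frac = np.where(t_frac >= 1.0, 0.0, t_frac)
    en = normalized_elastance(t_frac, p.shape)
    out = p.Eed + (p.Ees - p.Eed) * np.asarray(en)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def lv_pressure(V, t, p: ElastanceParams):
    """Left-ventricular pressure (mmHg) from the elastance law E(t)·(V − V0)."""
    return elastance_at(t, p) * (np.asarray(V, dtype=float) - p.V0)
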