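"""Four-element Windkessel model of the systemic arterial tree.

Electrical analogue: the aortic inlet sees the total arterial inertance L in
parallel with the characteristic impedance Zc; both branches rejoin at the
compliance node, where the total arterial compliance C stores volume and the
vascular resistance R drains it to a zero-pressure venous ground.  This
parallel-L topology has the physiologically required high-frequency limit
|Z(inf)| = Zc.

Also provides the prescribed arterial aging schedule: per decade from 20 to
80 years, compliance falls linearly 2.8 -> 0.7 mL/mmHg (a factor 4, matching
a doubling of pulse wave velocity), resistance rises 5% per decade
(0.8 -> 1.04 mmHg·s/mL), inertance stays constant, and Zc follows the
published per-decade values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArterialParams",
    "WindkesselState",
    "wk4_derivatives",
    "input_impedance",
    "decade_arterial_params",
    "DECADE_AGES",
]

DECADE_AGES = (20, 30, 40, 50, 60, 70, 80)

# Young-adult (age 20) reference values.
C_20, C_80 = 2.8, 0.7          # mL/mmHg
R_20, R_80 = 0.8, 1.04         # mmHg·s/mL
L_ALL_AGES = 0.005             # mmHg·s²/mL

# Characteristic impedance per decade (mmHg·s/mL), as published.
ZC_BY_AGE = {20: 0.020, 30: 0.021, 40: 0.023, 50: 0.025,
             60: 0.028, 70: 0.033, 80: 0.040}


@dataclass(frozen=True)
class ArterialParams:
    """Windkessel elements: C (mL/mmHg), R (mmHg·s/mL), Zc (mmHg·s/mL), L (mmHg·s²/mL)."""

    C: float = C_20
    R: float = R_20
    Zc: float = ZC_BY_AGE[20]
    L: float = L_ALL_AGES

    def __post_init__(self) -> None:
        for name in ("C", "R", "Zc", "L"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ArterialParams.{name} must be finite and > 0, got {v}")


@dataclass
class WindkesselState:
    """Dynamic state: pressure at the compliance node and flow through L."""

    compliance_pressure: float = 0.0
    inertance_flow: float = 0.0


def wk4_derivatives(
    state: WindkesselState, q_in: float, p: ArterialParams
) -> tuple[float, float, float]:
    """Time derivatives of the Windkessel state for inlet flow ``q_in`` (mL/s).

    Returns ``(d compliance_pressure/dt, d inertance_flow/dt, p_in)`` where
    ``p_in`` is the instantaneous inlet (aortic) pressure in mmHg.  The inlet
    flow splits between the L and Zc branches (q_Zc = q_in − q_L); the Zc
    branch drop gives the inlet pressure, and the same drop drives the
    inductor: ``L dq_L/dt = p_in − p_C = Zc (q_in − q_L)``.
    """
    pc = state.compliance_pressure
    ql = state.inertance_flow
    if not (np.isfinite(pc) and np.isfinite(ql) and np.isfinite(q_in)):
        raise FloatingPointError("non-finite Windkessel state or inflow")
    p_in = pc + p.Zc * (q_in - ql)
    dpc = (q_in - pc / p.R) / p.C
    dql = p.Zc * (q_in - ql) / p.L
    return dpc, dql, p_in


def input_impedance(f, p: ArterialParams):
    """Complex aortic input impedance Z(f) of the four-element Windkessel.

    ``Z(ω) = jωL·Zc/(jωL + Zc) + R/(1 + jωRC)`` with ω = 2πf.  At f = 0 this
    reduces to R (the inductor shorts the Zc branch); as f → ∞ it tends to Zc.
    Accepts scalar or array frequency in Hz (f ≥ 0).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("frequency must be >= 0")
    w = 2.0 * np.pi * f_arr
    jwl = 1j * w * p.L
    z_prox = np.where(w == 0, 0.0 + 0.0j, jwl * p.Zc / (jwl + p.Zc))
    z_wk = p.R / (1.0 + 1j * w * p.R * p.C)
    z = z_prox + z_wk
    if np.isscalar(f) or np.ndim(f) == 0:
        return complex(z)
    return z


def decade_arterial_params(age: int) -> ArterialParams:
    """Prescribed arterial parameters at a decade age in {20, 30, ..., 80}.

    C and R interpolate linearly between their 20- and 80-year endpoints;
    L is age-independent; Zc takes the published per-decade value.
    """
    if age not in ZC_BY_AGE:
        raise ValueError(f"age must be one of {sorted(ZC_BY_AGE)}, got {age!r}")
    frac = (age - 20) / 60.0
    return ArterialParams(
        C=C_20 + frac * (C_80 - C_20),
        R=R_20 + frac * (R_80 - R_20),
        Zc=ZC_BY_AGE[age],
        L=L_ALL_AGES,
    )
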