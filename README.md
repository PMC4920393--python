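# cardioage

Lumped-parameter simulation of how the arterial system **and** the heart
shape arterial blood pressure during normal human aging (ages 20–80).

Systolic blood pressure rises steadily with age, while diastolic pressure
rises to middle age and then falls.  The conventional explanation is purely
arterial — stiffer large arteries and higher vascular resistance.  This
package quantifies a complementary mechanism: the systolic pressure rise
triggered by arterial aging induces concentric left-ventricular hypertrophy,
and the stiffer, stronger ventricle in turn pushes systolic pressure further
up while mitigating the diastolic fall.

## The model

* **Left ventricle** — time-varying elastance: `P_LV(t) = E(t)·(V − V0)`,
  with `E(t)` a max-normalized "double-Hill" activation waveform scaled
  between the end-diastolic elastance `Eed` (0.025 mmHg/mL) and the
  end-systolic elastance `Ees` (1 mmHg/mL) at heart rate 67 /min
  (period 0.89 s).
* **Valves** — ideal diodes with small resistance (0.003 mmHg·s/mL) and
  inertance (3·10⁻⁵ mmHg·s²/mL); fully open or fully closed, forward flow
  only.  The ventricle fills from a constant-pressure venous source
  calibrated so the end-diastolic LV pressure `Ped` is 5 mmHg at age 20.
* **Arterial tree** — four-element Windkessel: characteristic impedance
  `Zc` with the total inertance `L` in parallel, feeding total arterial
  compliance `C` drained by vascular resistance `R`
  (age 20: C = 2.8 mL/mmHg, R = 0.8 mmHg·s/mL, Zc = 0.02 mmHg·s/mL,
  L = 0.005 mmHg·s²/mL).
* **Arterial aging (prescribed)** — per decade, `C` falls linearly to
  0.7 mL/mmHg at 80 (stiffness ×4), `R` rises 5 % per decade to 1.04,
  `Zc` follows its published per-decade table, `L` is constant.
* **Cardiac aging (computed)** — two physiological rules iterated to a
  fixed point per decade: (1) compensated hypertrophy — by Laplace's law
  (σ = P·r/2h, constant lumen radius) wall stress is normalized when wall
  thickness, and with it both elastances, scale with systolic pressure,
  `Ees/Ees₂₀ = Eed/Eed₂₀ = Psys/Psys₂₀`; (2) preserved end-diastolic
  volume — the filling pressure is recalibrated each iterate so EDV stays
  at its age-20 value.  Iteration stops when successive changes are below
  1 mmHg and 1 mL.

Beats are integrated with fixed-step RK4 (0.2 ms) and repeated until the
beat-to-beat change in stroke volume and systolic/diastolic pressure is
below 0.1 mL / 0.1 mmHg (periodic steady state).

## Worked example

```bash
cardioage aging-study --mode combined --no-plot
```

```text
 age     C     R    Zc   Ees   Eed   Ped    Psys   Pdia     MAP     PP      SV  ejection_time
  20 2.800 0.800 0.020 1.000 0.025 5.000 100.372 77.435  91.003 22.937 101.140          0.294
  30 2.450 0.840 0.021 1.043 0.026 5.216 105.424 79.576  94.820 25.848 100.370          0.295
  40 2.100 0.880 0.023 1.100 0.027 5.499 111.332 81.591  99.113 29.741 100.189          0.298
  50 1.750 0.920 0.025 1.177 0.029 5.883 118.655 83.227 104.023 35.428 100.577          0.302
  60 1.400 0.960 0.028 1.257 0.031 6.286 126.773 83.153 108.595 43.620 100.627          0.308
  70 1.050 1.000 0.033 1.359 0.034 6.794 137.097 80.297 113.125 56.800 100.671          0.318
  80 0.700 1.040 0.040 1.526 0.038 7.629 153.715 71.692 118.221 82.024 101.166          0.333
```

Reading the table: with both arterial and cardiac aging active, systolic
aortic pressure climbs from ~100 to ~154 mmHg while diastolic pressure
rises to a mid-life plateau (~83 mmHg at 50–60) before falling back to
~72 mmHg at 80 — the population pattern.  The computed cardiac columns show
the adapted heart: both elastances grow ~53 % (the hypertrophy needed to
normalize wall stress against the higher systolic load) and the filling
pressure `Ped` rises from 5.0 to 7.6 mmHg to keep the end-diastolic volume
constant (EDV column ≈ 200 mL at every age).  Stroke volume is preserved
(~100 mL) and ejection time lengthens ~13 %.  Running
`--mode arterial_only` instead freezes the heart at its age-20 parameters:
pressures then reach only ~123/57 mmHg at 80 and stroke volume drops ~22 %
— arterial aging alone cannot reproduce the observed pressure course.

Single beats, comparisons against a (synthetic or user-supplied) reference
trajectory, and CSV/plot export are available via
`cardioage simulate`, `cardioage compare`, and `cardioage synth-ref`;
every command accepts a YAML config layered over the packaged defaults.

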