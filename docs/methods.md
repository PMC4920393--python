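# Methods

## Model overview

The circulation is reduced to five ordinary differential equations: left
ventricular (LV) volume, the flows through the mitral and aortic valves
(each with its own inertance, making valve flow a state variable), and the
two states of a four-element Windkessel (pressure at the compliance node,
flow through the total arterial inertance).  The LV is a time-varying
elastance chamber, `P_LV = E(t)·(V − V0)`; the arterial load is the
parallel-inertance variant of the four-element Windkessel, whose input
impedance is

```
Z(ω) = jωL·Zc / (jωL + Zc) + R / (1 + jωRC)
```

so `|Z(0)| = R` and `|Z(∞)| = Zc`, matching the physical meaning of
characteristic impedance.  The Windkessel drains through R to a
zero-pressure venous ground; the LV fills from a separate constant-pressure
venous source through the mitral valve.  Atrial contraction, the right
heart, the pulmonary circulation, reflex control, and wave
transmission/reflection are all outside the model's scope.

### Assumptions worth stating explicitly

* Valves are ideal diodes: fully open or fully closed, forward flow only.
  A closed valve opens when upstream pressure exceeds downstream pressure;
  an open valve closes when its flow decays through zero, and the flow
  state is clamped to zero at that instant.  Because closure is
  instantaneous the dicrotic notch is not rendered faithfully; systolic and
  diastolic pressures (waveform extrema) are insensitive to this.
* The normalized activation waveform (see below) is identical at all ages;
  only its amplitude endpoints `Eed`, `Ees` change.
* The venous filling source is constant over the beat.  The filling
  pressure is never prescribed directly: it is calibrated by root-finding
  so that a *target* (end-diastolic pressure at age 20, end-diastolic
  volume during adaptation) is met on the *converged* beat.
* End diastole is the cycle boundary, where the activation waveform is at
  its minimum (`E = Eed` exactly).  Mitral closure follows a few
  milliseconds later, once rising elastance reverses the filling gradient.
  With this definition the baseline identity `Ped = Eed·EDV`
  (5 mmHg = 0.025 mmHg/mL × 200 mL) holds exactly, which anchors the
  adaptation rules.
* `V0 = 0` by default.  Only `V − V0` enters any equation, so all reported
  volumes are relative to the unstressed volume.

## Activation waveform and its calibration

`E(t)` interpolates between `Eed` and `Ees` through a "double-Hill"
product — a rising Hill term `(t/a)^m / (1 + (t/a)^m)` times a decaying
term `1 / (1 + (t/b)^n)` on normalized time `t/T` — rescaled so its
maximum over the cycle is exactly 1 (hence `Ees` and `Eed` are the exact
elastance extremes).  The value at the cycle boundary is exactly zero.

The four shape constants are free parameters of this model family; they
live in the study config, never hard-coded in equations.  The packaged
defaults (rise exponent 1.2, rise timescale 0.26, decay exponent 40, decay
timescale 0.46, as fractions of the 0.89 s cycle) were calibrated **once**
against the age-20 operating point — systolic/diastolic aortic pressure
100/76 mmHg with `Ees = 1`, `Eed = 0.025`, `Ped = 5`, heart rate 67 /min
and the young arterial parameters — under two structural constraints: the
activation peak falls in [0.25, 0.45] of the cycle and ejection time is
physiological (~0.29 s at rest).  The exponents published for this waveform
family in other studies (≈1.9 rise, ≈22 decay, with timescales near 0.26
and 0.44 of this cycle) produce a nearby but slightly stiffer beat
(≈102.5/76 mmHg at baseline); the recalibration stays within the same
family and is shared, unchanged, by every age and both study modes.

## The aging protocol

Arterial parameters are *prescribed* per decade: `C` linear from 2.8 to
0.7 mL/mmHg, `R` linear from 0.8 to 1.04 mmHg·s/mL (+5 %/decade), `L`
constant, `Zc` from a per-decade table (0.020, 0.021, 0.023, 0.025, 0.028,
0.033, 0.040).  The table is authoritative for `Zc`: it follows
approximately `Zc ∝ 1/√C`, and no attempt is made to force a strict `1/C`
proportionality.

Cardiac parameters are *computed*.  In combined mode, each decade runs a
fixed-point loop:

1. simulate to periodic steady state with filling calibrated so
   `EDV = EDV₂₀` (preserved end-diastolic volume);
2. read the systolic aortic pressure `Psys` of the converged beat;
3. set `Ees = Ees₂₀·Psys/Psys₂₀` and `Eed = Eed₂₀·Psys/Psys₂₀`
   (compensated concentric hypertrophy: by Laplace's law with constant
   lumen radius, wall thickness — and with it both elastances — must scale
   with systolic pressure to hold wall stress at its baseline value);
4. repeat until successive iterates change `Psys` by < 1 mmHg and EDV by
   < 1 mL.

Two readings of rule 1 are possible; this package scales the elastances
**relative to the age-20 anchor** rather than chaining decade-to-decade
increments, because only the anchored form makes the converged
`Ees(age)/Ees(20)` equal `Psys(age)/Psys(20)` — an invariant the test
suite asserts to 1 %.  `Psys` in the rule is systolic *aortic* pressure
(peak LV pressure differs only by the small transvalvular drop and gives
the same fixed point).  Each decade warm-starts from the previous decade's
converged parameters; this changes iteration counts (3–5 per decade), not
the fixed point, which is also insensitive to cold starts.  The reported
`Ped` is an output: the end-diastolic pressure that the EDV-preserving
calibration produces.

In arterial-only mode the cardiac parameters *and* the venous source stay
frozen at their age-20 calibration while the arterial schedule advances.

## Numerics

* Fixed-step classical RK4 at `dt = 0.2 ms` (the step is snapped to divide
  the period exactly, so every beat shares one phase grid).  Valve flags
  are frozen within a step and updated at step boundaries; waveform samples
  are recorded after the update, so clamped flows never appear negative in
  outputs.  A tenfold step refinement changes the converged aortic pressure
  trace by well under 0.1 mmHg.
* Periodic steady state: consecutive beats until stroke volume changes
  < 0.1 mL and systolic/diastolic pressure < 0.1 mmHg beat-to-beat
  (typically 8–15 beats from cold start, 2–4 warm; hard cap 100 with a
  diagnostic error).  Results are initialization-independent to the same
  tolerance.
* Filling calibration: Brent root-finding on the converged-beat residual
  with automatic bracket expansion; venous pressure resolved to 10⁻³ mmHg,
  giving `Ped` within 0.05 mmHg or EDV within 0.1 mL of target.
* The beat kernel is JIT-compiled (numba); a full two-mode, seven-decade
  study with all adaptation loops runs in a few seconds on one core.
* Degenerate inputs fail loudly: non-finite states, a mitral valve that
  never closes, unbracketable filling targets and non-convergent loops all
  raise errors carrying diagnostics rather than returning partial results.

## Synthetic reference data

Real reference trajectories (population systolic/diastolic pressure by
age) are external to the package, so the generator produces
population-*like* curves for testing the comparison path: systolic linear
in age, diastolic quadratic through three anchors (rise to a mid-fifties
peak, then decline), plus optional i.i.d. Gaussian noise, fully determined
by a seed.  Defaults (systolic 110→150, diastolic 72→78→74 mmHg) are
illustrative normotensive values.  The generator makes no claim about
cohort structure, treatment effects or measurement error; tests passing
against it validate the comparison *machinery* (normalized RMSE, brachial
amplification, plotting), not agreement with any real population.

The normalized RMSE pools systolic and diastolic relative residuals into
one statistic, `100·sqrt(mean(((model−ref)/ref)²))`, over all ages — one
number per scenario.  Central-to-brachial systolic amplification is
additive in mmHg per decade and defaults to zero; supply a table in the
config when comparing against brachial measurements.

## Known limitations

* Single ventricle, no atrium: diastolic inflow lacks the late atrial
  kick, so filling-phase waveforms are simpler than reality even though
  end-diastolic state variables are calibrated.
* The linear end-diastolic pressure-volume relation underestimates the
  curvature of real diastolic stiffness at high volumes; age-related
  fibrosis, which would raise `Eed` beyond the hypertrophy-proportional
  rule, is not modelled.
* The Windkessel has no wave transmission, so waveform *shape* features
  that depend on reflections (augmentation, late-systolic peaking in the
  periphery) are outside scope; comparisons use waveform extrema.
* The aging schedule is a population average; no gender, fitness or
  disease stratification.
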