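# chemodrift

Run-and-tumble bacterial chemotaxis with behavioral feedback: a stochastic
single-cell simulator and the matching analytic drift-velocity theory.

*E. coli* climbs chemical gradients by biasing a random walk: straight runs
(flagellar motors CCW) alternate with reorienting tumbles (CW), and the
phosphorylated response regulator CheY-P couples the adapting
receptor-kinase sensor to the ultrasensitive motor.  For a cell swimming
freely, the input statistics depend on the cell's own drift — climbing an
exponential gradient `L(x) = L0·e^{gx}` feeds an effective temporal ramp
back into the sensor, pushing CheY-P from its adapted level `Y0` down to an
*operational* level `Y_m`.  This package is for modellers who want to ask
quantitatively how the phenotype — adapted CheY-P `Y0` (equivalently
adapted tumble bias `TB0`) and receptor adaptation time `tau` — sets
chemotactic drift velocity `V_D` across gradients, including the regimes
where the feedback turns bistable (the "chemotactic trap") and how slow
FliM-ring adaptation of the motor rescues it.

The core objects:

- **pathway** — two-state MWC receptor cluster,
  `F(m, L) = eps0 + eps1·m + N·ln[(1+L/Ki)/(1+L/Ka)]`, output
  `Y = alpha/(1+e^F)`, integral-feedback methylation
  `dF/dt = (F0−F)/tau + s·f` with gradient drive `f ≈ vNg`.
- **motor** — bistable switch, `CW(Y) = 1/(1+e^{dG})`,
  `dG = eps2/2 − eps3·Y/(Y+K)` (effective Hill coefficient 20), rates
  `lam_R = omega·e^{−dG/2}`, `lam_T = omega·e^{+dG/2}`; optional slow FliM
  remodelling `n ∈ [n1, n2]` moving `eps3(n)` — the motor's own adaptation.
- **simulate** — vectorized 3-D run-and-tumble populations (inhomogeneous
  Poisson switching, rotational diffusion `Dr`), drift velocity and
  operational CheY-P over the standard 60–300 s window.
- **analytic** — expected run durations, the linearized drift curve
  `V_D = (1/d)·v·f·[tau·tauR/(tau+tauR)]·tauR²·G/(tauR+tauT)`, the feedback
  line `F_m = F0 + tau·N·g·V_D`, fixed points with stability, bifurcation
  scans, motor-adapted theory, optimal-`Y0` curves and maximin phenotype
  maps.
- **workbench** — YAML configs, canonical scenario fixtures, CSV outputs,
  and a `chemodrift` command-line tool (`simulate`, `analyze`, `figure`,
  `compare`).

See `docs/methods.md` for the full model description, assumptions and
numerical choices.

## Worked example

Where should a cell set its adapted CheY-P?  Theory says at the *foot* of
the motor response, not in its sensitive core — and in a steep gradient the
behavioral feedback drags the operating point below the adapted one:

```python
import numpy as np
from chemodrift import (Environment, MotorParams, Phenotype, PathwayParams,
                        drift_curve, fixed_points, run_population)

shallow, steep = Environment(g=1/5000), Environment(g=1/1000)
mp, pw = MotorParams(), PathwayParams()

# 1. linearized optimum in a shallow gradient (tau = 10 s)
y0 = np.arange(1.0, 4.0, 0.01)
vd = drift_curve(y0, 10.0, shallow, mp)
print(f"shallow optimum: Y0 = {y0[vd.argmax()]:.2f} uM, "
      f"V_D = {vd.max():.2f} um/s")

# 2. steady states of a trap-prone phenotype in the steep gradient
for fp in fixed_points(Phenotype(Y0=3.5, tau=30.0), steep, mp):
    print(f"fixed point: Y_m = {fp.Y_m:.2f} uM, V_D = {fp.V_D:.2f} um/s "
          f"({fp.stability})")

# 3. simulate 2000 cells of a well-placed phenotype in the steep gradient
res = run_population(2000, 300.0, Phenotype(Y0=2.6, tau=10.0), steep, mp,
                     pw.with_tau(10.0), seed=1)
print(f"simulated: V_D = {res.vd:.2f} ± {res.vd_se:.2f} um/s, "
      f"operational Y_m = {res.ym:.2f} uM (adapted Y0 = 2.6)")
```

Output:

```
shallow optimum: Y0 = 2.44 uM, V_D = 1.33 um/s
fixed point: Y_m = 2.10 uM, V_D = 5.32 um/s (stable)
fixed point: Y_m = 2.97 uM, V_D = 1.99 um/s (unstable)
fixed point: Y_m = 3.49 uM, V_D = 0.04 um/s (stable)
simulated: V_D = 3.55 ± 0.04 um/s, operational Y_m = 2.36 uM (adapted Y0 = 2.6)
```

Reading it: the shallow-gradient optimum sits at `Y0 ≈ 2.4 µM`, at the foot
of the CW response curve (half-max 3.06 µM).  The `Y0 = 3.5 µM, tau = 30 s`
phenotype in the steep gradient is bistable — a fast-drifting state at
`Y_m = 2.10 µM` coexists with a trapped, nearly non-chemotactic state at
`Y_m = 3.49 µM`.  The simulated phenotype drifts at 3.6 µm/s while its
population-average CheY-P runs 0.25 µM below the adapted level — the
behavioral feedback in action.

From the shell, the canonical scenarios are one command each:

```bash
chemodrift figure fig4 --out out/ --scale desk     # trap fixed points
chemodrift figure fig6 --out out/ --scale desk     # trade-off maps
chemodrift simulate config.yaml --out out --cells 2000 --seed 1
```

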