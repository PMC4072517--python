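# Methods

`chemodrift` models chemotaxis of a single-flagellum *E. coli*-like cell as
a sensor → response-regulator → actuator chain, simulates populations of
such cells swimming in static exponential attractant gradients, and carries
the matching analytic drift-velocity theory including the feedback of the
cell's own drift onto its sensory input.

## Pathway model

The receptor cluster is a two-state (MWC) cooperative unit with free-energy
difference between inactive and active conformations

    F(m, L) = eps0 + eps1*m + N*ln[(1 + L/Ki)/(1 + L/Ka)],

with offset `eps0 = 6`, per-methylation increment `eps1 = -1`, cluster gain
`N = 6`, and Tar/methyl-aspartate dissociation constants `Ki = 18.2 µM`
(inactive), `Ka = 3 mM` (active).  Concentrations are µM internally; the
constants are entered in mM.  Between `Ki` and `Ka` the cluster log-senses:
an exponential spatial gradient `L(x) = L0 e^{g x}` traversed at speed `v`
drives `F` at the nearly constant rate `f ≈ v N g`.  The exact drive is

    f(L) = v N g [L/(L + Ki) − L/(L + Ka)],

which at the default `L0 = 200 µM` is 0.854·vNg — the upper dissociation
constant is only 15× above `L0`, so the ideal plateau is approached but not
reached.  The analytic fixed-point machinery uses the ideal `f = vNg` (the
constant-force idealization under which a steady drift state is defined);
theory–simulation concordance checks evaluate the theory at the exact local
`f(L0)`, since the simulated cells swim through the saturating field.

The pathway output is the CheY-P concentration `Y = alpha/(1 + e^F)` with
cascade gain `alpha = 6 µM`; the adapted state of a phenotype with adapted
concentration `Y0` is `F0 = ln(alpha/Y0 − 1)`.

Methylation provides integral feedback.  The default (symmetric) kinetics
are the minimal law giving spring-like relaxation of the free energy,

    dm/dt = (F0 − F)/(tau * eps1)   ⇒   dF/dt = (F0 − F)/tau + s·f,

with `s = ±1, 0` for runs up/down the gradient and tumbles.  `m` is
continuous and deterministic (the model's stochasticity lives in the
motor), clamped to `[0, 48]` sites with a flag when the adaptation range is
exceeded.  An alternative asymmetric variant uses activity-dependent rates
`dm/dt = VR(1−a) − VB·a` with activity `a = Y/alpha`; only `VR` is a free
rate, and `VB = VR(1−a0)/a0` is pinned so the adapted activity is the
phenotype's `a0 = Y0/alpha`.  Its linearized relaxation rate is
`(VR+VB)·a0(1−a0)`, so quadrupling `VR` quarters the effective adaptation
time (tested).

## Motor model

The motor is a bistable two-state unit.  Its CW/CCW free-energy difference
as a function of CheY-P,

    dG(Y) = eps2/2 − eps3·Y/(Y + K),      eps2 = eps3 = 80, K = 3.06 µM,

fixes the stationary clockwise bias `CW(Y) = 1/(1 + e^dG)`.  This form is
pinned by four facts: `eps2` sets the basal switching rate at `Y = 0`,
`eps3` the cooperativity, the half-maximum sits exactly at `Y = K` (because
`eps2 = eps3`), and the effective Hill coefficient at half-max is
`4·K·(dCW/dY) = eps3·K/(4K) ... = 20` at the defaults — the value measured
for individual motors.  Switching rates use the symmetric Arrhenius split

    lam_R = omega·e^{−dG/2},   lam_T = omega·e^{+dG/2},   omega = 1.3 s⁻¹,

which makes `omega` the switching frequency at the midpoint, keeps
`lam_R·lam_T = omega²` exactly, and gives the two-state chain the
stationary occupancy `CW(Y)` (cross-checked against an event-driven
telegraph simulation).  A cell with one motor tumbles exactly when the
motor turns CW, so tumble bias equals CW bias.

### FliM-ring adaptation

With adaptation enabled, the FliM ring size `n ∈ [34, 44]` remodels slowly,

    dn/dt = k_on(1−CW)·(n2−n)/((n2−n)+Δn) − k_off·CW·(n−n1)/((n−n1)+Δn),

with `k_on = 0.025 s⁻¹`, `k_off = 0.0063 s⁻¹`, `Δn = 4.16` (the saturation
scale that shuts both effective rates off at the ring bounds), and the ring
size moves the motor cooperativity linearly, `eps3(n) = 80 + 1.96(n−36)`.
CCW rotation recruits FliM, so a drop in CheY-P grows the ring,
raises `eps3`, and partially restores CW — a slow negative feedback.  The
direction of the rate law was a genuinely open design choice; the
implemented arrangement is the one whose quasi-steady fixed-point analysis
reproduces the published rescue value (see "Design choices" below).  The
swapped arrangement stays available (`MotorParams(convention="B")`) for
sensitivity analysis.

In the simulation `n` evolves per cell with the mean-field instantaneous
bias `CW(Y; eps3(n))` (not the binary motor mode), consistent with the
quasi-equilibrium analysis; in the theory, the quasi-steady value
`eps3(Y_m)` solves `dn/dt = 0` jointly with `CW = CW(Y_m; eps3(n))` —
a root that depends only on the `k_on/k_off` ratio, not the absolute rates
(tested).

## Swimming simulation

Cells swim at `v = 20 µm/s` in 3-D; headings decorrelate by rotational
diffusion with `Dr = 0.062 rad²/s`.  Per time step (`dt = 0.01 s`):

1. methylation update at the local ligand level (tumbling cells hold
   position, so their ligand is fixed but the spring keeps integrating);
2. CheY-P and switching rates from the current state;
3. mode switch with probability `1 − e^{−lam·dt}` (per-step Bernoulli
   rather than event-driven switching, for vectorization across the
   population; a dt-halving check guards the discretization);
4. runners advance `v·dt` and receive two independent Gaussian angular
   increments of variance `2·Dr·dt` in the plane normal to the heading
   (giving the 3-D autocorrelation `e^{−2 Dr t}`, verified); tumbling cells
   stand still and draw a uniform heading at tumble exit — no directional
   persistence;
5. FliM remodelling, when enabled.

The domain is boundary-free.  Populations start adapted at the origin:
`m` from the adapted-methylation root at `L0`, uniform headings, motor mode
Bernoulli with the adapted tumble bias, ring at `n0 = 36`.  One numpy
Generator drives the whole population per run; every result is bitwise
reproducible from (config, seed).

Observables follow the standard protocol: drift velocity is the
population mean of per-cell displacement along the gradient between
`t = 60 s` and `t = 300 s` divided by the window; the operational CheY-P
`Y_m` is instantaneous CheY-P averaged over cells and over the same window
(sampled every 0.1 s).  Population sizes: the full protocol uses 10,000
cells; the package's desk-scale presets use 2,000 cells and report
standard errors, which puts ~0.04 µm/s of noise on a typical drift velocity
— the scale at which all shipped checks are calibrated.

## Drift-velocity theory

In the 1-D two-state representation, runs up/down the gradient terminate by
tumbling or by rotational-diffusion reorientation at combined rate
`lam_R + (d−1)Dr`, and

    V_D = (1/d) · v · (⟨t_up⟩ − ⟨t_down⟩) / (⟨t_up⟩ + ⟨t_down⟩ + 2⟨t_T⟩).

The `1/d` factor is the rescaling from the 1-D representation back to `d`
dimensions; with it the theory matches both the stochastic simulation and
the published fixed-point values.  Expected run durations are survival
integrals over the deterministic CheY-P excursion during a run
(`F(t) = F_inf + (F_i − F_inf)e^{−t/tau}`, `F_inf = F_i + s·f·tau`),
evaluated by trapezoidal quadrature on `[0, 12·tau]` plus an exact
exponential tail (relative error ~1e-4; the constant-rate limit is exact).
Expanding to first order in the free-energy deviation gives the closed
form

    V_D = (1/d) · v · f · [tau·tauR/(tau+tauR)] · tauR² · G / (tauR + tauT)

with `tauR = 1/((d−1)Dr + lam_R)`, `tauT = 1/lam_T`, and motor sensitivity
`G = −d(lam_R)/dF = lam_R/2 · eps3·K/(Y+K)² · Y(1 − Y/alpha)`, all at the
operating point.  The kernel `tau·tauR/(tau+tauR)` grows linearly for
`tau ≪ tauR` and saturates at `tauR` for `tau ≫ tauR`: longer adaptation
memory helps until rotational diffusion caps the usable run length.  The
drift optimum therefore sits at the *foot* of the CW response curve
(≈2.4 µM at the defaults), not in its sensitive core.  The linearized and
exact forms agree within 10% in the shallow fixture wherever drift is
non-negligible; at the near-zero-drift tails the relative measure degrades
(an absolute floor of 0.01 µm/s covers it), which is where linearization is
expected to fail.

### Behavioral feedback and fixed points

A drifting cell rides an effective temporal ramp `g·V_D`, so at quasi-steady
state its operational free energy obeys `F_m = F0 + tau·N·g·V_D` — the
feedback line, intercepting `V_D = 0` at `Y0` with slope ∝ `1/(tau N g)` in
the `(Y_m, V_D)` plane.  Steady states are intersections of this line with
the drift curve evaluated *at the operating point* `Y_m`.  Roots are
located by sign-change bracketing on a ≤0.005 µM grid with Brent
refinement; a root is stable iff the residual
`V_drift(Y_m) − V_feedback(Y_m)` has positive slope there (equivalent to
the relaxation `dF/dt = (F0−F)/tau + N g V_D(Y(F))` being contracting;
verified against forward integration).  Weak feedback gives one stable
state; strong feedback (steep gradient, long `tau`, high `Y0`) creates a
bistable pair — a fast-drifting state at low `Y_m` and a "trapped"
near-zero-drift state just below `Y0` — separated by an unstable root.
Scanning `Y0` at `tau = 30 s`, `g⁻¹ = 1000 µm` passes 1 → 3 → 1 roots.

With motor adaptation the drift curve is rebuilt with `eps3 → eps3(Y_m)`
(quasi-steady FliM) before intersecting.  The resensitised ring lifts the
low-`Y_m` branch and moves the trap phenotype's drifting state to
`Y_m ≈ 1.6 µM`.  In our analysis a weak-drift root near `Y0` survives as
well; "steady-state drift" of a phenotype is therefore defined throughout
as the stable root with the largest drift velocity (the performance of the
chemotactic state), and the residual weak root is reported alongside by
`fixed_points`.

### Optima and trade-off maps

`optimal_y0` maximizes the steady-state drift over `Y0` and flags optima
inside the multi-stable region (where part of a real population dwells in
the trap).  `phenotype_map` grids `(tau, TB0)`, converts the adapted tumble
bias to `Y0` by inverting the (adapted) motor response, computes
steady-state drift per gradient, normalizes each gradient's surface by its
maximum, and reports the maximin phenotype.  On a 50×50 grid over
`tau ∈ [1, 30] s`, `TB0 ∈ [0.01, 0.4]` (geometric spacing in `TB0`, which
resolves the low-bias region where the optimum lies) and gradients
`g⁻¹ ∈ {1000, 2000, 5000} µm`, the best generalist reaches ~70% of each
gradient's maximum near `tau ≈ 7 s`, `TB0 ≈ 0.04`: steep gradients reward
fast adaptation and higher bias, shallow ones the reverse, and no single
phenotype is optimal everywhere.

## Design choices and numerical notes

- **FliM rate-law direction.**  Only the rate constants and the ring-size
  range are published; the published formula itself was not available.  Of
  the consistent arrangements, binding ∝ (1−CW) with `eps3` increasing in
  `n` matches the biology (CCW recruits FliM) and reproduces the published
  rescue fixed point (1.60 vs 1.6 µM) and a flattened adapted response
  curve; the alternative with the CW factors swapped adapts the bias toward
  `k_off/(k_on+k_off) ≈ 0.2` but misses the rescue value by ~0.35 µM and
  steepens the adapted curve.  The first is the default; the second is kept
  behind `convention="B"`.
- **Integrators.**  In-simulation ODEs (methylation, FliM) use explicit
  Euler at the simulation `dt = 0.01 s`, justified by `tau ≥ 1 s ≫ dt`;
  standalone ODE checks integrate with finer steps or closed forms.
- **Root finding.**  Fixed-point tangencies at a bifurcation appear as a
  vanishing residual slope and are labelled `degenerate`; an even root
  count triggers one 4× grid refinement to split near-tangent pairs.
- **Degenerate inputs.**  `Y0` outside `(0, alpha)` is rejected naming
  `alpha`; negative ligand is rejected; a run-termination rate below
  1e-6 s⁻¹ (no tumbling and no rotational diffusion) makes the expected run
  duration non-convergent and is rejected.
- **Sampling.**  Population observables are sampled every 0.1 s to bound
  memory; per-cell position series are kept only on request.

## What the shipped scenarios do and do not show

All inputs are synthetic by construction: the model *is* the study object,
and the canonical scenarios (`workbench.FIXTURES`) replicate its published
operating points — shallow (`g⁻¹ = 5000 µm`) and steep (`g⁻¹ = 1000 µm`)
gradients at `L0 = 200 µM`, `tau ∈ {5, 10, 30} s`, `Y0 ∈ [1, 4] µM`, plus
`Dr`, `omega` and `VR` sweeps.  Passing checks demonstrate internal
consistency of simulator and theory and reproduction of the published
operating points; they do not validate the model against swimming-cell
data.  Real cells differ in ways the model deliberately omits: multiple
motors and flagellar bundling (so tumble bias ≠ CW bias), directional
persistence at tumble exit, receptor-cluster and CheY-P copy-number noise,
discrete FliM stochastics, variable swim speed, and consumption or
dynamics of the attractant field.

## Known limitations

- The trapped state in our simulations is slightly stickier than in the
  published ones: near-bifurcation phenotypes average an operational CheY-P
  ~0.2 µM above the published common value, and the simulated steep-gradient
  optimum sits at `Y0 ≈ 2.6` rather than ~2.7 µM.  Both are at the edge of
  the corresponding tolerance bands; the cause is plausibly an
  implementation detail of the original tumble/switching discretization
  that the available description does not pin down.
- The quasi-steady motor-adaptation analysis retains a weak-drift stable
  root for trap phenotypes where the published analysis reports a unique
  state (see the FliM design choice above).
- The linearized theory is trusted only where mutual-oracle agreement with
  the exact integrals and the simulation holds; in steep gradients at high
  `Y_m` all conclusions rest on the fixed-point structure, not on absolute
  drift magnitudes.
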