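"""Stochastic run-and-tumble simulation of swimming cells in 3-D.

Cells swim at constant speed in a static exponential attractant gradient
``L(x) = L0*e^{g x}`` along the first axis.  Each cell carries a receptor
methylation level (deterministic ODE), and a two-state motor driven as an
inhomogeneous Poisson process by the instantaneous CheY-P concentration:
per step the mode switches with probability ``1 - exp(-lam*dt)``.  During
runs the position advances and the heading undergoes rotational diffusion;
tumbles hold the position and the exit heading is drawn uniformly on the
sphere (no directional persistence).  The pathway keeps integrating during
tumbles at the (fixed) local ligand level.

Population observables follow the drift-velocity protocol: the drift
velocity is the population mean of the per-cell displacement difference
along the gradient over the measurement window, and the operational CheY-P
``Y_m`` is the population-and-time mean of instantaneous CheY-P over the
same window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import motor, pathway
from .params import Environment, MotorParams, PathwayParams, Phenotype

__all__ = [
    "CellStates",
    "PopulationResult",
    "init_population",
    "step_population",
    "run_population",
    "bimodality_summary",
]


@dataclass
class CellStates:
    """Arrays of per-cell dynamic state (positions in µm, unit headings)."""

    x: np.ndarray          # (n, 3)
    u: np.ndarray          # (n, 3) unit headings
    m: np.ndarray          # (n,) methylation level
    tumbling: np.ndarray   # (n,) bool
    n_flim: np.ndarray     # (n,) FliM ring size
    t: float = 0.0


@dataclass
class PopulationResult:
    """Population time series and drift summaries for one scenario."""

    times: np.ndarray
    mean_Y: np.ndarray
    mean_L: np.ndarray
    vd_per_cell: np.ndarray
    ym_per_cell: np.ndarray
    perp_per_cell: np.ndarray
    vd: float
    vd_se: float
    ym: float
    rms_perp: float
    window: tuple[float, float]
    seed: int
    config: dict = field(default_factory=dict)
    x1_series: np.ndarray | None = None

    def summary_row(self) -> dict:
        c = self.config
        return {
            "Y0_uM": c.get("Y0"),
            "tau_s": c.get("tau"),
            "g_per_um": c.get("g"),
            "V_D_um_per_s": self.vd,
            "V_D_se_um_per_s": self.vd_se,
            "Y_m_uM": self.ym,
            "rms_perp_um": self.rms_perp,
            "n_cells": len(self.vd_per_cell),
            "seed": self.seed,
        }


def _uniform_sphere(rng: np.random.Generator, k: int) -> np.ndarray:
    u = rng.normal(size=(k, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def init_population(n_cells: int, pheno: Phenotype, env: Environment,
                    mp: MotorParams, pp: PathwayParams,
                    seed: int) -> CellStates:
    """Adapted initial population at the origin.

    All cells start at x = 0 with methylation adapted to L(0) = L0, headings
    uniform on the sphere, motor mode Bernoulli with P(tumble) = TB0, and
    the FliM ring at its pre-stimulus size n0.  Deterministic given seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    m0, _ = pathway.adapted_methylation(env.L0, pheno.F0, pp)
    tb0 = float(motor.cw_bias(pheno.Y0, mp))
    return CellStates(
        x=np.zeros((n_cells, 3)),
        u=_uniform_sphere(rng, n_cells),
        m=np.full(n_cells, float(m0)),
        tumbling=rng.random(n_cells) < tb0,
        n_flim=np.full(n_cells, mp.n0),
    )


def step_population(states: CellStates, pheno: Phenotype, env: Environment,
                    mp: MotorParams, pp: PathwayParams, dt: float,
                    rng: np.random.Generator,
                    freeze_pathway: bool = False,
                    VB: float | None = None) -> np.ndarray:
    """Advance every cell by one time step dt (in place).  Returns Y.

    Order per step: methylation update at the local ligand level; CheY-P and
    switching rates; Bernoulli mode switch with p = 1 - e^{-lam dt} (heading
    redrawn uniformly at tumble exit); runners advance and their headings
    rotationally diffuse (two transverse Gaussian increments of variance
    2*Dr*dt); FliM remodelling if motor adaptation is on.
    """
    L = env.ligand(states.x[:, 0])
    if freeze_pathway:
        Y = np.full(len(states.m), pheno.Y0)
    else:
        if pp.variant == "asymmetric":
            vb = VB if VB is not None else pathway.asymmetric_vb(
                pp.VR, pheno.Y0, pp.alpha)
            rec = pathway.methylation_step_asymmetric(
                pathway.ReceptorState(m=states.m, F=None, Y=None), L, dt, pp, vb)
        else:
            rec = pathway.methylation_step(
                pathway.ReceptorState(m=states.m, F=None, Y=None), L, dt, pp,
                pheno.F0)
        states.m = rec.m
        Y = rec.Y

    e3 = motor.eps3_of_n(states.n_flim, mp) if mp.adapt else None
    lam_r, lam_t = motor.switching_rates(Y, mp, e3)
    lam = np.where(states.tumbling, lam_t, lam_r)
    switch = rng.random(len(lam)) < -np.expm1(-lam * dt)

    exit_tumble = states.tumbling & switch
    k = int(exit_tumble.sum())
    if k:
        states.u[exit_tumble] = _uniform_sphere(rng, k)
    states.tumbling = states.tumbling ^ switch

    run = ~states.tumbling
    if run.any():
        ur = states.u[run]
        states.x[run] += env.v * dt * ur
        # rotational diffusion: Gaussian angular kicks in the plane normal to u
        a = np.zeros_like(ur)
        near_axis = np.abs(ur[:, 0]) < 0.9
        a[near_axis, 0] = 1.0
        a[~near_axis, 1] = 1.0
        e1 = np.cross(ur, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(ur, e1)
        th = rng.normal(scale=np.sqrt(2.0 * env.Dr * dt), size=(len(ur), 2))
        ur = ur + th[:, :1] * e1 + th[:, 1:] * e2
        ur /= np.linalg.norm(ur, axis=1, keepdims=True)
        states.u[run] = ur

    if mp.adapt:
        cw = motor.cw_bias(Y, mp, e3)
        states.n_flim = np.clip(
            states.n_flim + dt * motor.flim_dndt(states.n_flim, cw, mp),
            mp.n1, mp.n2)

    states.t += dt
    return Y


def run_population(n_cells: int, T: float, pheno: Phenotype, env: Environment,
                   mp: MotorParams, pp: PathwayParams | None = None,
                   dt: float = 0.01, seed: int = 0,
                   window: tuple[float, float] = (60.0, 300.0),
                   sample_every: float = 0.1,
                   store_series: bool = False,
                   freeze_pathway: bool = False) -> PopulationResult:
    """Simulate a clonal population and measure drift observables.

    ``V_D`` is the mean over cells of the gradient-axis displacement between
    the window endpoints divided by the window length; ``Y_m`` averages the
    instantaneous CheY-P over cells and sampled times inside the window.
    """
    if pp is None:
        pp = PathwayParams(tau=pheno.tau)
    elif pp.tau != pheno.tau:
        pp = pp.with_tau(pheno.tau)
    t0, t1 = window
    if T < t1:
        raise ValueError("simulation length T must cover the window")
    max_rate = mp.omega * np.exp(mp.eps2 / 4.0)
    if dt > 0.011:
        import warnings

        warnings.warn(f"dt={dt} s is coarse for switching rates up to "
                      f"{max_rate:.2g} 1/s", stacklevel=2)

    rng = np.random.default_rng(seed)
    states = init_population(n_cells, pheno, env, mp, pp, seed)
    VB = (pathway.asymmetric_vb(pp.VR, pheno.Y0, pp.alpha)
          if pp.variant == "asymmetric" else None)

    nsteps = int(round(T / dt))
    stride = max(1, int(round(sample_every / dt)))
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    n_samples = nsteps // stride + 1
    times = np.empty(n_samples)
    mean_Y = np.empty(n_samples)
    mean_L = np.empty(n_samples)
    series = np.empty((n_samples, n_cells)) if store_series else None

    x1_at_t0 = None
    y_accum = np.zeros(n_cells)
    n_accum = 0
    js = 0
    for it in range(nsteps + 1):
        if it == i0:
            x1_at_t0 = states.x[:, 0].copy()
        if it % stride == 0:
            L = env.ligand(states.x[:, 0])
            F = pathway.free_energy(states.m, L, pp)
            Y = pathway.chey_p(F, pp.alpha)
            times[js] = it * dt
            mean_Y[js] = Y.mean()
            mean_L[js] = L.mean()
            if store_series:
                series[js] = states.x[:, 0]
            if i0 <= it <= i1:
                y_accum += Y
                n_accum += 1
            js += 1
        if it == nsteps:
            break
        step_population(states, pheno, env, mp, pp, dt, rng,
                        freeze_pathway=freeze_pathway, VB=VB)

    vd_per_cell = (states.x[:, 0] - x1_at_t0) / (t1 - t0)
    ym_per_cell = y_accum / n_accum
    perp = np.sqrt(states.x[:, 1] ** 2 + states.x[:, 2] ** 2)
    config = {
        "Y0": pheno.Y0, "tau": pheno.tau, "g": env.g, "L0": env.L0,
        "v": env.v, "Dr": env.Dr, "dt": dt, "n_cells": n_cells, "T": T,
        "motor_adapt": mp.adapt, "variant": pp.variant,
    }
    return PopulationResult(
        times=times, mean_Y=mean_Y, mean_L=mean_L,
        vd_per_cell=vd_per_cell, ym_per_cell=ym_per_cell,
        perp_per_cell=perp,
        vd=float(vd_per_cell.mean()),
        vd_se=float(vd_per_cell.std(ddof=1) / np.sqrt(n_cells)),
        ym=float(ym_per_cell.mean()),
        rms_perp=float(np.sqrt((perp ** 2).mean())),
        window=window, seed=seed, config=config,
        x1_series=series,
    )


def bimodality_summary(result: PopulationResult,
                       vd_threshold: float | None = None) -> pd.DataFrame:
    """Per-cell (V_D, RMS-perpendicular, Y_m) scatter with a mode split.

    ``vd_threshold`` — normally the drift velocity of the analytic unstable
    fixed point when the phenotype is bistable — separates "trapped" from
    "drifting" cells; with no threshold all cells form one mode.
    """
    df = pd.DataFrame({
        "vd_um_per_s": result.vd_per_cell,
        "perp_um": result.perp_per_cell,
        "ym_uM": result.ym_per_cell,
    })
    if vd_threshold is None:
        df["mode"] = "single"
    else:
        df["mode"] = np.where(df["vd_um_per_s"] < vd_threshold,
                              "trapped", "drifting")
    return df
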