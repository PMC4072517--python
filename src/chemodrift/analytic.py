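"""Drift-velocity theory: linearized drift, behavioral feedback, bifurcations.

The 1-D two-state representation of a run-and-tumble swimmer in d dimensions
gives the steady-state drift velocity

    V_D = (1/d) * v * (<t_up> - <t_down>) / (<t_up> + <t_down> + 2 <t_T>),

where the expected run duration along a direction is limited jointly by
tumbling and rotational diffusion (termination rate lam_R + (d-1)*Dr) and
the 1/d factor rescales the 1-D representation back to d dimensions.

Linearizing around an operating point (F_op, Y_op) for a constant
free-energy drive f yields the closed form

    V_D = (1/d) * v * f * [tau*tauR/(tau+tauR)] * tauR^2 * G / (tauR + tauT)

with tauR = 1/((d-1)*Dr + lam_R), tauT = 1/lam_T, and the motor sensitivity
G = -d(lam_R)/dF, all evaluated at the operating point.

Swimming up the gradient feeds back on the signal: at quasi-steady state
the operational free energy sits at F_m = F0 + tau*N*g*V_D.  Intersecting
this feedback line with the drift curve (evaluated at operating point Y_m)
yields the steady states; in steep gradients or for slow adaptation the
system is bistable, creating a non-chemotactic "trapped" state next to the
fast-drifting one.  With FliM adaptation the motor cooperativity eps3 is
replaced by its quasi-steady value eps3(Y_m) before intersecting.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from . import motor, pathway
from .params import Environment, MotorParams, PathwayParams, Phenotype

__all__ = [
    "OperatingPoint",
    "FixedPoint",
    "PhenotypeMap",
    "operating_point",
    "expected_run_duration",
    "drift_exact",
    "drift_linearized",
    "drift_curve",
    "feedback_line",
    "feedback_drift",
    "eps3_quasi_steady",
    "motor_adapted_drift",
    "fixed_points",
    "steady_state_drift",
    "optimal_y0",
    "phenotype_map",
    "chemotaxis_coefficient",
]


@dataclass(frozen=True)
class OperatingPoint:
    """Motor/pathway quantities evaluated at one CheY-P level."""

    Y: float
    F: float
    lam_r: float
    lam_t: float
    tau_r: float      # expected run duration along a direction, 1/((d-1)Dr + lam_r)
    tau_t: float      # expected tumble duration, 1/lam_t
    tb: float         # tumble bias lam_r/(lam_r+lam_t)
    G: float          # motor sensitivity -d(lam_r)/dF


@dataclass(frozen=True)
class FixedPoint:
    """Intersection of the drift curve with the behavioral-feedback line."""

    Y_m: float
    V_D: float
    stability: Literal["stable", "unstable", "degenerate"]


@dataclass
class PhenotypeMap:
    """Relative-performance surfaces over (tau, TB0) for several gradients."""

    tau_grid: np.ndarray
    tb0_grid: np.ndarray
    y0_grid: np.ndarray              # Y0 corresponding to each TB0
    gradients: np.ndarray            # g values (1/µm)
    vd: np.ndarray                   # (n_grad, n_tau, n_tb)
    relative: np.ndarray             # vd normalized by each gradient's max
    maximin_tau: float
    maximin_tb0: float
    maximin_value: float             # min over gradients of relative vd


def _g_sensitivity(Y, mp: MotorParams, eps3, alpha: float):
    """G = -d(lam_R)/dF > 0, by the chain rule through Y(F)."""
    lam_r, _ = motor.switching_rates(Y, mp, eps3)
    ddg_dy = -eps3 * mp.K / (Y + mp.K) ** 2
    dy_df = Y * (Y / alpha - 1.0)
    return 0.5 * lam_r * ddg_dy * dy_df


def operating_point(Y: float, env: Environment, mp: MotorParams,
                    eps3: float | None = None,
                    alpha: float = 6.0) -> OperatingPoint:
    e3 = mp.eps3 if eps3 is None else eps3
    lam_r, lam_t = (float(x) for x in motor.switching_rates(Y, mp, e3))
    tau_r = 1.0 / ((env.d - 1) * env.Dr + lam_r)
    return OperatingPoint(
        Y=Y, F=pathway.f0_of_y0(Y, alpha), lam_r=lam_r, lam_t=lam_t,
        tau_r=tau_r, tau_t=1.0 / lam_t, tb=lam_r / (lam_r + lam_t),
        G=float(_g_sensitivity(Y, mp, e3, alpha)),
    )


def expected_run_duration(F_i: float, s: int, tau: float, f: float,
                          env: Environment, mp: MotorParams,
                          eps3: float | None = None, alpha: float = 6.0,
                          n_grid: int = 40001) -> float:
    """Expected run duration along direction s = ±1 starting from F_i.

    During the run the free energy relaxes toward F0 + s*f*tau... more
    precisely toward ``F_inf = F_i0 + s*f*tau`` where the spring pulls to the
    adapted value: F(t) = F_inf + (F_i - F_inf) e^{-t/tau} with
    F_inf = F0 + s*f*tau.  Here F0 is taken equal to F_i (runs start at the
    operating point).  The run survives termination by tumbling or
    rotational diffusion:

        <t_s> = ∫_0^∞ exp(-∫_0^t [lam_R(F(t')) + (d-1) Dr] dt') dt.

    The integral is evaluated by trapezoidal quadrature on [0, 12 tau] plus
    an exact exponential tail at the asymptotic rate.
    """
    e3 = mp.eps3 if eps3 is None else eps3
    dr_rate = (env.d - 1) * env.Dr
    F_inf = F_i + s * f * tau

    t1 = 12.0 * tau
    t = np.linspace(0.0, t1, n_grid)
    F = F_inf + (F_i - F_inf) * np.exp(-t / tau)
    Y = pathway.chey_p(F, alpha)
    lam_r, _ = motor.switching_rates(Y, mp, e3)
    rate = lam_r + dr_rate
    rate_inf = float(motor.switching_rates(pathway.chey_p(F_inf, alpha),
                                           mp, e3)[0]) + dr_rate
    if rate_inf <= 1e-6:
        raise ValueError("run-termination rate effectively vanishes "
                         "(no tumbling, no rotational diffusion); the "
                         "expected run duration does not converge")
    dt = t[1] - t[0]
    cum = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)))
    surv = np.exp(-cum)
    return float(np.trapezoid(surv, t) + surv[-1] / rate_inf)


def drift_exact(pheno: Phenotype, env: Environment, mp: MotorParams,
                Y_op: float | None = None, eps3: float | None = None,
                f: float | None = None) -> float:
    """Drift velocity from the full expected-run-duration integrals."""
    Y = pheno.Y0 if Y_op is None else Y_op
    if f is None:
        f = env.v * PathwayParams().N * env.g
    F_op = pathway.f0_of_y0(Y, pheno.alpha)
    t_up = expected_run_duration(F_op, +1, pheno.tau, f, env, mp, eps3,
                                 pheno.alpha)
    t_down = expected_run_duration(F_op, -1, pheno.tau, f, env, mp, eps3,
                                   pheno.alpha)
    _, lam_t = motor.switching_rates(Y, mp, mp.eps3 if eps3 is None else eps3)
    t_t = 1.0 / float(lam_t)
    return env.v * (t_up - t_down) / (t_up + t_down + 2.0 * t_t) / env.d


def drift_curve(Y, tau: float, env: Environment, mp: MotorParams,
                eps3=None, f: float | None = None, alpha: float = 6.0,
                N: float = 6.0):
    """Vectorized linearized drift velocity at operating point(s) Y.

    ``f`` defaults to the ideal constant drive v*N*g of an exponential
    gradient in the log-sensing regime.
    """
    Y = np.asarray(Y, dtype=float)
    e3 = mp.eps3 if eps3 is None else np.asarray(eps3, dtype=float)
    if f is None:
        f = env.v * N * env.g
    lam_r, lam_t = motor.switching_rates(Y, mp, e3)
    tau_r = 1.0 / ((env.d - 1) * env.Dr + lam_r)
    tau_t = 1.0 / lam_t
    G = _g_sensitivity(Y, mp, e3, alpha)
    kernel = tau * tau_r / (tau + tau_r)
    return env.v * f * kernel * tau_r ** 2 * G / (tau_r + tau_t) / env.d


def drift_linearized(op: OperatingPoint, tau: float, f: float,
                     env: Environment) -> float:
    """Linearized drift velocity at a precomputed operating point."""
    kernel = tau * op.tau_r / (tau + op.tau_r)
    return env.v * f * kernel * op.tau_r ** 2 * op.G / (op.tau_r + op.tau_t) / env.d


def feedback_line(V_D, pheno: Phenotype, env: Environment, N: float = 6.0):
    """Operational CheY-P sustained at drift V_D: Y_m = Y(F0 + tau*N*g*V_D)."""
    F_m = pheno.F0 + pheno.tau * N * env.g * np.asarray(V_D, dtype=float)
    return pathway.chey_p(F_m, pheno.alpha)


def feedback_drift(Y_m, pheno: Phenotype, env: Environment, N: float = 6.0):
    """Inverse of the feedback line: drift required to sustain Y_m."""
    Y_m = np.asarray(Y_m, dtype=float)
    F_m = np.log(pheno.alpha / Y_m - 1.0)
    return (F_m - pheno.F0) / (pheno.tau * N * env.g)


@functools.lru_cache(maxsize=8)
def _eps3_table(mp: MotorParams, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    y = np.linspace(1e-3, alpha - 1e-3, 1500)
    _, e3, _ = motor.adapted_cw_curve(y, mp)
    return y, e3


def eps3_quasi_steady(Y, mp: MotorParams, alpha: float = 6.0):
    """Quasi-steady motor cooperativity eps3(Y) under FliM remodelling.

    Interpolated from the joint root of dn/dt = 0 and CW = cw_bias(Y;
    eps3(n)) tabulated on a fine CheY-P grid.
    """
    ytab, e3tab = _eps3_table(mp, alpha)
    return np.interp(np.asarray(Y, dtype=float), ytab, e3tab)


def motor_adapted_drift(Y_m, tau: float, env: Environment, mp: MotorParams,
                        f: float | None = None, alpha: float = 6.0,
                        N: float = 6.0):
    """Linearized drift curve with eps3 at its FliM quasi-steady value."""
    e3 = eps3_quasi_steady(Y_m, mp, alpha)
    return drift_curve(Y_m, tau, env, mp, eps3=e3, f=f, alpha=alpha, N=N)


def _residual_grid(pheno: Phenotype, env: Environment, mp: MotorParams,
                   motor_adapt: bool, grid: np.ndarray, N: float):
    if motor_adapt:
        vd = motor_adapted_drift(grid, pheno.tau, env, mp, alpha=pheno.alpha,
                                 N=N)
    else:
        vd = drift_curve(grid, pheno.tau, env, mp, alpha=pheno.alpha, N=N)
    return vd - feedback_drift(grid, pheno, env, N)


def fixed_points(pheno: Phenotype, env: Environment, mp: MotorParams,
                 motor_adapt: bool = False, N: float = 6.0,
                 spacing: float = 0.005) -> list[FixedPoint]:
    """All intersections of the drift curve with the feedback line.

    Sign changes of the residual on a fine Y_m grid are refined by Brent's
    method; a root is stable when the residual slope is positive there
    (derived from the relaxation of F under Eq.-of-motion + feedback: the
    negative-feedback side of the drift curve attracts).  The generic count
    is 1 or 3; the grid auto-refines once if an even count suggests an
    unresolved pair.
    """
    lo, hi = 0.02, pheno.alpha - 0.02

    def resid(y):
        return float(_residual_grid(pheno, env, mp, motor_adapt,
                                    np.atleast_1d(y), N)[0])

    def scan(n_pts):
        grid = np.linspace(lo, hi, n_pts)
        r = _residual_grid(pheno, env, mp, motor_adapt, grid, N)
        roots = []
        sgn = np.sign(r)
        for i in np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]:
            y = brentq(resid, grid[i], grid[i + 1], xtol=1e-9)
            slope = resid(y + 5e-7) - resid(y - 5e-7)
            if abs(slope) < 1e-14:
                lab = "degenerate"
            else:
                lab = "stable" if slope > 0 else "unstable"
            roots.append(FixedPoint(
                Y_m=float(y),
                V_D=float(feedback_drift(y, pheno, env, N)),
                stability=lab))
        return roots

    n_pts = max(int((hi - lo) / spacing) + 2, 200)
    roots = scan(n_pts)
    if len(roots) % 2 == 0:
        roots = scan(4 * n_pts)
    return roots


def steady_state_drift(pheno: Phenotype, env: Environment, mp: MotorParams,
                       motor_adapt: bool = False,
                       N: float = 6.0) -> tuple[float, float, int]:
    """Best attainable steady state: stable root with the largest drift.

    Returns ``(V_D, Y_m, n_roots)``; (0, Y0) when no stable intersection
    exists (non-chemotactic).
    """
    fps = fixed_points(pheno, env, mp, motor_adapt, N)
    stable = [fp for fp in fps if fp.stability == "stable"]
    if not stable:
        return 0.0, pheno.Y0, len(fps)
    best = max(stable, key=lambda fp: fp.V_D)
    return best.V_D, best.Y_m, len(fps)


def optimal_y0(tau: float, env: Environment, mp: MotorParams,
               motor_adapt: bool = False, N: float = 6.0,
               y0_grid=None, alpha: float = 6.0) -> tuple[float, float, bool]:
    """Adapted CheY-P maximizing steady-state drift at adaptation time tau.

    Returns ``(Y0*, V_D*, bifurcated)``; the flag marks an optimum lying in
    the multi-stable region (the best state may be dynamically inaccessible
    for part of a population).
    """
    if y0_grid is None:
        y0_grid = np.arange(1.0, 4.5, 0.01)
    best = (0.0, y0_grid[0], 1)
    for y0 in y0_grid:
        pheno = Phenotype(Y0=float(y0), tau=tau, alpha=alpha)
        vd, _, n_roots = steady_state_drift(pheno, env, mp, motor_adapt, N)
        if vd > best[0]:
            best = (vd, float(y0), n_roots)
    return best[1], best[0], best[2] > 1


def phenotype_map(tau_grid: Sequence[float], tb0_grid: Sequence[float],
                  gradients: Sequence[float], mp: MotorParams,
                  env: Environment | None = None, motor_adapt: bool = True,
                  N: float = 6.0, alpha: float = 6.0) -> PhenotypeMap:
    """Relative drift-velocity surfaces over (tau, TB0) for several gradients.

    TB0 is the adapted tumble bias of the resting cell and is converted to
    Y0 by inverting the (adapted, when ``motor_adapt``) motor response
    curve.  Each gradient's surface is normalized by its own maximum; the
    maximin phenotype maximizes the worst-case relative performance.
    """
    if env is None:
        env = Environment()
    tau_grid = np.asarray(tau_grid, dtype=float)
    tb0_grid = np.asarray(tb0_grid, dtype=float)
    gradients = np.asarray(gradients, dtype=float)

    ytab = np.linspace(1e-3, alpha - 1e-3, 1500)
    if motor_adapt:
        cwtab, _, _ = motor.adapted_cw_curve(ytab, mp)
    else:
        cwtab = motor.cw_bias(ytab, mp)
    y0_grid = np.interp(tb0_grid, cwtab, ytab)

    vd = np.zeros((len(gradients), len(tau_grid), len(tb0_grid)))
    for kg, g in enumerate(gradients):
        env_g = Environment(L0=env.L0, g=float(g), v=env.v, Dr=env.Dr, d=env.d)
        for it, tau in enumerate(tau_grid):
            for ib, y0 in enumerate(y0_grid):
                pheno = Phenotype(Y0=float(y0), tau=float(tau), alpha=alpha)
                vd[kg, it, ib] = steady_state_drift(
                    pheno, env_g, mp, motor_adapt, N)[0]
    peaks = vd.reshape(len(gradients), -1).max(axis=1)
    relative = vd / peaks[:, None, None]
    worst = relative.min(axis=0)
    it, ib = np.unravel_index(int(np.argmax(worst)), worst.shape)
    return PhenotypeMap(
        tau_grid=tau_grid, tb0_grid=tb0_grid, y0_grid=y0_grid,
        gradients=gradients, vd=vd, relative=relative,
        maximin_tau=float(tau_grid[it]), maximin_tb0=float(tb0_grid[ib]),
        maximin_value=float(worst[it, ib]),
    )


def chemotaxis_coefficient(pheno: Phenotype, env: Environment,
                           mp: MotorParams, N: float = 6.0) -> float:
    """Chemotaxis coefficient chi = V_D/g of the linearized theory (µm²/s)."""
    vd = float(drift_curve(pheno.Y0, pheno.tau, env, mp, alpha=pheno.alpha,
                           N=N))
    return vd / env.g
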