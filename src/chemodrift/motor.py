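"""Two-state flagellar motor: switching rates, CW bias, FliM-ring adaptation.

The motor is a bistable unit whose CW/CCW free-energy difference depends on
CheY-P occupancy of FliM,

    dG(Y) = eps2/2 - eps3 * Y/(Y + K),

so the stationary clockwise bias is CW(Y) = 1/(1 + e^dG), an ultrasensitive
sigmoid with effective Hill coefficient 20 at the defaults (eps2 = eps3 = 80,
K = 3.06 µM; the half-max sits exactly at Y = K).  Switching rates follow a
symmetric Arrhenius split around the switching frequency omega,

    lam_R = omega * e^{-dG/2}   (run -> tumble),
    lam_T = omega * e^{+dG/2}   (tumble -> run),

so lam_R * lam_T = omega² for every Y and the stationary occupancy of the
two-state chain equals CW(Y).

Slow adaptation: the FliM ring size n drifts between n1 and n2 with
CW-dependent binding/unbinding, remodelling the motor's cooperativity
through eps3(n) = eps3_0 + eps3_1*(n - n0).  CCW rotation recruits FliM
(binding ∝ 1-CW), so a drop in CheY-P resensitises the motor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .params import MotorParams

__all__ = [
    "MotorState",
    "motor_free_energy",
    "cw_bias",
    "switching_rates",
    "eps3_of_n",
    "flim_dndt",
    "flim_step",
    "flim_steady_n",
    "adapted_cw_curve",
    "hill_coefficient",
]


@dataclass
class MotorState:
    """Dynamic motor state: rotation mode and FliM ring size."""

    tumbling: np.ndarray | bool
    n: np.ndarray | float

    def eps3_eff(self, mp: MotorParams):
        return eps3_of_n(self.n, mp)


def motor_free_energy(Y, eps2: float, eps3, K: float):
    """Non-dimensional CW/CCW free-energy difference dG(Y)."""
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("CheY-P concentration must be non-negative")
    return eps2 / 2.0 - eps3 * Y / (Y + K)


def cw_bias(Y, mp: MotorParams, eps3=None):
    """Stationary clockwise (= tumble) bias CW(Y) = 1/(1 + e^dG)."""
    e3 = mp.eps3 if eps3 is None else eps3
    return 1.0 / (1.0 + np.exp(motor_free_energy(Y, mp.eps2, e3, mp.K)))


def switching_rates(Y, mp: MotorParams, eps3=None):
    """(lam_R, lam_T): run->tumble and tumble->run rates in 1/s.

    Symmetric split lam_R = omega*e^{-dG/2}, lam_T = omega*e^{+dG/2}; the
    product is exactly omega² and lam_R/(lam_R+lam_T) equals ``cw_bias``.
    """
    e3 = mp.eps3 if eps3 is None else eps3
    dG = motor_free_energy(Y, mp.eps2, e3, mp.K)
    return mp.omega * np.exp(-dG / 2.0), mp.omega * np.exp(dG / 2.0)


def eps3_of_n(n, mp: MotorParams):
    """Linear map from FliM ring size to motor cooperativity."""
    return mp.eps3_0 + mp.eps3_1 * (np.asarray(n, dtype=float) - mp.n0)


def flim_dndt(n, CW, mp: MotorParams):
    """FliM ring remodelling rate dn/dt at ring size n and clockwise bias CW.

    Convention A (default): binding ∝ (1-CW), unbinding ∝ CW — CCW intervals
    recruit FliM.  Both effective rates saturate to zero at the ring-size
    bounds over the half-max scale dn.  Convention B swaps the CW factors
    (kept for sensitivity analysis).
    """
    n = np.asarray(n, dtype=float)
    CW = np.asarray(CW, dtype=float)
    bind = (mp.n2 - n) / ((mp.n2 - n) + mp.dn)
    unbind = (n - mp.n1) / ((n - mp.n1) + mp.dn)
    if mp.convention == "A":
        return mp.k_on * (1.0 - CW) * bind - mp.k_off * CW * unbind
    return mp.k_on * CW * bind - mp.k_off * (1.0 - CW) * unbind


def flim_step(state: MotorState, CW, dt: float, mp: MotorParams) -> MotorState:
    """One Euler step of the FliM remodelling ODE; n stays in [n1, n2]."""
    n = np.clip(state.n + dt * flim_dndt(state.n, CW, mp), mp.n1, mp.n2)
    return MotorState(tumbling=state.tumbling, n=n)


def flim_steady_n(Y: float, mp: MotorParams) -> tuple[float, bool]:
    """Quasi-steady ring size: joint root of dn/dt = 0 and CW = cw_bias.

    Solves g(n) = dn/dt(n, CW(Y; eps3(n))) = 0 for n in [n1, n2].  Returns
    ``(n*, pinned)`` where ``pinned`` flags a boundary solution (no interior
    root; remodelling saturated at a ring-size bound).
    """

    def g(n):
        return float(flim_dndt(n, cw_bias(Y, mp, eps3_of_n(n, mp)), mp))

    lo, hi = mp.n1 + 1e-12, mp.n2 - 1e-12
    glo, ghi = g(lo), g(hi)
    if glo <= 0.0:
        return mp.n1, True
    if ghi >= 0.0:
        return mp.n2, True
    return brentq(g, lo, hi, xtol=1e-10), False


def adapted_cw_curve(Y_grid, mp: MotorParams):
    """Quasi-steady adapted motor response CW*(Y) over a CheY-P grid.

    For each Y the FliM ring relaxes to its steady size n*(Y); the adapted
    bias is CW(Y; eps3(n*)).  The adapted curve is shallower than the
    fixed-ring response and is bracketed between the eps3(n1) and eps3(n2)
    curves.  Returns ``(cw_star, eps3_star, pinned)`` arrays.
    """
    Y_grid = np.atleast_1d(np.asarray(Y_grid, dtype=float))
    n_star = np.empty_like(Y_grid)
    pinned = np.zeros(Y_grid.shape, dtype=bool)
    for i, y in enumerate(Y_grid):
        n_star[i], pinned[i] = flim_steady_n(float(y), mp)
    e3 = eps3_of_n(n_star, mp)
    return cw_bias(Y_grid, mp, e3), e3, pinned


def hill_coefficient(Y, CW, fit: bool = False) -> float:
    """Effective Hill coefficient of a monotone response curve at half-max.

    Slope method: n_H = 4 * Y_half * (dCW/dY at CW = 1/2), exact for a Hill
    function.  With ``fit=True`` a least-squares Hill fit
    CW = Y^n/(Y^n + Yh^n) is returned instead.
    """
    Y = np.asarray(Y, dtype=float)
    CW = np.asarray(CW, dtype=float)
    if CW.min() > 0.5 or CW.max() < 0.5:
        raise ValueError("curve must span both sides of its half-maximum")
    if fit:
        def hill(y, n, yh):
            return y ** n / (y ** n + yh ** n)

        y_half0 = float(np.interp(0.5, CW, Y))
        popt, _ = curve_fit(hill, Y, CW, p0=(10.0, y_half0), maxfev=20000)
        return float(popt[0])
    y_half = float(np.interp(0.5, CW, Y))
    slope = float(np.interp(y_half, Y, np.gradient(CW, Y)))
    return 4.0 * y_half * slope
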