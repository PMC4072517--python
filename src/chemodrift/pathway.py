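"""Receptor-cluster free energy, CheY-P output and methylation dynamics.

The receptor cluster is a two-state (MWC) unit: the free-energy difference
between inactive and active conformations,

    F(m, L) = eps0 + eps1*m + N*ln[(1 + L/Ki) / (1 + L/Ka)],

falls linearly with methylation ``m`` (eps1 < 0 raises activity) and rises
with attractant ``L`` between the two dissociation constants (log-sensing).
The pathway output is the CheY-P concentration ``Y = alpha/(1 + e^F)``.

Methylation provides integral feedback: the symmetric variant relaxes ``F``
toward the adapted value ``F0`` with time constant ``tau`` (spring-like
dynamics, dm/dt = (F0 - F)/(tau*eps1)); the asymmetric variant uses
activity-dependent rates dm/dt = VR*(1-a) - VB*a with a = Y/alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Environment, PathwayParams

__all__ = [
    "ReceptorState",
    "free_energy",
    "ligand_term",
    "chey_p",
    "f0_of_y0",
    "adapted_methylation",
    "methylation_step",
    "methylation_step_asymmetric",
    "asymmetric_vb",
    "ramp_magnitude",
]


@dataclass
class ReceptorState:
    """Dynamic receptor state of one cell (or an array of cells)."""

    m: np.ndarray | float
    F: np.ndarray | float
    Y: np.ndarray | float
    clamped: np.ndarray | bool = False


def ligand_term(L, p: PathwayParams):
    """N * ln[(1 + L/Ki)/(1 + L/Ka)] with Ki, Ka in µM."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    return p.N * np.log((1.0 + L / p.ki_um) / (1.0 + L / p.ka_um))


def free_energy(m, L, p: PathwayParams):
    """Free-energy difference F(m, L) of the receptor cluster.

    Strictly increasing in L (attractant deactivates the kinase) and linear
    in m with slope eps1.
    """
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > p.m_max)):
        raise ValueError(f"methylation level outside [0, {p.m_max}]")
    return p.eps0 + p.eps1 * m + ligand_term(L, p)


def chey_p(F, alpha: float = 6.0):
    """CheY-P concentration Y = alpha/(1 + e^F), in (0, alpha)."""
    return alpha / (1.0 + np.exp(np.asarray(F, dtype=float)))


def f0_of_y0(Y0: float, alpha: float = 6.0) -> float:
    """Adapted free-energy difference F0 = ln(alpha/Y0 - 1)."""
    if not (0 < Y0 < alpha):
        raise ValueError(f"Y0 must lie in (0, alpha={alpha} µM); got {Y0}")
    return float(np.log(alpha / Y0 - 1.0))


def adapted_methylation(L, F0: float, p: PathwayParams):
    """Methylation level solving F(m, L) = F0, clamped to [0, m_max].

    Returns ``(m, clamped)``; the flag marks ligand levels outside the
    adaptation range where precise adaptation is impossible.
    """
    m = (F0 - p.eps0 - ligand_term(L, p)) / p.eps1
    clamped = (m < 0) | (m > p.m_max)
    return np.clip(m, 0.0, p.m_max), clamped


def methylation_step(state: ReceptorState, L, dt: float, p: PathwayParams,
                     F0: float) -> ReceptorState:
    """One explicit-Euler step of the symmetric methylation dynamics.

    dm/dt = (F0 - F)/(tau*eps1), so the methylation contribution to dF/dt is
    (F0 - F)/tau; at constant L, F relaxes exponentially to F0 with time
    constant tau.
    """
    F = free_energy(state.m, L, p)
    m = state.m + dt * (F0 - F) / (p.tau * p.eps1)
    clamped = (m < 0) | (m > p.m_max)
    m = np.clip(m, 0.0, p.m_max)
    F = free_energy(m, L, p)
    return ReceptorState(m=m, F=F, Y=chey_p(F, p.alpha), clamped=clamped)


def asymmetric_vb(VR: float, Y0: float, alpha: float = 6.0) -> float:
    """Demethylation rate pinning the adapted activity a0 = Y0/alpha.

    Chosen so dm/dt = VR*(1-a) - VB*a vanishes at a = a0.
    """
    a0 = Y0 / alpha
    if not (0 < a0 < 1):
        raise ValueError("adapted activity must lie strictly in (0, 1)")
    return VR * (1.0 - a0) / a0


def methylation_step_asymmetric(state: ReceptorState, L, dt: float,
                                p: PathwayParams, VB: float) -> ReceptorState:
    """One Euler step of activity-dependent (de)methylation kinetics.

    dm/dt = VR*(1-a) - VB*a with activity a = Y/alpha.  The zero of dm/dt
    sits at the adapted activity through the choice of VB (``asymmetric_vb``).
    """
    F = free_energy(state.m, L, p)
    a = 1.0 / (1.0 + np.exp(np.asarray(F, dtype=float)))  # activity Y/alpha
    m = state.m + dt * (p.VR * (1.0 - a) - VB * a)
    clamped = (m < 0) | (m > p.m_max)
    m = np.clip(m, 0.0, p.m_max)
    F = free_energy(m, L, p)
    return ReceptorState(m=m, F=F, Y=chey_p(F, p.alpha), clamped=clamped)


def ramp_magnitude(L, env: Environment, p: PathwayParams):
    """Magnitude f of the free-energy drive at ligand level L (1/s).

    For a cell swimming at speed v through L(x) = L0*e^{g x},

        f(L) = v * N * g * [L/(L+Ki) - L/(L+Ka)],

    which approaches the constant v*N*g in the log-sensing regime
    Ki << L << Ka and vanishes in both saturation limits.
    """
    L = np.asarray(L, dtype=float)
    return env.v * p.N * env.g * (L / (L + p.ki_um) - L / (L + p.ka_um))
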