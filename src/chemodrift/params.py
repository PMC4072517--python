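"""Parameter records for the chemotaxis pathway, flagellar motor and environment.

All concentrations are micromolar internally.  The receptor dissociation
constants ``ki``/``ka`` are entered in millimolar, matching how they are
usually tabulated for Tar/methyl-aspartate, and converted on access.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np

__all__ = [
    "PathwayParams",
    "MotorParams",
    "Environment",
    "Phenotype",
    "DEFAULT_PATHWAY",
    "DEFAULT_MOTOR",
    "DEFAULT_ENVIRONMENT",
]


@dataclass(frozen=True)
class PathwayParams:
    """Receptor-cluster and adaptation constants (Tar / methyl-aspartate).

    Parameters
    ----------
    alpha : float
        Gain of the phosphorylation cascade (µM); CheY-P is ``alpha/(1+e^F)``.
    eps0, eps1 : float
        Free-energy offset and per-methylation increment (dimensionless).
    N : float
        Cooperative receptor-cluster gain.
    ki, ka : float
        Ligand dissociation constants of the inactive / active receptor
        conformation, in mM.
    m_max : float
        Total methylation sites per cooperative unit.
    tau : float
        Receptor (methylation) adaptation time in seconds.
    variant : {"symmetric", "asymmetric"}
        Methylation kinetics: spring-like relaxation of the free energy, or
        activity-dependent first-order (de)methylation rates.
    VR, VB : float
        Methylation / demethylation rates (1/s), asymmetric variant only.
        ``VB`` defaults to the value pinning the adapted activity (set per
        phenotype at simulation time when left as ``None``).
    """

    alpha: float = 6.0
    eps0: float = 6.0
    eps1: float = -1.0
    N: float = 6.0
    ki: float = 0.0182
    ka: float = 3.0
    m_max: float = 48.0
    tau: float = 10.0
    variant: Literal["symmetric", "asymmetric"] = "symmetric"
    VR: float = 0.1
    VB: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0 < self.ki < self.ka):
            raise ValueError("need 0 < ki < ka")
        if self.m_max <= 0:
            raise ValueError("m_max must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.variant not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def ki_um(self) -> float:
        """Inactive-state dissociation constant in µM."""
        return self.ki * 1e3

    @property
    def ka_um(self) -> float:
        """Active-state dissociation constant in µM."""
        return self.ka * 1e3

    def with_tau(self, tau: float) -> "PathwayParams":
        return replace(self, tau=tau)


@dataclass(frozen=True)
class MotorParams:
    """Two-state flagellar motor constants, with optional FliM-ring adaptation.

    ``omega`` is the switching frequency at the response midpoint, ``eps2``
    sets the basal (Y=0) switching rate, ``eps3`` the cooperativity, and ``K``
    the CheY-P/FliM binding constant.  The FliM ring remodels between ``n1``
    and ``n2`` subunits with rates ``k_on``/``k_off`` saturating over the
    half-max scale ``dn``; the ring size moves the cooperativity linearly,
    ``eps3(n) = eps3_0 + eps3_1*(n - n0)``.
    """

    omega: float = 1.3
    eps2: float = 80.0
    eps3: float = 80.0
    K: float = 3.06
    adapt: bool = False
    k_on: float = 0.025
    k_off: float = 0.0063
    n1: float = 34.0
    n2: float = 44.0
    n0: float = 36.0
    dn: float = 4.16
    eps3_0: float = 80.0
    eps3_1: float = 1.96
    convention: Literal["A", "B"] = "A"

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (self.n1 < self.n0 < self.n2):
            raise ValueError("need n1 < n0 < n2")
        if self.convention not in ("A", "B"):
            raise ValueError(f"unknown FliM convention {self.convention!r}")


@dataclass(frozen=True)
class Environment:
    """Static exponential attractant field and swimming parameters.

    ``L(x) = L0 * exp(g * x)`` along the first spatial axis.  ``d`` is the
    spatial dimensionality used by the analytic 1-D mapping (runs terminate
    by rotational diffusion at rate ``(d-1)*Dr``, and the two-state drift is
    rescaled by ``1/d``).
    """

    L0: float = 200.0
    g: float = 1.0 / 5000.0
    v: float = 20.0
    Dr: float = 0.062
    d: int = 3

    def __post_init__(self) -> None:
        if self.L0 < 0:
            raise ValueError("L0 must be non-negative")
        if self.v <= 0:
            raise ValueError("v must be positive")
        if self.Dr < 0:
            raise ValueError("Dr must be non-negative")
        if self.d not in (2, 3):
            raise ValueError("d must be 2 or 3")

    def ligand(self, x: np.ndarray | float) -> np.ndarray | float:
        """Ligand concentration (µM) at gradient-axis position x (µm)."""
        return self.L0 * np.exp(self.g * np.asarray(x))


@dataclass(frozen=True)
class Phenotype:
    """A cell phenotype: adapted CheY-P concentration and adaptation time."""

    Y0: float
    tau: float
    alpha: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.Y0 < self.alpha):
            raise ValueError(
                f"Y0 must lie in (0, alpha={self.alpha} µM); got {self.Y0}"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def F0(self) -> float:
        """Adapted free-energy difference, ln(alpha/Y0 - 1)."""
        return float(np.log(self.alpha / self.Y0 - 1.0))

    def tb0(self, mp: MotorParams) -> float:
        """Adapted tumble bias for a non-adapting motor."""
        from . import motor

        return float(motor.cw_bias(self.Y0, mp))


DEFAULT_PATHWAY = PathwayParams()
DEFAULT_MOTOR = MotorParams()
DEFAULT_ENVIRONMENT = Environment()


def params_dict(obj) -> dict:
    """Plain-dict view of a parameter record (for config echo / hashing)."""
    return asdict(obj)
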