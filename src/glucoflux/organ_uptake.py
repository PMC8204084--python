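"""Muscle and liver insulin-dependent glucose uptake.

Both organs take up interstitial glucose with Michaelis–Menten kinetics
whose maximal rate grows linearly with interstitial insulin::

    Uidm = part_m * (V + VX*INS) * Gt / (Km + Gt)
    Uidl = part_l * (V + VX*INS) * Gt / (Kl + Gt)

``V`` (basal utilization) and ``VX`` (insulin sensitivity) are a single
source of truth shared by the two organs; only the organ partition
(part_m / part_l) and the Michaelis constant (Km / Kl) differ.  The
shared interstitial insulin INS (pmol/l above basal) lags plasma insulin
with distinct entry and degradation rate constants::

    dINS/dt = kins1*(I - Ib) - kins2*INS

Setting kins1 == kins2 recovers the earlier single-rate-constant
formulation.  The liver's insulin dependence is an explicit modeling
approximation: hepatic uptake runs through GLUT2 and responds to insulin
indirectly via phosphorylation/utilization, but with no intracellular
liver module the direct form is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, SignalError
from .params import ParameterSet

__all__ = [
    "InterstitialInsulinState",
    "InterstitialInsulinParams",
    "MuscleParams",
    "LiverParams",
    "interstitial_insulin_rhs",
    "muscle_uptake",
    "liver_uptake",
]


@dataclass(frozen=True)
class InterstitialInsulinState:
    """Interstitial insulin above basal (pmol/l)."""

    INS: float


@dataclass(frozen=True)
class InterstitialInsulinParams:
    kins1: float  # 1/min, transport into the interstitium
    kins2: float  # 1/min, degradation

    def __post_init__(self) -> None:
        if self.kins1 <= 0 or self.kins2 <= 0:
            raise ConfigurationError("kins1 and kins2 must be > 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "InterstitialInsulinParams":
        return cls(kins1=p.kins1, kins2=p.kins2)


@dataclass(frozen=True)
class MuscleParams:
    part_m: float  # organ scaling
    V: float       # mg/kg/min, basal utilization (shared with liver)
    VX: float      # per pmol/l, insulin sensitivity (shared with liver)
    Km: float      # mg/dl

    def __post_init__(self) -> None:
        for name in ("part_m", "V", "VX"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.Km <= 0:
            raise ConfigurationError("Km must be > 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "MuscleParams":
        return cls(part_m=p.part_m, V=p.V, VX=p.VX, Km=p.Km)


@dataclass(frozen=True)
class LiverParams:
    part_l: float
    Kl: float

    def __post_init__(self) -> None:
        if self.part_l < 0:
            raise ConfigurationError("part_l must be >= 0")
        if self.Kl <= 0:
            raise ConfigurationError("Kl must be > 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "LiverParams":
        return cls(part_l=p.part_l, Kl=p.Kl)


def interstitial_insulin_rhs(
    INS: float, I: float, Ib: float, params: InterstitialInsulinParams
) -> float:
    """dINS/dt = kins1*(I - Ib) - kins2*INS.

    Plasma insulin below basal is allowed and drives INS toward zero;
    INS is floored at zero only by the dynamics, never clamped.
    """
    if not math.isfinite(I):
        raise SignalError("insulin", float("nan"))
    return params.kins1 * (I - Ib) - params.kins2 * INS


def muscle_uptake(Gt: float, INS: float, params: MuscleParams) -> float:
    """Muscle uptake part_m*(V + VX*INS)*Gt/(Km + Gt), mg/kg/min.

    Zero at zero substrate, strictly increasing in both Gt and INS, and
    saturating at the insulin-set maximum Vmmax = part_m*(V + VX*INS).
    """
    vmax = params.part_m * (params.V + params.VX * INS)
    return vmax * Gt / (params.Km + Gt)


def liver_uptake(Gt: float, INS: float, params: LiverParams, shared: MuscleParams) -> float:
    """Liver uptake part_l*(V + VX*INS)*Gt/(Kl + Gt), mg/kg/min.

    ``shared`` supplies V and VX — the same values that parameterize the
    muscle, by construction.
    """
    vmax = params.part_l * (shared.V + shared.VX * INS)
    return vmax * Gt / (params.Kl + Gt)
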