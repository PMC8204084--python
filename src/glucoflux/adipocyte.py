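"""Adipose-tissue glucose transport and intracellular metabolism.

Net adipose uptake is a bidirectional, insulin-scaled transmembrane flux::

    Vin  = p4 * Gt * INSfe          (influx,  interstitium -> cell)
    Vout = p3 * Gluin * INSfe       (efflux,  cell -> interstitium)
    Uidf = part_f * (Vin - Vout)

so uptake follows the transmembrane glucose gradient and may transiently
go negative.  Inside the cell, glucose is phosphorylated to
glucose-6-phosphate by a hexokinase step with *product inhibition*::

    VG6P = VG6Pmax * Gluin/(kgluin + Gluin) * 1/(kG6P + G6P)
    dGluin/dt = p1*(Vin - Vout) - VG6P
    dG6P/dt   = VG6P - p2*G6P

When G6P accumulates it throttles phosphorylation, intracellular glucose
builds up, the gradient collapses, and net uptake falls back toward
baseline even while the insulin effect is still high — the mechanism
behind the early adipose uptake peak relative to plasma insulin.

The insulin effect on transport combines the two membrane transporters
and the blood-flow effect::

    INSfe = nC * (k8*GLUT4m^pf + GLUT1^pf + bfe_f)

GLUT1 is constitutive; membrane GLUT4 responds to insulin.  The full
receptor-to-GLUT4 signaling cascade is behind a pluggable driver
contract (time, interstitial insulin) -> GLUT4m; the packaged default is
a first-order relaxation toward a Hill function of insulin.  ``bfe_f``
has three modes: 0 for in-vitro experiments (isolated adipocytes have no
blood flow), a constant in-situ scaling when no blood-flow data exist,
or the dynamic blood-flow model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

from scipy.optimize import brentq

from .errors import ConfigurationError
from .params import ParameterSet

__all__ = [
    "AdipocyteState",
    "AdipocyteParams",
    "InsulinEffectParams",
    "Glut4Driver",
    "HillGlut4Driver",
    "transport_fluxes",
    "net_adipose_uptake",
    "phosphorylation_rate",
    "adipocyte_rhs",
    "insulin_effect",
    "adipocyte_steady_state",
]


@dataclass(frozen=True)
class AdipocyteState:
    """Intracellular glucose and glucose-6-phosphate (model units)."""

    Gluin: float
    G6P: float


@dataclass(frozen=True)
class AdipocyteParams:
    part_f: float
    p1: float
    p2: float
    p3: float
    p4: float
    kgluin: float
    kG6P: float
    VG6Pmax: float

    def __post_init__(self) -> None:
        for name in ("part_f", "p1", "p2", "p3", "p4", "VG6Pmax"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kgluin <= 0 or self.kG6P <= 0:
            raise ConfigurationError("kgluin and kG6P must be > 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "AdipocyteParams":
        return cls(part_f=p.part_f, p1=p.p1, p2=p.p2, p3=p.p3, p4=p.p4,
                   kgluin=p.kgluin, kG6P=p.kG6P, VG6Pmax=p.VG6Pmax)


@dataclass(frozen=True)
class InsulinEffectParams:
    nC: float
    k8: float
    pf: float
    GLUT1: float

    def __post_init__(self) -> None:
        for name in ("nC", "k8", "pf", "GLUT1"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "InsulinEffectParams":
        return cls(nC=p.nC, k8=p.k8, pf=p.pf, GLUT1=p.GLUT1)


class Glut4Driver(Protocol):
    """Signal contract mapping (t, interstitial insulin) -> membrane GLUT4.

    Implementations must return a bounded, nonnegative membrane fraction
    and reduce to their configured basal value at basal insulin.  The
    packaged default is the surrogate below; a full insulin-signaling
    cascade can be dropped in by satisfying this contract (either as a
    static map or, for stateful cascades, via ``rhs``/``steady_state``).
    """

    def steady_state(self, INS: float) -> float: ...
    def rhs(self, GLUT4m: float, INS: float) -> float: ...
    def basal(self) -> float: ...


@dataclass(frozen=True)
class HillGlut4Driver:
    """First-order relaxation toward a Hill function of interstitial insulin.

    dGLUT4m/dt = rate * (target(INS) - GLUT4m), with
    target(INS) = basal + amp * INS^h / (ec50^h + INS^h) and INS the
    interstitial insulin above basal (pmol/l, floored at 0).
    """

    basal_level: float = 0.1
    amp: float = 5.0
    ec50: float = 200.0
    hill: float = 2.0
    rate: float = 0.05

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.rate <= 0 or self.hill <= 0:
            raise ConfigurationError("Glut4 driver ec50, rate and hill must be > 0")
        if self.basal_level < 0 or self.amp < 0:
            raise ConfigurationError("Glut4 driver levels must be >= 0")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "HillGlut4Driver":
        return cls(basal_level=p.glut4_basal, amp=p.glut4_amp, ec50=p.glut4_ec50,
                   hill=p.glut4_hill, rate=p.glut4_rate)

    def steady_state(self, INS: float) -> float:
        x = max(INS, 0.0)
        if x == 0.0:
            return self.basal_level
        xh = x**self.hill
        return self.basal_level + self.amp * xh / (self.ec50**self.hill + xh)

    def rhs(self, GLUT4m: float, INS: float) -> float:
        return self.rate * (self.steady_state(INS) - GLUT4m)

    def basal(self) -> float:
        return self.basal_level


def transport_fluxes(
    Gt: float, Gluin: float, INSfe: float, params: AdipocyteParams
) -> tuple[float, float]:
    """(Vin, Vout): both linear in the insulin effect INSfe."""
    Vin = params.p4 * Gt * INSfe
    Vout = params.p3 * Gluin * INSfe
    return Vin, Vout


def net_adipose_uptake(Vin: float, Vout: float, part_f: float) -> float:
    """Uidf = part_f*(Vin - Vout); signed with the transmembrane gradient."""
    return part_f * (Vin - Vout)


def phosphorylation_rate(Gluin: float, G6P: float, params: AdipocyteParams) -> float:
    """Hexokinase rate with G6P product inhibition.

    Strictly increasing in substrate Gluin, strictly decreasing in
    product G6P; as G6P grows without bound the rate shuts down to zero.
    """
    if params.kG6P + G6P <= 0:
        raise ConfigurationError("kG6P + G6P must be > 0 (product-inhibition singularity)")
    return (
        params.VG6Pmax
        * Gluin / (params.kgluin + Gluin)
        / (params.kG6P + G6P)
    )


def adipocyte_rhs(
    state: AdipocyteState, Gt: float, INSfe: float, params: AdipocyteParams
) -> tuple[float, float]:
    """(dGluin/dt, dG6P/dt) for the intracellular pools.

    Note p1 scales only the transport contribution to Gluin, not the
    phosphorylative removal — implemented exactly as formulated.
    """
    Vin, Vout = transport_fluxes(Gt, state.Gluin, INSfe, params)
    VG6P = phosphorylation_rate(state.Gluin, state.G6P, params)
    dGluin = params.p1 * (Vin - Vout) - VG6P
    dG6P = VG6P - params.p2 * state.G6P
    return dGluin, dG6P


def insulin_effect(GLUT4m: float, bfe_f: float, params: InsulinEffectParams) -> float:
    """INSfe = nC*(k8*GLUT4m^pf + GLUT1^pf + bfe_f).

    The exponent pf applies to both transporter terms.  ``bfe_f`` follows
    the active blood-flow mode (0 in vitro, constant, or dynamic).
    """
    if GLUT4m < 0 and params.pf != int(params.pf):
        raise ConfigurationError("negative GLUT4m with fractional exponent pf")
    return params.nC * (params.k8 * GLUT4m**params.pf + params.GLUT1**params.pf + bfe_f)


def adipocyte_steady_state(
    Gt: float, INSfe: float, params: AdipocyteParams
) -> AdipocyteState:
    """Solve the intracellular fixed point for constant Gt and INSfe.

    At steady state p2*G6P = VG6P and p1*(Vin - Vout) = VG6P, which pins
    Gluin in (0, p4*Gt/p3); solved by bracketing root-finding.
    """
    if INSfe <= 0 or Gt <= 0 or params.p3 == 0:
        # No transport or no efflux: flux balance degenerates; with no
        # insulin effect the cell simply holds whatever it has.
        return AdipocyteState(Gluin=0.0, G6P=0.0)
    hi = params.p4 * Gt / params.p3

    def g6p_of(gluin: float) -> float:
        return params.p1 * INSfe * (params.p4 * Gt - params.p3 * gluin) / params.p2

    def resid(gluin: float) -> float:
        g6p = g6p_of(gluin)
        return phosphorylation_rate(gluin, g6p, params) - params.p2 * g6p

    lo = hi * 1e-12
    if resid(lo) > 0 or resid(hi) < 0:  # pragma: no cover - defensive
        raise ConfigurationError("adipocyte steady state not bracketed; check parameters")
    gluin = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)
    return AdipocyteState(Gluin=gluin, G6P=g6p_of(gluin))
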