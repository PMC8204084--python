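"""Plasma/interstitial glucose balance and the forcing-signal contract.

The whole-body level carries two glucose pools: plasma glucose ``Gp`` and
interstitial-tissue glucose ``Gt`` (both mg/dl).  Plasma receives endogenous
glucose production (EGP), meal glucose appearing from the intestine (Ra),
loses renal excretion (E) and a constant insulin-independent uptake (Uii,
brain/kidneys), and exchanges with the interstitium at first-order rates
kgp1 (plasma->tissue) and kgp2 (tissue->plasma).  The interstitium is
drained by the insulin-dependent uptake Uid, which is the sum of the
muscle, liver and adipose organ uptakes::

    dGt/dt = -Uid + kgp1*Gp - kgp2*Gt
    dGp/dt =  EGP + Ra - E - Uii - kgp1*Gp + kgp2*Gt
    Uid    =  Uidm + Uidl + Uidf

Plasma insulin I(t), EGP(t), Ra(t) and E(t) are external forcing signals:
the upstream whole-body submodel that generates them (gastric emptying,
insulin secretion and kinetics, EGP regulation) is pluggable, and the
built-in parametric meal curves below provide realistic postprandial
shapes for simulation and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError, SignalError
from .params import ParameterSet

__all__ = [
    "GlucoseState",
    "GlucoseExchangeParams",
    "Signal",
    "ConstantSignal",
    "TabulatedSignal",
    "ParametricSignal",
    "ForcingSet",
    "ForcingValues",
    "MealConfig",
    "glucose_rhs",
    "total_insulin_dependent_uptake",
    "parametric_meal_forcings",
    "default_meal_forcings",
    "basal_forcings",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlucoseState:
    """Plasma and interstitial glucose (mg/dl)."""

    Gp: float
    Gt: float


@dataclass(frozen=True)
class GlucoseExchangeParams:
    """Glucose exchange rates and the constant insulin-independent uptake.

    ``conv`` converts mass fluxes (mg/kg/min) into concentration units
    (mg/dl/min); the default 1 keeps the printed unit convention, where
    states are carried in mg/dl and fluxes treated as already scaled.
    """

    kgp1: float
    kgp2: float
    Uii: float
    conv: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kgp1", "kgp2", "Uii", "conv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "GlucoseExchangeParams":
        return cls(kgp1=p.kgp1, kgp2=p.kgp2, Uii=p.Uii, conv=p.conv)


# ---------------------------------------------------------------------------
# forcing signals
# ---------------------------------------------------------------------------

class Signal:
    """A scalar signal of time, evaluable at arbitrary t (minutes).

    Implementations must be defined on the whole simulation window and
    clamp to endpoint values outside any tabulated range.
    """

    name: str = "signal"

    def __call__(self, t):  # pragma: no cover - abstract
        raise NotImplementedError


class ConstantSignal(Signal):
    def __init__(self, value: float, name: str = "signal"):
        if not math.isfinite(value):
            raise ConfigurationError(f"constant signal {name!r} must be finite")
        self.value = float(value)
        self.name = name

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value) if np.ndim(t) else self.value


class TabulatedSignal(Signal):
    """Piecewise-linear interpolation of a tabulated signal, clamped to
    its endpoint values outside the table."""

    def __init__(self, times: Sequence[float], values: Sequence[float], name: str = "signal"):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.size < 2 or t.shape != v.shape:
            raise ConfigurationError(f"tabulated signal {name!r} needs >= 2 matching (time, value) pairs")
        if not np.all(np.diff(t) > 0):
            raise ConfigurationError(f"tabulated signal {name!r} times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError(f"tabulated signal {name!r} contains non-finite values")
        self.times = t
        self.values = v
        self.name = name

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


class ParametricSignal(Signal):
    """Closed-form signal wrapping a vectorized callable of time."""

    def __init__(self, fn: Callable, name: str = "signal"):
        self.fn = fn
        self.name = name

    def __call__(self, t):
        return self.fn(t)


class ForcingValues(NamedTuple):
    """One time-slice of the external forcings."""

    I: float
    EGP: float
    Ra: float
    E: float


@dataclass
class ForcingSet:
    """Time-parameterized external signals driving the model.

    I: plasma insulin (pmol/l); EGP: endogenous glucose production
    (mg/kg/min); Ra: meal glucose rate of appearance (mg/kg/min);
    E: renal excretion (mg/kg/min); Ib: basal plasma insulin (pmol/l).
    ``bradykinin_present`` and ``insulin_infusion`` are scenario flags
    consumed by the blood-flow factorial experiment.
    """

    I: Signal
    EGP: Signal
    Ra: Signal
    E: Signal
    Ib: float
    bradykinin_present: bool = False
    insulin_infusion: bool = False

    def at(self, t: float) -> ForcingValues:
        """Evaluate all signals at time t, checking finiteness."""
        out = []
        for name, sig in (("insulin", self.I), ("EGP", self.EGP), ("Ra", self.Ra), ("E", self.E)):
            v = float(sig(t))
            if not math.isfinite(v):
                raise SignalError(name, t)
            out.append(v)
        return ForcingValues(*out)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def glucose_rhs(
    state: GlucoseState,
    Uid: float,
    forcings: ForcingValues,
    params: GlucoseExchangeParams,
) -> tuple[float, float]:
    """Time derivatives (dGt/dt, dGp/dt) of the two glucose pools.

    ``Uid`` is the total insulin-dependent uptake at this instant; the
    forcings are the values of (I, EGP, Ra, E) already evaluated at t.
    """
    for name, v in (("EGP", forcings.EGP), ("Ra", forcings.Ra), ("E", forcings.E)):
        if not math.isfinite(v):
            raise SignalError(name, float("nan"))
    c = params.conv
    dGt = -c * Uid + params.kgp1 * state.Gp - params.kgp2 * state.Gt
    dGp = (
        c * (forcings.EGP + forcings.Ra - forcings.E - params.Uii)
        - params.kgp1 * state.Gp
        + params.kgp2 * state.Gt
    )
    return dGt, dGp


def total_insulin_dependent_uptake(Uidm: float, Uidl: float, Uidf: float) -> float:
    """Total insulin-dependent uptake: the sum over muscle, liver, adipose.

    The adipose term is a net transmembrane flux and may transiently be
    negative; the signed value is propagated.
    """
    total = Uidm + Uidl + Uidf
    if not math.isfinite(total):
        raise ConfigurationError("non-finite uptake term in Uid sum")
    return total


# ---------------------------------------------------------------------------
# parametric meal curves
# ---------------------------------------------------------------------------

def _gamma_pulse(t, t_peak: float, shape: float):
    """Smooth rise-and-decay pulse, normalized to peak value 1 at t_peak."""
    t = np.asarray(t, dtype=float)
    x = np.clip(t / t_peak, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = np.where(x > 0, np.exp(shape * (np.log(np.where(x > 0, x, 1.0)) + 1.0 - x)), 0.0)
    return out if out.ndim else float(out)


def _gamma_density(t, a: float, scale: float):
    """Gamma probability density in time; integrates to 1 over [0, inf)."""
    t = np.asarray(t, dtype=float)
    norm = math.gamma(a) * scale**a
    tt = np.clip(t, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tt > 0, np.power(np.where(tt > 0, tt, 1.0), a - 1.0) * np.exp(-tt / scale) / norm, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MealConfig:
    """Parametric postprandial forcing curves.

    The defaults emulate a standard mixed-meal tolerance test for a
    ~75-kg adult: ~70 g of glucose (900 mg/kg appearing in plasma after
    first-pass extraction), plasma insulin peaking ~60 min after the meal
    and relaxing back to basal within the 6-h window, EGP suppressed to
    roughly a third of basal near the insulin peak, and negligible renal
    excretion (plasma glucose stays below the renal threshold).
    """

    dose: float = 900.0            # mg/kg, total Ra integral
    ra_shape: float = 2.5          # gamma shape of the appearance curve
    ra_scale: float = 35.0         # min, gamma scale (peak at (shape-1)*scale)
    insulin_amp: float = 275.0     # pmol/l, peak increment above basal
    insulin_peak_min: float = 60.0
    insulin_shape: float = 3.0
    egp_suppression: float = 1.35  # mg/kg/min, max suppression depth
    egp_peak_min: float = 90.0
    egp_shape: float = 2.0
    Ib: float = 25.0               # pmol/l, basal plasma insulin
    EGP_b: float = 2.783008509313  # mg/kg/min, basal EGP

    def __post_init__(self) -> None:
        for name in ("ra_shape", "ra_scale", "insulin_peak_min", "insulin_shape",
                     "egp_peak_min", "egp_shape"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"meal config {name} must be > 0")
        for name in ("dose", "insulin_amp", "egp_suppression", "Ib", "EGP_b"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"meal config {name} must be >= 0")


def parametric_meal_forcings(config: MealConfig | None = None) -> ForcingSet:
    """Build a :class:`ForcingSet` of smooth parametric meal curves.

    Insulin and EGP-suppression are unit-peak gamma pulses; Ra is a gamma
    density scaled so its integral over [0, inf) equals ``config.dose``.
    EGP is floored at zero.  With all amplitudes zero this reduces to a
    basal day: I = Ib, Ra = 0, EGP = EGP_b, E = 0.
    """
    cfg = config or MealConfig()

    def insulin(t):
        return cfg.Ib + cfg.insulin_amp * _gamma_pulse(t, cfg.insulin_peak_min, cfg.insulin_shape)

    def egp(t):
        return np.maximum(cfg.EGP_b - cfg.egp_suppression * _gamma_pulse(t, cfg.egp_peak_min, cfg.egp_shape), 0.0)

    def ra(t):
        return cfg.dose * _gamma_density(t, cfg.ra_shape, cfg.ra_scale)

    return ForcingSet(
        I=ParametricSignal(insulin, "insulin"),
        EGP=ParametricSignal(egp, "EGP"),
        Ra=ParametricSignal(ra, "Ra"),
        E=ConstantSignal(0.0, "E"),
        Ib=cfg.Ib,
    )


def default_meal_forcings(params: ParameterSet, **overrides) -> ForcingSet:
    """The packaged 6-h meal: parametric curves anchored at the basal
    operating point of ``params``."""
    return parametric_meal_forcings(
        MealConfig(Ib=params.Ib, EGP_b=params.EGP_b, **overrides))


def basal_forcings(params: ParameterSet) -> ForcingSet:
    """Constant basal-day forcings consistent with a parameter set."""
    return ForcingSet(
        I=ConstantSignal(params.Ib, "insulin"),
        EGP=ConstantSignal(params.EGP_b, "EGP"),
        Ra=ConstantSignal(0.0, "Ra"),
        E=ConstantSignal(0.0, "E"),
        Ib=params.Ib,
    )
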