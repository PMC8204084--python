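"""Full model assembly, steady-state initialization, and derived metrics.

The coupled state vector is

    [Gp, Gt, INS, INSfbf, GLUT4m, Gluin, G6P]

with plasma insulin, EGP, Ra and E supplied as forcing signals.  Three
blood-flow modes select how the adipose insulin effect sees blood flow:
``in_vitro`` (bfe_f = 0, isolated adipocytes), ``constant_bf`` (a fixed
in-situ scaling, used when no blood-flow data exist — the default for
meal simulations) and ``dynamic_bf`` (the INSfbf-driven model).

``adipocyte_detail=False`` switches to the reduced variant without the
intracellular Gluin/G6P states, in which adipose uptake is simply
proportional to INSfe*Gt (matched to the same basal uptake).  This
variant cannot reproduce the early adipose uptake peak and exists for
exactly that comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import adipocyte as adi
from . import organ_uptake as org
from . import whole_body as wb
from .blood_flow import (
    BloodFlowParams,
    blood_flow as _blood_flow,
    blood_flow_effect as _blood_flow_effect,
    bloodflow_insulin_rhs as _bloodflow_insulin_rhs,
)
from .errors import ConfigurationError, InitializationError, SimulationError
from .params import ParameterSet

__all__ = [
    "STATE_COLUMNS",
    "FLUX_COLUMNS",
    "MODES",
    "Model",
    "Trajectory",
    "UptakeSummary",
    "steady_state_initialize",
    "simulate",
    "auc",
    "uptake_fractions",
    "calibrate_basal",
]

STATE_COLUMNS = ["Gp", "Gt", "INS", "INSfbf", "GLUT4m", "Gluin", "G6P"]
FLUX_COLUMNS = ["Uidm", "Uidl", "Uidf", "Uii", "Uid",
                "Vin", "Vout", "VG6P", "INSfe", "bf_f", "bfe_f"]
MODES = ("in_vitro", "constant_bf", "dynamic_bf")


@dataclass
class Model:
    """The assembled multi-level model for one parameterization and mode."""

    params: ParameterSet
    mode: str = "constant_bf"
    adipocyte_detail: bool = True
    glut4_driver: adi.Glut4Driver | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.glut4_driver is None:
            self.glut4_driver = adi.HillGlut4Driver.from_params(self.params)
        p = self.params
        self._gx = wb.GlucoseExchangeParams.from_params(p)
        self._ins = org.InterstitialInsulinParams.from_params(p)
        self._mus = org.MuscleParams.from_params(p)
        self._liv = org.LiverParams.from_params(p)
        self._adip = adi.AdipocyteParams.from_params(p)
        self._eff = adi.InsulinEffectParams.from_params(p)
        self._bf = BloodFlowParams.from_params(p)
        # reduced-variant coefficient: matches the detailed model's basal
        # adipose uptake at the basal operating point
        self._m2a_coeff = p.part_f * (p.p4 - p.p3 * p.Gluin_b / p.Gt_b) if p.Gt_b > 0 else 0.0

    # -- pointwise algebra ---------------------------------------------------

    def _bfe(self, INSfbf: float) -> float:
        if self.mode == "in_vitro":
            return 0.0
        if self.mode == "constant_bf":
            return self.params.bfe_const
        bf_f = _blood_flow(INSfbf, self._bf)
        return _blood_flow_effect(bf_f, INSfbf + self._bf.INSoffset, self._bf,
                                  warn_negative=False)

    def fluxes(self, t: float, y: np.ndarray, forcings: wb.ForcingSet) -> dict[str, float]:
        """All reaction rates at one instant, recomputable from the state."""
        Gp, Gt, INS, INSfbf, GLUT4m, Gluin, G6P = y
        f = forcings.at(t)
        bfe = self._bfe(INSfbf)
        if self.mode == "dynamic_bf":
            bf_f = _blood_flow(INSfbf, self._bf)
        else:
            bf_f = self.params.bf_b
        INSfe = adi.insulin_effect(GLUT4m, bfe, self._eff)
        Uidm = org.muscle_uptake(Gt, INS, self._mus)
        Uidl = org.liver_uptake(Gt, INS, self._liv, self._mus)
        if self.adipocyte_detail:
            Vin, Vout = adi.transport_fluxes(Gt, Gluin, INSfe, self._adip)
            Uidf = adi.net_adipose_uptake(Vin, Vout, self._adip.part_f)
            VG6P = adi.phosphorylation_rate(Gluin, G6P, self._adip)
        else:
            Vin = Vout = VG6P = 0.0
            Uidf = self._m2a_coeff * INSfe * Gt
        Uid = wb.total_insulin_dependent_uptake(Uidm, Uidl, Uidf)
        return {
            "I": f.I, "EGP": f.EGP, "Ra": f.Ra, "E": f.E,
            "Uidm": Uidm, "Uidl": Uidl, "Uidf": Uidf, "Uii": self.params.Uii,
            "Uid": Uid, "Vin": Vin, "Vout": Vout, "VG6P": VG6P,
            "INSfe": INSfe, "bf_f": bf_f, "bfe_f": bfe,
        }

    def rhs(self, t: float, y: np.ndarray, forcings: wb.ForcingSet) -> np.ndarray:
        Gp, Gt, INS, INSfbf, GLUT4m, Gluin, G6P = y
        fx = self.fluxes(t, y, forcings)
        dGt, dGp = wb.glucose_rhs(
            wb.GlucoseState(Gp=Gp, Gt=Gt), fx["Uid"],
            wb.ForcingValues(I=fx["I"], EGP=fx["EGP"], Ra=fx["Ra"], E=fx["E"]),
            self._gx,
        )
        dINS = org.interstitial_insulin_rhs(INS, fx["I"], forcings.Ib, self._ins)
        dINSfbf = _bloodflow_insulin_rhs(INSfbf, fx["I"], forcings.Ib, self._bf)
        dGLUT4m = self.glut4_driver.rhs(GLUT4m, INS)
        if self.adipocyte_detail:
            dGluin, dG6P = adi.adipocyte_rhs(
                adi.AdipocyteState(Gluin=Gluin, G6P=G6P), Gt, fx["INSfe"], self._adip
            )
        else:
            dGluin = dG6P = 0.0
        return np.array([dGp, dGt, dINS, dINSfbf, dGLUT4m, dGluin, dG6P])

    def initial_guess(self) -> np.ndarray:
        p = self.params
        return np.array([p.Gp_b, p.Gt_b, 0.0, 0.0, self.glut4_driver.basal(),
                         p.Gluin_b, p.G6P_b])


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Timestamped states and derived fluxes on a strictly increasing grid."""

    frame: pd.DataFrame
    mode: str = "constant_bf"

    def __post_init__(self) -> None:
        t = self.frame["time_min"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ConfigurationError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise ConfigurationError(f"unknown trajectory column {name!r}")
        return self.frame[name].to_numpy()

    def interpolate(self, name: str, t) -> np.ndarray:
        """Piecewise-linear interpolation of a column onto arbitrary times."""
        return np.interp(t, self.times, self.column(name))


@dataclass
class UptakeSummary:
    """Per-organ 6-h uptake AUCs and their fractions of the total."""

    auc: dict[str, float]
    fraction: dict[str, float]
    window: tuple[float, float] = (0.0, 360.0)

    organs = ("muscle", "liver", "adipose", "other")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def calibrate_basal(params: ParameterSet, mode: str = "constant_bf") -> ParameterSet:
    """Close the basal balance so (Gp_b, Gt_b) is an exact steady state.

    Given the uptake kinetics, recompute the dependent basal quantities:
    the adipocyte fixed point (Gluin_b, G6P_b) at basal insulin effect,
    basal EGP (= Uii + basal Uid, since production must balance disposal
    at rest) and the tissue->plasma exchange rate kgp2 (so the exchange
    flux balances basal Uid at the printed glucose levels).  Users who
    modify uptake parameters should re-run this closure.
    """
    p = params
    driver = adi.HillGlut4Driver.from_params(p)
    bfe = {"in_vitro": 0.0, "constant_bf": p.bfe_const, "dynamic_bf": 0.0}[mode]
    eff = adi.InsulinEffectParams.from_params(p)
    insfe_b = adi.insulin_effect(driver.basal(), bfe, eff)
    adip = adi.AdipocyteParams.from_params(p)
    ss = adi.adipocyte_steady_state(p.Gt_b, insfe_b, adip)
    vin, vout = adi.transport_fluxes(p.Gt_b, ss.Gluin, insfe_b, adip)
    uidf_b = adi.net_adipose_uptake(vin, vout, p.part_f)
    uidm_b = org.muscle_uptake(p.Gt_b, 0.0, org.MuscleParams.from_params(p))
    uidl_b = org.liver_uptake(p.Gt_b, 0.0, org.LiverParams.from_params(p),
                              org.MuscleParams.from_params(p))
    uid_b = uidm_b + uidl_b + uidf_b
    kgp2 = (p.kgp1 * p.Gp_b - p.conv * uid_b) / p.Gt_b
    if kgp2 <= 0:
        raise ConfigurationError(
            "basal closure failed: kgp1*Gp_b must exceed basal Uid "
            f"(kgp1*Gp_b={p.kgp1 * p.Gp_b:.3g}, Uid_b={uid_b:.3g})")
    return p.replace(EGP_b=p.Uii + uid_b, kgp2=kgp2,
                     Gluin_b=ss.Gluin, G6P_b=ss.G6P)


def steady_state_initialize(
    model: Model,
    forcings: wb.ForcingSet | None = None,
    *,
    horizon: float = 5000.0,
    tol: float = 1e-8,
    literal: bool = False,
) -> np.ndarray:
    """Find the basal steady state of the full system.

    Long-horizon integration under constant basal forcings, followed by a
    Newton polish and a residual check (< ``tol`` on every component).
    With ``literal=True`` the glucose states are pinned to the printed
    initial values Gp = Gp_b, Gt = Gt_b and only the remaining states are
    equilibrated conditional on them.
    """
    p = model.params
    if forcings is None:
        forcings = wb.basal_forcings(p)

    if literal:
        y = model.initial_guess()
        bfe = model._bfe(0.0)
        insfe = adi.insulin_effect(model.glut4_driver.basal(), bfe, model._eff)
        if model.adipocyte_detail:
            ss = adi.adipocyte_steady_state(p.Gt_b, insfe, model._adip)
            y[5], y[6] = ss.Gluin, ss.G6P
        return y

    fun = lambda t, y: model.rhs(t, y, forcings)
    sol = solve_ivp(fun, (0.0, horizon), model.initial_guess(),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise InitializationError(f"steady-state integration failed: {sol.message}")
    y = sol.y[:, -1]
    polish = root(lambda v: model.rhs(0.0, v, forcings), y, method="hybr", tol=1e-12)
    if polish.success:
        y = polish.x
    resid = np.abs(model.rhs(0.0, y, forcings))
    if resid.max() > tol:
        raise InitializationError(
            f"steady state did not converge within horizon {horizon} min: "
            f"max residual {resid.max():.3e}"
        )
    return y


def simulate(
    params: ParameterSet | Model,
    forcings: wb.ForcingSet,
    t_grid: np.ndarray | None = None,
    mode: str = "constant_bf",
    *,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    adipocyte_detail: bool = True,
) -> Trajectory:
    """Integrate the coupled system and return a :class:`Trajectory`.

    A stiff-capable integrator (LSODA) solves the system at relative
    tolerance ``rtol`` / absolute ``atol``; the solution is sampled onto
    ``t_grid`` (default: a uniform 1-min grid over 0-360 min).  The run
    is deterministic given its inputs.
    """
    model = params if isinstance(params, Model) else Model(
        params, mode=mode, adipocyte_detail=adipocyte_detail)
    if t_grid is None:
        t_grid = np.arange(0.0, 361.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ConfigurationError("t_grid must be a strictly increasing 1-D grid")
    if y0 is None:
        y0 = steady_state_initialize(model, wb.basal_forcings(model.params))
    sol = solve_ivp(
        lambda t, y: model.rhs(t, y, forcings),
        (t_grid[0], t_grid[-1]), np.asarray(y0, dtype=float),
        method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed at t={sol.t[-1] if sol.t.size else t_grid[0]:g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = [STATE_COLUMNS[i] for i in range(len(STATE_COLUMNS))
               if not np.all(np.isfinite(sol.y[i]))]
        raise SimulationError(f"non-finite state(s) in solution: {bad}")
    rows = []
    for k, t in enumerate(sol.t):
        fx = model.fluxes(t, sol.y[:, k], forcings)
        rows.append(fx)
    frame = pd.DataFrame(rows)
    for i, name in enumerate(STATE_COLUMNS):
        frame[name] = sol.y[i]
    frame.insert(0, "time_min", sol.t)
    return Trajectory(frame=frame, mode=model.mode)


def auc(values: np.ndarray, times: np.ndarray, window: tuple[float, float] | None = None) -> float:
    """Composite trapezoid integral of a sampled curve over a time window."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        values, times = values[mask], times[mask]
    if times.size < 2:
        raise ConfigurationError("AUC needs at least 2 points in the window")
    return float(np.trapezoid(values, times))


def uptake_fractions(traj: Trajectory, window: tuple[float, float] = (0.0, 360.0)) -> UptakeSummary:
    """Per-organ AUC of uptake over the window and fractions of the total.

    Organs: muscle (Uidm), liver (Uidl), adipose (Uidf), other (the
    constant insulin-independent uptake Uii).  Fractions sum to 1; a
    negative adipose AUC is reported signed with a warning.
    """
    t = traj.times
    if t[0] > window[0] or t[-1] < window[1]:
        raise ConfigurationError(
            f"trajectory [{t[0]:g}, {t[-1]:g}] does not cover the window {window}")
    aucs = {
        "muscle": auc(traj.column("Uidm"), t, window),
        "liver": auc(traj.column("Uidl"), t, window),
        "adipose": auc(traj.column("Uidf"), t, window),
        "other": auc(traj.column("Uii"), t, window),
    }
    total = sum(aucs.values())
    if total == 0:
        raise ConfigurationError("total uptake AUC is zero; fractions undefined")
    if aucs["adipose"] < 0:
        warnings.warn("adipose uptake AUC is negative; reporting signed fraction",
                      RuntimeWarning, stacklevel=2)
    fractions = {k: v / total for k, v in aucs.items()}
    return UptakeSummary(auc=aucs, fraction=fractions, window=window)
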