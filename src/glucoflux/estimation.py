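"""Weighted least-squares calibration, chi-square testing, and envelopes.

The cost is the conventional SEM-weighted sum of squares

    v(p) = sum_i ((y_i - yhat_i(p)) / SEM_i)^2

compared against the inverse cumulative chi-square quantile at a chosen
significance level: a model whose best cost exceeds the threshold is
rejected.  Degrees of freedom default to the number of data points N;
reducing df by the number of estimated parameters is an explicit option
(used in the blood-flow factorial test).

Fitting is a two-stage global-then-local search (differential evolution
followed by a Nelder–Mead polish), multi-started from a seeded sequence.
Every parameter vector evaluated during the search that passes the
chi-square test is archived; the archive is the *acceptable set*, and
pointwise min/max of simulations across it give the prediction
uncertainty envelope.

Organ-fraction penalties: a smoothly increasing punishment is added when
the liver's share of total 6-h uptake leaves [40, 50]% or the constant
"other organs" share leaves [18, 30]% (a quadratic hinge that is zero
inside the band, with configurable steepness).

The modular structure is exploited for sub-model fitting: the adipose
(or muscle) sub-model can be fitted separately with interstitial glucose
Gt treated as a fixed input signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution, minimize

from . import adipocyte as adi
from . import organ_uptake as org
from .errors import ConfigurationError, GlucofluxError
from .params import ParameterSet
from .simulation import Trajectory, UptakeSummary
from .whole_body import ForcingSet, Signal

__all__ = [
    "Dataset",
    "FitResult",
    "PenaltyConfig",
    "cost",
    "cost_from_trajectory",
    "chi2_threshold",
    "chi2_test",
    "fraction_penalty",
    "fit",
    "uncertainty_envelope",
    "adipose_submodel_simulator",
    "muscle_submodel_simulator",
    "COST_SENTINEL",
    "DEFAULT_SCOPE_FREE",
]

#: Large finite penalty returned when a candidate simulation fails, so
#: global optimizers keep going instead of crashing.
COST_SENTINEL = 1e12

#: Default free parameters per fitting scope.
DEFAULT_SCOPE_FREE: dict[str, tuple[str, ...]] = {
    "adipose": ("p3", "p4", "VG6Pmax"),
    "muscle": ("part_m", "VX", "Km"),
    "full": ("part_m", "part_l", "part_f"),
}


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Observed uptake time-series: (time, observable, value, SEM) points."""

    frame: pd.DataFrame  # columns: time_min, observable, value, sem

    REQUIRED = ("time_min", "observable", "value", "sem")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"dataset missing column(s): {missing}")
        sems = self.frame["sem"].to_numpy(dtype=float)
        if not np.all(np.isfinite(sems)) or np.any(sems <= 0):
            bad = int(np.argmin(sems)) + 1
            raise ConfigurationError(f"dataset SEMs must be > 0 (first offending row: {bad})")

    @property
    def N(self) -> int:
        return len(self.frame)

    @classmethod
    def from_arrays(cls, times, observable: str | Sequence[str], values, sems) -> "Dataset":
        times = np.asarray(times, dtype=float)
        obs = [observable] * len(times) if isinstance(observable, str) else list(observable)
        return cls(pd.DataFrame({
            "time_min": times, "observable": obs,
            "value": np.asarray(values, dtype=float),
            "sem": np.asarray(sems, dtype=float),
        }))

    def with_sem_floor(self, floor: float | None = None) -> "Dataset":
        """Raise unusually narrow SEMs to the dataset mean uncertainty.

        Points with SEM below ``floor`` (default: half the mean SEM) are
        assigned the mean SEM — the preprocessing used when a few points
        report implausibly tight uncertainties.
        """
        sems = self.frame["sem"].to_numpy(dtype=float).copy()
        mean = float(sems.mean())
        cutoff = mean / 2 if floor is None else floor
        sems[sems < cutoff] = mean
        out = self.frame.copy()
        out["sem"] = sems
        return Dataset(out)


# ---------------------------------------------------------------------------
# cost and chi-square machinery
# ---------------------------------------------------------------------------

def cost_from_trajectory(dataset: Dataset, traj: Trajectory) -> float:
    """v = sum(((y - yhat)/SEM)^2) with yhat linearly interpolated from
    the dense simulation output at the dataset times."""
    total = 0.0
    for obs, grp in dataset.frame.groupby("observable", sort=False):
        yhat = traj.interpolate(str(obs), grp["time_min"].to_numpy(dtype=float))
        r = (grp["value"].to_numpy(dtype=float) - yhat) / grp["sem"].to_numpy(dtype=float)
        total += float(np.dot(r, r))
    return total


def cost(params, dataset: Dataset, simulator: Callable[..., Trajectory]) -> float:
    """Evaluate the weighted least-squares cost for one candidate.

    ``simulator`` maps the candidate parameters to a Trajectory exposing
    every observable in the dataset.  A failed simulation yields the
    documented finite sentinel rather than an exception.
    """
    try:
        traj = simulator(params)
    except (GlucofluxError, ValueError, FloatingPointError):
        return COST_SENTINEL
    v = cost_from_trajectory(dataset, traj)
    return v if math.isfinite(v) else COST_SENTINEL


def chi2_threshold(df: int, alpha: float) -> float:
    """(1 - alpha) quantile of the chi-square distribution with df dof."""
    if df < 1 or int(df) != df:
        raise ConfigurationError(f"degrees of freedom must be a positive integer, got {df}")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def chi2_test(cost_value: float, df: int, alpha: float, *, n_estimated: int = 0) -> bool:
    """Accept the model iff cost < threshold (strict inequality at the
    boundary).  ``n_estimated`` optionally reduces df by the number of
    estimated parameters (the convention used in the factorial test)."""
    eff_df = df - n_estimated
    return cost_value < chi2_threshold(eff_df, alpha)


@dataclass(frozen=True)
class PenaltyConfig:
    """Bands and steepness for the ad-hoc organ-fraction penalties."""

    liver_band: tuple[float, float] = (0.40, 0.50)
    other_band: tuple[float, float] = (0.18, 0.30)
    weight: float = 1e4  # cost units per (fraction)^2 outside the band


def _hinge(x: float, band: tuple[float, float]) -> float:
    lo, hi = band
    if x < lo:
        return (lo - x) ** 2
    if x > hi:
        return (x - hi) ** 2
    return 0.0


def fraction_penalty(summary: UptakeSummary, config: PenaltyConfig | None = None) -> float:
    """Quadratic-hinge penalty on the liver and "other" uptake shares.

    Zero inside the bands, continuous with continuous derivative at the
    band edges, and monotonically increasing with distance outside.
    """
    cfg = config or PenaltyConfig()
    return cfg.weight * (
        _hinge(summary.fraction["liver"], cfg.liver_band)
        + _hinge(summary.fraction["other"], cfg.other_band)
    )


# ---------------------------------------------------------------------------
# sub-model simulators (module-scoped fitting)
# ---------------------------------------------------------------------------

def adipose_submodel_simulator(
    base_params: ParameterSet,
    Gt_signal: Signal,
    forcings: ForcingSet,
    *,
    mode: str = "constant_bf",
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Callable[[ParameterSet], Trajectory]:
    """Simulator for the adipose sub-model with Gt as a fixed input signal.

    States: INS (drives GLUT4), GLUT4m, Gluin, G6P.  Returns a callable
    mapping a ParameterSet to a Trajectory with columns Uidf, INSfe,
    Gluin, G6P, VG6P — the adipose-scope fitting backend.
    """
    grid = np.arange(0.0, 361.0) if t_grid is None else np.asarray(t_grid, dtype=float)

    def run(p: ParameterSet) -> Trajectory:
        ins_par = org.InterstitialInsulinParams.from_params(p)
        adip = adi.AdipocyteParams.from_params(p)
        eff = adi.InsulinEffectParams.from_params(p)
        driver = adi.HillGlut4Driver.from_params(p)
        bfe = 0.0 if mode == "in_vitro" else p.bfe_const
        insfe_b = adi.insulin_effect(driver.basal(), bfe, eff)
        ss = adi.adipocyte_steady_state(float(Gt_signal(grid[0])), insfe_b, adip)
        y0 = np.array([0.0, driver.basal(), ss.Gluin, ss.G6P])

        def rhs(t, y):
            INS, GLUT4m, Gluin, G6P = y
            I = float(forcings.I(t))
            insfe = adi.insulin_effect(GLUT4m, bfe, eff)
            gt = float(Gt_signal(t))
            dGluin, dG6P = adi.adipocyte_rhs(
                adi.AdipocyteState(Gluin=Gluin, G6P=G6P), gt, insfe, adip)
            return [
                org.interstitial_insulin_rhs(INS, I, forcings.Ib, ins_par),
                driver.rhs(GLUT4m, INS),
                dGluin,
                dG6P,
            ]

        sol = solve_ivp(rhs, (grid[0], grid[-1]), y0, method="LSODA",
                        t_eval=grid, rtol=rtol, atol=atol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise GlucofluxError(f"adipose sub-model integration failed: {sol.message}")
        INS, GLUT4m, Gluin, G6P = sol.y
        gt = np.asarray(Gt_signal(sol.t), dtype=float)
        insfe = np.array([adi.insulin_effect(g, bfe, eff) for g in GLUT4m])
        vin = adip.p4 * gt * insfe
        vout = adip.p3 * Gluin * insfe
        frame = pd.DataFrame({
            "time_min": sol.t,
            "INS": INS, "GLUT4m": GLUT4m, "Gluin": Gluin, "G6P": G6P,
            "Gt": gt, "INSfe": insfe, "Vin": vin, "Vout": vout,
            "Uidf": adip.part_f * (vin - vout),
            "VG6P": np.array([adi.phosphorylation_rate(g, s, adip)
                              for g, s in zip(Gluin, G6P)]),
        })
        return Trajectory(frame=frame, mode=mode)

    return run


def muscle_submodel_simulator(
    base_params: ParameterSet,
    Gt_signal: Signal,
    forcings: ForcingSet,
    *,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Callable[[ParameterSet], Trajectory]:
    """Simulator for the muscle sub-model (state: INS) with fixed Gt input."""
    grid = np.arange(0.0, 361.0) if t_grid is None else np.asarray(t_grid, dtype=float)

    def run(p: ParameterSet) -> Trajectory:
        ins_par = org.InterstitialInsulinParams.from_params(p)
        mus = org.MuscleParams.from_params(p)

        def rhs(t, y):
            return [org.interstitial_insulin_rhs(y[0], float(forcings.I(t)), forcings.Ib, ins_par)]

        sol = solve_ivp(rhs, (grid[0], grid[-1]), [0.0], method="LSODA",
                        t_eval=grid, rtol=rtol, atol=atol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise GlucofluxError(f"muscle sub-model integration failed: {sol.message}")
        INS = sol.y[0]
        gt = np.asarray(Gt_signal(sol.t), dtype=float)
        frame = pd.DataFrame({
            "time_min": sol.t, "INS": INS, "Gt": gt,
            "Uidm": np.array([org.muscle_uptake(g, i, mus) for g, i in zip(gt, INS)]),
        })
        return Trajectory(frame=frame, mode="constant_bf")

    return run


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: dict[str, float]          # best-fit values of the free parameters
    cost: float
    df: int
    alpha: float
    threshold: float
    accepted: bool
    acceptable_set: pd.DataFrame      # archived vectors passing the test (+ cost)
    seed: int
    restarts: int
    n_evaluations: int
    stage_costs: list[float] = field(default_factory=list)


def fit(
    dataset: Dataset,
    simulator: Callable[[ParameterSet], Trajectory],
    free_names: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    base_params: ParameterSet,
    *,
    restarts: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    df: int | None = None,
    n_estimated: int = 0,
    penalty: Callable[[Trajectory], float] | None = None,
    de_popsize: int = 10,
    de_maxiter: int = 40,
    polish_maxiter: int = 300,
    archive_limit: int = 5000,
) -> FitResult:
    """Two-stage global-then-local weighted-least-squares fit.

    Stage 1 is a population-based global search (differential evolution)
    per restart, each with its own seed derived from ``seed``; stage 2 is
    a Nelder–Mead polish from the overall best point.  The objective is
    the chi-square cost plus any configured penalty; candidates whose
    simulation fails receive a large finite sentinel cost augmented by
    their distance to the bounds box.  Every evaluated vector passing the
    chi-square test is archived as the acceptable set.
    """
    free_names = list(free_names)
    missing = [n for n in free_names if n not in bounds]
    if missing:
        raise ConfigurationError(f"no bounds supplied for free parameter(s): {missing}")
    box = [tuple(map(float, bounds[n])) for n in free_names]
    for n, (lo, hi) in zip(free_names, box):
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ConfigurationError(f"invalid bounds for {n}: ({lo}, {hi})")
    eff_df = (dataset.N if df is None else df)
    threshold = chi2_threshold(eff_df - n_estimated, alpha)

    archive_x: list[np.ndarray] = []
    archive_c: list[float] = []
    n_eval = 0

    lo_arr = np.array([b[0] for b in box])
    hi_arr = np.array([b[1] for b in box])

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        x = np.asarray(x, dtype=float)
        outside = np.maximum(lo_arr - x, 0.0) + np.maximum(x - hi_arr, 0.0)
        if outside.any():
            return COST_SENTINEL + float(np.sum(outside**2))
        try:
            p = base_params.replace(**dict(zip(free_names, x)))
            traj = simulator(p)
        except (GlucofluxError, ValueError, FloatingPointError):
            return COST_SENTINEL
        v = cost_from_trajectory(dataset, traj)
        if penalty is not None:
            v += penalty(traj)
        if not math.isfinite(v):
            return COST_SENTINEL
        if v < threshold and len(archive_x) < archive_limit:
            archive_x.append(x.copy())
            archive_c.append(v)
        return v

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(max(restarts, 1))]

    best_x, best_c = None, np.inf
    stage_costs: list[float] = []
    for rs in child_seeds:
        res = differential_evolution(
            objective, box, seed=rs, popsize=de_popsize, maxiter=de_maxiter,
            tol=1e-8, init="sobol", polish=False, updating="deferred", workers=1,
        )
        stage_costs.append(float(res.fun))
        if res.fun < best_c:
            best_x, best_c = np.asarray(res.x, dtype=float), float(res.fun)
    if best_x is None or not math.isfinite(best_c):
        raise GlucofluxError("all optimization starts failed")

    local = minimize(objective, best_x, method="Nelder-Mead",
                     options={"maxiter": polish_maxiter, "xatol": 1e-8, "fatol": 1e-10})
    if math.isfinite(local.fun) and local.fun <= best_c:
        best_x, best_c = np.clip(local.x, lo_arr, hi_arr), float(local.fun)
        best_c = objective(best_x)  # re-evaluate at clipped point

    arch = pd.DataFrame(archive_x, columns=free_names)
    arch["cost"] = archive_c
    arch = arch.sort_values("cost", kind="stable").reset_index(drop=True)
    return FitResult(
        params=dict(zip(free_names, map(float, best_x))),
        cost=float(best_c),
        df=eff_df - n_estimated,
        alpha=alpha,
        threshold=threshold,
        accepted=chi2_test(best_c, eff_df, alpha, n_estimated=n_estimated),
        acceptable_set=arch,
        seed=seed,
        restarts=restarts,
        n_evaluations=n_eval,
        stage_costs=stage_costs,
    )


# ---------------------------------------------------------------------------
# uncertainty envelope
# ---------------------------------------------------------------------------

def uncertainty_envelope(
    acceptable_set: pd.DataFrame,
    simulator: Callable[[ParameterSet], Trajectory],
    columns: Sequence[str],
    base_params: ParameterSet,
    *,
    max_members: int | None = None,
) -> pd.DataFrame:
    """Pointwise min/max bands over simulations of the acceptable set.

    Each archived parameter vector is simulated and, per requested
    column, the running elementwise min and max are kept.  Adding a
    member can only widen or preserve the band, and a singleton set
    collapses the band onto that trajectory.
    """
    if len(acceptable_set) == 0:
        raise ConfigurationError(
            "acceptable set is empty; re-run the optimization from a wider "
            "variety of starting guesses to populate it")
    free_names = [c for c in acceptable_set.columns if c != "cost"]
    members = acceptable_set if max_members is None else acceptable_set.head(max_members)
    mins: dict[str, np.ndarray] = {}
    maxs: dict[str, np.ndarray] = {}
    times = None
    for _, row in members.iterrows():
        p = base_params.replace(**{n: float(row[n]) for n in free_names})
        traj = simulator(p)
        if times is None:
            times = traj.times
        for col in columns:
            y = traj.column(col)
            if col not in mins:
                mins[col], maxs[col] = y.copy(), y.copy()
            else:
                np.minimum(mins[col], y, out=mins[col])
                np.maximum(maxs[col], y, out=maxs[col])
    out = {"time_min": times}
    for col in columns:
        out[f"{col}_min"] = mins[col]
        out[f"{col}_max"] = maxs[col]
    return pd.DataFrame(out)
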