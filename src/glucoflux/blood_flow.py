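"""Adipose blood-flow dynamics and their AND-gate effect on glucose uptake.

Insulin reaches the adipose blood-flow pathway through the same two-rate
linear kinetics used for interstitial insulin::

    dINSfbf/dt = C2bf*(I - Ib) - C1bf*INSfbf

Blood flow responds to bradykinin directly and to insulin via INSfbf::

    bf_f = (be + kbf*(INSfbf + INSoffset)) * bradykinin

with ``bradykinin`` = 1 in its absence and an elevated multiplier when
present (2.2 in the meal-scale preset; 3500 in the hand-estimated
factorial preset).  The resulting effect on uptake is the product of the
flow excursion and the insulin excursion::

    bfe_f = (bf_f - bf_b) * (INSfbf - INS_b) * p_bf

This is an AND gate: the effect vanishes whenever either flow or insulin
sits at its basal value, which is why raising blood flow alone (e.g., a
bradykinin infusion) leaves glucose uptake unchanged while bradykinin
plus insulin outperforms insulin alone.

Insulin infusion in the factorial experiment is represented by raising
``INSoffset`` from 0.  Because INSoffset is an offset on the pathway
insulin concentration, the effective insulin INSfbf + INSoffset enters
both the flow expression (as written above) and the insulin factor of
``bfe_f`` — otherwise an infusion modeled purely through INSoffset could
never open the gate.  The scenario layer below passes that effective
value into :func:`blood_flow_effect`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .adipocyte import (
    AdipocyteParams,
    HillGlut4Driver,
    InsulinEffectParams,
    adipocyte_steady_state,
    insulin_effect,
    phosphorylation_rate,
)
from .errors import ConfigurationError
from .params import ParameterSet

__all__ = [
    "BloodFlowState",
    "BloodFlowParams",
    "SCENARIOS",
    "SCENARIO_PRESETS",
    "bloodflow_insulin_rhs",
    "blood_flow",
    "blood_flow_effect",
    "factorial_scenario",
]


@dataclass(frozen=True)
class BloodFlowState:
    """Blood-flow-pathway insulin in adipose tissue (pmol/l above basal)."""

    INSfbf: float


@dataclass(frozen=True)
class BloodFlowParams:
    C1bf: float
    C2bf: float
    be: float
    kbf: float
    INSoffset: float
    bradykinin: float
    bf_b: float
    p_bf: float
    INS_b: float

    def __post_init__(self) -> None:
        if self.C1bf <= 0 or self.C2bf <= 0:
            raise ConfigurationError("C1bf and C2bf must be > 0")
        if self.bradykinin < 1:
            raise ConfigurationError("bradykinin multiplier must be >= 1")

    @classmethod
    def from_params(cls, p: ParameterSet) -> "BloodFlowParams":
        return cls(C1bf=p.C1bf, C2bf=p.C2bf, be=p.be, kbf=p.kbf,
                   INSoffset=p.INSoffset, bradykinin=p.bradykinin,
                   bf_b=p.bf_b, p_bf=p.p_bf, INS_b=p.INS_b)


def bloodflow_insulin_rhs(INSfbf: float, I: float, Ib: float, params: BloodFlowParams) -> float:
    """dINSfbf/dt = C2bf*(I - Ib) - C1bf*INSfbf (same form as muscle INS)."""
    return params.C2bf * (I - Ib) - params.C1bf * INSfbf


def blood_flow(INSfbf: float, params: BloodFlowParams) -> float:
    """bf_f = (be + kbf*(INSfbf + INSoffset)) * bradykinin."""
    return (params.be + params.kbf * (INSfbf + params.INSoffset)) * params.bradykinin


def blood_flow_effect(bf_f: float, INSfbf_eff: float, params: BloodFlowParams,
                      *, warn_negative: bool = True) -> float:
    """bfe_f = (bf_f - bf_b)*(INSfbf_eff - INS_b)*p_bf.

    ``INSfbf_eff`` is the effective pathway insulin (INSfbf + INSoffset).
    The product is passed through unclamped; a negative value (insulin
    below basal while flow is elevated, or vice versa) triggers a
    diagnostic warning.
    """
    bfe = (bf_f - params.bf_b) * (INSfbf_eff - params.INS_b) * params.p_bf
    if warn_negative and bfe < 0:
        warnings.warn("blood-flow effect bfe_f is negative (one excursion below basal)",
                      RuntimeWarning, stacklevel=2)
    return bfe


# ---------------------------------------------------------------------------
# factorial scenario (bradykinin x insulin)
# ---------------------------------------------------------------------------

SCENARIOS = ("control", "bradykinin", "insulin", "bradykinin+insulin")

#: Named presets for the factorial experiment.  ``meal_bf`` uses the
#: physiological bradykinin multiplier 2.2; ``bradykinin_infusion`` the
#: hand-estimated multiplier 3500 with insulin infusion INSoffset = 7.
#: Both are kept as printed rather than reconciled.
SCENARIO_PRESETS: dict[str, dict[str, float]] = {
    "meal_bf": {"bradykinin": 2.2, "INSoffset": 7.0},
    "bradykinin_infusion": {"bradykinin": 3500.0, "INSoffset": 7.0},
}


def _scenario_steady_uptake(p: ParameterSet, bradykinin: float, insoffset: float) -> dict[str, float]:
    """Steady-state adipose uptake with Gt clamped at its basal value.

    Plasma insulin is at basal, so raw INSfbf = 0 and GLUT4m is basal;
    the infusion acts through INSoffset alone.
    """
    bf = BloodFlowParams(
        C1bf=p.C1bf, C2bf=p.C2bf, be=p.be, kbf=p.kbf, INSoffset=insoffset,
        bradykinin=bradykinin, bf_b=p.bf_b, p_bf=p.p_bf, INS_b=p.INS_b,
    )
    insfbf = 0.0
    bf_f = blood_flow(insfbf, bf)
    bfe = blood_flow_effect(bf_f, insfbf + insoffset, bf, warn_negative=False)
    eff = InsulinEffectParams.from_params(p)
    glut4_b = HillGlut4Driver.from_params(p).basal()
    insfe = insulin_effect(glut4_b, bfe, eff)
    adip = AdipocyteParams.from_params(p)
    ss = adipocyte_steady_state(p.Gt_b, insfe, adip)
    vg6p = phosphorylation_rate(ss.Gluin, ss.G6P, adip) if adip.p1 > 0 else 0.0
    uptake = adip.part_f * vg6p / adip.p1 if adip.p1 > 0 else 0.0
    return {
        "bradykinin": bradykinin,
        "INSoffset": insoffset,
        "bf_f": bf_f,
        "bfe_f": bfe,
        "INSfe": insfe,
        "uptake": uptake,
        "clearance": uptake / p.Gt_b,
    }


def factorial_scenario(
    params: ParameterSet,
    preset: str = "bradykinin_infusion",
    scenarios: tuple[str, ...] = SCENARIOS,
) -> pd.DataFrame:
    """Four-cell factorial table of steady-state adipose uptake.

    Each cell toggles the bradykinin multiplier and the insulin-infusion
    offset per the chosen preset; uptake and clearance are reported both
    raw and normalized to control = 100%.
    """
    if preset not in SCENARIO_PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {sorted(SCENARIO_PRESETS)}")
    brad = SCENARIO_PRESETS[preset]["bradykinin"]
    offs = SCENARIO_PRESETS[preset]["INSoffset"]
    cells = {
        "control": (1.0, 0.0),
        "bradykinin": (brad, 0.0),
        "insulin": (1.0, offs),
        "bradykinin+insulin": (brad, offs),
    }
    rows = []
    for name in scenarios:
        if name not in cells:
            raise ConfigurationError(f"unknown scenario {name!r}; choose from {sorted(cells)}")
        row = {"scenario": name}
        row.update(_scenario_steady_uptake(params, *cells[name]))
        rows.append(row)
    df = pd.DataFrame(rows)
    control = df.loc[df.scenario == "control", "uptake"]
    if len(control) == 1 and control.iloc[0] > 0:
        df["relative_uptake_percent"] = 100.0 * df["uptake"] / control.iloc[0]
        df["relative_clearance_percent"] = 100.0 * df["clearance"] / (control.iloc[0] / params.Gt_b)
    return df
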