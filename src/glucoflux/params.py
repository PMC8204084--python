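"""Parameter registry for the multi-level glucose-homeostasis model.

All rate constants and organ-partition parameters live in one flat,
validated :class:`ParameterSet`.  Names follow the field's symbols with two
deliberate renames to avoid a symbol collision: the glucose-exchange rate
constants are ``kgp1``/``kgp2`` (plasma->tissue and back) and the
interstitial-insulin rate constants are ``kins1``/``kins2`` (entry and
degradation) — in the original formulation both pairs are called k1/k2.

Units
-----
Glucose states are carried in mg/dl as printed by the source model; fluxes
are mg/kg/min.  A single conversion constant ``conv`` (default 1) scales
mass fluxes into concentration units for users who want to supply
distribution volumes.  Insulin concentrations are pmol/l.  Intracellular
adipocyte pools (Gluin, G6P) are in arbitrary model units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace as _dc_replace

from .errors import ConfigurationError

__all__ = [
    "ParameterSet",
    "DEFAULT_BOUNDS",
    "PARAM_SYMBOLS",
    "param_names",
]


@dataclass(frozen=True)
class ParameterSet:
    """Every model parameter, with packaged defaults.

    The defaults are the package's final-model parameterization: kinetic
    constants on physiological timescales, with the organ partition
    parameters (``part_m``, ``part_l``, ``part_f``), ``Uii`` and the basal
    closure values (``EGP_b``, ``kgp2``, ``Gluin_b``, ``G6P_b``) calibrated
    once so that (a) the basal state (Gp, Gt) = (178, 130) mg/dl is an
    exact steady state and (b) the 6-h meal response splits total glucose
    uptake as liver ~45%, muscle ~27%, adipose ~5%, other ~23%.
    """

    # --- plasma/interstitial glucose exchange -------------------------------
    kgp1: float = 0.065      # 1/min, plasma -> interstitial tissue
    kgp2: float = 0.075284549928  # 1/min, tissue -> plasma (basal closure)
    Uii: float = 1.0         # mg/kg/min, constant insulin-independent uptake
    conv: float = 1.0        # flux (mg/kg/min) -> concentration (mg/dl/min)

    # --- basal operating point ---------------------------------------------
    Gp_b: float = 178.0      # mg/dl, basal plasma glucose (printed initial value)
    Gt_b: float = 130.0      # mg/dl, basal interstitial glucose (printed initial value)
    Ib: float = 25.0         # pmol/l, basal plasma insulin
    EGP_b: float = 2.783008509313  # mg/kg/min, basal endogenous glucose production (closure)

    # --- shared interstitial insulin (muscle & liver pathway) ---------------
    kins1: float = 0.03      # 1/min, transport into interstitium
    kins2: float = 0.06      # 1/min, degradation

    # --- muscle uptake ------------------------------------------------------
    part_m: float = 1.2557047088  # dimensionless organ scaling
    V: float = 1.0           # mg/kg/min, basal utilization rate (shared with liver)
    VX: float = 0.02         # per pmol/l, insulin sensitivity (shared with liver)
    Km: float = 150.0        # mg/dl, Michaelis constant

    # --- liver uptake -------------------------------------------------------
    part_l: float = 1.7217264921  # dimensionless organ scaling
    Kl: float = 90.0         # mg/dl, Michaelis constant

    # --- adipocyte transport & metabolism -----------------------------------
    part_f: float = 2.4890714379  # dimensionless organ scaling
    p1: float = 6.0          # uptake-to-pool scaling
    p2: float = 0.03         # 1/min, G6P consumption rate constant
    p3: float = 0.02         # efflux transport parameter
    p4: float = 0.01         # influx transport parameter
    kgluin: float = 10.0     # Michaelis constant for phosphorylation substrate (a.u.)
    kG6P: float = 1.0        # product-inhibition constant (a.u.)
    VG6Pmax: float = 8.0     # maximal phosphorylation rate (a.u./min)
    Gluin_b: float = 62.707240933618  # a.u., basal intracellular glucose (closure)
    G6P_b: float = 14.673658024842  # a.u., basal glucose-6-phosphate (closure)

    # --- insulin effect on adipocyte transport ------------------------------
    nC: float = 1.0          # overall scaling
    k8: float = 1.0          # GLUT4 weight
    pf: float = 1.0          # transporter exponent
    GLUT1: float = 1.0       # a.u., constitutive membrane GLUT1
    bfe_const: float = 0.5   # blood-flow effect in constant mode (in situ scaling)

    # --- surrogate GLUT4 translocation driver -------------------------------
    glut4_basal: float = 0.1   # a.u., membrane GLUT4 at basal insulin
    glut4_amp: float = 5.0     # a.u., maximal insulin-stimulated increment
    glut4_ec50: float = 60.0   # pmol/l interstitial insulin at half-maximal response
    glut4_hill: float = 2.0    # Hill coefficient
    glut4_rate: float = 0.03   # 1/min, first-order translocation rate

    # --- blood flow (adipose) -----------------------------------------------
    C1bf: float = 0.07       # 1/min, clearance of blood-flow-pathway insulin
    C2bf: float = 0.021      # 1/min, entry of blood-flow-pathway insulin
    be: float = 1.0          # direct bradykinin effect on flow
    kbf: float = 0.1         # combined insulin-bradykinin flow sensitivity
    INSoffset: float = 0.0   # pmol/l, positivity offset (scenario: insulin infusion)
    bradykinin: float = 1.0  # multiplier; 1 absent, scenario value when present
    bf_b: float = 1.0        # basal blood flow
    p_bf: float = 0.05       # effect-scaling parameter
    INS_b: float = 0.0       # pmol/l, basal blood-flow-pathway insulin in adipose

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` on any contract violation."""
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} is not a finite number: {v!r}")
            if v < 0:
                raise ConfigurationError(f"parameter {f.name} must be >= 0, got {v}")
        for name in ("Km", "Kl", "kgluin", "kG6P", "kins1", "kins2", "C1bf", "C2bf"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name} must be > 0")
        if self.bradykinin < 1:
            raise ConfigurationError("bradykinin multiplier must be >= 1")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a validated copy with the given fields replaced."""
        return _dc_replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float], *, strict: bool = True) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown and strict:
            raise ConfigurationError(
                f"unknown parameter name(s): {sorted(unknown)}; known names: {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in d.items() if k in known})


def param_names() -> list[str]:
    """All registered parameter names, in declaration order."""
    return [f.name for f in fields(ParameterSet)]


#: Default box bounds for parameter estimation (only parameters that are
#: ever estimated need an entry; others are held fixed).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kgp1": (0.01, 0.3),
    "kgp2": (0.01, 0.3),
    "Uii": (0.3, 3.0),
    "kins1": (0.005, 0.2),
    "kins2": (0.01, 0.5),
    "part_m": (0.05, 5.0),
    "V": (0.2, 5.0),
    "VX": (0.001, 0.2),
    "Km": (30.0, 500.0),
    "part_l": (0.05, 5.0),
    "Kl": (30.0, 500.0),
    "part_f": (0.2, 10.0),
    "p1": (0.1, 10.0),
    "p2": (0.003, 0.3),
    "p3": (0.001, 0.12),
    "p4": (0.0003, 0.03),
    "kgluin": (2.0, 1000.0),
    "kG6P": (0.5, 50.0),
    "VG6Pmax": (0.1, 11.0),
}

#: Internal name -> symbol used in the field's standard notation.
PARAM_SYMBOLS: dict[str, str] = {
    "kgp1": "k1 (glucose exchange, plasma->tissue)",
    "kgp2": "k2 (glucose exchange, tissue->plasma)",
    "Uii": "U_ii",
    "Gp_b": "G_p(0)",
    "Gt_b": "G_t(0)",
    "Ib": "I_b",
    "EGP_b": "EGP (basal)",
    "kins1": "k1 (interstitial insulin entry)",
    "kins2": "k2 (interstitial insulin degradation)",
    "part_m": "part_m",
    "V": "V",
    "VX": "V_X",
    "Km": "K_m",
    "part_l": "part_l",
    "Kl": "K_l",
    "part_f": "part_f",
    "p1": "p1",
    "p2": "p2",
    "p3": "p3",
    "p4": "p4",
    "kgluin": "k_gluin",
    "kG6P": "k_G6P",
    "VG6Pmax": "V_G6Pmax",
    "nC": "nC",
    "k8": "k8",
    "pf": "pf",
    "GLUT1": "GLUT1",
    "bfe_const": "bfe_f (constant mode)",
    "C1bf": "C1_bf",
    "C2bf": "C2_bf",
    "be": "be",
    "kbf": "kbf",
    "INSoffset": "INS_offset",
    "bradykinin": "bradykinin",
    "bf_b": "bf_b",
    "p_bf": "p_bf",
    "INS_b": "INS_b",
}
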