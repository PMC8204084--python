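# Methods

## Model structure

The simulator couples three levels: whole-body glucose pools, organ
uptake fluxes, and intracellular adipocyte metabolism. The state vector
is

| state | meaning | units |
|---|---|---|
| `Gp` | plasma glucose | mg/dl |
| `Gt` | interstitial-tissue glucose | mg/dl |
| `INS` | interstitial insulin above basal (muscle/liver pathway) | pmol/l |
| `INSfbf` | blood-flow-pathway insulin in adipose tissue | pmol/l |
| `GLUT4m` | membrane GLUT4 (surrogate driver state) | a.u. |
| `Gluin` | intracellular adipocyte glucose | a.u. |
| `G6P` | glucose-6-phosphate | a.u. |

Plasma insulin `I(t)`, endogenous glucose production `EGP(t)`, meal
glucose appearance `Ra(t)` and renal excretion `E(t)` are *forcings*:
the upstream whole-body machinery that generates them (gastric emptying,
beta-cell secretion, insulin kinetics, EGP regulation) is deliberately
outside this package's scope and enters through a signal contract
(evaluable at arbitrary t; tabulated CSV signals are interpolated
piecewise-linearly and clamped to endpoint values outside their table).
Built-in parametric curves provide realistic postprandial shapes: `Ra`
is a gamma density scaled to integrate exactly to the meal dose, insulin
and EGP-suppression are unit-peak gamma pulses, and `E` is zero (plasma
glucose stays below the renal threshold in the scenarios covered).

Two naming conventions need care. The glucose-exchange rate constants
and the interstitial-insulin rate constants are *both* conventionally
written k1/k2; internally they are distinct:

| internal name | role |
|---|---|
| `kgp1`, `kgp2` | glucose exchange plasma→tissue and tissue→plasma |
| `kins1`, `kins2` | interstitial insulin entry and degradation |
| `C1bf`, `C2bf` | blood-flow-pathway insulin clearance and entry |

Units are carried as printed by the lineage of whole-body models this
follows: glucose states in mg/dl, fluxes in mg/kg/min. These are
strictly speaking incommensurable (the states are distributed masses per
body weight); a single conversion constant `conv` (default 1) is the
hook for users who want to supply distribution volumes. We keep the
printed convention and document it rather than silently rescaling.

## Adipocyte module and the timing mechanism

Net adipose uptake is `part_f*(Vin − Vout)` with both transport fluxes
linear in the insulin effect `INSfe`. The phosphorylation step carries
the product inhibition: `VG6P = VG6Pmax·Gluin/(kgluin+Gluin)·1/(kG6P+G6P)`.
The exponent `pf` in `INSfe = nC·(k8·GLUT4m^pf + GLUT1^pf + bfe_f)` is
applied to both transporter terms (the typography of the source
formulation is ambiguous; applying `pf` to both is the reading
consistent with `pf` being a single listed parameter). `p1` scales only
the transport contribution to `dGluin/dt`, not the phosphorylative
removal, exactly as formulated.

The insulin-signaling cascade from receptor binding to GLUT4
translocation is replaced by a surrogate with a documented plug-in
contract: any object mapping (time, interstitial insulin) to a bounded,
nonnegative membrane GLUT4 with a fixed basal value can drive the
module. The packaged surrogate is a first-order relaxation (rate 0.03
min⁻¹, i.e. ~33-min translocation timescale) toward a Hill function of
`INS` (EC50 60 pmol/l above basal, Hill coefficient 2, basal 0.1 a.u.,
amplitude 5 a.u.). A published cascade model can be dropped in without
touching the adipocyte module.

`bfe_f` has three modes: `in_vitro` (0 — isolated adipocytes see no
blood flow), `constant_bf` (a fixed in-situ scaling, default 0.5, used
when no blood-flow data exist — the default for meal simulations), and
`dynamic_bf` (the INSfbf-driven model below).

## Blood flow and the factorial experiment

Blood flow responds to bradykinin directly and to insulin via `INSfbf`;
its effect on uptake is the product of the flow excursion and the
insulin excursion (`bfe_f = (bf_f − bf_b)·(INSfbf − INS_b)·p_bf`), an
AND gate that is exactly zero on the basal boundary. Two scenario
presets are packaged rather than reconciled, because the source
formulation gives both: `meal_bf` with bradykinin multiplier 2.2 (the
stated physiological value) and `bradykinin_infusion` with the
hand-estimated multiplier 3500 and insulin-infusion offset 7.

Insulin infusion in the factorial experiment is represented by raising
`INSoffset` from 0 to 7. Read literally, with the insulin factor
`(INSfbf − INS_b)` and plasma insulin at basal, an infusion modeled
purely through `INSoffset` could never open the gate — insulin-only
would equal control, contradicting the experimental pattern it is meant
to reproduce. Since `INSoffset` is an offset on the pathway insulin
concentration, this package passes the effective insulin
`INSfbf + INSoffset` into both the flow expression (where it appears
explicitly) and the insulin factor of `bfe_f`. With `INS_b = 0` this
preserves the AND gate exactly (bradykinin-only ≡ control) and gives
insulin-only a small positive effect.

The factorial table reports *steady-state* uptake with `Gt` clamped at
basal (the experimental preparation holds glycemia roughly constant).
At steady state the adipocyte's uptake equals its phosphorylation flux,
which saturates in `INSfe`; the packaged parameterization therefore
shows the correct qualitative pattern (bradykinin ≡ control;
bradykinin+insulin > insulin > control) with modest magnitudes. The
transient uptake response to the same perturbations is considerably
larger; users wanting transient contrasts should simulate the
`dynamic_bf` mode directly.

## Parameterization

No complete numeric parameter table is printed in the primary
description of this model family; the packaged defaults are therefore
this package's own final-model calibration, fixed once against the
published study conditions and then frozen:

- **Basal operating point.** `Gp(0) = 178`, `Gt(0) = 130` (printed
  initial values), basal plasma insulin 25 pmol/l, `Uii = 1` mg/kg/min
  (classic insulin-independent utilization). `kgp1 = 0.065` min⁻¹ is of
  the order used in the whole-body lineage; `kgp2`, basal EGP and the
  basal adipocyte fixed point are then *derived* by the basal closure
  (`calibrate_basal`) so that the printed basal state is an exact steady
  state: EGP_b = Uii + basal Uid (production balances disposal at rest).
  Users who modify uptake parameters should re-run the closure.
- **Organ partitions.** `part_m`, `part_l`, `part_f` were solved (least
  squares on the simulated fractions) so the packaged 6-h meal splits
  total uptake AUC as liver 45%, muscle 27%, adipose 5%, other 23% —
  the published distribution this model family is calibrated to. The
  liver and "other" shares sit inside the penalty bands ([40, 50]% and
  [18, 30]%) by construction.
- **Adipocyte kinetics.** `p1…p4`, `kgluin`, `kG6P`, `VG6Pmax` were
  chosen so that (a) the intracellular pool equilibrates on a ~15–30 min
  timescale, fast enough for net uptake to collapse back to baseline by
  ~2 h, and (b) phosphorylation runs deep in substrate saturation
  (`kgluin` well below the operating `Gluin` range), which makes the
  late-meal quasi-steady uptake nearly independent of the still-elevated
  insulin effect. This is what produces the timing dissociation: in the
  packaged meal, net adipose uptake is back within 10% of its excursion
  at ~126 min while the insulin effect is still at ~97% of its peak
  excursion. The reduced variant without the intracellular states
  (`adipocyte_detail=False`, uptake ∝ INSfe·Gt matched to the same
  basal) fails this property by a wide margin (return at ~286 min, with
  the insulin effect long decayed) — the comparison that motivates the
  metabolism module.
- **Meal forcings.** ~900 mg/kg glucose appearing in plasma (a ~70-g
  meal for a 75-kg adult after first-pass extraction), insulin peaking
  +275 pmol/l at 60 min, EGP suppressed by up to 1.35 mg/kg/min around
  90 min. `Gluin`/`G6P` are in arbitrary model units; no mapping to mM
  is attempted because none is defined for this model family.

## Estimation machinery

- **Cost.** SEM-weighted least squares, `v(p) = Σ((y−ŷ)/SEM)²`, with ŷ
  interpolated from dense simulation output at the data times. A failed
  candidate simulation returns a finite sentinel (10¹², plus a
  distance-to-bounds term for out-of-box proposals) so global optimizers
  continue. An `with_sem_floor` preprocessing option raises implausibly
  narrow SEMs to the dataset mean uncertainty.
- **χ² test.** Acceptance iff cost < the (1−α) quantile at df degrees
  of freedom (strict at the boundary). df defaults to the number of data
  points N; reduction by the number of estimated parameters is an
  explicit flag (used for the 4-point factorial comparison, 4−2 = 2).
  Note the df-corrected threshold at df=2, α=0.05 is 5.99; a value of
  3.8 (the χ² quantile at df=1) also circulates for this comparison —
  both are obtainable from `chi2_threshold` and the package does not
  adjudicate between them.
- **Penalties.** Quadratic hinges on the liver ([40, 50]%) and "other"
  ([18, 30]%) uptake shares: zero inside the band, C¹ at the edges,
  weight configurable (default 10⁴ cost units per squared fraction).
  The exact steepness of the original "slightly increasing punishment"
  is unspecified; the quadratic hinge is this package's choice.
- **Fitting.** Two-stage global-then-local per restart: differential
  evolution (Sobol-initialized, seeded) followed by a Nelder–Mead
  polish, multi-started from a `SeedSequence`-derived seed stream; runs
  are exactly reproducible given the seed. Sub-model scopes exploit the
  modular structure: the adipose (or muscle) sub-model is fitted
  separately with `Gt` as a fixed input signal, cutting the ODE system
  to 3–4 states per evaluation.
- **Uncertainty.** Every parameter vector evaluated during the search
  that passes the χ² test is archived; the envelope is the pointwise
  min/max of simulations across the archive. This is a cheap
  re-utilization of the optimization by-product, not a calibrated
  confidence band: profile likelihood and MCMC are out of scope (the
  individual parameters are not practically identifiable, which is also
  why results should be read as curve-level, not parameter-level).

## Synthetic data

The generator simulates the model at known "true" parameters, samples
named observables at the requested times, and adds independent Gaussian
noise with stated SEMs (relative 5% by default, floored at 5% of the
observable's maximum so baseline points keep realistic uncertainty).
It emulates arteriovenous-difference-style organ uptake series: rise to
a peak within ~60–100 min and return toward baseline by 360 min. It does
*not* emulate correlated errors between neighboring samples,
between-subject variability, measurement drift, or occasional negative
net-uptake readings; passing recovery tests therefore demonstrates
internal consistency of the estimator under ideal noise, not performance
on real AV-difference data. All randomness flows through one seeded
generator.

## Numerical choices

- LSODA (stiff-capable) throughout; default tolerances rtol 10⁻⁸ /
  atol 10⁻¹⁰ for full simulations, relaxed to 10⁻⁵/10⁻⁸ inside fitting
  loops. Dense output is sampled on a uniform 1-min grid for export;
  halving the tolerances moves `Gp(360)` by < 10⁻⁴ relative.
- Steady-state initialization: 5000-min integration under constant
  basal forcings, then a Newton polish, then a residual check (< 10⁻⁸
  on every component; the packaged defaults reach ~10⁻¹⁵). A literal
  mode instead pins `Gp`/`Gt` to their printed initial values and
  equilibrates only the remaining states conditional on them.
- AUCs use the composite trapezoid rule over 0–360 min (exact for
  piecewise-linear output; fraction results change by < 10⁻⁴ between
  2-min and 0.5-min grids).
- Degenerate inputs: `kG6P + G6P = 0` is guarded as a configuration
  error; `p3 = 0` (no efflux) has no finite intracellular steady state
  and must be initialized literally; negative `I − Ib` is allowed and
  drives the insulin states toward zero without clamping; a negative
  `bfe_f` or adipose AUC is passed through signed with a diagnostic
  warning.
- Problem sizes in the test suite are chosen to keep the full run in a
  few minutes: sub-model fits use a 5-min reporting grid, 12-point
  datasets, differential evolution with popsize 5 × 15 generations and
  one restart; parameter-recovery statistics use 20 replicates and the
  cost-calibration check 200 noise replicates against one cached truth
  simulation.

## Known limitations

- Meal-induced blood-flow regulation is not modeled; the blood-flow
  module covers pharmacological perturbations (bradykinin, insulin
  infusion) only.
- Liver insulin dependence is modeled as direct although hepatic uptake
  runs through insulin-independent GLUT2; the indirect route (insulin
  up-regulating phosphorylation/utilization) is approximated by the same
  functional form as muscle. Liver and muscle modules carry no
  intracellular detail.
- The factorial scenario's steady-state uptake contrasts are small
  because phosphorylation saturates; only the qualitative ordering is a
  designed property of the packaged parameterization.
- Parameters are not individually identifiable from uptake curves alone;
  the acceptable-set envelope under-covers true uncertainty when the
  optimizer explores narrowly.
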