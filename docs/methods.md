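# Methods

`metaflex` simulates whole-body carbohydrate and fat metabolism after a mixed
meal with a twelve-state compartmental ODE model, and asks how the response
changes when individual tissues — adipose tissue, the liver, skeletal muscle —
lose insulin sensitivity.

## Model

The body is reduced to three tissue compartments exchanging substrates through
the blood plasma:

| compartment | states |
|---|---|
| plasma | insulin `I`, glucose `G_b`, triacylglycerol `T_b`, free fatty acids `A_b` |
| liver | glycogen `Y_L`, FFA `A_L`, TAG `T_L` |
| skeletal muscle | AMP marker `P`, glucose `G_m`, glycogen `Y_m`, FFA `A_m`, TAG `T_m` |

All concentrations are dimensionless, scaled by their healthy fasting values,
so the healthy fasting state is the unit vector; dimensionless time is read as
hours. Plasma and liver equations carry the volume ratios `alpha = 0.17`
(plasma/muscle) and `eta = 0.064` (liver/muscle) on the left-hand side, so a
given flux moves liver concentrations ~16x faster than muscle concentrations —
the liver is a small, fast buffer between meals and the large muscle mass.

Every right-hand side is assembled from named, non-negative fluxes
(`FluxSet`), each of which appears in the donor and acceptor equations with
opposite signs; `rhs_direct` is an independent term-by-term transcription kept
only to cross-check the assembly (they must agree to 1e-12 at random states).

Key kinetic forms:

* **Insulin** is produced as a function of plasma glucose — by default the
  quadratic law `f0 = k_IG*G_b + k_I2*G_b^2` used for all numerical work, with
  a sigmoidal alternative `f0 = k_1 + k_2*erf((G_b - v)/c)` behind the
  `insulin_model="erf"` switch — plus a small FFA-dependent term `k_IA*A_b`,
  and is cleared at rate `lambda_I`. The pancreas is not modelled as adapting:
  chronic hyperinsulinaemic compensation is deliberately outside scope, so the
  simulations isolate the tissue-level consequences of resistance.
* **Hepatic stores** act through saturation factors
  `f1 = Y_L/(Y_0+Y_L)` (glycogenolysis needs glycogen),
  `f2 = (Y_max-Y_L)/(Y_0+Y_max-Y_L)` (glycogen synthesis shuts off at the
  capacity `Y_max`), and `f3 = T_L/(T_0+T_L)` (TAG export needs hepatic TAG).
  The hard capacity `Y_max` is what produces the double glucose spike under
  muscle insulin resistance (below).
* **The meal** enters as two Rayleigh-shaped plasma source pulses
  `F*theta*t/B^2 * exp(-t^2/2B^2)` peaking at `t = B` and integrating exactly
  to `F*theta`: glucose with delay `B_G = 0.5 h`, TAG with `B_T = 2 h`. The
  split `theta_G : theta_T` is the meal's macronutrient ratio (550:150 kcal by
  default) and the magnitude `F` scales linearly with total energy
  (`F = 1.5` for the 700 kcal reference meal).
* **The AMP marker `P`** tracks cellular energy demand in muscle: produced at
  `mu`, consumed by glucose oxidation (weight `gamma_g`) and FFA oxidation
  (weight `gamma_a`), so high oxidation depletes `P` and `P` in turn
  stimulates glycogenolysis and TAG lipolysis.

## Insulin sensitivity

Insulin resistance is a multiplicative de-rating of insulin action, one factor
per pathway, all equal to 1 in health:

| tissue | factors (resistant value) | pathway |
|---|---|---|
| liver | `sigma_Y = 0.5` | insulin-stimulated glucose uptake |
| liver | `sigma_L = 0.06` | insulin suppression of glycogenolysis output |
| liver | `sigma_T = 0.25` | insulin suppression of TAG export |
| adipose | `sigma_A = sigma_AT = 0.1` | insulin suppression of FFA release / stimulation of TAG uptake |
| adipose | `phi_A = phi_AT = 0.4` | overall adipose FFA-release and TAG-uptake capacity |
| muscle | `sigma_G = 0.2` | insulin-stimulated glucose uptake, oxidation and glycogen handling |

The resistant values are estimates derived from human clamp and
arterio-venous-difference studies; they are taken as given here.
`apply_insulin_resistance({...})` sets exactly the factors of the listed
tissues and leaves the rest at 1. Two documented text variants exist:
`sigma_G_text_value=True` uses 0.15 for muscle (both values appear in the
source material) and `strict_liver_text=True` keeps `sigma_Y = 1` for a
resistant liver (the stricter reading of the liver-scenario prose). Defaults
follow the tabulated values.

## Closing the fasting glucose balance

The reaction network stores fat in an unmodelled adipose reservoir — the
plasma FFA source `beta_A` — but, as drawn, it has **no glucose source in the
fasted state**. Summing the glucose-sector equations (weighted by their volume
factors) gives

```
d/dt (alpha*G_b + eta*Y_L + G_m + Y_m) = F_G(t) - S_G*G_b - k_AL*I*G_b - sigma_G*M_G*P*I*G_m
```

so with the meal off every steady state must have zero whole-body glucose
consumption, zero lipogenesis and zero muscle glucose oxidation: the model
cannot hold a fasting equilibrium while burning glucose. Physiologically the
missing flux is endogenous glucose production from substrates outside the
model (lactate, amino acids, glycerol). The package therefore adds one term to
the plasma glucose equation:

```
hepatic gluconeogenesis = beta_N / (1 + k_GL * I^2)
```

insulin-suppressed with the same binding constant as glycogenolysis but *not*
scaled by `sigma_L` (which is treated as the sensitivity of the
glycogen-derived output path; coupling the basal production to `sigma_L` would
raise fasting insulin far above baseline in hepatic-resistance scenarios,
whereas fasting insulin and glucose shifts are assumed small in early insulin
resistance). `beta_N` is fixed by calibration; setting `beta_N = 0` recovers
the bare network exactly.

## Calibration to the unity fasting state

`calibrate_to_unity_steady_state` solves the twelve fasting balances at the
unit state in closed form for twelve designated coefficients, one per
equation, touching no printed value:

| balance | solved coefficient |
|---|---|
| plasma insulin | `lambda_I` |
| plasma glucose | `beta_N` |
| plasma TAG | `T_0` |
| plasma FFA | `k_A` |
| hepatic glycogen | `Y_0` |
| hepatic FFA | `S_L` |
| hepatic TAG | `k_TH` |
| AMP marker | `mu` |
| muscle glucose | `M_G` |
| muscle glycogen | `k_CP` |
| muscle FFA | `M_A` |
| muscle TAG | `k_DP` |

Each solution has an admissibility condition (e.g. the hepatic TAG export
needed at the unit state must stay below its saturable maximum, which bounds
`beta_T` from below; the glycogenolysis/uptake ratio must lie strictly between
1 and `Y_max - 1` for a positive `Y_0`); violations raise a
`CalibrationError` naming the offending balance. Calibration is exact (the
residual is machine precision), idempotent, and perturbing any solved
coefficient by 10% breaks the residual — the test suite checks all three.

## Parameter provenance and default choices

Every registry entry carries one of five provenance tags, logged with every
run:

* **printed** — dimensionless constants used verbatim: `alpha = 0.17`,
  `eta = 0.064`, and the structurally-zero constants
  `k_CI = k_XI = k_XP = k_DI = 0` (kept in the code paths so the full
  equations stay testable).
* **printed_scaled** — published insulin-binding constants made dimensionless
  with a nominal high-normal fasting insulin of 97 pmol/l:
  `k_GI = 1.6975`, `k_GL = 0.99744`, `k_AA = 1.8818`, `k_TL = 0.2425`,
  `k_AI = 0.485`; and the glycogen capacity 310 mmol/l divided by a nominal
  fasting hepatic glycogen of ~103 mmol/l, `Y_max = 3.0`.
* **placeholder** — rate constants whose values were never published. They are
  the package's own nominal choices (every one overridable through
  configuration) and were selected so that the *healthy* response to the
  reference meal is physiologically shaped — glucose peaking ~2.3x fasting at
  ~35 min and returning within ~4 h, insulin tracking glucose with a ~1 h
  clearance time, TAG peaking later (~3.4 h) and lower, FFA suppressed to
  ~0.73 of fasting, hepatic glycogen rising to ~93% of capacity but not
  saturating — and so that the tissue-resistance scenarios fall in the regime
  the model is meant to exhibit (the glycogen cap reached only under muscle
  resistance, bounded fasting states for every tissue combination).
* **calibrated** — the twelve coefficients above.
* **unused** — `k_FG`, `k_FT` are retained as registry entries for
  traceability but do not enter the kinetics: the meal pulses are fully
  specified by `F`, `theta`, `B`.

Two placeholder choices deserve emphasis. First, `k_AA ~ 1.88` puts adipose
tissue in the regime where, at the resistant values
(`sigma_A = 0.1, phi_A = 0.4`), the *fasting* FFA release is only mildly below
healthy (the reduced suppression almost cancels the reduced capacity) while
the *postprandial* suppression is strongly blunted — this is what lets plasma
FFA stay elevated through the meal and drive fat into the liver. Second,
`beta_T` sits 1.3x above its calibration bound: tighter margins leave the
hepatic TAG export with too little headroom, and scenarios that raise fasting
insulin (muscle + adipose resistance) then have *no* fasting steady state —
hepatic TAG grows without bound. The margin guarantees a bounded, locally
stable fasting equilibrium for all eight tissue combinations.

## Scenario simulations

A scenario run (`simulate_scenario`, `compare_scenarios`) starts by default
from the scenario's **own fasting steady state** (`pre_relax=True`), computed
by damped root-finding seeded at the unit state and cross-checked against long
relaxation. This is the physiological reading — a chronically resistant
subject is at their own baseline before the meal — and it is why resistant and
healthy curves separate already at t = 0: fasting plasma FFA is lower with
resistant adipose tissue, fasting plasma TAG higher with whole-body
resistance. `pre_relax=False` starts from the shared healthy unit state
instead; in that mode slow relaxation toward the resistant baseline overlays
the meal response and dominates window-integrated quantities such as the net
hepatic TAG gain.

Derived observables:

* **fractional glucose oxidation** — the share of muscle oxidation drawn from
  glucose, `gamma_g*sigma_G*M_G*P*I*G_m / (gamma_g*sigma_G*M_G*P*I*G_m +
  gamma_a*M_A*P*A_m)`; the energy-yield weighting by `gamma` is the default
  and a config switch compares raw substrate fluxes instead. Its range over
  the 12 h window is the metabolic-flexibility measure.
* **adipose TAG clearance** — `phi_AT*k_TA*(1 + sigma_AT*k_AI*I)*T_b`.
* **total oxidation** — the time integral of the `P`-consuming oxidation
  fluxes.
* **recovery time** — the last (linearly interpolated) instant any state
  component sits outside a 1% relative band around its fasting value; a run
  still outside the band at the window end is reported as *not recovered*.
* **double-spike detection** — local plasma-glucose maxima separated by at
  least 5 minutes with a dip of at least 0.1% of the peak; the dip between
  the two spikes produced by glycogen-cap saturation is shallow and lasts
  only minutes, which these thresholds are set to resolve without picking up
  grid noise.

## Numerics

* Integration uses `scipy.integrate.solve_ivp`; LSODA by default
  (stiff-capable), `rtol = 1e-8`, `atol = 1e-10`. Output is sampled on a
  fixed grid (1-minute spacing by default) independent of internal steps, so
  summaries are solver-agnostic: a fully implicit method (Radau) and an
  explicit one (RK45) agree on every summary field to better than 1e-4, and
  halving the tolerances moves summaries by less than 1e-5.
* The glycogen cap is handled smoothly: the vector field clamps
  `f2` to 0 at or beyond `Y_max`, so solver trial steps that overshoot are
  pushed back; an accepted trajectory breaching the cap by more than 1e-3 is
  rejected as an error. Public evaluation of the saturation functions above
  the cap raises a domain error.
* Tiny negative excursions from the integrator (bounded by ten times the
  absolute tolerance) are clipped to zero before flux evaluation; larger ones
  abort the run.
* Peak values/times are refined with a local quartic fit (O(dt^4) bias; a
  three-point parabola leaves grid-scale bias in peak times), anchored at the
  earliest grid point within solver noise of the maximum so that flat or
  boundary maxima are well-conditioned. Peak *times* of plateau-shaped
  maxima remain conditioned as `sqrt(eps/|y''|)` and are only meaningful to a
  few seconds.
* The fasting root-find retries from progressively longer relaxation
  horizons; the slowest fasting mode (hepatic glycogen draining through its
  saturable output) has a time constant of roughly 35 h.

## What the defaults do and do not show

With the default registry the model reproduces, qualitatively, the
characteristic per-tissue phenotypes: resistant adipose tissue blunts the
postprandial FFA dip, halves TAG clearance into adipose tissue and produces a
net 12 h gain in liver fat; a resistant liver stores less glycogen and diverts
glucose into muscle; resistant muscle causes hyperglycaemia and
hyperinsulinaemia, drives hepatic glycogen into its capacity and produces the
tell-tale double glucose spike; whole-body resistance raises fasting TAG,
reduces metabolic flexibility and total oxidation, fails to recover the
fasting state within 12 h, and — because hepatic glucose uptake is itself
impaired — does *not* saturate the glycogen store.

Limitations to keep in mind:

* All statements are about the dimensionless model; no re-dimensionalisation
  to mmol/l is provided, and the placeholder rate constants are nominal, not
  fitted to any subject data. Passing tests show internal consistency and the
  qualitative resistance phenotypes, not quantitative agreement with human
  time courses.
* Protein metabolism, fructose, pancreatic glucose sensing (adaptive insulin
  secretion) and meal timing variability are outside the model.
* The glycogen capacity is a hard switch; in reality intermediate processes
  smooth it, and the double glucose spike's dip would likely not be resolved
  experimentally.
* Healthy hepatic glycogen unloads with a ~35 h time constant, so even the
  healthy run does not re-enter the 1% recovery band of *all twelve*
  components within 12 h — an overnight fast is exactly the timescale on
  which glycogen is still draining. The recovery sentinel is therefore most
  informative for the plasma variables and for cross-scenario comparison.
* The fixture generator jitters only unpublished placeholder coefficients
  (±20%) and re-calibrates, so test fixtures explore the admissible
  neighbourhood of the default regime, not qualitatively different
  parameterisations.
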