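"""Whole-body postprandial glucose/fat metabolism with tissue-level insulin resistance.

This module implements a dimensionless, twelve-state compartmental ODE model of
human carbohydrate and fat metabolism.  The compartments are the blood plasma
(insulin ``I``, glucose ``G_b``, triacylglycerol ``T_b``, free fatty acids
``A_b``), the liver (glycogen ``Y_L``, FFA ``A_L``, TAG ``T_L``) and skeletal
muscle (an AMP energy-state marker ``P``, glucose ``G_m``, glycogen ``Y_m``,
FFA ``A_m``, TAG ``T_m``).  All concentrations are scaled so that the healthy
fasting value is 1, and dimensionless time is measured in hours.

Insulin sensitivity is parametrised by multiplicative factors (``sigma``/``phi``)
on every insulin-stimulated or insulin-suppressed flux; setting a factor below 1
renders the corresponding tissue insulin resistant.  The module covers, in the
order the method runs:

1.  domain types (parameter registry, sensitivity factors, metabolic state,
    named fluxes);
2.  the kinetic building blocks (insulin production, meal source terms,
    hepatic saturation functions) and the vector field assembled from named
    fluxes;
3.  scenario construction, calibration of the unknown coefficients so that the
    unity fasting state is an exact equilibrium, and fasting steady states;
4.  postprandial simulation, derived observables (fractional glucose oxidation,
    adipose TAG clearance), trajectory summaries and scenario comparison;
5.  configuration, serialisation and a fixture generator for tests.

One modelling note up front: the reaction network stores fat in an unmodelled
adipose reservoir (the plasma FFA source ``beta_A``) but, as printed, has no
analogous glucose source, so a fasting equilibrium with non-zero glucose
turnover cannot exist — summing the glucose-sector equations shows every
glucose sink would have to vanish.  The model here therefore closes the fasting
glucose balance with a basal endogenous glucose production term (hepatic
gluconeogenesis, rate ``beta_N``, insulin-suppressed like glycogenolysis and
fed by substrates outside the model, exactly as ``beta_A`` is for fat).
``beta_N`` is fixed by calibration; setting it to zero recovers the bare
network.  See ``docs/methods.md`` for the full discussion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import erf

logger = logging.getLogger("metaflex")

__all__ = [
    "STATE_VARS",
    "PLASMA_VARS",
    "ParameterSet",
    "SensitivityFactors",
    "MetabolicState",
    "FluxSet",
    "Meal",
    "Trajectory",
    "ScenarioSummary",
    "RunConfig",
    "ModelInputError",
    "ConfigError",
    "CalibrationError",
    "NumericalError",
    "GlycogenCapError",
    "insulin_production_erf",
    "insulin_production_quadratic",
    "meal_sources",
    "saturation_functions",
    "compute_fluxes",
    "rhs",
    "rhs_direct",
    "apply_insulin_resistance",
    "scenario_tissues",
    "calibrate_to_unity_steady_state",
    "default_parameters",
    "healthy_parameters",
    "steady_state",
    "simulate",
    "fractional_glucose_oxidation",
    "adipose_tag_clearance",
    "summarise",
    "compare_scenarios",
    "generate_fixture",
    "resolve_config",
    "SCENARIO_NAMES",
    "TABLE3_FACTORS",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class ModelInputError(ValueError):
    """Invalid state, parameter or argument passed to a model operation."""


class ConfigError(ValueError):
    """Malformed or unresolvable run configuration."""


class CalibrationError(RuntimeError):
    """No admissible (non-negative) solution for a calibration coefficient."""


class NumericalError(RuntimeError):
    """Integration or root finding failed to converge."""


class GlycogenCapError(ModelInputError):
    """Hepatic glycogen exceeded its maximum capacity ``Y_max``."""


# ---------------------------------------------------------------------------
# State ordering and scenario vocabulary
# ---------------------------------------------------------------------------

#: Fixed serialisation order of the twelve state variables.
STATE_VARS: tuple[str, ...] = (
    "I", "G_b", "T_b", "A_b",          # plasma
    "Y_L", "A_L", "T_L",               # liver
    "P", "G_m", "Y_m", "A_m", "T_m",   # skeletal muscle
)

PLASMA_VARS: tuple[str, ...] = ("I", "G_b", "T_b", "A_b")

TISSUES: frozenset[str] = frozenset({"adipose", "liver", "muscle"})

#: Scenario name -> set of insulin-resistant tissues.
SCENARIO_NAMES: dict[str, frozenset[str]] = {
    "healthy": frozenset(),
    "adipose": frozenset({"adipose"}),
    "liver": frozenset({"liver"}),
    "muscle": frozenset({"muscle"}),
    "adipose+liver": frozenset({"adipose", "liver"}),
    "adipose+muscle": frozenset({"adipose", "muscle"}),
    "liver+muscle": frozenset({"liver", "muscle"}),
    "all": frozenset({"adipose", "liver", "muscle"}),
}

#: Clamp-literature sensitivity values for a resistant tissue (healthy = 1).
TABLE3_FACTORS: dict[str, dict[str, float]] = {
    "adipose": {"sigma_A": 0.1, "sigma_AT": 0.1, "phi_A": 0.4, "phi_AT": 0.4},
    "liver": {"sigma_Y": 0.5, "sigma_L": 0.06, "sigma_T": 0.25},
    "muscle": {"sigma_G": 0.2},
}

#: Text-variant value for muscle glucose-uptake sensitivity (0.15 instead of 0.2).
SIGMA_G_TEXT_VALUE: float = 0.15


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All rate constants of the dimensionless model (time unit: hours).

    Provenance of each default is recorded in :data:`PARAM_PROVENANCE`:

    ``printed``
        dimensionless values taken verbatim from the source parameter table
        (the volume ratios ``alpha``, ``eta`` and the structurally zero
        constants ``k_CI``, ``k_XI``, ``k_XP``, ``k_DI``);
    ``printed_scaled``
        printed insulin-binding constants made dimensionless with a nominal
        fasting insulin concentration of 60 pmol/l, and the glycogen capacity
        ``Y_max`` scaled by a nominal fasting hepatic glycogen of 103 mmol/l;
    ``placeholder``
        unpublished coefficients, set to documented physiologically plausible
        defaults (every one overridable through configuration);
    ``calibrated``
        the twelve coefficients solved by
        :func:`calibrate_to_unity_steady_state` so that the unity fasting
        state is an exact meal-free equilibrium;
    ``unused``
        registry entries retained for traceability that do not enter the
        kinetics (the meal source terms are fully specified by
        ``F``, ``theta``, ``B``).
    """

    # --- insulin kinetics -------------------------------------------------
    k_IG: float = 0.85  # quadratic insulin production, linear coefficient
    k_I2: float = 0.20  # quadratic insulin production, quadratic coefficient
    k_IA: float = 0.05  # FFA-dependent insulin production
    k_1: float = 2.7947  # erf insulin production, offset
    k_2: float = 3.3520  # erf insulin production, amplitude (printed ratio k_2/k_1)
    v: float = 1.50  # erf switch centre (dimensionless glucose)
    c: float = 1.00  # erf switch width
    lambda_I: float = 1.10  # insulin degradation [calibrated]

    # --- plasma glucose ---------------------------------------------------
    beta_G: float = 0.12943  # hepatic glycogenolysis output scale
    beta_N: float = 1.0781  # basal gluconeogenesis output [calibrated]
    k_GL: float = 0.99744  # insulin inhibition of hepatic glucose output
    S_G: float = 0.15  # whole-body (brain etc.) glucose sink
    k_G: float = 0.10  # muscle glucose uptake, basal
    k_GI: float = 1.6975  # muscle glucose uptake, insulin stimulated
    k_L: float = 0.06  # hepatic glucose uptake
    k_AL: float = 0.12  # hepatic de novo lipogenesis (glucose -> FFA)

    # --- plasma TAG -------------------------------------------------------
    beta_T: float = 0.2085  # hepatic TAG output scale
    k_TL: float = 0.2425  # insulin inhibition of hepatic TAG output
    k_T: float = 0.04  # muscle TAG uptake
    k_TA: float = 0.06  # adipose TAG uptake, basal
    k_AI: float = 0.485  # adipose TAG uptake, insulin stimulated

    # --- plasma FFA -------------------------------------------------------
    beta_A: float = 0.80  # adipose FFA release scale
    k_AA: float = 1.8818  # insulin inhibition of adipose FFA release
    k_A: float = 0.1276  # muscle FFA uptake [calibrated]
    k_BL: float = 0.40  # hepatic FFA uptake from plasma
    k_LB: float = 0.25  # hepatic FFA release to plasma

    # --- liver stores -----------------------------------------------------
    Y_max: float = 3.00  # hepatic glycogen capacity (310 mmol/l / ~103 mmol/l)
    Y_0: float = 0.174  # glycogen saturation half-constant [calibrated]
    T_0: float = 0.300  # hepatic TAG saturation half-constant [calibrated]
    k_TH: float = 0.129  # hepatic TAG synthesis from FFA [calibrated]
    k_AS: float = 0.50  # insulin inhibition of hepatic FFA oxidation
    S_L: float = 0.211  # hepatic FFA oxidation [calibrated]

    # --- muscle energy state (AMP marker) ---------------------------------
    mu: float = 1.156  # P production [calibrated]
    lambda_P: float = 0.50  # P decay
    gamma_a: float = 2.3  # P consumed per unit FFA oxidation
    gamma_g: float = 1.0  # P consumed per unit glucose oxidation
    M_G: float = 0.270  # muscle glucose oxidation rate [calibrated]
    M_A: float = 0.168  # muscle FFA oxidation rate [calibrated]

    # --- muscle stores ----------------------------------------------------
    k_Y: float = 0.50  # muscle glycogen synthesis, basal
    k_YI: float = 1.00      # glycogen synthesis, insulin stimulated
    k_YP: float = 1.00      # glycogen synthesis, AMP inhibited
    k_CP: float = 0.50  # glycogenolysis, AMP stimulated [calibrated]
    k_CI: float = 0.0       # glycogenolysis, insulin inhibited (printed zero)
    k_X: float = 0.35  # muscle TAG synthesis, basal
    k_XI: float = 0.0       # TAG synthesis, insulin stimulated (printed zero)
    k_XP: float = 0.0       # TAG synthesis, AMP inhibited (printed zero)
    k_DP: float = 0.35  # muscle TAG lipolysis, AMP stimulated [calibrated]
    k_DI: float = 0.0       # TAG lipolysis, insulin inhibited (printed zero)

    # --- volume ratios and meal -------------------------------------------
    alpha: float = 0.17     # plasma volume / muscle volume (printed)
    eta: float = 0.064      # liver volume / muscle volume (printed)
    B_G: float = 0.50       # meal-to-plasma delay for glucose (h)
    B_T: float = 2.00       # meal-to-plasma delay for TAG (h)
    theta_G: float = 550.0 / 700.0  # carbohydrate fraction of the meal
    theta_T: float = 150.0 / 700.0  # fat fraction of the meal
    F: float = 1.50         # dimensionless meal magnitude
    k_FG: float = 0.0       # registry entry, not part of the meal kinetics [unused]
    k_FT: float = 0.0       # registry entry, not part of the meal kinetics [unused]

    def validate(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not math.isfinite(value):
                raise ModelInputError(f"parameter {name} is not finite: {value!r}")
            if value < 0:
                raise ModelInputError(f"parameter {name} is negative: {value!r}")
        if self.alpha <= 0 or self.eta <= 0:
            raise ModelInputError("volume ratios alpha and eta must be positive")
        if self.Y_max <= 0:
            raise ModelInputError("Y_max must be positive")
        if self.theta_G + self.theta_T > 1 + 1e-12:
            raise ModelInputError("meal fractions theta_G + theta_T must not exceed 1")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Names of the twelve coefficients solved by calibration, keyed by the state
#: variable whose balance fixes them.
CALIBRATED_COEFFICIENTS: dict[str, str] = {
    "I": "lambda_I",
    "G_b": "beta_N",
    "T_b": "T_0",
    "A_b": "k_A",
    "Y_L": "Y_0",
    "A_L": "S_L",
    "T_L": "k_TH",
    "P": "mu",
    "G_m": "M_G",
    "Y_m": "k_CP",
    "A_m": "M_A",
    "T_m": "k_DP",
}

_PRINTED = ("alpha", "eta", "k_CI", "k_XI", "k_XP", "k_DI")
_PRINTED_SCALED = ("k_GI", "k_GL", "k_AA", "k_TL", "k_AI", "Y_max")
_UNUSED = ("k_FG", "k_FT")

PARAM_PROVENANCE: dict[str, str] = {
    name: (
        "printed" if name in _PRINTED
        else "printed_scaled" if name in _PRINTED_SCALED
        else "calibrated" if name in set(CALIBRATED_COEFFICIENTS.values())
        else "unused" if name in _UNUSED
        else "placeholder"
    )
    for name in ParameterSet.__dataclass_fields__
}


@dataclass(frozen=True)
class SensitivityFactors:
    """Insulin sensitivity multipliers; 1 means normal sensitivity.

    Each factor lives in (0, 1] and scales one insulin-dependent term:
    ``sigma_Y`` hepatic glucose uptake, ``sigma_L`` suppression of hepatic
    glucose output, ``sigma_T`` suppression of hepatic TAG output,
    ``sigma_A``/``phi_A`` adipose FFA release, ``sigma_AT``/``phi_AT`` adipose
    TAG uptake, ``sigma_G`` muscle glucose handling (uptake, oxidation and
    glycogen turnover).
    """

    sigma_Y: float = 1.0
    sigma_L: float = 1.0
    sigma_T: float = 1.0
    sigma_A: float = 1.0
    sigma_AT: float = 1.0
    phi_A: float = 1.0
    phi_AT: float = 1.0
    sigma_G: float = 1.0

    def validate(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not (0.0 < value <= 1.0) or not math.isfinite(value):
                raise ModelInputError(
                    f"sensitivity factor {name} must lie in (0, 1]; got {value!r}"
                )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


HEALTHY_SENSITIVITY = SensitivityFactors()


@dataclass(frozen=True)
class MetabolicState:
    """Dimensionless concentrations of the twelve model species."""

    I: float
    G_b: float
    T_b: float
    A_b: float
    Y_L: float
    A_L: float
    T_L: float
    P: float
    G_m: float
    Y_m: float
    A_m: float
    T_m: float

    @classmethod
    def unity(cls) -> "MetabolicState":
        """The healthy fasting reference state (all concentrations 1)."""
        return cls(*([1.0] * len(STATE_VARS)))

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "MetabolicState":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(STATE_VARS),):
            raise ModelInputError(f"state vector must have length {len(STATE_VARS)}")
        return cls(*arr.tolist())

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_VARS], dtype=float)

    def validate(self) -> None:
        for name in STATE_VARS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ModelInputError(f"state component {name} is not finite")
            if value < 0:
                raise ModelInputError(f"state component {name} is negative: {value!r}")


@dataclass(frozen=True)
class FluxSet:
    """Named non-negative rates, one per arrow of the reaction network.

    Transport/conversion fluxes are shared verbatim between the equations of
    the donor and acceptor compartments; :func:`rhs` assembles the vector
    field exclusively from these entries (plus volume factors).
    """

    insulin_production: float
    insulin_degradation: float
    hepatic_glucose_output: float
    hepatic_gluconeogenesis: float
    body_glucose_sink: float
    muscle_glucose_uptake: float
    hepatic_glucose_uptake: float
    lipogenesis: float
    meal_glucose_input: float
    hepatic_tag_output: float
    muscle_tag_uptake: float
    adipose_tag_uptake: float
    meal_tag_input: float
    adipose_ffa_output: float
    muscle_ffa_uptake: float
    hepatic_ffa_uptake: float
    hepatic_ffa_output: float
    hepatic_ffa_oxidation: float
    hepatic_tag_synthesis: float
    amp_production: float
    amp_decay: float
    muscle_glucose_oxidation: float
    muscle_glycogen_synthesis: float
    muscle_glycogenolysis: float
    muscle_ffa_oxidation: float
    muscle_tag_synthesis: float
    muscle_tag_lipolysis: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Meal:
    """A mixed meal given at t = 0.

    ``F`` is the total dimensionless meal magnitude; when ``None`` it scales
    linearly with caloric content at :data:`F_PER_KCAL` (chosen so the
    reference 700 kcal meal has F = 1.5).  The macronutrient split sets the
    glucose/TAG partition ``theta_G``/``theta_T``.
    """

    carb_kcal: float = 550.0
    fat_kcal: float = 150.0
    F: float | None = None

    #: dimensionless meal magnitude per kcal (1.5 / 700 kcal).
    F_PER_KCAL = 1.5 / 700.0

    def __post_init__(self) -> None:
        if self.carb_kcal < 0 or self.fat_kcal < 0:
            raise ModelInputError("meal kcal must be non-negative")
        if self.carb_kcal + self.fat_kcal <= 0 and self.F is None:
            raise ModelInputError("meal must contain energy or an explicit F")

    @property
    def total_kcal(self) -> float:
        return self.carb_kcal + self.fat_kcal

    @property
    def magnitude(self) -> float:
        return self.F if self.F is not None else self.F_PER_KCAL * self.total_kcal

    @property
    def theta_G(self) -> float:
        return self.carb_kcal / self.total_kcal if self.total_kcal else 0.0

    @property
    def theta_T(self) -> float:
        return self.fat_kcal / self.total_kcal if self.total_kcal else 0.0

    def apply(self, params: ParameterSet) -> ParameterSet:
        """Return ``params`` with the meal magnitude and split installed."""
        return replace(
            params, F=self.magnitude, theta_G=self.theta_G, theta_T=self.theta_T
        )


# ---------------------------------------------------------------------------
# Kinetic building blocks
# ---------------------------------------------------------------------------


def insulin_production_quadratic(G_b: float, params: ParameterSet) -> float:
    """Quadratic glucose-dependent insulin production k_IG*G_b + k_I2*G_b^2.

    The quadratic law is the production term used in all numerical work; it
    vanishes at zero glucose and is monotone increasing for non-negative
    coefficients.
    """
    G_b = np.asarray(G_b, dtype=float)
    if not np.all(np.isfinite(G_b)):
        raise ModelInputError("G_b must be finite")
    out = params.k_IG * G_b + params.k_I2 * G_b**2
    return float(out) if out.ndim == 0 else out


def insulin_production_erf(G_b: float, params: ParameterSet) -> float:
    """Sigmoidal insulin production k_1 + k_2*erf((G_b - v)/c).

    Bounded in [k_1 - k_2, k_1 + k_2]; retained as a switchable alternative
    to the quadratic law.
    """
    G_b = np.asarray(G_b, dtype=float)
    if not np.all(np.isfinite(G_b)):
        raise ModelInputError("G_b must be finite")
    if params.c <= 0:
        raise ModelInputError("erf width c must be positive")
    out = params.k_1 + params.k_2 * erf((G_b - params.v) / params.c)
    return float(out) if out.ndim == 0 else out


def _f0(G_b: float, params: ParameterSet, insulin_model: str) -> float:
    if insulin_model == "quadratic":
        return insulin_production_quadratic(G_b, params)
    if insulin_model == "erf":
        return insulin_production_erf(G_b, params)
    raise ModelInputError(f"unknown insulin model {insulin_model!r}")


def meal_sources(t: float, params: ParameterSet) -> tuple[float, float]:
    """Dietary glucose and TAG delivery rates (F_G(t), F_T(t)) at time ``t``.

    Each source is a Rayleigh-shaped pulse ``F*theta*t/B^2 * exp(-t^2/2B^2)``
    peaking at ``t = B`` and integrating to ``F*theta`` over the half line, so
    ``F`` is the total dimensionless meal mass and ``theta`` its partition.
    """
    if params.B_G <= 0 or params.B_T <= 0:
        raise ModelInputError("meal delay constants B_G, B_T must be positive")
    t = np.asarray(t, dtype=float)
    F_G = params.F * params.theta_G * t / params.B_G**2 * np.exp(-(t**2) / (2 * params.B_G**2))
    F_T = params.F * params.theta_T * t / params.B_T**2 * np.exp(-(t**2) / (2 * params.B_T**2))
    if t.ndim == 0:
        return float(F_G), float(F_T)
    return F_G, F_T


def saturation_functions(
    Y_L: float, T_L: float, params: ParameterSet
) -> tuple[float, float, float]:
    """Hepatic store saturation factors (f1, f2, f3).

    ``f1 = Y_L/(Y_0+Y_L)`` gates glycogenolysis on available glycogen,
    ``f2 = (Y_max-Y_L)/(Y_0+Y_max-Y_L)`` shuts glycogen synthesis off at the
    capacity ``Y_max``, and ``f3 = T_L/(T_0+T_L)`` gates hepatic TAG export on
    the hepatic TAG pool.  All three lie in [0, 1).
    """
    if params.Y_0 <= 0 or params.T_0 <= 0:
        raise ModelInputError("saturation half-constants Y_0, T_0 must be positive")
    if Y_L < 0 or T_L < 0:
        raise ModelInputError("store concentrations must be non-negative")
    if Y_L > params.Y_max:
        raise GlycogenCapError(
            f"hepatic glycogen {Y_L!r} exceeds capacity Y_max = {params.Y_max!r}"
        )
    f1 = Y_L / (params.Y_0 + Y_L)
    headroom = params.Y_max - Y_L
    f2 = headroom / (params.Y_0 + headroom)
    f3 = T_L / (params.T_0 + T_L)
    return f1, f2, f3


#: Absolute slack on the glycogen cap tolerated during integration before a
#: trajectory is rejected as having breached the store capacity.
CAP_SLACK = 1e-3

_NEG_SLACK = 1e-7  # transient negative excursions tolerated from the integrator


def compute_fluxes(
    state: MetabolicState | Sequence[float],
    t: float,
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    insulin_model: str = "quadratic",
) -> FluxSet:
    """Evaluate every named flux of the network at ``state`` and time ``t``.

    Sensitivity factors multiply the insulin-dependent terms in place:
    ``sigma`` factors scale insulin inside stimulation/suppression factors,
    ``phi`` factors scale the whole adipose fluxes.  Raises
    :class:`ModelInputError` for meaningfully negative state components and
    :class:`GlycogenCapError` when hepatic glycogen exceeds its capacity by
    more than a small integration slack.
    """
    y = state.to_array() if isinstance(state, MetabolicState) else np.asarray(state, float)
    if y.shape != (len(STATE_VARS),):
        raise ModelInputError("state must have 12 components")
    if not np.all(np.isfinite(y)):
        raise ModelInputError("state components must be finite")
    if np.min(y) < -_NEG_SLACK:
        raise ModelInputError(f"negative state component: min = {np.min(y)!r}")
    y = np.clip(y, 0.0, None)
    I, G_b, T_b, A_b, Y_L, A_L, T_L, P, G_m, Y_m, A_m, T_m = y

    p, s = params, sens
    # Clamp at the store capacity: f2 = 0 there, so the dynamics push any
    # (trial-step) overshoot back.  Accepted trajectories are checked against
    # CAP_SLACK by `simulate`.
    Y_L = min(Y_L, p.Y_max)

    f1 = Y_L / (p.Y_0 + Y_L)
    f2 = (p.Y_max - Y_L) / (p.Y_0 + p.Y_max - Y_L)
    f3 = T_L / (p.T_0 + T_L)
    F_G, F_T = meal_sources(t, params) if p.F > 0 else (0.0, 0.0)

    glucose_output_suppression = 1.0 + s.sigma_L * p.k_GL * I**2

    return FluxSet(
        insulin_production=_f0(G_b, params, insulin_model) + p.k_IA * A_b,
        insulin_degradation=p.lambda_I * I,
        hepatic_glucose_output=p.beta_G * f1 / glucose_output_suppression,
        hepatic_gluconeogenesis=p.beta_N / (1.0 + p.k_GL * I**2),
        body_glucose_sink=p.S_G * G_b,
        muscle_glucose_uptake=p.k_G * (1.0 + s.sigma_G * p.k_GI * I) * G_b,
        hepatic_glucose_uptake=p.k_L * s.sigma_Y * I * G_b * f2,
        lipogenesis=p.k_AL * I * G_b,
        meal_glucose_input=F_G,
        hepatic_tag_output=p.beta_T * f3 / (1.0 + s.sigma_T * p.k_TL * I),
        muscle_tag_uptake=p.k_T * T_b,
        adipose_tag_uptake=s.phi_AT * p.k_TA * (1.0 + s.sigma_AT * p.k_AI * I) * T_b,
        meal_tag_input=F_T,
        adipose_ffa_output=s.phi_A * p.beta_A / (1.0 + s.sigma_A * p.k_AA * I**2),
        muscle_ffa_uptake=p.k_A * A_b,
        hepatic_ffa_uptake=p.k_BL * A_b,
        hepatic_ffa_output=p.k_LB * A_L,
        hepatic_ffa_oxidation=p.S_L * A_L / (1.0 + p.k_AS * I),
        hepatic_tag_synthesis=p.k_TH * I * A_L,
        amp_production=p.mu,
        amp_decay=p.lambda_P * P,
        muscle_glucose_oxidation=s.sigma_G * p.M_G * P * I * G_m,
        muscle_glycogen_synthesis=p.k_Y * (1.0 + s.sigma_G * p.k_YI * I)
        / (1.0 + p.k_YP * P) * G_m,
        muscle_glycogenolysis=p.k_CP * P * Y_m / (1.0 + s.sigma_G * p.k_CI * I),
        muscle_ffa_oxidation=p.M_A * P * A_m,
        muscle_tag_synthesis=p.k_X * (1.0 + p.k_XI * I) / (1.0 + p.k_XP * P) * A_m,
        muscle_tag_lipolysis=p.k_DP * P * T_m / (1.0 + p.k_DI * I),
    )


def rhs(
    state: MetabolicState | Sequence[float],
    t: float,
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    insulin_model: str = "quadratic",
) -> np.ndarray:
    """Time derivatives of the twelve states, assembled from named fluxes.

    Each derivative is a signed sum of :class:`FluxSet` entries divided by its
    compartment volume factor (``alpha`` for plasma, ``eta`` for liver, 1 for
    muscle and insulin); every transport flux enters exactly two equations
    with opposite signs.
    """
    f = compute_fluxes(state, t, params, sens, insulin_model)
    p = params
    dI = f.insulin_production - f.insulin_degradation
    dG_b = (
        f.hepatic_glucose_output + f.hepatic_gluconeogenesis - f.body_glucose_sink
        - f.muscle_glucose_uptake - f.hepatic_glucose_uptake - f.lipogenesis
        + f.meal_glucose_input
    ) / p.alpha
    dT_b = (
        f.hepatic_tag_output - f.muscle_tag_uptake - f.adipose_tag_uptake
        + f.meal_tag_input
    ) / p.alpha
    dA_b = (
        f.adipose_ffa_output - f.muscle_ffa_uptake - f.hepatic_ffa_uptake
        + f.hepatic_ffa_output
    ) / p.alpha
    dY_L = (f.hepatic_glucose_uptake - f.hepatic_glucose_output) / p.eta
    dA_L = (
        f.lipogenesis + f.hepatic_ffa_uptake - f.hepatic_ffa_oxidation
        - f.hepatic_ffa_output - f.hepatic_tag_synthesis
    ) / p.eta
    dT_L = (f.hepatic_tag_synthesis - f.hepatic_tag_output) / p.eta
    dP = (
        f.amp_production - f.amp_decay
        - p.gamma_a * f.muscle_ffa_oxidation - p.gamma_g * f.muscle_glucose_oxidation
    )
    dG_m = (
        f.muscle_glucose_uptake - f.muscle_glucose_oxidation
        - f.muscle_glycogen_synthesis + f.muscle_glycogenolysis
    )
    dY_m = f.muscle_glycogen_synthesis - f.muscle_glycogenolysis
    dA_m = (
        f.muscle_tag_uptake + f.muscle_ffa_uptake - f.muscle_ffa_oxidation
        - f.muscle_tag_synthesis + f.muscle_tag_lipolysis
    )
    dT_m = f.muscle_tag_synthesis - f.muscle_tag_lipolysis
    return np.array(
        [dI, dG_b, dT_b, dA_b, dY_L, dA_L, dT_L, dP, dG_m, dY_m, dA_m, dT_m]
    )


def rhs_direct(
    state: MetabolicState | Sequence[float],
    t: float,
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    insulin_model: str = "quadratic",
) -> np.ndarray:
    """Literal transcription of the model equations, term by term.

    Kept deliberately independent of :func:`compute_fluxes`/:func:`rhs` as a
    structural cross-check: both routes must agree to machine precision at any
    admissible state.
    """
    y = state.to_array() if isinstance(state, MetabolicState) else np.asarray(state, float)
    I, G_b, T_b, A_b, Y_L, A_L, T_L, P, G_m, Y_m, A_m, T_m = np.clip(y, 0.0, None)
    p, s = params, sens
    Y_L = min(Y_L, p.Y_max)

    f1 = Y_L / (p.Y_0 + Y_L)
    f2 = (p.Y_max - Y_L) / (p.Y_0 + p.Y_max - Y_L)
    f3 = T_L / (p.T_0 + T_L)
    if p.F > 0:
        F_G = p.F * p.theta_G * t / p.B_G**2 * math.exp(-(t**2) / (2 * p.B_G**2))
        F_T = p.F * p.theta_T * t / p.B_T**2 * math.exp(-(t**2) / (2 * p.B_T**2))
    else:
        F_G = F_T = 0.0
    if insulin_model == "quadratic":
        f0 = p.k_IG * G_b + p.k_I2 * G_b**2
    else:
        f0 = p.k_1 + p.k_2 * math.erf((G_b - p.v) / p.c)

    dI = f0 + p.k_IA * A_b - p.lambda_I * I
    dG_b = (
        p.beta_G * f1 / (1 + s.sigma_L * p.k_GL * I**2)
        + p.beta_N / (1 + p.k_GL * I**2)
        - p.S_G * G_b
        - p.k_G * (1 + s.sigma_G * p.k_GI * I) * G_b
        - p.k_L * s.sigma_Y * I * G_b * f2
        - p.k_AL * I * G_b
        + F_G
    ) / p.alpha
    dT_b = (
        p.beta_T / (1 + s.sigma_T * p.k_TL * I) * f3
        - p.k_T * T_b
        - s.phi_AT * p.k_TA * (1 + s.sigma_AT * p.k_AI * I) * T_b
        + F_T
    ) / p.alpha
    dA_b = (
        s.phi_A * p.beta_A / (1 + s.sigma_A * p.k_AA * I**2)
        - p.k_A * A_b
        - p.k_BL * A_b
        + p.k_LB * A_L
    ) / p.alpha
    dY_L = (
        p.k_L * s.sigma_Y * I * G_b * f2
        - p.beta_G / (1 + s.sigma_L * p.k_GL * I**2) * f1
    ) / p.eta
    dA_L = (
        p.k_AL * I * G_b
        - p.S_L * A_L / (1 + p.k_AS * I)
        + p.k_BL * A_b
        - p.k_LB * A_L
        - p.k_TH * I * A_L
    ) / p.eta
    dT_L = (
        p.k_TH * I * A_L - p.beta_T / (1 + s.sigma_T * p.k_TL * I) * f3
    ) / p.eta
    dP = (
        p.mu - p.lambda_P * P - p.gamma_a * p.M_A * A_m * P
        - s.sigma_G * p.gamma_g * p.M_G * P * I * G_m
    )
    dG_m = (
        p.k_G * (1 + s.sigma_G * p.k_GI * I) * G_b
        - s.sigma_G * p.M_G * P * I * G_m
        - p.k_Y * (1 + s.sigma_G * p.k_YI * I) / (1 + p.k_YP * P) * G_m
        + p.k_CP * P * Y_m / (1 + s.sigma_G * p.k_CI * I)
    )
    dY_m = (
        p.k_Y * (1 + s.sigma_G * p.k_YI * I) / (1 + p.k_YP * P) * G_m
        - p.k_CP * P * Y_m / (1 + s.sigma_G * p.k_CI * I)
    )
    dA_m = (
        p.k_T * T_b
        + p.k_A * A_b
        - p.M_A * P * A_m
        - p.k_X * (1 + p.k_XI * I) / (1 + p.k_XP * P) * A_m
        + p.k_DP * P * T_m / (1 + p.k_DI * I)
    )
    dT_m = (
        p.k_X * (1 + p.k_XI * I) / (1 + p.k_XP * P) * A_m
        - p.k_DP * P * T_m / (1 + p.k_DI * I)
    )
    return np.array(
        [dI, dG_b, dT_b, dA_b, dY_L, dA_L, dT_L, dP, dG_m, dY_m, dA_m, dT_m]
    )


# ---------------------------------------------------------------------------
# Scenarios and calibration
# ---------------------------------------------------------------------------


def scenario_tissues(name: str) -> frozenset[str]:
    """Resolve a scenario name to its set of insulin-resistant tissues."""
    try:
        return SCENARIO_NAMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_NAMES)}"
        ) from None


def apply_insulin_resistance(
    resistant_tissues: Iterable[str],
    *,
    sigma_G_text_value: bool = False,
    strict_liver_text: bool = False,
    overrides: Mapping[str, float] | None = None,
) -> SensitivityFactors:
    """Build sensitivity factors for a set of insulin-resistant tissues.

    A tissue listed as resistant sets exactly its clamp-literature factors and
    leaves every other factor at 1.  ``sigma_G_text_value`` selects the 0.15
    text variant for muscle glucose uptake (the table prints 0.2);
    ``strict_liver_text`` keeps hepatic glucose uptake sensitivity at 1 for a
    resistant liver, following the stricter reading of the liver scenario
    prose.  Explicit ``overrides`` by factor name win over everything.
    """
    tissues = set(resistant_tissues)
    unknown = tissues - TISSUES
    if unknown:
        raise ConfigError(f"unknown tissue name(s): {sorted(unknown)}")
    values: dict[str, float] = {}
    for tissue in sorted(tissues):  # sorted: composition independent of order
        values.update(TABLE3_FACTORS[tissue])
    if "muscle" in tissues and sigma_G_text_value:
        values["sigma_G"] = SIGMA_G_TEXT_VALUE
    if "liver" in tissues and strict_liver_text:
        values["sigma_Y"] = 1.0
    if overrides:
        bad = set(overrides) - set(SensitivityFactors.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown sensitivity factor(s): {sorted(bad)}")
        values.update(overrides)
    factors = SensitivityFactors(**values)
    factors.validate()
    return factors


def default_parameters() -> ParameterSet:
    """The registry defaults (placeholders; run calibration before simulating)."""
    return ParameterSet()


def calibrate_to_unity_steady_state(
    params: ParameterSet | None = None, insulin_model: str = "quadratic"
) -> ParameterSet:
    """Solve the twelve free coefficients so unity is a fasting equilibrium.

    With healthy sensitivities and the meal off, the twelve steady-state
    balances at the unity state are solved in closed form for the twelve
    designated coefficients (:data:`CALIBRATED_COEFFICIENTS`), one per
    equation, without touching any printed value:

    * ``lambda_I``: insulin degradation balances production at unit glucose;
    * ``T_0``: hepatic TAG export at unity balances plasma TAG clearance;
    * ``k_TH``: hepatic TAG synthesis balances that same export;
    * ``Y_0``: hepatic glycogen synthesis balances glycogenolysis;
    * ``beta_N``: basal gluconeogenesis covers the net fasting glucose
      disposal (body sink + muscle uptake + lipogenesis);
    * ``k_A``: muscle FFA uptake closes the plasma FFA balance;
    * ``S_L``: hepatic FFA oxidation closes the hepatic FFA balance;
    * ``M_G``, ``M_A``: muscle oxidation balances substrate uptake;
    * ``k_CP``, ``k_DP``: store breakdown balances store synthesis;
    * ``mu``: AMP production balances decay plus oxidative consumption.

    Raises :class:`CalibrationError`, naming the offending balance, whenever a
    coefficient would have to be negative (or a saturation constant
    inadmissible) to close its equation.
    """
    p = params if params is not None else default_parameters()
    p.validate()

    f0_unity = _f0(1.0, p, insulin_model)
    lambda_I = f0_unity + p.k_IA

    # Plasma TAG balance (T_b): hepatic export feeds muscle + adipose uptake.
    tag_clearance = p.k_T + p.k_TA * (1.0 + p.k_AI)
    if p.beta_T <= 0:
        raise CalibrationError("plasma TAG balance: beta_T must be positive")
    f3_unity = tag_clearance * (1.0 + p.k_TL) / p.beta_T
    if not (0.0 < f3_unity < 1.0):
        raise CalibrationError(
            "plasma TAG balance: required hepatic TAG export exceeds the "
            f"saturable maximum (needed f3(1) = {f3_unity:.4g}, must be < 1); "
            "increase beta_T or reduce the TAG clearance constants"
        )
    T_0 = 1.0 / f3_unity - 1.0

    # Hepatic TAG balance (T_L): synthesis from hepatic FFA matches export.
    k_TH = tag_clearance

    # Hepatic glycogen balance (Y_L): uptake k_L*f2(1) = output beta_G*f1(1)/(1+k_GL).
    if p.k_L <= 0:
        raise CalibrationError("hepatic glycogen balance: k_L must be positive")
    ratio = p.beta_G / (p.k_L * (1.0 + p.k_GL))
    if not (1.0 < ratio < p.Y_max - 1.0):
        raise CalibrationError(
            "hepatic glycogen balance: beta_G/(k_L*(1+k_GL)) = "
            f"{ratio:.4g} must lie strictly between 1 and Y_max - 1 = "
            f"{p.Y_max - 1.0:.4g} for an admissible Y_0"
        )
    Y_0 = (p.Y_max - 1.0) * (ratio - 1.0) / (p.Y_max - 1.0 - ratio)

    # Plasma glucose balance (G_b): gluconeogenesis covers net fasting disposal.
    beta_N = (1.0 + p.k_GL) * (p.S_G + p.k_G * (1.0 + p.k_GI) + p.k_AL)

    # Plasma FFA balance (A_b).
    k_A = p.beta_A / (1.0 + p.k_AA) + p.k_LB - p.k_BL
    if k_A <= 0:
        raise CalibrationError(
            "plasma FFA balance: adipose release + hepatic export do not cover "
            f"hepatic uptake (k_A = {k_A:.4g} <= 0)"
        )

    # Hepatic FFA balance (A_L).
    hepatic_ox = p.k_AL + p.k_BL - p.k_LB - k_TH
    if hepatic_ox < 0:
        raise CalibrationError(
            "hepatic FFA balance: lipogenesis + uptake do not cover export + "
            f"TAG synthesis (required oxidation = {hepatic_ox:.4g} < 0)"
        )
    S_L = hepatic_ox * (1.0 + p.k_AS)

    # Muscle glucose / glycogen balances (G_m, Y_m).
    M_G = p.k_G * (1.0 + p.k_GI)
    k_CP = p.k_Y * (1.0 + p.k_YI) / (1.0 + p.k_YP)

    # Muscle FFA / TAG balances (A_m, T_m).
    M_A = p.k_T + k_A
    k_DP = p.k_X

    # AMP marker balance (P).
    mu = p.lambda_P + p.gamma_a * M_A + p.gamma_g * M_G

    calibrated = replace(
        p,
        lambda_I=lambda_I, beta_N=beta_N, T_0=T_0, k_A=k_A, Y_0=Y_0,
        S_L=S_L, k_TH=k_TH, mu=mu, M_G=M_G, k_CP=k_CP, M_A=M_A, k_DP=k_DP,
    )
    residual = rhs(
        MetabolicState.unity(), 0.0, replace(calibrated, F=0.0),
        HEALTHY_SENSITIVITY, insulin_model,
    )
    if np.max(np.abs(residual)) > 1e-12:
        raise CalibrationError(
            f"internal error: calibration residual {np.max(np.abs(residual)):.3g}"
        )
    return calibrated


def healthy_parameters(insulin_model: str = "quadratic") -> ParameterSet:
    """Registry defaults calibrated to the unity fasting steady state."""
    return calibrate_to_unity_steady_state(default_parameters(), insulin_model)


def steady_state(
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    insulin_model: str = "quadratic",
    tol: float = 1e-11,
) -> MetabolicState:
    """Fasting (meal-free) equilibrium for an arbitrary parameterisation.

    Root-finds the vector field from the unity state (pre-relaxing by a short
    integration when the direct root search strays), and rejects solutions
    with negative components or residual above ``tol``.
    """
    p = replace(params, F=0.0)

    def fun(y: np.ndarray) -> np.ndarray:
        return rhs(np.clip(y, 0.0, None), 0.0, p, sens, insulin_model)

    best: np.ndarray | None = None
    x0 = np.ones(len(STATE_VARS))
    for attempt in range(6):
        sol = optimize.root(fun, x0, method="hybr", tol=1e-13)
        y = np.clip(sol.x, 0.0, None)
        res = float(np.max(np.abs(fun(y))))
        if res < tol and np.min(sol.x) > -1e-9:
            best = y
            break
        # pre-relax towards the attractor and retry from there, doubling the
        # horizon each time (slow store pools need long horizons)
        relax = integrate.solve_ivp(
            lambda t, y: fun(y), (0.0, 100.0 * 2.0**attempt),
            np.clip(x0, 0.0, None),
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        if not relax.success:
            raise NumericalError(f"steady-state relaxation failed: {relax.message}")
        x0 = relax.y[:, -1]
    if best is None:
        res = float(np.max(np.abs(fun(np.clip(x0, 0.0, None)))))
        raise NumericalError(
            f"steady-state search did not converge (final residual {res:.3g})"
        )
    return MetabolicState.from_array(best)


# ---------------------------------------------------------------------------
# Simulation and observables
# ---------------------------------------------------------------------------


@dataclass
class SolverOptions:
    """Integrator settings; the output grid is independent of internal steps."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_minutes: float = 1.0


@dataclass
class Trajectory:
    """A postprandial solution on a fixed output grid with derived observables."""

    t: np.ndarray                      # hours, strictly increasing
    states: np.ndarray                 # shape (len(t), 12), columns STATE_VARS
    frac_glucose_oxidation: np.ndarray
    adipose_tag_clearance: np.ndarray
    meal: Meal
    scenario: str
    params: ParameterSet
    sens: SensitivityFactors
    insulin_model: str
    solver: SolverOptions
    n_steps: int                       # right-hand-side evaluations used
    gamma_weighted: bool = True

    def series(self, name: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for i, name in enumerate(STATE_VARS):
            data[name] = self.states[:, i]
        data["frac_glucose_oxidation"] = self.frac_glucose_oxidation
        data["adipose_tag_clearance"] = self.adipose_tag_clearance
        return pd.DataFrame(data, columns=["t", *STATE_VARS,
                                           "frac_glucose_oxidation",
                                           "adipose_tag_clearance"])


def fractional_glucose_oxidation(
    state: MetabolicState | Sequence[float],
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    gamma_weighted: bool = True,
) -> float:
    """Fraction of muscle oxidation drawn from glucose, in [0, 1].

    The measure of metabolic flexibility: the insulin-stimulated glucose
    oxidation flux over total (glucose + FFA) oxidation.  By default the
    fluxes are weighted by their energy yields ``gamma_g``/``gamma_a`` (their
    AMP consumption); ``gamma_weighted=False`` compares raw substrate fluxes.
    Returns 0 by convention when both fluxes vanish.
    """
    y = state.to_array() if isinstance(state, MetabolicState) else np.asarray(state, float)
    I, G_m, A_m, P = y[0], y[8], y[10], y[7]
    glu = sens.sigma_G * params.M_G * P * I * G_m
    fat = params.M_A * P * A_m
    if gamma_weighted:
        glu, fat = params.gamma_g * glu, params.gamma_a * fat
    total = glu + fat
    return float(glu / total) if total > 0 else 0.0


def adipose_tag_clearance(
    state: MetabolicState | Sequence[float],
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
) -> float:
    """Rate of plasma TAG uptake into adipose tissue at ``state``."""
    y = state.to_array() if isinstance(state, MetabolicState) else np.asarray(state, float)
    I, T_b = y[0], y[2]
    return float(sens.phi_AT * params.k_TA * (1.0 + sens.sigma_AT * params.k_AI * I) * T_b)


def simulate(
    params: ParameterSet,
    sens: SensitivityFactors = HEALTHY_SENSITIVITY,
    meal: Meal | None = None,
    t_end: float = 12.0,
    insulin_model: str = "quadratic",
    solver: SolverOptions | None = None,
    initial_state: MetabolicState | None = None,
    scenario: str = "custom",
    gamma_weighted: bool = True,
) -> Trajectory:
    """Integrate the postprandial response to a meal given at t = 0.

    Starts from the unity fasting state (the shared initial condition of all
    scenario comparisons) unless ``initial_state`` is supplied.  The stiff-
    capable adaptive integrator is sampled on a fixed grid (default 1-minute
    spacing) so summaries do not depend on internal step placement.
    """
    if t_end <= 0:
        raise ModelInputError("t_end must be positive")
    meal = meal if meal is not None else Meal()
    solver = solver if solver is not None else SolverOptions()
    sens.validate()
    p = meal.apply(params)
    p.validate()
    y0 = (initial_state or MetabolicState.unity()).to_array()

    n = int(round(t_end * 60.0 / solver.grid_minutes))
    grid = np.linspace(0.0, t_end, n + 1)

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(y, t, p, sens, insulin_model)

    sol = integrate.solve_ivp(
        fun, (0.0, t_end), y0, method=solver.method,
        rtol=solver.rtol, atol=solver.atol, t_eval=grid,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise NumericalError(
            f"integration failed at t = {last_t:.4g} h: {sol.message}"
        )
    states = sol.y.T
    min_component = float(states.min())
    if min_component < -10.0 * solver.atol:
        raise NumericalError(
            f"non-negativity violated: min component {min_component:.3g}"
        )
    states = np.clip(states, 0.0, None)
    y_l = states[:, STATE_VARS.index("Y_L")]
    if float(y_l.max()) > p.Y_max + CAP_SLACK:
        raise GlycogenCapError(
            f"hepatic glycogen breached Y_max by {float(y_l.max()) - p.Y_max:.3g}"
        )
    states[:, STATE_VARS.index("Y_L")] = np.minimum(y_l, p.Y_max)

    I = states[:, 0]
    G_m = states[:, 8]
    A_m = states[:, 10]
    P = states[:, 7]
    T_b = states[:, 2]
    glu = sens.sigma_G * p.M_G * P * I * G_m
    fat = p.M_A * P * A_m
    if gamma_weighted:
        glu, fat = p.gamma_g * glu, p.gamma_a * fat
    total = glu + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, glu / np.where(total > 0, total, 1.0), 0.0)
    clearance = sens.phi_AT * p.k_TA * (1.0 + sens.sigma_AT * p.k_AI * I) * T_b

    return Trajectory(
        t=grid, states=states, frac_glucose_oxidation=frac,
        adipose_tag_clearance=clearance, meal=meal, scenario=scenario,
        params=p, sens=sens, insulin_model=insulin_model, solver=solver,
        n_steps=int(sol.nfev),
        gamma_weighted=gamma_weighted,
    )


def _refine_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak value and time with parabolic refinement around the grid maximum.

    The earliest grid point within solver noise of the maximum anchors the
    peak, so near-flat maxima (e.g. a series that starts at its fasting
    maximum and only declines) get a well-conditioned peak time; interpolation
    is applied only where the local curvature clearly exceeds the noise floor.
    """
    vmax = float(np.max(y))
    noise = 1e-9 * max(1.0, abs(vmax))
    i = int(np.argmax(y >= vmax - noise))
    if 1 < i < len(y) - 2:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        curvature = y0 - 2.0 * y1 + y2
        if curvature < -100.0 * noise:
            # local quartic fit: O(dt^4) bias instead of the parabola's O(dt^2)
            dt = t[i + 1] - t[i]
            xs = (t[i - 2:i + 3] - t[i]) / dt
            coeffs = np.polyfit(xs, y[i - 2:i + 3], 4)
            roots = np.roots(np.polyder(coeffs))
            best_x, best_v = 0.0, y1
            for r in roots:
                if abs(r.imag) < 1e-9 and -1.0 <= r.real <= 1.0:
                    v = float(np.polyval(coeffs, r.real))
                    if v > best_v:
                        best_x, best_v = float(r.real), v
            return best_v, float(t[i] + best_x * dt)
    return float(y[i]), float(t[i])


def _last_exit_time(
    t: np.ndarray, deviation: np.ndarray, threshold: float
) -> float | None:
    """Last time the deviation profile exits the band, linearly interpolated.

    Returns 0.0 when the band is never exited and ``None`` when the profile is
    still outside the band at the end of the window.
    """
    outside = deviation > threshold
    if not outside.any():
        return 0.0
    if outside[-1]:
        return None
    i = int(np.max(np.nonzero(outside)[0]))  # last sample outside
    d0, d1 = deviation[i], deviation[i + 1]
    frac = (d0 - threshold) / (d0 - d1) if d0 > d1 else 1.0
    return float(t[i] + frac * (t[i + 1] - t[i]))


#: Sentinel recovery value used in flattened summaries (JSON/CSV) when the
#: fasting state has not been recovered within the simulated window.
NOT_RECOVERED = "not recovered"


@dataclass
class ScenarioSummary:
    """Derived scalar descriptors of one postprandial trajectory."""

    scenario: str
    t_end: float
    peaks: dict[str, float]
    peak_times: dict[str, float]
    fasting: dict[str, float]
    net_hepatic_tag_gain: float
    flexibility_range: float
    total_oxidation: float
    peak_adipose_tag_clearance: float
    mean_adipose_tag_clearance: float
    recovery_time: float | None          # None => not recovered in the window
    recovery_times: dict[str, float | None]
    recovery_tol: float

    @property
    def recovered(self) -> bool:
        return self.recovery_time is not None

    def to_dict(self) -> dict[str, object]:
        """Flatten to plain scalars for tabulation / JSON."""
        out: dict[str, object] = {"scenario": self.scenario, "t_end": self.t_end}
        for name in STATE_VARS:
            out[f"peak_{name}"] = self.peaks[name]
            out[f"t_peak_{name}"] = self.peak_times[name]
        for name in STATE_VARS:
            out[f"fasting_{name}"] = self.fasting[name]
        out["net_hepatic_tag_gain"] = self.net_hepatic_tag_gain
        out["flexibility_range"] = self.flexibility_range
        out["total_oxidation"] = self.total_oxidation
        out["peak_adipose_tag_clearance"] = self.peak_adipose_tag_clearance
        out["mean_adipose_tag_clearance"] = self.mean_adipose_tag_clearance
        out["recovery_time"] = (
            self.recovery_time if self.recovery_time is not None else NOT_RECOVERED
        )
        out["recovered"] = self.recovered
        return out


def summarise(
    traj: Trajectory,
    recovery_tol: float = 0.01,
    fasting_state: MetabolicState | None = None,
    window: float = 12.0,
) -> ScenarioSummary:
    """Reduce a trajectory to the scalar descriptors used across scenarios.

    Peaks are componentwise maxima (parabolically interpolated between grid
    points), the net hepatic TAG gain is ``T_L(t_end) - T_L(0)``, metabolic
    flexibility is the range of fractional glucose oxidation over the window,
    and recovery is the last (interpolated) time any state component leaves
    the ``recovery_tol`` relative band around its fasting value — ``None``
    when the trajectory is still outside the band at the end of the window.
    The fasting reference defaults to the trajectory's initial state; for
    insulin-resistant scenarios started from the shared unity state, pass the
    scenario's own :func:`steady_state`.
    """
    if traj.t[-1] < window - 1e-9:
        raise ModelInputError(
            f"trajectory covers {traj.t[-1]:.3g} h < configured window {window:g} h"
        )
    fasting = (
        fasting_state.to_array() if fasting_state is not None else traj.states[0]
    )
    peaks: dict[str, float] = {}
    peak_times: dict[str, float] = {}
    recovery_times: dict[str, float | None] = {}
    worst: float | None = 0.0
    for i, name in enumerate(STATE_VARS):
        series = traj.states[:, i]
        peaks[name], peak_times[name] = _refine_peak(traj.t, series)
        ref = max(abs(fasting[i]), 1e-12)
        deviation = np.abs(series - fasting[i]) / ref
        r = _last_exit_time(traj.t, deviation, recovery_tol)
        recovery_times[name] = r
        if worst is not None:
            worst = None if r is None else max(worst, r)

    p, s = traj.params, traj.sens
    I, P, G_m, A_m = (traj.series(v) for v in ("I", "P", "G_m", "A_m"))
    glu = s.sigma_G * p.M_G * P * I * G_m
    fat = p.M_A * P * A_m
    total_ox = float(np.trapezoid(p.gamma_g * glu + p.gamma_a * fat, traj.t))

    frac = traj.frac_glucose_oxidation
    clearance = traj.adipose_tag_clearance
    return ScenarioSummary(
        scenario=traj.scenario,
        t_end=float(traj.t[-1]),
        peaks=peaks,
        peak_times=peak_times,
        fasting={name: float(fasting[i]) for i, name in enumerate(STATE_VARS)},
        net_hepatic_tag_gain=float(traj.series("T_L")[-1] - traj.series("T_L")[0]),
        flexibility_range=float(frac.max() - frac.min()),
        total_oxidation=total_ox,
        peak_adipose_tag_clearance=float(clearance.max()),
        mean_adipose_tag_clearance=float(np.trapezoid(clearance, traj.t) / (traj.t[-1] - traj.t[0])),
        recovery_time=worst,
        recovery_times=recovery_times,
        recovery_tol=recovery_tol,
    )


def count_glucose_peaks(
    traj: Trajectory, min_separation_minutes: float = 5.0, min_dip: float = 0.001
) -> int:
    """Number of distinct local maxima in plasma glucose.

    Maxima must be separated by at least ``min_separation_minutes`` and by a
    dip of at least ``min_dip`` times the global peak (the saturation of the
    hepatic glycogen store produces a shallow, minutes-long dip between two
    spikes when muscle is insulin resistant).
    """
    from scipy.signal import find_peaks

    g = traj.series("G_b")
    dt_minutes = (traj.t[1] - traj.t[0]) * 60.0
    distance = max(1, int(round(min_separation_minutes / dt_minutes)))
    peaks, _ = find_peaks(g, distance=distance, prominence=min_dip * float(g.max()))
    return int(len(peaks))


def simulate_scenario(
    name: str,
    params: ParameterSet | None = None,
    meal: Meal | None = None,
    t_end: float = 12.0,
    insulin_model: str = "quadratic",
    solver: SolverOptions | None = None,
    *,
    sigma_G_text_value: bool = False,
    strict_liver_text: bool = False,
    gamma_weighted: bool = True,
    pre_relax: bool = True,
) -> Trajectory:
    """Simulate a named insulin-resistance scenario.

    By default the run starts from the scenario's own fasting steady state
    (``pre_relax=True``): a chronically insulin-resistant subject is at their
    own baseline before the meal, which is also why resistant and healthy
    curves separate already at t = 0 (lower fasting plasma FFA with resistant
    adipose tissue, raised fasting TAG with whole-body resistance).  Pass
    ``pre_relax=False`` to start from the shared healthy unity state instead.
    """
    p = params if params is not None else healthy_parameters(insulin_model)
    sens = apply_insulin_resistance(
        scenario_tissues(name),
        sigma_G_text_value=sigma_G_text_value,
        strict_liver_text=strict_liver_text,
    )
    initial = steady_state(p, sens, insulin_model) if pre_relax else None
    return simulate(
        p, sens, meal, t_end, insulin_model, solver,
        initial_state=initial, scenario=name, gamma_weighted=gamma_weighted,
    )


def compare_scenarios(
    scenarios: Sequence[str],
    params: ParameterSet | None = None,
    meal: Meal | None = None,
    t_end: float = 12.0,
    insulin_model: str = "quadratic",
    solver: SolverOptions | None = None,
    recovery_tol: float = 0.01,
    **scenario_kwargs,
) -> pd.DataFrame:
    """One summary row per scenario, all computed with the same meal and solver.

    The fasting reference of each row is the scenario's own meal-free steady
    state, so fasting shifts caused by insulin resistance (e.g. lowered plasma
    FFA with resistant adipose tissue, raised plasma TAG with whole-body
    resistance) are visible next to the postprandial peaks.
    """
    p = params if params is not None else healthy_parameters(insulin_model)
    rows = []
    for name in scenarios:
        traj = simulate_scenario(
            name, p, meal, t_end, insulin_model, solver, **scenario_kwargs
        )
        fasting = steady_state(p, traj.sens, insulin_model)
        summary = summarise(traj, recovery_tol, fasting_state=fasting, window=t_end)
        rows.append(summary.to_dict())
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# Configuration, serialisation, fixtures
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """A fully resolvable run description (mirrors the CLI surface)."""

    scenario: str = "healthy"
    carb_kcal: float = 550.0
    fat_kcal: float = 150.0
    F: float | None = None
    duration: float = 12.0
    insulin_model: str = "quadratic"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_minutes: float = 1.0
    recovery_tol: float = 0.01
    parameters: dict[str, float] = field(default_factory=dict)
    sensitivities: dict[str, float] = field(default_factory=dict)
    sigma_G_text_value: bool = False
    strict_liver_text: bool = False
    gamma_weighted_oxidation: bool = True
    pre_relax: bool = True

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)


def resolve_config(
    config: RunConfig,
) -> tuple[ParameterSet, SensitivityFactors, Meal, SolverOptions, dict[str, str]]:
    """Resolve a :class:`RunConfig` into model inputs with full provenance.

    Parameter overrides are applied by symbol name *before* calibration, the
    printed values are never altered by calibration, and the returned
    provenance map records for every coefficient whether its value is
    printed, a scaled printed value, a placeholder default, calibrated, or
    user-overridden.
    """
    if config.insulin_model not in ("quadratic", "erf"):
        raise ConfigError(f"unknown insulin model {config.insulin_model!r}")
    base = default_parameters()
    provenance = dict(PARAM_PROVENANCE)
    if config.parameters:
        unknown = set(config.parameters) - set(ParameterSet.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown parameter override(s): {sorted(unknown)}")
        base = replace(base, **{k: float(v) for k, v in config.parameters.items()})
        for key in config.parameters:
            provenance[key] = "overridden"
    try:
        params = calibrate_to_unity_steady_state(base, config.insulin_model)
    except CalibrationError:
        raise
    for key in set(CALIBRATED_COEFFICIENTS.values()) - set(config.parameters):
        provenance[key] = "calibrated"

    sens = apply_insulin_resistance(
        scenario_tissues(config.scenario),
        sigma_G_text_value=config.sigma_G_text_value,
        strict_liver_text=config.strict_liver_text,
        overrides={k: float(v) for k, v in config.sensitivities.items()},
    )
    meal = Meal(config.carb_kcal, config.fat_kcal, config.F)
    solver = SolverOptions(
        rtol=config.rtol, atol=config.atol, grid_minutes=config.grid_minutes
    )
    for name, origin in sorted(provenance.items()):
        logger.debug("parameter %-10s = %-12.6g [%s]", name,
                     getattr(params, name), origin)
    return params, sens, meal, solver, provenance


def resolved_parameter_record(
    params: ParameterSet, sens: SensitivityFactors, provenance: Mapping[str, str]
) -> dict[str, object]:
    """JSON-ready dump of resolved parameters with per-symbol provenance."""
    return {
        "parameters": {
            name: {"value": getattr(params, name), "provenance": provenance[name]}
            for name in ParameterSet.__dataclass_fields__
        },
        "sensitivities": sens.to_dict(),
    }


#: Placeholder coefficients the fixture generator jitters (never printed ones,
#: never the calibrated slots — those are re-solved afterwards).
_JITTERABLE = (
    "k_IG", "k_I2", "k_IA", "beta_G", "S_G", "k_G", "k_L", "k_AL",
    "beta_T", "k_T", "k_TA", "beta_A", "k_BL", "k_LB", "k_AS",
    "lambda_P", "k_Y", "k_YI", "k_YP", "k_X",
)


def generate_fixture(seed: int) -> tuple[ParameterSet, SensitivityFactors]:
    """A calibrated parameter set with placeholder coefficients jittered ±20%.

    Deterministic per seed; retries up to five derived seeds when a jitter
    lands outside the admissible calibration region.
    """
    last_error: Exception | None = None
    for attempt in range(5):
        rng = np.random.default_rng(int(seed) + attempt)
        base = default_parameters()
        jitter = {
            name: getattr(base, name) * rng.uniform(0.8, 1.2)
            for name in _JITTERABLE
        }
        try:
            params = calibrate_to_unity_steady_state(replace(base, **jitter))
            return params, SensitivityFactors()
        except CalibrationError as exc:  # pragma: no cover - rare with ±20%
            last_error = exc
    raise CalibrationError(
        f"fixture generation failed for seed {seed} after 5 attempts: {last_error}"
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write the trajectory grid as RFC-4180 CSV with a stable column order."""
    traj.to_frame().to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def summary_to_json(summary: ScenarioSummary | pd.DataFrame, path) -> None:
    if isinstance(summary, pd.DataFrame):
        payload = json.loads(summary.reset_index().to_json(orient="records"))
    else:
        payload = summary.to_dict()
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
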