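"""Population PK model specification and individual parameter realisation.

A model is a one- or two-compartment IV disposition structure with
multiplicative covariate effects on its typical parameter values and
log-normal between-subject variability:

    P_i = TV_P * prod_k f_k(covariates_i) * exp(eta_i),   eta_i ~ N(0, omega_P)

Supported covariate effect forms:

``allometric_power``
    ``(cov / reference)**exponent`` — allometric body-size scaling.
``sigmoid_maturation``
    ``PMA**hill / (pma50**hill + PMA**hill)`` — sigmoidal maturation of
    clearance with postmenstrual age (weeks); bounded in (0, 1) and
    monotone increasing.
``linear``
    ``1 + slope * (cov - reference)`` — e.g. postnatal-age effect in days.
``power``
    same algebra as ``allometric_power``; kept as a separate label for
    non-size covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0

#: Covariate names a VirtualSubject must provide, with units.
COVARIATE_UNITS = {"birth_weight": "kg", "pma": "weeks", "pna": "days"}


class CovariateEffect(BaseModel):
    """One multiplicative covariate effect on a structural parameter."""

    target_parameter: str
    covariate: Literal["birth_weight", "pma", "pna"]
    kind: Literal["allometric_power", "sigmoid_maturation", "linear", "power"]
    reference: Optional[float] = None
    exponent: Optional[float] = None
    pma50: Optional[float] = None
    hill: Optional[float] = None
    slope: Optional[float] = None

    @model_validator(mode="after")
    def _check_constants(self) -> "CovariateEffect":
        if self.kind in ("allometric_power", "power"):
            if self.reference is None or self.exponent is None:
                raise ValueError(f"{self.kind} effect needs 'reference' and 'exponent'")
            if self.reference <= 0:
                raise ValueError("reference value must be > 0")
        elif self.kind == "sigmoid_maturation":
            if self.pma50 is None or self.hill is None:
                raise ValueError("sigmoid_maturation effect needs 'pma50' and 'hill'")
            if self.pma50 <= 0 or self.hill <= 0:
                raise ValueError("pma50 and hill must be > 0")
            if self.covariate != "pma":
                raise ValueError("sigmoid_maturation is defined on the 'pma' covariate")
        elif self.kind == "linear":
            if self.reference is None or self.slope is None:
                raise ValueError("linear effect needs 'reference' and 'slope'")
        return self

    def factor(self, value: float) -> float:
        """Multiplicative factor for a covariate value."""
        if self.kind in ("allometric_power", "power"):
            return (value / self.reference) ** self.exponent
        if self.kind == "sigmoid_maturation":
            num = value**self.hill
            return num / (self.pma50**self.hill + num)
        return 1.0 + self.slope * (value - self.reference)


class ResidualErrorSpec(BaseModel):
    """Combined proportional + additive residual error.

    ``sd(obs | pred) = sqrt((proportional_sd * pred)**2 + additive_sd**2)``,
    proportional_sd as a fraction, additive_sd in mg/L.
    """

    proportional_sd: float = Field(ge=0.0)
    additive_sd: float = Field(ge=0.0)

    def sd(self, pred: np.ndarray) -> np.ndarray:
        return np.sqrt((self.proportional_sd * np.asarray(pred)) ** 2 + self.additive_sd**2)


class ModelSpec(BaseModel):
    """Structural model + covariate model + variability, loaded from config."""

    drug_name: str
    n_compartments: Literal[1, 2]
    parameter_names: list[str]
    typical_values: dict[str, float]
    covariate_effects: list[CovariateEffect] = Field(default_factory=list)
    omega: dict[str, float] = Field(default_factory=dict)
    residual_error: ResidualErrorSpec

    @field_validator("omega")
    @classmethod
    def _nonneg_omega(cls, v: dict[str, float]) -> dict[str, float]:
        for name, var in v.items():
            if var < 0:
                raise ValueError(f"omega variance for {name!r} must be >= 0, got {var}")
        return v

    @model_validator(mode="after")
    def _check_structure(self) -> "ModelSpec":
        required = {"CL", "V"} | ({"Q", "V2"} if self.n_compartments == 2 else set())
        if not required <= set(self.parameter_names):
            raise ValueError(f"parameter_names must include {sorted(required)}")
        for name in self.parameter_names:
            if name not in self.typical_values:
                raise ValueError(f"missing typical value for parameter {name!r}")
            if self.typical_values[name] <= 0:
                raise ValueError(f"typical value for {name!r} must be > 0")
        declared = set(self.parameter_names)
        for eff in self.covariate_effects:
            if eff.target_parameter not in declared:
                raise ValueError(
                    f"covariate effect targets undeclared parameter {eff.target_parameter!r}"
                )
        for name in self.omega:
            if name not in declared:
                raise ValueError(f"omega given for undeclared parameter {name!r}")
        return self

    @property
    def random_effect_names(self) -> list[str]:
        """Parameters with a (possibly zero) BSV variance, in declaration order."""
        return [p for p in self.parameter_names if p in self.omega]


@dataclass(frozen=True)
class IndividualParameters:
    """Realised PK parameters for one subject (L/h and L)."""

    subject_id: str
    cl: float
    v: float
    q: Optional[float] = None
    v2: Optional[float] = None

    def __post_init__(self) -> None:
        for name, val in (("CL", self.cl), ("V", self.v), ("Q", self.q), ("V2", self.v2)):
            if val is not None and val <= 0:
                raise ValueError(f"individual {name} must be > 0, got {val}")
        if (self.q is None) != (self.v2 is None):
            raise ValueError("Q and V2 must be given together")


def subject_covariates(subject, at_time_h: float = 24.0) -> dict[str, float]:
    """Covariate vector for a subject at ``at_time_h`` hours after birth.

    Time origin is birth, so PNA(t) = t/24 days and PMA(t) = GA + t/168 weeks.
    The default (24 h) is the midpoint of the 48-h analysis window; over that
    window PMA changes by <0.3 weeks, so a single evaluation point is adequate.
    """
    return {
        "birth_weight": subject.birth_weight,
        "pma": subject.ga_weeks + at_time_h / HOURS_PER_WEEK,
        "pna": at_time_h / HOURS_PER_DAY,
    }


def individual_parameters(
    subject,
    spec: ModelSpec,
    typical_values: Optional[dict[str, float]] = None,
    eta: Optional[dict[str, float] | np.ndarray] = None,
    at_time_h: float = 24.0,
) -> IndividualParameters:
    """Realise individual PK parameters from covariates and random effects.

    ``eta`` may be a dict keyed by parameter name or an array ordered as
    ``spec.random_effect_names``; omitted entries are 0 (population-typical).
    """
    tvs = typical_values if typical_values is not None else spec.typical_values
    cov = subject_covariates(subject, at_time_h)

    if isinstance(eta, np.ndarray):
        names = spec.random_effect_names
        if eta.shape[-1] != len(names):
            raise ValueError(f"eta array must have {len(names)} entries ({names})")
        eta = dict(zip(names, np.asarray(eta, dtype=float)))
    eta = eta or {}

    values: dict[str, float] = {}
    for name in spec.parameter_names:
        p = float(tvs[name])
        for eff in spec.covariate_effects:
            if eff.target_parameter != name:
                continue
            if eff.covariate not in cov:
                raise KeyError(f"subject {subject.subject_id} lacks covariate {eff.covariate!r}")
            p *= eff.factor(cov[eff.covariate])
        p *= float(np.exp(eta.get(name, 0.0)))
        if not p > 0:
            raise ValueError(
                f"non-positive individual {name} ({p}) for subject {subject.subject_id}"
            )
        values[name] = p

    return IndividualParameters(
        subject_id=str(subject.subject_id),
        cl=values["CL"],
        v=values["V"],
        q=values.get("Q"),
        v2=values.get("V2"),
    )


def sample_etas(spec: ModelSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent random-effect vectors, one column per entry of
    ``spec.random_effect_names``; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sds = np.sqrt([spec.omega[name] for name in spec.random_effect_names])
    return rng.standard_normal((n, len(sds))) * sds


_DATA_DIR = Path(__file__).parent / "data"

#: Bundled model configurations (name -> file). The two drug models carry
#: synthetic, literature-informed parameter values (see their YAML headers);
#: ``demo`` is a fully invented model for tests and examples.
BUNDLED_MODELS = {
    "amoxicillin": "amoxicillin_onecpt_synthetic.yaml",
    "benzylpenicillin": "benzylpenicillin_twocpt_synthetic.yaml",
    "demo": "demo_model.yaml",
}


def load_model_spec(source: str | Path) -> ModelSpec:
    """Load and validate a model config from a YAML file or a bundled name."""
    if isinstance(source, str) and source in BUNDLED_MODELS:
        source = _DATA_DIR / BUNDLED_MODELS[source]
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    return ModelSpec.model_validate(raw)


def warn_if_extrapolating(spec: ModelSpec, cov: dict[str, float]) -> None:
    """Log a warning when covariates fall outside typical neonatal ranges.

    Values are used as-is (no clamping): the simulations deliberately
    extrapolate the published models down to GA 24 weeks.
    """
    if not 24.0 <= cov.get("pma", 30.0) <= 46.0:
        msg = f"PMA {cov['pma']:.1f} weeks outside typical neonatal range; extrapolating"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
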