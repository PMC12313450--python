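"""GA-stratified virtual neonatal population with GA-matched birth weights.

Birth weight at a given whole gestational week is drawn from a log-normal
distribution fitted to published-growth-chart-style 3rd/50th/97th percentile
values shipped as editable config (mu = ln p50; sigma from the p3-p97 span).
Postnatal growth over the 48-h analysis window is ignored: dosing weight and
allometric weight equal birth weight throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .model import ModelSpec, sample_etas

_Z97 = norm.ppf(0.97)
_Z999 = norm.ppf(0.999)


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated neonate at birth."""

    subject_id: str
    ga_weeks: float
    birth_weight: float  # kg
    eta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 24.0 <= self.ga_weeks <= 42.0:
            raise ValueError(f"GA must be within 24-42 weeks, got {self.ga_weeks}")
        if self.birth_weight <= 0:
            raise ValueError("birth_weight must be > 0")


@dataclass
class GrowthReference:
    """Per-GA-week log-normal birth-weight distributions."""

    mu: dict[int, float]  # ln(kg)
    sigma: dict[int, float]

    def __post_init__(self) -> None:
        weeks = sorted(self.mu)
        medians = [np.exp(self.mu[w]) for w in weeks]
        if np.any(np.diff(medians) <= 0):
            raise ValueError("median birth weight must increase strictly with GA week")
        if any(self.sigma[w] < 0 for w in weeks):
            raise ValueError("sigma must be >= 0")

    @classmethod
    def from_percentiles(cls, table: pd.DataFrame) -> "GrowthReference":
        """Fit from a table with columns ga_week, p3_kg, p50_kg, p97_kg."""
        mu, sigma = {}, {}
        for row in table.itertuples(index=False):
            week = int(row.ga_week)
            mu[week] = float(np.log(row.p50_kg))
            sigma[week] = float((np.log(row.p97_kg) - np.log(row.p3_kg)) / (2.0 * _Z97))
        return cls(mu=mu, sigma=sigma)

    def median(self, ga_week: int) -> float:
        return float(np.exp(self.mu[ga_week]))

    @property
    def weeks(self) -> list[int]:
        return sorted(self.mu)


_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_GROWTH_REFERENCE = _DATA_DIR / "growth_reference.yaml"


def load_growth_reference(path: str | Path = DEFAULT_GROWTH_REFERENCE) -> GrowthReference:
    """Load the percentile config and fit per-week log-normals."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GrowthReference.from_percentiles(pd.DataFrame(raw["birth_weight_percentiles"]))


def sample_birth_weight(
    ga_week: int,
    ref: GrowthReference,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` birth weights (kg) for a whole GA week; reproducible under seed."""
    if ga_week not in ref.mu:
        raise ValueError(f"GA week {ga_week} outside growth reference ({min(ref.mu)}-{max(ref.mu)})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    # truncate to the 0.1st-99.9th percentile envelope: growth charts do not
    # support weights beyond it and downstream dosing strata assume plausible
    # weights
    z = np.clip(z, -_Z999, _Z999)
    return np.exp(ref.mu[ga_week] + ref.sigma[ga_week] * z)


def generate_population(
    ga_min: int,
    ga_max: int,
    n_per_week: int,
    ref: GrowthReference,
    seed: int,
    model_spec: Optional[ModelSpec] = None,
) -> list[VirtualSubject]:
    """GA-stratified population: exactly ``n_per_week`` subjects per whole GA
    week from ``ga_min`` to ``ga_max`` inclusive (defaults elsewhere: 24-42,
    500/week -> N=9500). If ``model_spec`` is given, each subject also receives
    a between-subject random-effect vector drawn from its omegas, so regimen
    comparisons on the same population are paired.
    """
    if n_per_week < 1:
        raise ValueError("n_per_week must be >= 1")
    if ga_min > ga_max:
        raise ValueError("ga_min must be <= ga_max")
    rng = np.random.default_rng(seed)
    subjects: list[VirtualSubject] = []
    for week in range(ga_min, ga_max + 1):
        weights = sample_birth_weight(week, ref, n_per_week, rng)
        etas = sample_etas(model_spec, n_per_week, rng) if model_spec is not None else None
        for i in range(n_per_week):
            subjects.append(
                VirtualSubject(
                    subject_id=f"GA{week}-{i + 1:04d}",
                    ga_weeks=float(week),
                    birth_weight=float(weights[i]),
                    eta=None if etas is None else etas[i],
                )
            )
    return subjects


def population_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    """Tidy view (id, GA, birth weight) for CSV export."""
    return pd.DataFrame(
        {
            "id": [s.subject_id for s in subjects],
            "ga_weeks": [s.ga_weeks for s in subjects],
            "birth_weight_kg": [s.birth_weight for s in subjects],
        }
    )
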