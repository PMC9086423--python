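"""Input data model for the FOLFOX-HAIC versus TACE cost-effectiveness model.

Everything the model consumes is collected in a single :class:`ParameterSet`:
the parametric survival curves fitted to the TACE arm of the source trial,
hazard ratios for the FOLFOX-HAIC arm, treatment schedules and unit costs,
adverse-event profiles, health-state utilities, an age-banded background
life table, and structural settings (cycle length, horizon, discount rate,
willingness-to-pay threshold).

The bundled baseline (``load_baseline``) reproduces the published input
table verbatim; any other configuration can be supplied as a YAML file with
the same schema (``read_config`` / ``write_config``).
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Family(str, enum.Enum):
    """Parametric survival families used for extrapolation."""

    log_logistic = "log_logistic"
    lognormal = "lognormal"


class Distribution(str, enum.Enum):
    """Distribution family attached to an uncertain parameter for PSA."""

    beta = "beta"
    gamma = "gamma"
    lognormal = "lognormal"
    uniform = "uniform"
    fixed = "fixed"


class StrategyName(str, enum.Enum):
    FOLFOX_HAIC = "FOLFOX_HAIC"
    TACE = "TACE"


class State(str, enum.Enum):
    """Health states of the cohort model."""

    PFD = "PFD"  # progression-free disease
    RFD = "RFD"  # recurrence-free disease (post-hepatectomy)
    PD = "PD"  # progressed disease
    DEATH = "Death"


class SurvivalModel(BaseModel):
    """A parametric survival curve, S(t) with t in months.

    ``log_logistic``: S(t) = 1 / (1 + theta * t**kappa), theta > 0, kappa > 0.
    ``lognormal``:    S(t) = 1 - Phi((ln t - mu) / sigma), sigma > 0.
    """

    model_config = ConfigDict(extra="forbid")

    family: Family
    params: dict[str, float]
    time_unit: Literal["months"] = "months"

    @model_validator(mode="after")
    def _check_params(self) -> "SurvivalModel":
        if self.family is Family.log_logistic:
            missing = {"theta", "kappa"} - set(self.params)
            if missing:
                raise ValueError(f"log_logistic model missing {sorted(missing)}")
            if self.params["theta"] <= 0 or self.params["kappa"] <= 0:
                raise ValueError("log_logistic requires theta > 0 and kappa > 0")
        else:
            missing = {"mu", "sigma"} - set(self.params)
            if missing:
                raise ValueError(f"lognormal model missing {sorted(missing)}")
            if self.params["sigma"] <= 0:
                raise ValueError("lognormal requires sigma > 0")
        return self


class UncertainParam(BaseModel):
    """A point estimate with an uncertainty range and a PSA distribution."""

    model_config = ConfigDict(extra="forbid")

    baseline: float
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: Distribution = Distribution.fixed

    @model_validator(mode="after")
    def _check_range(self) -> "UncertainParam":
        if self.low is not None and self.high is not None:
            if not (self.low <= self.baseline <= self.high):
                raise ValueError(
                    f"range must satisfy low <= baseline <= high, got "
                    f"[{self.low}, {self.baseline}, {self.high}]"
                )
        if self.distribution is Distribution.beta and not 0.0 <= self.baseline <= 1.0:
            raise ValueError("beta-distributed baseline must lie in [0, 1]")
        if self.distribution is Distribution.gamma and self.baseline < 0.0:
            raise ValueError("gamma-distributed baseline must be >= 0")
        return self

    def has_range(self) -> bool:
        return self.low is not None and self.high is not None


def default_range(p: UncertainParam) -> UncertainParam:
    """Fill a missing uncertainty range as +/-20% of baseline.

    The range is clamped to the distribution's support (beta: [0, 1];
    gamma: [0, inf)).  Parameters that already carry a range are returned
    unchanged.
    """
    if p.has_range():
        return p
    low = 0.8 * p.baseline
    high = 1.2 * p.baseline
    if p.baseline < 0:
        low, high = high, low
    if p.distribution is Distribution.beta:
        low = max(low, 0.0)
        high = min(high, 1.0)
    elif p.distribution is Distribution.gamma:
        low = max(low, 0.0)
    return p.model_copy(update={"low": low, "high": high})


class AdverseEvent(BaseModel):
    """One grade >=3 adverse event: incidence, management cost, disutility."""

    model_config = ConfigDict(extra="forbid")

    label: str
    incidence: UncertainParam
    unit_cost: UncertainParam
    disutility: UncertainParam


class StrategyParams(BaseModel):
    """Treatment-arm-specific inputs: schedule, costs, AEs, downstream mix."""

    model_config = ConfigDict(extra="forbid")

    name: StrategyName
    per_session_costs: dict[str, UncertainParam]
    n_sessions: float = Field(gt=0)
    session_interval_days: float = Field(gt=0)
    hepatectomy_proportion: UncertainParam
    ae_profile: list[AdverseEvent]
    subsequent_mix: dict[Literal["bsc", "crossover"], UncertainParam]

    @model_validator(mode="after")
    def _check_mix(self) -> "StrategyParams":
        missing = {"bsc", "crossover"} - set(self.subsequent_mix)
        if missing:
            raise ValueError(f"subsequent_mix missing {sorted(missing)}")
        return self


class LifeTable(BaseModel):
    """Age-banded annual background mortality probabilities.

    Bands are (age_low, age_high, annual_probability); the terminal band is
    open-ended (age_high = inf) with probability 1.
    """

    model_config = ConfigDict(extra="forbid")

    age_bands: list[tuple[float, float, float]]

    @model_validator(mode="after")
    def _check_bands(self) -> "LifeTable":
        if not self.age_bands:
            raise ValueError("life table must have at least one band")
        prev_high = 0.0
        for low, high, p in self.age_bands:
            if not math.isclose(low, prev_high, abs_tol=1e-9):
                raise ValueError(f"life-table bands not contiguous at age {low}")
            if high <= low:
                raise ValueError(f"empty life-table band [{low}, {high})")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"annual probability {p} outside [0, 1]")
            prev_high = high
        if not math.isinf(self.age_bands[-1][1]):
            raise ValueError("terminal life-table band must be open-ended")
        if self.age_bands[-1][2] != 1.0:
            raise ValueError("terminal life-table band must have probability 1")
        return self

    def annual_probability(self, age: float) -> float:
        """Annual background mortality probability for a given age (total lookup)."""
        if age < 0:
            raise ValueError("age must be >= 0")
        for low, high, p in self.age_bands:
            if low <= age < high:
                return p
        return self.age_bands[-1][2]


class Structural(BaseModel):
    """Structural model settings (not sampled in the PSA)."""

    model_config = ConfigDict(extra="forbid")

    cycle_length_days: float = 21.0
    start_age_years: float = 55.0
    horizon_years: float = 30.0
    wtp_per_qaly: float = 30552.0
    half_cycle_correction: bool = False
    # Death hazard applied in the post-hepatectomy RFD state: "os_hazard"
    # keeps RFD patients on the arm's all-cause OS-implied hazard (the trial
    # ITT OS curve already includes patients who underwent hepatectomy);
    # "background" grants them general-population mortality until recurrence.
    rfd_mortality: Literal["os_hazard", "background"] = "os_hazard"
    # How life-table mortality enters the disease curves: "floor" takes the
    # per-cycle death probability as max(disease-implied, background);
    # "multiplicative" multiplies the survival functions (independent risks).
    background_mortality: Literal["floor", "multiplicative"] = "floor"
    # Hospitalization cost accrual: one stay per treatment administration,
    # or per 21-day model cycle across the first-line treatment period.
    hospitalization: Literal["per_session", "per_cycle"] = "per_session"


class ParameterSet(BaseModel):
    """The complete model input vector."""

    model_config = ConfigDict(extra="forbid")

    os_tace: SurvivalModel
    pfs_tace: SurvivalModel
    hr_os: UncertainParam
    hr_pfs: UncertainParam
    strategies: dict[StrategyName, StrategyParams]
    recurrence_5yr: UncertainParam
    utilities: dict[Literal["PFD", "RFD", "PD"], UncertainParam]
    shared_costs: dict[
        Literal["hepatectomy", "hospitalization_per_cycle", "bsc_per_cycle"],
        UncertainParam,
    ]
    discount_rate_annual: UncertainParam
    life_table: LifeTable
    structural: Structural = Structural()

    @model_validator(mode="after")
    def _check_complete(self) -> "ParameterSet":
        for name in (StrategyName.FOLFOX_HAIC, StrategyName.TACE):
            if name not in self.strategies:
                raise ValueError(f"strategies missing {name.value}")
        for key in ("PFD", "RFD", "PD"):
            if key not in self.utilities:
                raise ValueError(f"utilities missing {key}")
        for key in ("hepatectomy", "hospitalization_per_cycle", "bsc_per_cycle"):
            if key not in self.shared_costs:
                raise ValueError(f"shared_costs missing {key}")
        for key, u in self.utilities.items():
            if not 0.0 <= u.baseline <= 1.0:
                raise ValueError(f"utility {key} baseline {u.baseline} outside [0, 1]")
        return self


_BASELINE_RESOURCE = "baseline.yaml"


def load_baseline() -> ParameterSet:
    """Return the bundled baseline parameter set (published input tables)."""
    text = resources.files("hcc_cea").joinpath("data", _BASELINE_RESOURCE).read_text()
    return ParameterSet.model_validate(yaml.safe_load(text))


def read_config(path: str | Path) -> ParameterSet:
    """Read a ParameterSet from a YAML config file (validated on load)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ParameterSet.model_validate(data)


def write_config(ps: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet to YAML such that ``read_config`` round-trips it."""
    path = Path(path)
    data = ps.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
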