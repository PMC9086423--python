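"""Parametric survival curves, hazard-ratio transforms and background mortality.

Time is measured in months throughout (1 month = 30.4375 days, so one
21-day model cycle is ~0.6899 months).  Disease-specific curves come from
the published parametric fits to the TACE arm; the FOLFOX-HAIC arm is
obtained by the proportional-hazards transform S(t)**HR.  Background
(all-cause) mortality from an age-banded life table is combined
multiplicatively, treating it as an independent competing risk.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats

from .parameters import Family, LifeTable, SurvivalModel

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0

# annual probability 1 in the terminal life-table band maps to a finite but
# effectively immediate hazard
_MAX_ANNUAL_PROB = 1.0 - 1e-12

SurvivalFunction = Callable[[np.ndarray], np.ndarray]


def survival_at(model: SurvivalModel, t) -> np.ndarray | float:
    """Evaluate S(t) for a parametric model; t in months, scalar or array."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be >= 0")
    if model.family is Family.log_logistic:
        theta = model.params["theta"]
        kappa = model.params["kappa"]
        s = 1.0 / (1.0 + theta * np.power(t_arr, kappa))
    else:
        mu = model.params["mu"]
        sigma = model.params["sigma"]
        with np.errstate(divide="ignore"):
            z = (np.log(t_arr, where=t_arr > 0, out=np.full_like(t_arr, -np.inf)) - mu) / sigma
        s = stats.norm.sf(z)
    s = np.where(t_arr == 0.0, 1.0, s)
    return float(s) if np.isscalar(t) or s.ndim == 0 else s


def survival_function(model: SurvivalModel) -> SurvivalFunction:
    """Return S as a callable of time in months."""
    return lambda t: survival_at(model, t)


def median_survival(model: SurvivalModel) -> float:
    """Closed-form median: (1/theta)**(1/kappa) (log-logistic) or e**mu (lognormal)."""
    if model.family is Family.log_logistic:
        return (1.0 / model.params["theta"]) ** (1.0 / model.params["kappa"])
    return float(np.exp(model.params["mu"]))


def apply_hr(s_base: SurvivalFunction, hr: float) -> SurvivalFunction:
    """Proportional-hazards transform: S_new(t) = S_base(t)**hr."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return lambda t: np.power(s_base(t), hr)


def cycle_event_prob(s: SurvivalFunction, t_start: float, t_end: float) -> float:
    """Conditional probability of the event within (t_start, t_end]."""
    if not 0 <= t_start < t_end:
        raise ValueError("need 0 <= t_start < t_end")
    s0 = float(s(t_start))
    if s0 <= 0.0:
        return 1.0
    return 1.0 - float(s(t_end)) / s0


def annual_to_cycle_prob(p_annual, cycle_days: float):
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year: p_cycle = 1 - (1-p)**(d/365.25).
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("annual probability must lie in [0, 1]")
    out = 1.0 - np.power(1.0 - np.minimum(p, _MAX_ANNUAL_PROB), cycle_days / DAYS_PER_YEAR)
    out = np.where(p >= 1.0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def background_mortality(lt: LifeTable, age: float, cycle_days: float) -> float:
    """Per-cycle background death probability at a given age."""
    return float(annual_to_cycle_prob(lt.annual_probability(age), cycle_days))


def life_table_log_survival(lt: LifeTable, start_age: float, t_years) -> np.ndarray:
    """log S_bg(t): cumulative-hazard survival from ``start_age``.

    Each band contributes a constant hazard -ln(1 - p) per year; the
    terminal band's probability of 1 is clipped to keep the hazard finite
    (survival decays to ~0 within a year of entering it).
    """
    t = np.atleast_1d(np.asarray(t_years, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    age = start_age + t
    rates = np.array(
        [-np.log1p(-min(p, _MAX_ANNUAL_PROB)) for _, _, p in lt.age_bands]
    )
    edges = np.array([b[0] for b in lt.age_bands] + [np.inf])
    cum = np.zeros_like(age)
    for i, rate in enumerate(rates):
        lo, hi = edges[i], edges[i + 1]
        overlap = np.clip(np.minimum(age, hi) - np.maximum(start_age, lo), 0.0, None)
        cum += rate * overlap
    out = -cum
    return out if np.asarray(t_years).ndim else float(out[0])


def life_table_survival(lt: LifeTable, start_age: float, t_years) -> np.ndarray:
    """S_bg(t) from the life table, t in years since model entry."""
    return np.exp(life_table_log_survival(lt, start_age, t_years))


def blend_background(
    s_disease: SurvivalFunction, lt: LifeTable, start_age: float
) -> SurvivalFunction:
    """All-cause survival S_disease(t) * S_bg(t) (independent risks); t in months."""

    def s_all(t):
        t_arr = np.asarray(t, dtype=float)
        return s_disease(t_arr) * life_table_survival(lt, start_age, t_arr / MONTHS_PER_YEAR)

    return s_all
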