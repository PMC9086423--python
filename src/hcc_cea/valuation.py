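"""Discounted cost and QALY accrual over a cohort trace.

Cost components per arm:

* first-line therapy — per-session drug/procedure costs on the calendar
  schedule (FOLFOX-HAIC every 21 days, mean 3.6 sessions; TACE every 42
  days, mean 2 sessions), weighted by progression-free occupancy at each
  session time;
* hospitalization — a per-cycle cost over the first-line treatment period,
  weighted by progression-free occupancy;
* hepatectomy — a one-off cost per RFD entrant;
* subsequent treatment — crossover therapy (the other arm's regimen, on its
  own schedule) for the crossover share of newly progressed patients, and a
  per-cycle best-supportive-care cost for the BSC share of PD occupancy
  (post-recurrence PD patients receive BSC only);
* adverse events — a one-off cost at model entry, sum of incidence x unit
  cost over grade >=3 events.

QALYs multiply state occupancy by the state utilities (PFD and RFD 0.76,
PD 0.68 at baseline) and subtract a one-off AE disutility decrement.  All
flows are discounted at the annual rate (3% baseline) from model entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import TraceArrays, cycle_accrual_weights, run_trace_arrays
from .parameters import ParameterSet, StrategyName
from .registry import EngineInputs, StrategyInputs, build_engine_inputs
from .survival import DAYS_PER_YEAR, MONTHS_PER_YEAR

COST_COMPONENTS = (
    "first_line",
    "hospitalization",
    "hepatectomy",
    "subsequent_crossover",
    "bsc",
    "adverse_events",
)


def discount_factor(t_years, annual_rate):
    """(1 + r)^(-t) discount factor at time t in years."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if np.any(np.asarray(annual_rate) <= -1):
        raise ValueError("annual rate must exceed -1")
    out = np.power(1.0 + annual_rate, -t)
    return float(out) if out.ndim == 0 else out


@dataclass
class CEAResult:
    """Discounted totals for one strategy."""

    strategy: StrategyName
    cost_total: float
    qalys: float
    life_years: float
    cost_components: dict[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        data = {
            "strategy": self.strategy.value,
            "cost_total": self.cost_total,
            "qalys": self.qalys,
            "life_years": self.life_years,
        }
        data.update({f"cost_{k}": v for k, v in self.cost_components.items()})
        return pd.Series(data)


def _session_schedule(si: StrategyInputs) -> tuple[np.ndarray, np.ndarray]:
    """(times_days, weights) of treatment sessions; fractional final session."""
    n_full = int(np.ceil(si.n_sessions - 1e-9))
    j = np.arange(n_full)
    weights = np.minimum(1.0, si.n_sessions - j)
    return j * si.interval_days, weights


def _col_at(arr: np.ndarray, idx: float) -> np.ndarray:
    """Occupancy column at a possibly fractional cycle index (linear interp)."""
    i0 = int(np.floor(idx))
    frac = idx - i0
    if frac < 1e-12 or i0 + 1 >= arr.shape[1]:
        return arr[:, min(i0, arr.shape[1] - 1)]
    return arr[:, i0] * (1.0 - frac) + arr[:, i0 + 1] * frac


def accrue_arrays(
    ps: ParameterSet, inp: EngineInputs, strategy: StrategyName, tr: TraceArrays
) -> dict[str, np.ndarray]:
    """Vectorized cost/QALY accrual; returns component arrays of shape (n,)."""
    st = ps.structural
    cycle_days = st.cycle_length_days
    cyc_years = cycle_days / DAYS_PER_YEAR
    t_years = tr.t_months / MONTHS_PER_YEAR
    rate = np.atleast_1d(inp.discount_rate)
    si = inp.strategies[strategy]
    other = (
        StrategyName.TACE if strategy is StrategyName.FOLFOX_HAIC else StrategyName.FOLFOX_HAIC
    )
    so = inp.strategies[other]

    d_bound = np.power(1.0 + rate[:, None], -t_years[None, :])  # (n, T+1)

    # first-line sessions, weighted by progression-free occupancy
    times_days, weights = _session_schedule(si)
    first_line = np.zeros_like(rate)
    for t_d, w in zip(times_days, weights):
        idx = t_d / cycle_days
        occ = _col_at(tr.pfd, idx)
        disc = np.power(1.0 + rate, -(t_d / DAYS_PER_YEAR))
        first_line = first_line + w * si.session_cost * occ * disc

    # hospitalization: one stay per treatment administration (default), or
    # per model cycle across the first-line treatment period
    hosp = np.zeros_like(rate)
    if st.hospitalization == "per_session":
        for t_d, w in zip(times_days, weights):
            occ = _col_at(tr.pfd, t_d / cycle_days)
            disc = np.power(1.0 + rate, -(t_d / DAYS_PER_YEAR))
            hosp = hosp + w * inp.cost_hospitalization * occ * disc
    else:
        dur_cycles = si.n_sessions * si.interval_days / cycle_days
        for c in range(int(np.ceil(dur_cycles - 1e-9))):
            w = min(1.0, dur_cycles - c)
            hosp = hosp + w * inp.cost_hospitalization * tr.pfd[:, c] * d_bound[:, c]

    # one-off hepatectomy cost per RFD entrant
    hepatectomy = inp.cost_hepatectomy * (tr.entrants_rfd * d_bound).sum(axis=1)

    # crossover therapy for newly progressed main-branch patients: the other
    # arm's regimen on its own schedule, discounted from PD entry
    x_times, x_weights = _session_schedule(so)
    sched_factor = np.sum(
        x_weights[None, :] * np.power(1.0 + rate[:, None], -(x_times[None, :] / DAYS_PER_YEAR)),
        axis=1,
    )
    crossover = (
        so.session_cost
        * si.cross_share
        * sched_factor
        * (tr.entrants_pd_main * d_bound).sum(axis=1)
    )

    # per-cycle BSC for the BSC share of PD occupancy (recurrence-origin PD
    # patients are all managed with BSC)
    half = st.half_cycle_correction
    bsc_occ = cycle_accrual_weights(tr.pd_main, t_years, rate, half) * si.bsc_share[:, None]
    bsc_occ = bsc_occ + cycle_accrual_weights(tr.pd_rfd, t_years, rate, half)
    bsc = inp.cost_bsc * bsc_occ.sum(axis=1)

    adverse_events = si.ae_cost * np.ones_like(rate)

    # QALYs and LYs
    utility_weighted = (
        inp.u_pfd[:, None] * cycle_accrual_weights(tr.pfd, t_years, rate, half)
        + inp.u_rfd[:, None] * cycle_accrual_weights(tr.rfd, t_years, rate, half)
        + inp.u_pd[:, None] * cycle_accrual_weights(tr.pd, t_years, rate, half)
    )
    qalys = utility_weighted.sum(axis=1) * cyc_years - si.ae_disutility * cyc_years
    qalys = np.clip(qalys, 0.0, None)
    lys = cycle_accrual_weights(tr.alive, t_years, rate, half).sum(axis=1) * cyc_years

    components = {
        "first_line": first_line,
        "hospitalization": hosp,
        "hepatectomy": hepatectomy,
        "subsequent_crossover": crossover,
        "bsc": bsc,
        "adverse_events": adverse_events,
    }
    total = sum(components.values())
    return {"cost_total": total, "qalys": qalys, "life_years": lys, **components}


def evaluate_strategy(
    ps: ParameterSet, strategy: StrategyName, inp: EngineInputs | None = None
) -> CEAResult:
    """Run the trace and accrue discounted costs and QALYs for one strategy."""
    strategy = StrategyName(strategy)
    if inp is None:
        inp = build_engine_inputs(ps)
    tr = run_trace_arrays(ps, inp, strategy)
    acc = accrue_arrays(ps, inp, strategy, tr)
    return CEAResult(
        strategy=strategy,
        cost_total=float(acc["cost_total"][0]),
        qalys=float(acc["qalys"][0]),
        life_years=float(acc["life_years"][0]),
        cost_components={k: float(acc[k][0]) for k in COST_COMPONENTS},
    )


def accrue_costs(ps: ParameterSet, strategy: StrategyName, tr: TraceArrays) -> dict[str, float]:
    """Cost breakdown (USD, discounted) for a trace; scalar convenience wrapper."""
    inp = build_engine_inputs(ps)
    acc = accrue_arrays(ps, inp, StrategyName(strategy), tr)
    return {k: float(acc[k][0]) for k in COST_COMPONENTS + ("cost_total",)}


def accrue_qalys(ps: ParameterSet, strategy: StrategyName, tr: TraceArrays) -> float:
    """Discounted QALYs for a trace."""
    inp = build_engine_inputs(ps)
    return float(accrue_arrays(ps, inp, StrategyName(strategy), tr)["qalys"][0])
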