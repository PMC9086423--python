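"""Cohort state-transition engine.

Four states: progression-free disease (PFD), recurrence-free disease after
hepatectomy (RFD), progressed disease (PD) and Death.  Transition
probabilities are derived each 21-day cycle from the arm's all-cause OS and
PFS curves so that, absent hepatectomy, the chain reproduces a partitioned
survival analysis exactly (PFD = S_PFS, PD = S_OS - S_PFS, Death = 1 - S_OS).

At the end of first-line treatment a fraction of the still progression-free
cohort undergoes hepatectomy and moves to RFD, where it faces a constant
recurrence hazard calibrated to the 5-year cumulative recurrence
probability; recurrence returns patients to PD, whose per-cycle death
hazard is the one implied by the main branch's curves.  The RFD death
hazard is a structural option: by default RFD keeps the arm's all-cause
OS-implied hazard (the trial intention-to-treat OS curve already contains
the hepatectomy patients' survival, so the split re-labels occupancy for
costs and utilities without manufacturing extra survival); alternatively
RFD can be given background mortality only.

The engine is vectorized over parameter draws: every occupancy array has
shape (n_draws, n_cycles + 1), with n_draws = 1 for a deterministic run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, StrategyName
from .registry import EngineInputs, build_engine_inputs
from .survival import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    MONTHS_PER_YEAR,
    life_table_survival,
    survival_at,
)

_TINY = 1e-300
_PD_EPS = 1e-12

STATES = ("PFD", "RFD", "PD", "Death")


@dataclass
class TraceArrays:
    """Vectorized cohort trace; occupancy arrays are (n, T+1)."""

    t_months: np.ndarray  # (T+1,), cycle-boundary times
    age_years: np.ndarray  # (T+1,)
    pfd: np.ndarray
    rfd: np.ndarray
    pd_main: np.ndarray  # progressed via the main (non-hepatectomy) branch
    pd_rfd: np.ndarray  # progressed after post-hepatectomy recurrence
    dead: np.ndarray
    entrants_rfd: np.ndarray  # mass entering RFD at each boundary
    entrants_pd_main: np.ndarray
    entrants_pd_rfd: np.ndarray

    @property
    def pd(self) -> np.ndarray:
        return self.pd_main + self.pd_rfd

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.dead

    @property
    def n_cycles(self) -> int:
        return self.t_months.size - 1


@dataclass
class CohortTrace:
    """Deterministic cohort trace (one parameter draw), exportable as a table."""

    cycle_index: np.ndarray
    time_months: np.ndarray
    occupancy: np.ndarray  # (T+1, 4) columns PFD, RFD, PD, Death
    entrants_rfd: np.ndarray
    entrants_pd: np.ndarray
    cohort_age: np.ndarray
    strategy: StrategyName

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "time_months", self.time_months)
        df.insert(0, "cycle", self.cycle_index)
        df["age"] = self.cohort_age
        return df


def n_cycles(ps: ParameterSet) -> int:
    st = ps.structural
    return int(round(st.horizon_years * DAYS_PER_YEAR / st.cycle_length_days))


def hepatectomy_cycle(ps: ParameterSet, strategy: StrategyName) -> int:
    """Cycle boundary at which the hepatectomy split occurs (end of first line)."""
    sp = ps.strategies[strategy]
    dur = sp.n_sessions * sp.session_interval_days / ps.structural.cycle_length_days
    return int(math.ceil(dur - 1e-9))


def arm_curves(
    ps: ParameterSet, inp: EngineInputs, strategy: StrategyName, t_months: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-cause (S_OS, S_PFS) grids for an arm plus the background grid.

    Returns arrays of shape (n, T+1) for the disease curves (hazard ratios
    applied for the FOLFOX-HAIC arm, both blended with background mortality,
    PFS capped at OS) and (1, T+1) for background survival.
    """
    s_os_base = survival_at(ps.os_tace, t_months)[None, :]
    s_pfs_base = survival_at(ps.pfs_tace, t_months)[None, :]
    if strategy is StrategyName.FOLFOX_HAIC:
        s_os_dis = np.power(s_os_base, inp.hr_os[:, None])
        s_pfs_dis = np.power(s_pfs_base, inp.hr_pfs[:, None])
    else:
        s_os_dis, s_pfs_dis = s_os_base, s_pfs_base
    s_bg = life_table_survival(
        ps.life_table, ps.structural.start_age_years, t_months / MONTHS_PER_YEAR
    )[None, :]
    if ps.structural.background_mortality == "multiplicative":
        s_os = s_os_dis * s_bg
        s_pfs = np.minimum(s_pfs_dis * s_bg, s_os)
    else:
        # hazard floor: per-cycle survival ratio is the smaller of the
        # disease-implied and background ratios
        s_os = _floor_hazard(s_os_dis, s_bg)
        s_pfs = np.minimum(_floor_hazard(s_pfs_dis, s_bg), s_os)
    return s_os, s_pfs, s_bg


def _floor_hazard(s_disease: np.ndarray, s_bg: np.ndarray) -> np.ndarray:
    """Apply background mortality as a per-cycle hazard floor."""
    ratios = np.minimum(
        s_disease[:, 1:] / np.maximum(s_disease[:, :-1], _TINY),
        s_bg[:, 1:] / np.maximum(s_bg[:, :-1], _TINY),
    )
    return np.concatenate(
        [np.ones((ratios.shape[0], 1)), np.cumprod(ratios, axis=1)], axis=1
    )


def run_trace_arrays(
    ps: ParameterSet, inp: EngineInputs, strategy: StrategyName
) -> TraceArrays:
    """Run the cohort simulation for one arm, vectorized over draws."""
    st = ps.structural
    T = n_cycles(ps)
    cyc_months = st.cycle_length_days / DAYS_PER_MONTH
    t = np.arange(T + 1) * cyc_months
    age = st.start_age_years + t / MONTHS_PER_YEAR

    s_os, s_pfs, s_bg = arm_curves(ps, inp, strategy, t)
    n = max(inp.n, s_os.shape[0])
    s_os = np.broadcast_to(s_os, (n, T + 1))
    s_pfs = np.broadcast_to(s_pfs, (n, T + 1))

    # per-cycle probabilities from the curve grids
    p_bg = 1.0 - s_bg[:, 1:] / np.maximum(s_bg[:, :-1], _TINY)  # (1, T)
    q_pfs = 1.0 - s_pfs[:, 1:] / np.maximum(s_pfs[:, :-1], _TINY)
    deaths_ref = s_os[:, :-1] - s_os[:, 1:]
    pd_ref = s_os - s_pfs

    # split each cycle's reference deaths between PFD and PD so the chain
    # reproduces the partitioned occupancy: PFD dies at background rate,
    # floored up by whatever the PD pool cannot supply (binding when the
    # PFS >= OS cap empties the PD state); the PD pool absorbs the rest.
    # Algebra guarantees p_bg <= d_pfd <= q_pfs and 0 <= h_pd <= 1.
    d_pfd = np.maximum(
        np.broadcast_to(p_bg, deaths_ref.shape),
        (deaths_ref - pd_ref[:, :-1]) / np.maximum(s_pfs[:, :-1], _TINY),
    )
    d_pfd = np.minimum(d_pfd, q_pfs)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_pd = np.where(
            pd_ref[:, :-1] > _PD_EPS,
            (deaths_ref - s_pfs[:, :-1] * d_pfd) / np.maximum(pd_ref[:, :-1], _PD_EPS),
            p_bg,
        )
    h_pd = np.clip(h_pd, 0.0, 1.0)

    # death hazard in the RFD state (structural choice, see Structural)
    if st.rfd_mortality == "os_hazard":
        p_rfd_death = 1.0 - s_os[:, 1:] / np.maximum(s_os[:, :-1], _TINY)
    else:
        p_rfd_death = np.broadcast_to(p_bg, (n, p_bg.shape[1]))

    cyc_years = st.cycle_length_days / DAYS_PER_YEAR
    p_rec = 1.0 - np.power(1.0 - inp.recurrence_5yr, cyc_years / 5.0)  # (n,) or (1,)
    p_rec = np.broadcast_to(np.atleast_1d(p_rec), (n,)).copy()

    si = inp.strategies[strategy]
    hep = np.broadcast_to(np.atleast_1d(si.hep_prop), (n,))
    k_hep = hepatectomy_cycle(ps, strategy)

    shape = (n, T + 1)
    pfd = np.zeros(shape)
    rfd = np.zeros(shape)
    pdm = np.zeros(shape)
    pdr = np.zeros(shape)
    dead = np.zeros(shape)
    e_rfd = np.zeros(shape)
    e_pdm = np.zeros(shape)
    e_pdr = np.zeros(shape)
    pfd[:, 0] = 1.0

    cur_pfd = pfd[:, 0].copy()
    cur_rfd = np.zeros(n)
    cur_pdm = np.zeros(n)
    cur_pdr = np.zeros(n)
    cur_dead = np.zeros(n)

    for i in range(T):
        if i == k_hep:
            moved = hep * cur_pfd
            cur_pfd = cur_pfd - moved
            cur_rfd = cur_rfd + moved
            e_rfd[:, i] = moved
            pfd[:, i] = cur_pfd
            rfd[:, i] = cur_rfd

        dbg = p_bg[0, i]
        q = q_pfs[:, i]
        hp = h_pd[:, i]

        to_pd = cur_pfd * np.clip(q - d_pfd[:, i], 0.0, None)
        pfd_deaths = cur_pfd * q - to_pd
        rec = cur_rfd * p_rec
        rfd_deaths = cur_rfd * (1.0 - p_rec) * p_rfd_death[:, i]
        pdm_deaths = cur_pdm * hp
        pdr_deaths = cur_pdr * hp

        cur_pfd = cur_pfd - to_pd - pfd_deaths
        cur_rfd = cur_rfd - rec - rfd_deaths
        cur_pdm = cur_pdm - pdm_deaths + to_pd
        cur_pdr = cur_pdr - pdr_deaths + rec
        cur_dead = cur_dead + pfd_deaths + rfd_deaths + pdm_deaths + pdr_deaths

        pfd[:, i + 1] = cur_pfd
        rfd[:, i + 1] = cur_rfd
        pdm[:, i + 1] = cur_pdm
        pdr[:, i + 1] = cur_pdr
        dead[:, i + 1] = cur_dead
        e_pdm[:, i + 1] = to_pd
        e_pdr[:, i + 1] = rec

    return TraceArrays(
        t_months=t,
        age_years=age,
        pfd=pfd,
        rfd=rfd,
        pd_main=pdm,
        pd_rfd=pdr,
        dead=dead,
        entrants_rfd=e_rfd,
        entrants_pd_main=e_pdm,
        entrants_pd_rfd=e_pdr,
    )


def run_trace(
    ps: ParameterSet, strategy: StrategyName, check_termination: bool = True
) -> CohortTrace:
    """Run the cohort model for one strategy at the baseline parameter values."""
    strategy = StrategyName(strategy)
    inp = build_engine_inputs(ps)
    tr = run_trace_arrays(ps, inp, strategy)
    if check_termination and tr.dead[0, -1] < 0.999:
        raise ValueError(
            f"horizon of {ps.structural.horizon_years} years is too short: death "
            f"occupancy at horizon is {tr.dead[0, -1]:.6f} < 0.999"
        )
    occ = np.column_stack([tr.pfd[0], tr.rfd[0], tr.pd[0], tr.dead[0]])
    return CohortTrace(
        cycle_index=np.arange(tr.t_months.size),
        time_months=tr.t_months,
        occupancy=occ,
        entrants_rfd=tr.entrants_rfd[0],
        entrants_pd=tr.entrants_pd_main[0] + tr.entrants_pd_rfd[0],
        cohort_age=tr.age_years,
        strategy=strategy,
    )


def cycle_accrual_weights(
    x: np.ndarray, t_years: np.ndarray, rate: np.ndarray, half_cycle: bool
) -> np.ndarray:
    """Per-cycle discounted accrual of a state-occupancy series.

    ``x`` is (n, T+1) occupancy at cycle boundaries.  Cycle-start accounting
    uses x at the opening boundary discounted at the opening time; the
    half-cycle correction averages the two boundaries and discounts at the
    cycle midpoint.  Returns (n, T) discounted occupancies (no cycle-length
    factor applied).
    """
    rate = np.atleast_1d(np.asarray(rate, dtype=float))[:, None]
    if half_cycle:
        occ = 0.5 * (x[:, :-1] + x[:, 1:])
        t_disc = 0.5 * (t_years[:-1] + t_years[1:])
    else:
        occ = x[:, :-1]
        t_disc = t_years[:-1]
    return occ * np.power(1.0 + rate, -t_disc[None, :])


def life_years(
    trace: CohortTrace | TraceArrays, discount_rate: float, half_cycle: bool = False
) -> float:
    """Discounted life-years over a trace (cycle-length-weighted alive time)."""
    if isinstance(trace, TraceArrays):
        alive = trace.alive
        t_years = trace.t_months / MONTHS_PER_YEAR
    else:
        alive = (1.0 - trace.occupancy[:, 3])[None, :]
        t_years = trace.time_months / MONTHS_PER_YEAR
    cyc_years = t_years[1] - t_years[0]
    acc = cycle_accrual_weights(alive, t_years, np.array([discount_rate]), half_cycle)
    return float(acc.sum(axis=1)[0] * cyc_years)
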