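"""Flat registry of the model's uncertain parameters.

The input table prints one row per uncertain quantity; several of those
rows feed more than one slot of :class:`ParameterSet` (e.g. the shared
ALT/AST management cost appears in both arms' adverse-event profiles, and
the PFD utility also values the post-hepatectomy RFD state).  The registry
maps each printed row to the set of paths it controls, so that one-way
sensitivity analysis moves all linked slots together and the PSA draws one
value per row.

It also provides :class:`EngineInputs`, the purely numeric view of a
ParameterSet consumed by the Markov engine and valuation.  Every field is a
numpy array of shape (1,) for a deterministic run or (n,) for a PSA, so the
same code path serves both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .parameters import ParameterSet, StrategyName, UncertainParam

Path = tuple[Any, ...]


@dataclass(frozen=True)
class ParamSpec:
    """One printed input-table row: a label plus the ParameterSet paths it sets."""

    label: str
    paths: tuple[Path, ...]


def _walk(obj: Any, path: Path) -> Any:
    for step in path:
        if isinstance(obj, list):
            # lists of labelled entries (adverse events) are addressed by label
            matches = [e for e in obj if getattr(e, "label", None) == step]
            if not matches:
                raise KeyError(f"no list entry labelled {step!r}")
            obj = matches[0]
        elif isinstance(obj, dict):
            obj = obj[step]
        else:
            obj = getattr(obj, step)
    return obj


def get_param(ps: ParameterSet, path: Path) -> UncertainParam:
    """Resolve a registry path to its UncertainParam."""
    out = _walk(ps, path)
    if not isinstance(out, UncertainParam):
        raise TypeError(f"path {path} does not point at an UncertainParam")
    return out


def set_baseline(ps: ParameterSet, spec: ParamSpec, value: float) -> ParameterSet:
    """Return a deep copy of ``ps`` with the row's baseline(s) set to ``value``."""
    new = ps.model_copy(deep=True)
    for path in spec.paths:
        parent = _walk(new, path[:-1])
        current = _walk(parent, path[-1:])
        updated = current.model_copy(update={"baseline": float(value)})
        last = path[-1]
        if isinstance(parent, dict):
            parent[last] = updated
        elif isinstance(parent, list):
            idx = next(i for i, e in enumerate(parent) if getattr(e, "label", None) == last)
            parent[idx] = updated
        else:
            setattr(parent, last, updated)
    return new


def _ae_paths(kind: str, labels: Sequence[str]) -> tuple[Path, ...]:
    arms = (StrategyName.FOLFOX_HAIC, StrategyName.TACE)
    return tuple(
        ("strategies", arm, "ae_profile", lab, kind) for arm in arms for lab in labels
    )


H = StrategyName.FOLFOX_HAIC
T = StrategyName.TACE

#: One entry per uncertain row of the published input table (30 rows).
PARAMETER_REGISTRY: tuple[ParamSpec, ...] = (
    ParamSpec("HR of OS (FOLFOX-HAIC vs TACE)", (("hr_os",),)),
    ParamSpec("HR of PFS (FOLFOX-HAIC vs TACE)", (("hr_pfs",),)),
    ParamSpec(
        "Hepatectomy proportion after FOLFOX-HAIC",
        (("strategies", H, "hepatectomy_proportion"),),
    ),
    ParamSpec(
        "Hepatectomy proportion after TACE",
        (("strategies", T, "hepatectomy_proportion"),),
    ),
    ParamSpec("5-year recurrence after hepatectomy", (("recurrence_5yr",),)),
    ParamSpec(
        "BSC proportion after FOLFOX-HAIC",
        (("strategies", H, "subsequent_mix", "bsc"),),
    ),
    ParamSpec(
        "BSC proportion after TACE",
        (("strategies", T, "subsequent_mix", "bsc"),),
    ),
    ParamSpec(
        "Crossover to TACE after FOLFOX-HAIC",
        (("strategies", H, "subsequent_mix", "crossover"),),
    ),
    ParamSpec(
        "Crossover to HAIC after TACE",
        (("strategies", T, "subsequent_mix", "crossover"),),
    ),
    ParamSpec(
        "Incidence of elevated ALT (FOLFOX-HAIC)",
        (("strategies", H, "ae_profile", "elevated_alt", "incidence"),),
    ),
    ParamSpec(
        "Incidence of elevated AST (FOLFOX-HAIC)",
        (("strategies", H, "ae_profile", "elevated_ast", "incidence"),),
    ),
    ParamSpec(
        "Incidence of vomiting (FOLFOX-HAIC)",
        (("strategies", H, "ae_profile", "vomiting", "incidence"),),
    ),
    ParamSpec(
        "Incidence of elevated ALT (TACE)",
        (("strategies", T, "ae_profile", "elevated_alt", "incidence"),),
    ),
    ParamSpec(
        "Incidence of elevated AST (TACE)",
        (("strategies", T, "ae_profile", "elevated_ast", "incidence"),),
    ),
    ParamSpec(
        "Incidence of vomiting (TACE)",
        (("strategies", T, "ae_profile", "vomiting", "incidence"),),
    ),
    ParamSpec("Utility of PFD/RFD", (("utilities", "PFD"), ("utilities", "RFD"))),
    ParamSpec("Utility of PD", (("utilities", "PD"),)),
    ParamSpec(
        "Disutility of elevated ALT/AST",
        _ae_paths("disutility", ("elevated_alt", "elevated_ast")),
    ),
    ParamSpec("Disutility of vomiting", _ae_paths("disutility", ("vomiting",))),
    ParamSpec(
        "Cost of elevated ALT/AST",
        _ae_paths("unit_cost", ("elevated_alt", "elevated_ast")),
    ),
    ParamSpec("Cost of vomiting", _ae_paths("unit_cost", ("vomiting",))),
    ParamSpec("Discount rate", (("discount_rate_annual",),)),
    ParamSpec(
        "Cost of oxaliplatin", (("strategies", H, "per_session_costs", "oxaliplatin"),)
    ),
    ParamSpec(
        "Cost of fluorouracil", (("strategies", H, "per_session_costs", "fluorouracil"),)
    ),
    ParamSpec(
        "Cost of leucovorin", (("strategies", H, "per_session_costs", "leucovorin"),)
    ),
    ParamSpec(
        "Cost of HAIC", (("strategies", H, "per_session_costs", "haic_procedure"),)
    ),
    ParamSpec(
        "Cost of TACE", (("strategies", T, "per_session_costs", "tace_procedure"),)
    ),
    ParamSpec("Cost of hepatectomy", (("shared_costs", "hepatectomy"),)),
    ParamSpec(
        "Cost of hospitalization", (("shared_costs", "hospitalization_per_cycle"),)
    ),
    ParamSpec("Cost of BSC", (("shared_costs", "bsc_per_cycle"),)),
)

REGISTRY_BY_LABEL: dict[str, ParamSpec] = {s.label: s for s in PARAMETER_REGISTRY}


@dataclass
class StrategyInputs:
    """Numeric per-arm inputs (arrays broadcastable over PSA draws)."""

    session_cost: np.ndarray  # total cost of one treatment session, USD
    n_sessions: float
    interval_days: float
    hep_prop: np.ndarray
    bsc_share: np.ndarray  # renormalized: bsc + crossover = 1
    cross_share: np.ndarray
    ae_cost: np.ndarray  # sum of incidence x unit cost, one-off USD
    ae_disutility: np.ndarray  # sum of incidence x disutility


@dataclass
class EngineInputs:
    """Numeric model inputs; shape (1,) deterministic, (n,) for a PSA."""

    hr_os: np.ndarray
    hr_pfs: np.ndarray
    recurrence_5yr: np.ndarray
    u_pfd: np.ndarray
    u_rfd: np.ndarray
    u_pd: np.ndarray
    discount_rate: np.ndarray
    cost_hepatectomy: np.ndarray
    cost_hospitalization: np.ndarray
    cost_bsc: np.ndarray
    strategies: dict[StrategyName, StrategyInputs] = field(default_factory=dict)
    n: int = 1


def build_engine_inputs(
    ps: ParameterSet, values: Mapping[str, np.ndarray] | None = None
) -> EngineInputs:
    """Extract numeric inputs from ``ps``, optionally overriding registry rows.

    ``values`` maps registry labels to arrays of sampled values (all of one
    common length n); rows not present fall back to their baselines.
    """
    resolved: dict[Path, np.ndarray] = {}
    n = 1
    if values:
        for label, arr in values.items():
            spec = REGISTRY_BY_LABEL[label]
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            n = max(n, arr.size)
            for path in spec.paths:
                resolved[path] = arr

    def val(*path: Any) -> np.ndarray:
        if path in resolved:
            return resolved[path]
        return np.array([get_param(ps, path).baseline], dtype=float)

    strategies: dict[StrategyName, StrategyInputs] = {}
    for name, sp in ps.strategies.items():
        session = sum(
            val("strategies", name, "per_session_costs", k) for k in sp.per_session_costs
        )
        bsc = val("strategies", name, "subsequent_mix", "bsc")
        cross = val("strategies", name, "subsequent_mix", "crossover")
        total = bsc + cross
        ae_cost = sum(
            val("strategies", name, "ae_profile", ae.label, "incidence")
            * val("strategies", name, "ae_profile", ae.label, "unit_cost")
            for ae in sp.ae_profile
        )
        ae_dis = sum(
            val("strategies", name, "ae_profile", ae.label, "incidence")
            * val("strategies", name, "ae_profile", ae.label, "disutility")
            for ae in sp.ae_profile
        )
        strategies[name] = StrategyInputs(
            session_cost=np.asarray(session, dtype=float),
            n_sessions=sp.n_sessions,
            interval_days=sp.session_interval_days,
            hep_prop=val("strategies", name, "hepatectomy_proportion"),
            bsc_share=bsc / total,
            cross_share=cross / total,
            ae_cost=np.asarray(ae_cost, dtype=float),
            ae_disutility=np.asarray(ae_dis, dtype=float),
        )

    return EngineInputs(
        hr_os=val("hr_os"),
        hr_pfs=val("hr_pfs"),
        recurrence_5yr=val("recurrence_5yr"),
        u_pfd=val("utilities", "PFD"),
        u_rfd=val("utilities", "RFD"),
        u_pd=val("utilities", "PD"),
        discount_rate=val("discount_rate_annual"),
        cost_hepatectomy=val("shared_costs", "hepatectomy"),
        cost_hospitalization=val("shared_costs", "hospitalization_per_cycle"),
        cost_bsc=val("shared_costs", "bsc_per_cycle"),
        strategies=strategies,
        n=n,
    )
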