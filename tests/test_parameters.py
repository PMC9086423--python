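"""Input data model: bundled baseline values, config IO, validation."""

import math

import pytest
from pydantic import ValidationError

from hcc_cea.parameters import (
    Distribution,
    ParameterSet,
    StrategyName,
    UncertainParam,
    default_range,
    load_baseline,
    read_config,
    write_config,
)
from hcc_cea.registry import PARAMETER_REGISTRY, REGISTRY_BY_LABEL, get_param

H = StrategyName.FOLFOX_HAIC
T = StrategyName.TACE

# label -> (baseline, low, high, distribution): the full published input table
INPUT_TABLE_MANIFEST = {
    "HR of OS (FOLFOX-HAIC vs TACE)": (0.58, 0.45, 0.75, "lognormal"),
    "HR of PFS (FOLFOX-HAIC vs TACE)": (0.57, 0.45, 0.72, "lognormal"),
    "Hepatectomy proportion after FOLFOX-HAIC": (0.24, 0.19, 0.29, "beta"),
    "Hepatectomy proportion after TACE": (0.12, 0.10, 0.14, "beta"),
    "5-year recurrence after hepatectomy": (0.19, 0.15, 0.20, "beta"),
    "BSC proportion after FOLFOX-HAIC": (0.95, 0.76, 1.14, "beta"),
    "BSC proportion after TACE": (0.87, 0.70, 1.04, "beta"),
    "Crossover to TACE after FOLFOX-HAIC": (0.05, 0.04, 0.06, "beta"),
    "Crossover to HAIC after TACE": (0.13, 0.10, 0.16, "beta"),
    "Incidence of elevated ALT (FOLFOX-HAIC)": (0.08, 0.06, 0.10, "beta"),
    "Incidence of elevated AST (FOLFOX-HAIC)": (0.18, 0.14, 0.22, "beta"),
    "Incidence of vomiting (FOLFOX-HAIC)": (0.06, 0.05, 0.07, "beta"),
    "Incidence of elevated ALT (TACE)": (0.19, 0.15, 0.23, "beta"),
    "Incidence of elevated AST (TACE)": (0.29, 0.23, 0.35, "beta"),
    "Incidence of vomiting (TACE)": (0.05, 0.04, 0.06, "beta"),
    "Utility of PFD/RFD": (0.76, 0.61, 0.91, "beta"),
    "Utility of PD": (0.68, 0.54, 0.82, "beta"),
    "Disutility of elevated ALT/AST": (0.0, 0.0, 0.0, "beta"),
    "Disutility of vomiting": (0.05, 0.04, 0.06, "beta"),
    "Cost of elevated ALT/AST": (43, 35, 52, "gamma"),
    "Cost of vomiting": (49, 39, 59, "gamma"),
    "Discount rate": (0.03, 0.01, 0.05, "uniform"),
    "Cost of oxaliplatin": (426, 340, 511, "gamma"),
    "Cost of fluorouracil": (524, 419, 629, "gamma"),
    "Cost of leucovorin": (24, 19, 29, "gamma"),
    "Cost of HAIC": (1850, 1480, 2220, "gamma"),
    "Cost of TACE": (1929, 1543, 2315, "gamma"),
    "Cost of hepatectomy": (9022, 7218, 10827, "gamma"),
    "Cost of hospitalization": (384, 307, 460, "gamma"),
    "Cost of BSC": (363, 291, 436, "gamma"),
}


def test_registry_covers_every_input_row():
    assert set(INPUT_TABLE_MANIFEST) == {s.label for s in PARAMETER_REGISTRY}


@pytest.mark.parametrize("label", sorted(INPUT_TABLE_MANIFEST))
def test_baseline_matches_input_table(baseline, label):
    """Every uncertain row of the published input table is bundled verbatim,
    at every ParameterSet slot it feeds."""
    b, lo, hi, dist = INPUT_TABLE_MANIFEST[label]
    for path in REGISTRY_BY_LABEL[label].paths:
        p = get_param(baseline, path)
        assert p.baseline == pytest.approx(b)
        assert p.low == pytest.approx(lo)
        assert p.high == pytest.approx(hi)
        assert p.distribution == Distribution(dist)


def test_baseline_survival_models(baseline):
    assert baseline.os_tace.params == {"theta": 0.00272126, "kappa": 2.184792}
    assert baseline.pfs_tace.params == {"mu": 1.682471, "sigma": 1.119812}


def test_baseline_structure(baseline):
    assert baseline.structural.cycle_length_days == 21
    assert baseline.structural.wtp_per_qaly == 30552
    assert baseline.strategies[H].n_sessions == pytest.approx(3.6)
    assert baseline.strategies[H].session_interval_days == 21
    assert baseline.strategies[T].n_sessions == 2
    assert baseline.strategies[T].session_interval_days == 42
    assert baseline.utilities["PD"].baseline == 0.68
    assert baseline.strategies[T].per_session_costs["tace_procedure"].baseline == 1929


def test_config_roundtrip(baseline, tmp_path):
    path = write_config(baseline, tmp_path / "cfg.yaml")
    assert read_config(path) == baseline


def test_invalid_utility_rejected(baseline, tmp_path):
    data = baseline.model_dump(mode="json")
    data["utilities"]["PFD"]["baseline"] = 1.2
    with pytest.raises(ValidationError):
        ParameterSet.model_validate(data)


def test_missing_field_named_in_error(baseline):
    data = baseline.model_dump(mode="json")
    del data["hr_pfs"]
    with pytest.raises(ValidationError, match="hr_pfs"):
        ParameterSet.model_validate(data)


def test_inverted_range_rejected():
    with pytest.raises(ValidationError):
        UncertainParam(baseline=1.0, low=2.0, high=0.5, distribution=Distribution.gamma)


@pytest.mark.parametrize(
    "baseline_value,dist,expected",
    [
        (1850, "gamma", (1480.0, 2220.0)),
        (0.0, "gamma", (0.0, 0.0)),
        (0.95, "beta", (0.76, 1.0)),  # clamped to the beta support
    ],
)
def test_default_range(baseline_value, dist, expected):
    p = UncertainParam(baseline=baseline_value, distribution=Distribution(dist))
    filled = default_range(p)
    assert filled.low == pytest.approx(expected[0])
    assert filled.high == pytest.approx(expected[1])


def test_default_range_keeps_existing(baseline):
    assert default_range(baseline.hr_os) == baseline.hr_os


def test_life_table_lookup_total(baseline):
    """Every age in [0, 120] resolves to exactly one band."""
    lt = baseline.life_table
    for age in [x / 2 for x in range(0, 241)]:
        p = lt.annual_probability(age)
        assert 0.0 <= p <= 1.0
    assert lt.annual_probability(52) == pytest.approx(0.01956602)
    assert lt.annual_probability(55) == pytest.approx(0.030500498)
    assert lt.annual_probability(90) == 1.0


def test_life_table_gaps_rejected(baseline):
    data = baseline.model_dump(mode="json")
    data["life_table"]["age_bands"][3][0] = 11  # break contiguity at age 10
    with pytest.raises(ValidationError, match="contiguous"):
        ParameterSet.model_validate(data)
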