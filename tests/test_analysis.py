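"""ICER logic, tornado, PSA sampling and CEAC behaviour."""

import numpy as np
import pytest

from hcc_cea.analysis import (
    SUBGROUPS,
    apply_subgroup,
    base_case,
    icer,
    one_way_sa,
    run_psa,
    sample_psa,
    sample_uncertain,
    sample_values,
)
from hcc_cea.parameters import (
    Distribution,
    ParameterSet,
    StrategyName,
    UncertainParam,
)
from hcc_cea.valuation import CEAResult


def _res(cost, qalys):
    return CEAResult(
        strategy=StrategyName.TACE, cost_total=cost, qalys=qalys, life_years=qalys
    )


def test_icer_ratio():
    cmp_ = icer(_res(0, 0), _res(9381, 1.01), wtp=30552)
    assert cmp_.icer == pytest.approx(9381 / 1.01)  # ~9288 on rounded inputs
    assert cmp_.dominance is None
    assert cmp_.cost_effective
    assert cmp_.nmb == pytest.approx(30552 * 1.01 - 9381)


def test_icer_dominance_flags():
    assert icer(_res(1, 0), _res(0, 1), wtp=1).dominance == "dominant"
    assert icer(_res(0, 1), _res(1, 0), wtp=1).dominance == "dominated"
    nodiff = icer(_res(5, 1), _res(5, 1), wtp=0)
    assert nodiff.dominance is None and nodiff.cost_effective
    # more cost, no QALY gain: dominated, ratio undefined
    flat = icer(_res(0, 1), _res(10, 1), wtp=30552)
    assert flat.dominance == "dominated" and flat.icer is None


def test_nmb_consistent_with_icer_threshold(basecase_results):
    ref, comp, cmp_ = basecase_results
    assert cmp_.incremental_qalys > 0 and cmp_.incremental_cost > 0
    assert cmp_.cost_effective == (cmp_.icer <= cmp_.wtp)


def test_tornado_zero_spread_for_fixed_parameter(baseline):
    df = one_way_sa(baseline, labels=["Disutility of elevated ALT/AST"])
    assert df.loc[0, "spread"] == pytest.approx(0.0)


def test_tornado_sorted_by_spread(baseline):
    df = one_way_sa(
        baseline,
        labels=[
            "HR of PFS (FOLFOX-HAIC vs TACE)",
            "Cost of leucovorin",
            "Utility of PD",
        ],
    )
    spreads = df["spread"].to_numpy()
    assert np.all(np.diff(spreads) <= 0)
    assert df.loc[0, "parameter"] == "HR of PFS (FOLFOX-HAIC vs TACE)"


def test_sampling_reproducible(baseline):
    a = sample_values(baseline, 50, np.random.default_rng(42))
    b = sample_values(baseline, 50, np.random.default_rng(42))
    for label in a:
        np.testing.assert_array_equal(a[label], b[label])


def test_hr_draws_match_stated_interval(baseline):
    """~95% of lognormal HR draws fall inside the printed 95% CI."""
    rng = np.random.default_rng(0)
    draws = sample_uncertain(baseline.hr_os, 10_000, rng)
    frac = np.mean((draws >= 0.45) & (draws <= 0.75))
    assert 0.93 <= frac <= 0.97
    assert np.median(draws) == pytest.approx(0.58, rel=0.02)


def test_probability_draws_in_unit_interval(baseline):
    rng = np.random.default_rng(1)
    values = sample_values(baseline, 2_000, rng)
    for label, draws in values.items():
        p = None
        from hcc_cea.registry import REGISTRY_BY_LABEL, get_param

        p = get_param(baseline, REGISTRY_BY_LABEL[label].paths[0])
        if p.distribution == Distribution.beta:
            assert np.all((draws >= 0.0) & (draws <= 1.0)), label
        if p.distribution == Distribution.gamma:
            assert np.all(draws >= 0.0), label


def test_beta_moment_fallback_warns(caplog):
    """An infeasible beta moment match falls back to a uniform draw."""
    p = UncertainParam(baseline=0.5, low=0.0, high=4.0, distribution=Distribution.beta)
    with caplog.at_level("WARNING", logger="hcc_cea.analysis"):
        draws = sample_uncertain(p, 500, np.random.default_rng(2))
    assert "beta moment match infeasible" in caplog.text
    assert np.all((draws >= 0) & (draws <= 1))


def test_sample_psa_returns_valid_parameter_set(baseline):
    sampled = sample_psa(baseline, np.random.default_rng(3))
    assert isinstance(sampled, ParameterSet)
    ParameterSet.model_validate(sampled.model_dump(mode="json"))
    assert sampled.hr_os.baseline != baseline.hr_os.baseline


def test_psa_basics(baseline):
    psa = run_psa(baseline, n_iter=400, seed=5)
    # probability at wtp 0 is the fraction of cost-saving draws
    assert psa.prob_ce_at(0.0) == pytest.approx(np.mean(psa.delta_cost <= 0))
    # two-strategy CEAC probabilities sum to one at every threshold
    totals = psa.ceac["p_folfox_haic"] + psa.ceac["p_tace"]
    np.testing.assert_allclose(totals, 1.0)
    assert psa.ceac["wtp"].iloc[-1] == pytest.approx(3 * 30552)


def test_psa_means_stable_across_seeds(baseline):
    a = run_psa(baseline, n_iter=4_000, seed=11)
    b = run_psa(baseline, n_iter=4_000, seed=12)
    assert a.delta_cost.mean() == pytest.approx(b.delta_cost.mean(), rel=0.05)
    assert a.delta_qalys.mean() == pytest.approx(b.delta_qalys.mean(), rel=0.05)


def test_base_case_invariant_to_psa_seed(baseline):
    before = base_case(baseline)[2]
    run_psa(baseline, n_iter=200, seed=13)
    after = base_case(baseline)[2]
    assert before.icer == after.icer


def test_subgroup_identity_hr_still_positive_icer(baseline):
    """With subgroup HRs of 1 the QALY gain comes only from the hepatectomy
    asymmetry; the comparison still yields a finite comparison."""
    from hcc_cea.analysis import SubgroupSpec, _hr

    sg = SubgroupSpec("identity", _hr(1.0, 0.8, 1.25), _hr(1.0, 0.8, 1.25))
    _, _, cmp_ = base_case(apply_subgroup(baseline, sg))
    assert cmp_.incremental_cost > 0
    assert cmp_.icer is None or np.isfinite(cmp_.icer)


def test_subgroup_table_covers_published_labels(baseline):
    from hcc_cea.analysis import subgroup_analysis

    df = subgroup_analysis(baseline, n_iter=0, run_psa_per_subgroup=False)
    assert len(df) == 16
    for key in ("Age", "Male", "Female", "ECOG", "Child-Pugh", "Hepatitis B", "AFP", "Tumor size", "Tumor number"):
        assert df["subgroup"].str.contains(key).any()
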