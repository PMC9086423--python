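"""Survival curves: closed forms, scipy oracles, hazard ratios, life table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hcc_cea.parameters import Family, SurvivalModel
from hcc_cea.survival import (
    annual_to_cycle_prob,
    apply_hr,
    background_mortality,
    blend_background,
    cycle_event_prob,
    life_table_survival,
    median_survival,
    survival_at,
    survival_function,
)

LL = SurvivalModel(family=Family.log_logistic, params={"theta": 0.00272126, "kappa": 2.184792})
LN = SurvivalModel(family=Family.lognormal, params={"mu": 1.682471, "sigma": 1.119812})


@pytest.mark.parametrize("model", [LL, LN], ids=["log_logistic", "lognormal"])
def test_survival_starts_at_one(model):
    assert survival_at(model, 0.0) == 1.0


def test_log_logistic_matches_fisk_oracle():
    """S(t) = 1/(1 + theta t^kappa) equals scipy's Fisk distribution with
    c = kappa and scale = (1/theta)^(1/kappa)."""
    t = np.linspace(0.01, 120, 200)
    scale = (1 / LL.params["theta"]) ** (1 / LL.params["kappa"])
    expected = stats.fisk.sf(t, c=LL.params["kappa"], scale=scale)
    np.testing.assert_allclose(survival_at(LL, t), expected, rtol=1e-12)


def test_lognormal_matches_scipy_oracle():
    t = np.linspace(0.01, 120, 200)
    expected = stats.lognorm.sf(t, s=LN.params["sigma"], scale=np.exp(LN.params["mu"]))
    np.testing.assert_allclose(survival_at(LN, t), expected, rtol=1e-12)


def test_medians_match_closed_forms():
    m_ll = median_survival(LL)
    assert m_ll == pytest.approx((1 / 0.00272126) ** (1 / 2.184792), abs=1e-9)
    assert survival_at(LL, m_ll) == pytest.approx(0.5, abs=1e-9)
    m_ln = median_survival(LN)
    assert m_ln == pytest.approx(np.exp(1.682471), abs=1e-9)
    assert survival_at(LN, m_ln) == pytest.approx(0.5, abs=1e-9)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        survival_at(LL, -0.1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    family=st.sampled_from([Family.log_logistic, Family.lognormal]),
    a=st.floats(0.001, 5.0),
    b=st.floats(0.1, 4.0),
)
def test_survival_non_increasing_in_bounds(family, a, b):
    if family is Family.log_logistic:
        model = SurvivalModel(family=family, params={"theta": a, "kappa": b})
    else:
        model = SurvivalModel(family=family, params={"mu": np.log(a), "sigma": b})
    s = survival_at(model, np.linspace(0, 240, 400))
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0) & (s <= 1))


def test_apply_hr_identity_and_power():
    s = survival_function(LL)
    assert apply_hr(s, 1.0)(13.7) == pytest.approx(s(13.7), abs=1e-15)
    const = lambda t: np.asarray(0.5)
    assert apply_hr(const, 0.58)(5.0) == pytest.approx(0.5**0.58)
    # hr doubles the cumulative hazard on the log scale
    assert np.log(apply_hr(s, 2.0)(20.0)) == pytest.approx(2 * np.log(s(20.0)))


def test_apply_hr_dominance():
    t = np.linspace(0.5, 100, 50)
    s = survival_function(LL)
    assert np.all(apply_hr(s, 0.58)(t) >= s(t))
    assert np.all(apply_hr(s, 1.7)(t) <= s(t))
    with pytest.raises(ValueError):
        apply_hr(s, 0.0)


def test_cycle_event_prob():
    assert cycle_event_prob(lambda t: np.asarray(0.8), 0.0, 1.0) == pytest.approx(0.0)
    r = 0.13
    s_exp = lambda t: np.exp(-r * np.asarray(t))
    assert cycle_event_prob(s_exp, 2.0, 3.5) == pytest.approx(1 - np.exp(-r * 1.5))
    # first 21-day cycle of the baseline OS curve, against brute evaluation
    s = survival_function(LL)
    dt = 21 / 30.4375
    p = cycle_event_prob(s, 0.0, dt)
    assert 0 < p < 1
    assert p == pytest.approx(1 - float(s(dt)) / float(s(0.0)))


@pytest.mark.parametrize(
    "p_annual,expected",
    [
        (0.0, 0.0),
        (1.0, 1.0),
        (0.01956602, 1 - 0.98043398 ** (21 / 365.25)),
    ],
)
def test_annual_to_cycle_prob(p_annual, expected):
    assert annual_to_cycle_prob(p_annual, 21) == pytest.approx(expected, abs=1e-12)


def test_background_mortality_band_lookup(baseline):
    lt = baseline.life_table
    assert background_mortality(lt, 52, 21) == pytest.approx(
        annual_to_cycle_prob(0.01956602, 21)
    )
    assert background_mortality(lt, 55, 21) == pytest.approx(
        annual_to_cycle_prob(0.030500498, 21)
    )
    assert background_mortality(lt, 90, 21) == 1.0


def test_life_table_survival_piecewise_hazard(baseline):
    lt = baseline.life_table
    # within a single band the hazard is constant
    s1 = life_table_survival(lt, 55.0, np.array([1.0]))[0]
    assert s1 == pytest.approx((1 - 0.030500498), rel=1e-9)
    # terminal band: essentially nobody survives past a year
    s_term = life_table_survival(lt, 90.0, np.array([2.0]))[0]
    assert s_term < 1e-10


def test_blend_background_bounds(baseline):
    lt = baseline.life_table
    s = survival_function(LL)
    blended = blend_background(s, lt, 55.0)
    t = np.linspace(0, 240, 100)
    s_all = blended(t)
    s_bg = life_table_survival(lt, 55.0, t / 12.0)
    assert np.all(s_all <= s(t) + 1e-12)
    assert np.all(s_all <= s_bg + 1e-12)
    np.testing.assert_allclose(s_all, s(t) * s_bg, rtol=1e-12)
    # disease-free curve reduces to the life table
    np.testing.assert_allclose(
        blend_background(lambda t: np.ones_like(np.asarray(t, float)), lt, 55.0)(t),
        s_bg,
        rtol=1e-12,
    )
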