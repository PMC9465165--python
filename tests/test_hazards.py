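"""Hazard families, closed-form integrals and the covariate multiplier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from survmeta.hazards import (
    CovariateError,
    CovariateModel,
    CovariateTerm,
    HazardModelSpec,
    InvalidParameterError,
    SurvivalCurve,
    apply_covariates,
    cumulative_hazard,
    hazard,
    median_survival_time,
    survival,
)

AGE_PS2_MODEL = CovariateModel(
    (CovariateTerm("age", 0.017, 72.5), CovariateTerm("ps2_pct", 0.004, 14.0))
)

spec_strategy = st.sampled_from(["constant", "gompertz", "weibull"]).flatmap(
    lambda fam: st.tuples(
        st.just(fam),
        st.floats(0.005, 2.0),
        st.floats(-0.5, 0.5) if fam != "weibull" else st.floats(-0.9, 2.0),
    )
).map(lambda t: HazardModelSpec(*t))


@pytest.mark.parametrize(
    "family,beta0,beta1,t,expected",
    [
        ("constant", 0.098, 0.0, 6.0, 0.098),
        ("gompertz", 0.098, 0.0, 17.0, 0.098),
        ("weibull", 2.0, 1.0, 3.0, 6.0),
    ],
)
def test_hazard_closed_forms(family, beta0, beta1, t, expected):
    assert hazard(HazardModelSpec(family, beta0, beta1), t) == pytest.approx(expected)


def test_hazard_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        HazardModelSpec("constant", -0.1)
    with pytest.raises(InvalidParameterError):
        HazardModelSpec("weibull", 0.1, -1.2)
    with pytest.raises(InvalidParameterError):
        hazard(HazardModelSpec("weibull", 0.1, -0.5), 0.0)
    with pytest.raises(InvalidParameterError):
        HazardModelSpec("gamma", 0.1)


@pytest.mark.parametrize(
    "spec,t0,t,expected",
    [
        (HazardModelSpec("constant", 0.098), 0.0, 12.0, 1.176),
        (HazardModelSpec("constant", 0.098), 5.0, 5.0, 0.0),
        (HazardModelSpec("gompertz", 0.1, 1e-9), 0.0, 10.0, 1.0),
    ],
)
def test_cumulative_hazard_examples(spec, t0, t, expected):
    assert cumulative_hazard(spec, t0, t) == pytest.approx(expected, rel=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(spec=spec_strategy, t0=st.floats(0.0, 20.0), dt=st.floats(0.0, 20.0))
def test_cumulative_hazard_matches_quadrature(spec, t0, dt):
    """The closed-form integral agrees with numerical quadrature of h(t)."""
    t = t0 + dt
    if spec.family == "weibull" and t0 == 0.0:
        t0 = 1e-6
        t = max(t, t0)
    expected, _err = quad(lambda u: hazard(spec, u), t0, t, limit=200)
    got = cumulative_hazard(spec, t0, t)
    assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)
    assert got >= 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(spec=spec_strategy, t=st.floats(0.0, 60.0))
def test_survival_starts_at_one_and_decreases(spec, t):
    assert survival(spec, 0.0) == pytest.approx(1.0)
    s_t = survival(spec, t)
    assert 0.0 <= s_t <= 1.0
    assert survival(spec, t + 1.0) <= s_t + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(beta0=st.floats(0.01, 1.0), t=st.floats(0.0, 40.0))
def test_shape_zero_reduces_to_constant(beta0, t):
    const = HazardModelSpec("constant", beta0)
    for family in ("gompertz", "weibull"):
        other = HazardModelSpec(family, beta0)
        if family == "weibull" and t == 0.0:
            continue
        assert hazard(other, t) == pytest.approx(hazard(const, t))
        assert survival(other, t) == pytest.approx(survival(const, t), rel=1e-9)


class TestMedianSurvival:
    def test_constant_family_is_exact(self):
        assert median_survival_time(HazardModelSpec("constant", math.log(2))) == 1.0
        assert median_survival_time(
            HazardModelSpec("constant", 0.098)
        ) == pytest.approx(math.log(2) / 0.098)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(beta0=st.floats(0.01, 2.0))
    def test_constant_identity(self, beta0):
        assert median_survival_time(
            HazardModelSpec("constant", beta0)
        ) * beta0 == pytest.approx(math.log(2))

    def test_weibull_matches_closed_form(self):
        spec = HazardModelSpec("weibull", 0.05, 0.5)
        closed = ((spec.beta1 + 1) * math.log(2) / spec.beta0) ** (
            1.0 / (spec.beta1 + 1)
        )
        got = median_survival_time(spec)
        assert got == pytest.approx(closed, abs=1e-7)
        assert survival(spec, got) == pytest.approx(0.5, abs=1e-7)


class TestApplyCovariates:
    def test_identity_at_reference(self):
        value = apply_covariates(0.098, AGE_PS2_MODEL,
                                 {"age": 72.5, "ps2_pct": 14.0}, eta=0.0)
        assert value == 0.098

    def test_age_80_hazard(self):
        """The published final model: h = 0.098*exp((80-72.5)*0.017)."""
        value = apply_covariates(0.098, AGE_PS2_MODEL,
                                 {"age": 80.0, "ps2_pct": 14.0})
        assert value == pytest.approx(0.098 * math.exp(7.5 * 0.017))

    def test_ten_year_age_multiplier(self):
        """A 10-year age shift multiplies the hazard by e^0.17 = 1.185."""
        older = apply_covariates(0.098, AGE_PS2_MODEL,
                                 {"age": 82.5, "ps2_pct": 14.0})
        ref = apply_covariates(0.098, AGE_PS2_MODEL,
                               {"age": 72.5, "ps2_pct": 14.0})
        assert older / ref == pytest.approx(1.185, abs=5e-4)

    def test_missing_covariate_is_named(self):
        with pytest.raises(CovariateError, match="ps2_pct"):
            apply_covariates(0.098, AGE_PS2_MODEL, {"age": 70.0})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(eta=st.floats(-1.0, 1.0), age=st.floats(59.0, 76.0))
    def test_eta_factors_out(self, eta, age):
        covs = {"age": age, "ps2_pct": 14.0}
        with_eta = apply_covariates(0.098, AGE_PS2_MODEL, covs, eta)
        without = apply_covariates(0.098, AGE_PS2_MODEL, covs, 0.0)
        assert with_eta == pytest.approx(without * math.exp(eta))


def test_survival_curve_validation():
    SurvivalCurve(np.array([0.0, 6.0, 12.0]), np.array([1.0, 0.6, 0.4]))
    with pytest.raises(ValueError):
        SurvivalCurve(np.array([0.0, 6.0]), np.array([1.0, 1.2]))
    with pytest.raises(ValueError):
        SurvivalCurve(np.array([0.0, 6.0]), np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        SurvivalCurve(np.array([6.0, 3.0]), np.array([0.8, 0.9]))
    curve = SurvivalCurve.from_spec(HazardModelSpec("constant", 0.1),
                                    [0.0, 12.0, 24.0])
    assert curve.survival[0] == 1.0
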