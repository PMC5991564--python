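"""Age and sex heteroplasmy adjustment transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetkit.adjustment import (
    DeclineParams,
    UrineSexParams,
    age_adjust_blood,
    composite_measure,
    fit_urine_linear,
    fit_urine_sex_params,
    inv_logit,
    logit,
    sex_adjust_urine,
)

proportions = st.floats(min_value=0.01, max_value=0.99)


def test_logit_inv_logit_basics():
    assert logit(0.5) == pytest.approx(0.0)
    assert inv_logit(0.0) == pytest.approx(0.5)
    # boundary values are clamped to eps, keeping the transform finite
    assert np.isfinite(logit(0.0)) and logit(0.0) == pytest.approx(logit(0.005))


@given(proportions)
def test_logit_round_trip(p):
    assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize(
    "level, age, expected, capped",
    [
        (0.0, 50.0, 0.0, False),
        (0.20, 30.0, 0.20 / 0.977**42, False),  # ~0.531
        (0.80, 60.0, 1.0, True),  # raw value > 1, truncated and flagged
    ],
)
def test_age_adjust_blood_examples(level, age, expected, capped):
    adj, cap = age_adjust_blood(level, age)
    assert adj == pytest.approx(expected, rel=1e-9)
    assert bool(cap) is capped


def test_age_adjust_blood_rejects_negative_age():
    with pytest.raises(ValueError):
        age_adjust_blood(0.3, -1.0)


@pytest.mark.parametrize(
    "sex, expected",
    [("male", inv_logit(-0.625)), ("female", inv_logit(0.608))],
)
def test_sex_adjust_urine_at_half(sex, expected):
    adj, clamped = sex_adjust_urine(0.5, sex)
    assert float(adj) == pytest.approx(float(expected), rel=1e-9)
    assert not clamped


def test_sex_adjust_urine_requires_known_sex():
    with pytest.raises(ValueError):
        sex_adjust_urine(0.4, "unknown")


def test_boundary_level_clamped_and_flagged():
    adj, clamped = sex_adjust_urine(0.0, "male")
    assert clamped and 0.0 < float(adj) < 1.0


@given(proportions, proportions)
def test_adjusters_strictly_monotone(p1, p2):
    """Both adjusters preserve the ordering of input levels (before capping)."""
    lo, hi = sorted([p1, p2])
    if lo == hi:
        return
    a_lo, _ = age_adjust_blood(lo, 20.0)
    a_hi, _ = age_adjust_blood(hi, 20.0)
    assert a_lo < a_hi or a_hi == 1.0
    for sex in ("male", "female"):
        u_lo, _ = sex_adjust_urine(lo, sex)
        u_hi, _ = sex_adjust_urine(hi, sex)
        assert u_lo < u_hi


@given(proportions)
def test_female_adjusted_exceeds_male_adjusted(p):
    m, _ = sex_adjust_urine(p, "male")
    f, _ = sex_adjust_urine(p, "female")
    assert f > m


@given(proportions, st.floats(min_value=0.0, max_value=80.0))
def test_generative_round_trips(true, age):
    """Forward models inverted by the published formulas recover the latent level."""
    d, u = DeclineParams(), UrineSexParams()
    blood = true * d.b ** (age + d.k)
    rec, _ = age_adjust_blood(blood, age, d)
    assert float(rec) == pytest.approx(true, rel=1e-9)

    urine_m = inv_logit(u.scale * (logit(true) + u.male_offset))
    rec_m, _ = sex_adjust_urine(urine_m, "male", u)
    assert float(rec_m) == pytest.approx(true, rel=1e-6)

    urine_f = inv_logit(u.scale * (logit(true) - u.female_offset))
    rec_f, _ = sex_adjust_urine(urine_f, "female", u)
    assert float(rec_f) == pytest.approx(true, rel=1e-6)


def test_age_adjust_identity_at_minus_k():
    d = DeclineParams(b=0.977, k=0.0)
    adj, _ = age_adjust_blood(0.4, 0.0, d)
    assert float(adj) == pytest.approx(0.4)
    # adjusted level grows with age for a fixed observed level
    a1, _ = age_adjust_blood(0.3, 20.0)
    a2, _ = age_adjust_blood(0.3, 40.0)
    assert a2 > a1


def test_composite_measure():
    assert float(composite_measure(0.4, 0.6)) == pytest.approx(0.5)
    assert float(composite_measure(0.3, 0.3)) == pytest.approx(0.3)
    assert np.isnan(composite_measure(np.nan, 0.6))


def test_fit_urine_sex_params_exact_on_noise_free_data(rng):
    true = rng.uniform(0.05, 0.95, 60)
    male = rng.random(60) < 0.5
    u = UrineSexParams()
    offset = np.where(male, u.male_offset, -u.female_offset)
    urine = inv_logit(u.scale * (logit(true) + offset))
    params, stats = fit_urine_sex_params(true, urine, male)
    assert params.scale == pytest.approx(u.scale, abs=1e-6)
    assert params.male_offset == pytest.approx(u.male_offset, abs=1e-6)
    assert params.female_offset == pytest.approx(u.female_offset, abs=1e-6)
    assert stats["r_squared"] == pytest.approx(1.0, abs=1e-9)


def test_fit_urine_linear_exact_on_noise_free_data(rng):
    muscle = rng.uniform(5, 95, 60)
    male = rng.random(60) < 0.5
    urine = 5.0 + 0.75 * muscle + 19.2 * male
    fit = fit_urine_linear(muscle, urine, male)
    assert fit["slope"] == pytest.approx(0.75, abs=1e-9)
    assert fit["sex_gap"] == pytest.approx(19.2, abs=1e-9)
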