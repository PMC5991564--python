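"""NMDAS scaling, burden points, burden regressions and bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest

from hetkit.association import (
    ITEM_COLS,
    bootstrap_r2_compare,
    burden_points,
    fit_burden_model,
    scale_nmdas,
)


def _assessment(scores: dict, subject="s1", age=40.0):
    row = {"subject_id": subject, "age_at_assessment": age}
    row.update({c: np.nan for c in ITEM_COLS})
    row.update(scores)
    return row


def _nmdas(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age_at_assessment"] + ITEM_COLS)


def test_all_answered_sum_passes_through():
    # 29 answered, scored (non-respiratory) items sum to 58 -> scaled 58
    scores = {c: 2 for c in ITEM_COLS}
    scores["item_08"] = 0  # respiratory item, excluded from the sum
    scores["item_09"] = 4  # keep the scored sum at 2*28 + 2 = 58
    df = _nmdas([_assessment(scores)])
    out = scale_nmdas(df, respiratory_item=8)
    assert out["n_answered"].iloc[0] == 29
    assert out["scaled_score"].iloc[0] == pytest.approx(58.0)
    assert out["included"].iloc[0]


def test_partial_answers_rescaled():
    # 25 answered (incl. respiratory scored 0), answered sum 50 -> 50/25*29 = 58
    answered = [c for c in ITEM_COLS if c != "item_08"][:24]
    scores = {c: v for c, v in zip(answered, [3] * 14 + [1] * 8 + [0] * 2)}
    assert sum(scores.values()) == 50
    scores["item_08"] = 0
    df = _nmdas([_assessment(scores)])
    out = scale_nmdas(df, respiratory_item=8)
    assert out["n_answered"].iloc[0] == 25
    assert out["scaled_score"].iloc[0] == pytest.approx(58.0)


def test_too_few_answers_excluded():
    scores = {c: 1 for c in ITEM_COLS[:24]}
    out = scale_nmdas(_nmdas([_assessment(scores)]))
    assert not out["included"].iloc[0]


def test_scaling_is_linear():
    scores = {c: 2 for c in ITEM_COLS[:26]}
    base = scale_nmdas(_nmdas([_assessment(scores)]))["scaled_score"].iloc[0]
    doubled = scale_nmdas(_nmdas([_assessment({c: 4 for c in ITEM_COLS[:26]})]))
    assert doubled["scaled_score"].iloc[0] == pytest.approx(2 * base)


def test_item_out_of_range_rejected():
    with pytest.raises(ValueError, match="0-5"):
        scale_nmdas(_nmdas([_assessment({"item_01": 7})]))


def test_burden_point_earliest_maximum():
    scaled = pd.DataFrame(
        {"subject_id": ["s"] * 3, "age_at_assessment": [30.0, 35.0, 40.0],
         "scaled_score": [10.0, 20.0, 20.0], "included": [True] * 3}
    )
    pts = burden_points(scaled)
    assert pts["max_scaled_score"].iloc[0] == 20.0
    assert pts["age_at_max"].iloc[0] == 35.0
    assert pts["sqrt_score"].iloc[0] == pytest.approx(np.sqrt(20.0))


@pytest.mark.parametrize("score, flag", [(4.9, False), (5.0, True)])
def test_symptomatic_threshold(score, flag):
    scaled = pd.DataFrame(
        {"subject_id": ["s"], "age_at_assessment": [30.0],
         "scaled_score": [score], "included": [True]}
    )
    assert bool(burden_points(scaled)["symptomatic"].iloc[0]) is flag


def _burden_data(rng, n=120, beta_het=0.0):
    age = rng.uniform(20, 80, n)
    het = rng.uniform(5, 95, n)
    noise = rng.normal(0, 1.0, n)
    return pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "age": age, "het": het,
         "sqrt_score": 2.0 + 0.02 * age + beta_het * het + noise}
    )


def test_null_model_r2_near_zero(rng):
    data = _burden_data(rng)
    data["sqrt_score"] = rng.normal(4, 1, len(data))
    fit = fit_burden_model(data, ["age", "het"])
    assert abs(fit.adjusted_r_squared) < 0.05


def test_collinear_design_rejected(rng):
    data = _burden_data(rng)
    data["het2"] = data["het"] * 1.0
    with pytest.raises(ValueError, match="collinear"):
        fit_burden_model(data, ["age", "het", "het2"])


def test_bootstrap_self_comparison_is_half(rng):
    data = _burden_data(rng, beta_het=0.02)
    res = bootstrap_r2_compare(data, ["age", "het"], ["age", "het"],
                               replicates=200, seed=1)
    assert res.estimate == 0.0
    assert res.p_value == 0.5  # ties split evenly


def test_bootstrap_prefers_informative_measure(rng):
    """A measure diluted with extra noise loses to the clean measure."""
    data = _burden_data(rng, beta_het=0.02)
    data["het_noisy"] = data["het"] + rng.normal(0, 60, len(data))
    res = bootstrap_r2_compare(data, ["age", "het"], ["age", "het_noisy"],
                               replicates=400, seed=2)
    assert res.p_value < 0.05  # noisy measure rarely wins
    assert res.estimate < 0


def test_bootstrap_null_extra_predictor_centred_at_or_below_zero(rng):
    data = _burden_data(rng, beta_het=0.02)
    data["noise"] = rng.normal(0, 1, len(data))
    res = bootstrap_r2_compare(data, ["age", "het"], ["age", "het", "noise"],
                               replicates=400, seed=3)
    # adjusted R2 penalises the useless predictor: no significant improvement
    assert res.ci[0] < 0 <= res.ci[1] + 0.01
    assert abs(res.estimate) < 0.05
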