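"""qPCR standard curves, sample QC, copy-number derivation, standardisation."""

import numpy as np
import pandas as pd
import pytest

from hetkit.copynumber import (
    SampleQuant,
    StandardCurve,
    copies_per_nucleus,
    copynumber_associations,
    fit_standard_curve,
    process_plates,
    quantify_sample,
    standardize_plate,
)
from hetkit.simulate import GeneratorConfig, generate_qpcr_plates


def _perfect_curve(efficiency=1.0, base=20.0, target="ND1"):
    slope = -1.0 / np.log10(1.0 + efficiency)
    steps = range(6)
    cts = [[base + slope * (-s)] * 3 for s in steps]
    return fit_standard_curve(list(steps), cts, target=target)


def test_perfect_chemistry_slope_and_qc():
    curve = _perfect_curve(efficiency=1.0)
    assert curve.slope == pytest.approx(-1.0 / np.log10(2.0), abs=1e-9)  # -3.3219
    assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
    assert curve.qc_pass  # boundary: -3.3219 lies inside [-3.6, -3.3]


def test_low_efficiency_curve_fails_qc():
    curve = _perfect_curve(efficiency=0.85)
    assert curve.slope == pytest.approx(-1.0 / np.log10(1.85), abs=1e-9)  # ~-3.743
    assert not curve.qc_pass


def test_curve_needs_four_points():
    with pytest.raises(ValueError, match=">= 4"):
        fit_standard_curve([0, 1, 2], [[20.0]] * 3)


def test_quantify_clean_triplicate():
    curve = _perfect_curve()
    q = quantify_sample([25.0, 25.1, 25.05], curve, "s1")
    assert q.qc_pass and q.outliers_removed == 0
    assert q.mean_ct == pytest.approx(25.05)


def test_quantify_removes_outlier_well():
    curve = _perfect_curve()
    q = quantify_sample([25.0, 25.1, 28.0], curve, "s1")
    assert q.outliers_removed == 1
    assert q.mean_ct == pytest.approx(25.05)  # mean of the two surviving wells


@pytest.mark.parametrize(
    "cts, reason",
    [([34.0, 34.1, 33.9], "mean Ct"), ([25.0, 25.45, 24.6], "Ct SD")],
)
def test_quantify_qc_failures(cts, reason):
    q = quantify_sample(cts, _perfect_curve())
    assert not q.qc_pass and reason in q.fail_reason


def test_quantity_decreasing_in_ct():
    curve = _perfect_curve()
    q_low = quantify_sample([24.0, 24.0, 24.0], curve).quantity
    q_high = quantify_sample([28.0, 28.0, 28.0], curve).quantity
    assert q_low > q_high


def _quant(quantity, target):
    return SampleQuant(
        sample_id="s", target=target, mean_ct=25.0, ct_sd=0.05,
        quantity=quantity, qc_pass=True,
    )


@pytest.mark.parametrize("ratio, expected", [(1.0, 2.0), (100.0, 200.0)])
def test_copies_per_nucleus_definition(ratio, expected):
    assert copies_per_nucleus(_quant(1.0, "ND1"), _quant(1.0, "B2M"), ratio) == expected


def test_copies_requires_qc_pass():
    bad = SampleQuant("s", "B2M", 34.0, 0.05, 1.0, qc_pass=False)
    with pytest.raises(ValueError):
        copies_per_nucleus(_quant(1.0, "ND1"), bad)


def test_standardize_formula():
    assert standardize_plate([200.0], 100.0, 120.0)[0] == pytest.approx(240.0)
    assert standardize_plate([333.0], 120.0, 120.0)[0] == pytest.approx(333.0)  # identity


def test_plate_round_trip_noise_free():
    cfg = GeneratorConfig(qpcr_ct_sd=0.0, plate_log_sd=0.0, qpcr_efficiency=1.0)
    truth = pd.DataFrame({"sample_id": [f"m{i}" for i in range(6)],
                          "copies": [3523.0, 1200.0, 500.0, 144.0, 2500.0, 900.0]})
    rng = np.random.default_rng(5)
    qpcr = generate_qpcr_plates(truth, cfg, rng)
    cn, qc = process_plates(qpcr)
    merged = cn.merge(truth, on="sample_id")
    assert np.allclose(merged["raw_copies_per_nucleus"], merged["copies"], rtol=1e-6)


def test_plate_round_trip_within_5pct_at_default_noise(rng):
    """Copies per nucleus recovered within 5% at Ct noise SD 0.1."""
    cfg = GeneratorConfig(plate_log_sd=0.0)
    n = 200
    truth = pd.DataFrame({"sample_id": [f"m{i}" for i in range(n)],
                          "copies": rng.uniform(500, 8000, n)})
    qpcr = generate_qpcr_plates(truth, cfg, rng)
    cn, _ = process_plates(qpcr)
    merged = cn.merge(truth, on="sample_id")
    rel = merged["raw_copies_per_nucleus"] / merged["copies"] - 1.0
    assert np.abs(rel).mean() < 0.05  # typical recovery error under 5%
    assert abs(rel.mean()) < 0.02  # and no systematic bias


def test_standardisation_removes_plate_effects(rng):
    """Injected multiplicative plate offsets are removed by the control-based
    standardisation: every plate's control maps to the grand mean exactly."""
    cfg = GeneratorConfig(qpcr_ct_sd=0.0, plate_log_sd=0.3, samples_per_plate=4)
    truth = pd.DataFrame({"sample_id": [f"m{i}" for i in range(12)],
                          "copies": [2000.0] * 12})
    qpcr = generate_qpcr_plates(truth, cfg, rng)
    cn, _ = process_plates(qpcr)
    # same true copies on all plates -> standardised values identical across plates
    per_plate = cn.groupby("plate_id")["standardized_copies_per_nucleus"].mean()
    assert per_plate.std() == pytest.approx(0.0, abs=1e-6 * per_plate.mean())
    # raw values differ across plates (the effect standardisation removed)
    raw_per_plate = cn.groupby("plate_id")["raw_copies_per_nucleus"].mean()
    assert raw_per_plate.std() > 0.01 * raw_per_plate.mean()


def test_copynumber_associations_detects_urine_sex_effect(rng):
    n = 150
    male = rng.random(n) < 0.4
    copies = np.exp(rng.normal(np.log(881.0) + 1.44 * male, 1.0))
    df = pd.DataFrame({"copies": copies, "het": rng.uniform(5, 95, n),
                       "age": rng.uniform(20, 80, n), "male": male})
    report = copynumber_associations(df, "urine")
    i = report["terms"].index("male")
    assert report["p_values"][i] < 0.01 and report["coef"][i] > 0


def test_copynumber_associations_null(rng):
    n = 120
    df = pd.DataFrame({"copies": rng.normal(144, 40, n), "het": rng.uniform(5, 95, n),
                       "age": rng.uniform(20, 80, n)})
    report = copynumber_associations(df, "blood")
    assert abs(report["r_squared"]) < 0.1
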