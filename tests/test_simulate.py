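"""Synthetic cohort generator: determinism, marginals, round trips."""

import numpy as np
import pandas as pd
import pytest

from hetkit import adjustment
from hetkit.decline import DECLINING, summarise_trajectories
from hetkit.simulate import (
    GeneratorConfig,
    decompose_items,
    generate_longitudinal,
    generate_subjects,
    generate_tissue_measurements,
    simulate_cohort,
)


def test_same_seed_identical_output():
    cfg = GeneratorConfig(n_subjects=40)
    a = simulate_cohort(cfg, seed=123)
    b = simulate_cohort(cfg, seed=123)
    for key in ("subjects", "heteroplasmy", "nmdas", "qpcr", "ground_truth"):
        pd.testing.assert_frame_equal(a[key], b[key])


def test_subject_marginals():
    cfg = GeneratorConfig(n_subjects=10_000)
    subjects = generate_subjects(cfg, np.random.default_rng(1))
    frac = (subjects["sex"] == "female").mean()
    p = 147 / 242
    se = np.sqrt(p * (1 - p) / len(subjects))
    assert abs(frac - p) < 2 * se + 1e-9 or abs(frac - p) < 0.015
    assert subjects["latent"].between(0.05, 0.95).all()
    assert subjects["age"].between(19.7, 79.9).all()


def test_noise_free_tissue_round_trip():
    """At zero noise every tissue observation inverts exactly to the latent level."""
    cfg = GeneratorConfig(
        n_subjects=50, muscle_logit_sd=0.0, urine_logit_sd=0.0, blood_level_sd=0.0
    )
    rng = np.random.default_rng(2)
    subjects = generate_subjects(cfg, rng)
    meas = generate_tissue_measurements(subjects, cfg, rng)
    wide = meas.pivot(index="subject_id", columns="tissue", values="level")
    wide = wide.join(subjects.set_index("subject_id")[["latent", "sex", "age"]])

    rec_blood, _ = adjustment.age_adjust_blood(wide["blood"], wide["age"])
    assert np.allclose(rec_blood, wide["latent"], atol=1e-9)
    rec_urine, _ = adjustment.sex_adjust_urine(
        wide["urine"].to_numpy(), wide["sex"].to_numpy()
    )
    assert np.allclose(rec_urine, wide["latent"], atol=1e-6)
    assert np.allclose(wide["muscle"], wide["latent"], atol=1e-9)


def test_blood_urine_correlation_in_cohort_regime():
    """Default noise keeps the blood-urine relationship strong (R² > 0.5)."""
    cfg = GeneratorConfig(n_subjects=500)
    rng = np.random.default_rng(3)
    subjects = generate_subjects(cfg, rng)
    meas = generate_tissue_measurements(subjects, cfg, rng)
    wide = meas.pivot(index="subject_id", columns="tissue", values="level")
    wide = wide.join(subjects.set_index("subject_id")[["sex", "age"]])
    # compare on comparable scales: age-adjusted blood vs sex-adjusted urine
    blood_adj, _ = adjustment.age_adjust_blood(wide["blood"], wide["age"])
    urine_adj, _ = adjustment.sex_adjust_urine(
        wide["urine"].to_numpy(), wide["sex"].to_numpy()
    )
    r = np.corrcoef(blood_adj, urine_adj)[0, 1]
    assert r**2 > 0.5


def test_male_urine_exceeds_female_on_average():
    cfg = GeneratorConfig(n_subjects=2000)
    rng = np.random.default_rng(4)
    subjects = generate_subjects(cfg, rng)
    meas = generate_tissue_measurements(subjects, cfg, rng, tissues=("urine",))
    merged = meas.merge(subjects[["subject_id", "sex"]], on="subject_id",
                        suffixes=("", "_s"))
    male = merged.loc[merged["sex"] == "male", "level"].mean()
    female = merged.loc[merged["sex"] == "female", "level"].mean()
    assert male > female + 0.05


@pytest.mark.parametrize("total", [0.0, 13.7, 58.0, 139.6, 145.0])
def test_item_decomposition_conserves_total(total):
    items = decompose_items(total, respiratory_item=8)
    scored = sum(v for k, v in items.items() if k != "item_08")
    assert scored == round(min(total, 140.0))
    assert all(0 <= v <= 5 for v in items.values())
    assert len(items) == 29


def test_longitudinal_majority_decline_over_four_years():
    cfg = GeneratorConfig(n_subjects=120)
    rng = np.random.default_rng(5)
    subjects = generate_subjects(cfg, rng)
    blood, nmdas, truth = generate_longitudinal(
        subjects, cfg, rng, visits_range=(3, 5), span_range=(4.0, 10.0)
    )
    traj = summarise_trajectories(blood)
    long_enough = traj[traj["trajectory_class"] != "short-span"]
    frac = (long_enough["trajectory_class"] == DECLINING).mean()
    assert frac > 0.5
    # NMDAS items reassemble to the scaled totals the model generated
    item_cols = [c for c in nmdas.columns if c.startswith("item_")]
    assert nmdas[item_cols].notna().all().all()


def test_zero_variance_components_share_trajectory_shape():
    cfg = GeneratorConfig(
        n_subjects=20, prog_age_slope_sd=0.0, prog_interaction_sd=0.0,
        prog_resid_sd=0.0, blood_level_sd=0.0
    )
    rng = np.random.default_rng(6)
    subjects = generate_subjects(cfg, rng)
    _, nmdas, _ = generate_longitudinal(subjects, cfg, rng, visits_range=(2, 2))
    # with no random slopes and no noise the sqrt-score is an exact function
    # of (age, latent): verify via the ground-truth model for a few subjects
    merged = nmdas.merge(subjects, left_on="subject_id", right_on="subject_id")
    item_cols = [c for c in nmdas.columns if c.startswith("item_")]
    scored = merged[item_cols].sum(axis=1) - merged["item_08"]
    expect = (0.05 * merged["age_at_assessment"]
              + 0.08 * merged["age_at_assessment"] * merged["latent"]) ** 2
    assert np.allclose(scored, np.round(np.clip(expect, 0, 140)), atol=0.5)


def test_simulate_cohort_writes_files(tmp_path):
    cfg = GeneratorConfig(n_subjects=12)
    simulate_cohort(cfg, seed=9, outdir=tmp_path)
    for name in ("heteroplasmy.csv", "nmdas.csv", "qpcr.csv", "ground_truth.csv"):
        assert (tmp_path / name).exists()
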