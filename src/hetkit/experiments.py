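"""Parameter-recovery experiments on synthetic cohorts.

Each experiment generates replicate cohorts under the generator's default
study conditions, runs the corresponding pipeline estimator on each, and
returns the Monte-Carlo mean of the recovered quantity.  These are the
closed-loop checks that the pipeline recovers the constants its forward
models were generated with; they back both the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import statsmodels.api as sm

from . import adjustment, decline, variability
from .simulate import (
    GeneratorConfig,
    generate_burden_cohort,
    generate_rate_trajectories,
    generate_repeated_measurements,
    generate_subjects,
    generate_tissue_measurements,
)


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def compound_decline_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover (b, k) of the compound blood decline from synthetic cohorts.

    Each cohort draws ~n_subjects carriers, observes blood through the
    compound forward model and urine through the logit model, sex-adjusts
    urine as the initial-level estimate, and fits the compound decline.
    """
    config = config or replace(GeneratorConfig(), n_subjects=n_subjects)
    bs, ks = [], []
    for rng in _rngs(seed, n_cohorts):
        subjects = generate_subjects(config, rng)
        meas = generate_tissue_measurements(
            subjects, config, rng, urine_mode="logit", tissues=("blood", "urine")
        )
        wide = meas.pivot(index="subject_id", columns="tissue", values="level")
        wide = wide.join(subjects.set_index("subject_id")[["sex", "age"]])
        init, _ = adjustment.sex_adjust_urine(
            wide["urine"].to_numpy(), wide["sex"].to_numpy(), config.urine_sex
        )
        fit = decline.fit_compound_decline(
            wide["blood"].to_numpy(), wide["age"].to_numpy(), init
        )
        bs.append(fit.params.b)
        ks.append(fit.params.k)
    bs = np.asarray(bs)
    return {
        "mean_b": float(bs.mean()),
        "sd_b": float(bs.std(ddof=1)),
        "mean_annual_percent_decline": float(((1.0 - bs) * 100.0).mean()),
        "mean_k": float(np.mean(ks)),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def urine_logit_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 75,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover the urine sex-transform constants from paired muscle/urine."""
    config = config or replace(GeneratorConfig(), n_subjects=n_subjects)
    scales, male_offs, female_offs = [], [], []
    for rng in _rngs(seed, n_cohorts):
        subjects = generate_subjects(config, rng)
        meas = generate_tissue_measurements(
            subjects, config, rng, urine_mode="logit", tissues=("urine", "muscle")
        )
        wide = meas.pivot(index="subject_id", columns="tissue", values="level")
        wide = wide.join(subjects.set_index("subject_id")["sex"])
        params, _ = adjustment.fit_urine_sex_params(
            wide["muscle"].to_numpy(),
            wide["urine"].to_numpy(),
            (wide["sex"] == "male").to_numpy(),
        )
        scales.append(params.scale)
        male_offs.append(params.male_offset)
        female_offs.append(params.female_offset)
    return {
        "mean_scale": float(np.mean(scales)),
        "mean_male_offset": float(np.mean(male_offs)),
        "mean_female_offset": float(np.mean(female_offs)),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def urine_linear_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 75,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover the percentage-scale muscle-to-urine slope and male excess."""
    config = config or replace(GeneratorConfig(), n_subjects=n_subjects)
    slopes, gaps = [], []
    for rng in _rngs(seed, n_cohorts):
        subjects = generate_subjects(config, rng)
        meas = generate_tissue_measurements(
            subjects, config, rng, urine_mode="linear", tissues=("urine", "muscle")
        )
        wide = meas.pivot(index="subject_id", columns="tissue", values="level")
        wide = wide.join(subjects.set_index("subject_id")["sex"])
        fit = adjustment.fit_urine_linear(
            wide["muscle"].to_numpy() * 100.0,
            wide["urine"].to_numpy() * 100.0,
            (wide["sex"] == "male").to_numpy(),
        )
        slopes.append(fit["slope"])
        gaps.append(fit["sex_gap"])
    return {
        "mean_slope": float(np.mean(slopes)),
        "mean_sex_gap": float(np.mean(gaps)),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def cv_experiment(
    n_cohorts: int = 500,
    n_subjects: int = 39,
    seed: int = 0,
    cv: float | None = None,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover the generating within-subject CV with the c4-corrected estimator."""
    config = config or GeneratorConfig()
    means = []
    for rng in _rngs(seed, n_cohorts):
        reps = generate_repeated_measurements(config, rng, n_subjects=n_subjects, cv=cv)
        _, summary = variability.cohort_cv(reps, measure="urine")
        means.append(summary["mean_cv"])
    return {
        "mean_cv": float(np.mean(means)),
        "sd_cv": float(np.std(means, ddof=1)),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def rate_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 35,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover the continuous decline rate with the rate-vs-initial estimator.

    Reports the mean fitted regression slope (negative: levels decline).
    """
    config = config or GeneratorConfig()
    slopes = []
    for rng in _rngs(seed, n_cohorts):
        blood = generate_rate_trajectories(config, rng, n_subjects=n_subjects)
        traj = decline.summarise_trajectories(blood)
        fit = decline.estimate_linear_decline(traj)
        slopes.append(fit.slope)
    return {
        "mean_slope": float(np.mean(slopes)),
        "mean_rate_constant": float(-np.mean(slopes)),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def muscle_burden_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 66,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover the burden-model coefficients on synthetic muscle cohorts.

    OLS of sqrt(scaled NMDAS) on age, muscle heteroplasmy (%) and
    standardised copy number; reports the mean heteroplasmy coefficient
    (per percentage point) and the mean copy-number effect per 100 copies.
    """
    config = config or GeneratorConfig()
    het_coefs, cn_coefs = [], []
    for rng in _rngs(seed, n_cohorts):
        cohort = generate_burden_cohort(config, rng, n_subjects=n_subjects)
        X = sm.add_constant(cohort[["age", "het_pct", "copies"]].to_numpy())
        fit = sm.OLS(cohort["sqrt_score"].to_numpy(), X).fit()
        het_coefs.append(fit.params[2])
        cn_coefs.append(fit.params[3])
    return {
        "mean_het_coef": float(np.mean(het_coefs)),
        "mean_cn_coef_per_100": float(np.mean(cn_coefs) * 100.0),
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }
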