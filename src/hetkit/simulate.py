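"""Synthetic m.3243A>G cohort generator.

Produces cohorts with the statistical structure the analysis pipeline
assumes, with known ground truth, so every stage can be exercised and its
estimators validated without patient data.  The observation models invert
the published adjustment formulas:

* muscle  = inv_logit(logit(latent) + e_m)            (age-stable reference)
* urine   = inv_logit(s * (logit(latent) + offset_sex) + e_u)
  with offset_male = +0.625, offset_female = -0.608, so the published
  inverse transforms recover the latent level exactly at zero noise;
  an alternative percentage-linear mode, urine% = a + 0.75*muscle% +
  19.2*I(male) + e, mirrors the linear urine-on-muscle parameterisation
* blood   = clip(latent * b**(age + k) + e_b, 0, 1)   with b=0.977, k=12

plus longitudinal NMDAS trajectories with by-subject random slopes and no
intercept, tissue copy-number distributions matched to the printed
median/IQR pairs, and plate-structured qPCR readouts with standard curves,
a shared control sample and per-plate effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _raw_logit

from .adjustment import DeclineParams, UrineSexParams

SQRT_NMDAS_MAX = math.sqrt(145.0)


def _lognorm_sigma_from_iqr(median: float, iqr: float) -> float:
    """Log-scale sigma of a lognormal with the given median and IQR.

    IQR = median * (e**(z*s) - e**(-z*s)) with z = 0.6745, so
    s = asinh(IQR / (2*median)) / z.
    """
    z = 0.674489750196082
    return float(np.arcsinh(iqr / (2.0 * median)) / z)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Values printed in the source study (cohort size, sex ratio, age range,
    adjustment constants, decline rates, CV levels, burden coefficients,
    copy-number medians/IQRs, control CV) are fixed here as defaults; noise
    SDs and baselines the study does not print are free choices documented
    in the methods note.
    """

    n_subjects: int = 242
    female_fraction: float = 147.0 / 242.0
    age_range: tuple = (19.7, 79.9)
    latent_range: tuple = (0.05, 0.95)

    decline: DeclineParams = field(default_factory=DeclineParams)
    urine_sex: UrineSexParams = field(default_factory=UrineSexParams)

    muscle_logit_sd: float = 0.15
    urine_logit_sd: float = 0.35
    blood_level_sd: float = 0.02

    #: continuous exponential decline rate of blood level (rate-regression model)
    linear_decline_rate: float = 0.0185

    # percentage-linear urine mode: urine% = intercept + slope*muscle% + gap*male
    urine_linear_slope: float = 0.75
    urine_linear_male_gap: float = 19.2
    urine_linear_intercept: float = 5.0
    urine_linear_sd: float = 10.0

    # within-subject repeated-measurement dispersion, as CV of the population mean
    urine_cv: float = 0.189
    blood_cv: float = 0.128

    # burden model on the sqrt-NMDAS scale (muscle cohort)
    burden_intercept: float = 3.4
    burden_age_coef: float = 0.04
    burden_het_coef: float = 0.027      # per percentage point muscle heteroplasmy
    burden_cn_coef: float = -0.00055    # per copy/nucleus
    burden_resid_sd: float = 1.5

    # progression model (sqrt-NMDAS, het as proportion)
    prog_age_coef: float = 0.05
    prog_interaction_coef: float = 0.08
    prog_age_slope_sd: float = 0.05
    prog_interaction_sd: float = 0.02
    prog_resid_sd: float = 0.5

    # copy number: tissue -> (median, log-scale sigma from printed median/IQR)
    cn_lognorm: dict = field(default_factory=lambda: {
        "muscle": (3523.0, _lognorm_sigma_from_iqr(3523.0, 1708.0)),
        "blood": (144.0, _lognorm_sigma_from_iqr(144.0, 81.0)),
        "urine": (1181.0, _lognorm_sigma_from_iqr(1181.0, 2870.0)),
    })
    urine_cn_male_log_offset: float = 1.44
    blood_cn_het_log_slope: float = 0.003  # log copies per % heteroplasmy

    # qPCR plate model
    qpcr_efficiency: float = 0.94
    qpcr_ct_sd: float = 0.1
    qpcr_base_ct: dict = field(default_factory=lambda: {"ND1": 18.0, "B2M": 22.0})
    plate_log_sd: float = 0.167  # reproduces the ~16.8% control CV across plates
    control_copies: float = 500.0
    dilution_ratio: float = 100.0
    #: mean sample template relative to the top standard; keeps sample Cts
    #: interpolating inside the calibrated dilution range, as in practice
    qpcr_sample_loading: float = 0.01
    n_dilutions: int = 6
    samples_per_plate: int = 12


def generate_subjects(config: GeneratorConfig, rng) -> pd.DataFrame:
    """Subjects with sex, age and a latent (whole-body) heteroplasmy level."""
    n = config.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = rng.uniform(*config.age_range, size=n)
    latent = rng.uniform(*config.latent_range, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "latent": latent,
        }
    )


def generate_tissue_measurements(
    subjects: pd.DataFrame,
    config: GeneratorConfig,
    rng,
    urine_mode: str = "logit",
    tissues=("blood", "urine", "muscle"),
) -> pd.DataFrame:
    """One cross-sectional measurement per subject per tissue (long format)."""
    if urine_mode not in ("logit", "linear"):
        raise ValueError(f"unknown urine mode {urine_mode!r}")
    n = len(subjects)
    latent = subjects["latent"].to_numpy()
    age = subjects["age"].to_numpy()
    male = (subjects["sex"] == "male").to_numpy()
    lat_logit = _raw_logit(latent)
    frames = []

    muscle = expit(lat_logit + rng.normal(0.0, config.muscle_logit_sd, n))
    if "muscle" in tissues:
        frames.append(("muscle", muscle))

    if "urine" in tissues:
        p = config.urine_sex
        if urine_mode == "logit":
            offset = np.where(male, p.male_offset, -p.female_offset)
            urine = expit(
                p.scale * (lat_logit + offset) + rng.normal(0.0, config.urine_logit_sd, n)
            )
        else:
            urine_pct = (
                config.urine_linear_intercept
                + config.urine_linear_slope * muscle * 100.0
                + config.urine_linear_male_gap * male
                + rng.normal(0.0, config.urine_linear_sd, n)
            )
            urine = np.clip(urine_pct, 0.0, 100.0) / 100.0
        frames.append(("urine", urine))

    if "blood" in tissues:
        d = config.decline
        blood = np.clip(
            latent * d.b ** (age + d.k) + rng.normal(0.0, config.blood_level_sd, n),
            0.0,
            1.0,
        )
        frames.append(("blood", blood))

    rows = []
    for tissue, level in frames:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"],
                    "sex": subjects["sex"],
                    "tissue": tissue,
                    "age_at_sample": age,
                    "level": level,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def decompose_items(scaled_total: float, respiratory_item: int = 8) -> dict:
    """Deterministically split a scaled NMDAS total over the 28 scored items.

    The integer total (capped at 140 = 28 items x 5) is spread as evenly as
    possible: floor(S/28) everywhere, +1 on the first S mod 28 items.  The
    respiratory item is answered but scored 0 (it is excluded from scoring).
    Summing the scored items recovers round(total) exactly.
    """
    S = int(round(min(max(scaled_total, 0.0), 140.0)))
    base, extra = divmod(S, 28)
    scores = {}
    scored_idx = [i for i in range(1, 30) if i != respiratory_item]
    for j, i in enumerate(scored_idx):
        scores[f"item_{i:02d}"] = base + (1 if j < extra else 0)
    scores[f"item_{respiratory_item:02d}"] = 0
    return scores


def generate_longitudinal(
    subjects: pd.DataFrame,
    config: GeneratorConfig,
    rng,
    visits_range=(2, 6),
    span_range=(1.0, 10.0),
    blood_mode: str = "compound",
    respiratory_item: int = 8,
):
    """Repeated blood measurements and NMDAS trajectories per subject.

    Blood follows either the compound decline (level = latent * b**(age+k))
    or a continuous exponential decline at ``linear_decline_rate`` from the
    first-visit level, plus observation noise.  sqrt-NMDAS follows the
    no-intercept random-slope model, truncated to [0, sqrt(145)], squared to
    the NMDAS scale and decomposed into item scores.

    Returns (blood long table, NMDAS wide table, ground-truth per subject).
    """
    if blood_mode not in ("compound", "exponential"):
        raise ValueError(f"unknown blood mode {blood_mode!r}")
    lo_s, hi_s = span_range
    if lo_s < 0:
        raise ValueError("span must be >= 0")
    n = len(subjects)
    u = rng.normal(0.0, config.prog_age_slope_sd, n)
    v = rng.normal(0.0, config.prog_interaction_sd, n)

    blood_rows, nmdas_rows, truth_rows = [], [], []
    for i, row in enumerate(subjects.itertuples(index=False)):
        n_visits = int(rng.integers(visits_range[0], visits_range[1] + 1))
        span = float(rng.uniform(lo_s, hi_s))
        offsets = np.sort(rng.uniform(0.0, span, size=n_visits)) if n_visits > 1 else np.array([0.0])
        offsets[0], offsets[-1] = 0.0, span if n_visits > 1 else offsets[-1]
        ages = row.age + offsets
        d = config.decline
        if blood_mode == "compound":
            blood_true = row.latent * d.b ** (ages + d.k)
        else:
            start = row.latent
            blood_true = start * np.exp(-config.linear_decline_rate * offsets)
        blood = np.clip(blood_true + rng.normal(0.0, config.blood_level_sd, n_visits), 0.0, 1.0)

        sqrt_true = (config.prog_age_coef + u[i]) * ages + (
            config.prog_interaction_coef + v[i]
        ) * ages * row.latent
        sqrt_obs = np.clip(
            sqrt_true + rng.normal(0.0, config.prog_resid_sd, n_visits), 0.0, SQRT_NMDAS_MAX
        )
        scaled = sqrt_obs**2

        for a, b_lvl, s in zip(ages, blood, scaled):
            blood_rows.append(
                {"subject_id": row.subject_id, "sex": row.sex, "tissue": "blood",
                 "age_at_sample": a, "level": b_lvl}
            )
            items = decompose_items(s, respiratory_item)
            nmdas_rows.append(
                {"subject_id": row.subject_id, "age_at_assessment": a, **items}
            )
        truth_rows.append(
            {"subject_id": row.subject_id, "latent": row.latent,
             "age_slope_dev": u[i], "interaction_dev": v[i]}
        )
    return (
        pd.DataFrame(blood_rows),
        pd.DataFrame(nmdas_rows),
        pd.DataFrame(truth_rows),
    )


def generate_rate_trajectories(
    config: GeneratorConfig,
    rng,
    n_subjects: int = 35,
    n_measurements_range=(2, 5),
    span_range=(4.0, 12.0),
) -> pd.DataFrame:
    """Longitudinal blood series declining exponentially at the default rate.

    Start levels are drawn from the latent distribution; each subject gets
    2-5 measurements over a 4-12 year span, with proportion-scale
    observation noise.  Used to validate the rate-vs-initial-level
    estimator.
    """
    rows = []
    for i in range(n_subjects):
        p0 = rng.uniform(*config.latent_range)
        m = int(rng.integers(n_measurements_range[0], n_measurements_range[1] + 1))
        span = float(rng.uniform(*span_range))
        times = np.sort(rng.uniform(0.0, span, size=m))
        times[0], times[-1] = 0.0, span
        age0 = rng.uniform(*config.age_range)
        levels = np.clip(
            p0 * np.exp(-config.linear_decline_rate * times)
            + rng.normal(0.0, config.blood_level_sd, m),
            0.0,
            1.0,
        )
        for t, lvl in zip(times, levels):
            rows.append(
                {"subject_id": f"R{i:04d}", "tissue": "blood",
                 "age_at_sample": age0 + t, "level": lvl}
            )
    return pd.DataFrame(rows)


def generate_repeated_measurements(
    config: GeneratorConfig,
    rng,
    n_subjects: int = 39,
    n_repeats_range=(3, 6),
    cv: float | None = None,
) -> pd.DataFrame:
    """Repeated same-tissue measurements with a prescribed within-subject CV.

    Subject means are drawn from the latent distribution; the within-subject
    Gaussian noise SD equals ``cv`` times the realised population mean of
    the subject means (default: the urine CV), so the c4-corrected cohort CV
    estimator should recover ``cv``.  Values are clipped to [0, 1].
    """
    if cv is None:
        cv = config.urine_cv
    means = rng.uniform(*config.latent_range, size=n_subjects)
    sd = cv * float(means.mean())
    rows = []
    for i, mu in enumerate(means):
        m = int(rng.integers(n_repeats_range[0], n_repeats_range[1] + 1))
        vals = np.clip(mu + rng.normal(0.0, sd, size=m), 0.0, 1.0)
        for v in vals:
            rows.append({"subject_id": f"C{i:04d}", "level": v})
    return pd.DataFrame(rows)


def generate_burden_cohort(
    config: GeneratorConfig,
    rng,
    n_subjects: int = 66,
) -> pd.DataFrame:
    """Muscle-cohort burden points from the linear sqrt-NMDAS model.

    sqrt(NMDAS) = a0 + a_age*age + a_het*muscle% + a_cn*copies + e,
    truncated to the attainable [0, sqrt(145)] range.
    """
    age = rng.uniform(*config.age_range, size=n_subjects)
    het_pct = rng.uniform(*config.latent_range, size=n_subjects) * 100.0
    median, sigma = config.cn_lognorm["muscle"]
    copies = np.exp(rng.normal(np.log(median), sigma, size=n_subjects))
    sqrt_score = np.clip(
        config.burden_intercept
        + config.burden_age_coef * age
        + config.burden_het_coef * het_pct
        + config.burden_cn_coef * copies
        + rng.normal(0.0, config.burden_resid_sd, size=n_subjects),
        0.0,
        SQRT_NMDAS_MAX,
    )
    return pd.DataFrame(
        {
            "subject_id": [f"B{i:04d}" for i in range(n_subjects)],
            "age": age,
            "het_pct": het_pct,
            "copies": copies,
            "sqrt_score": sqrt_score,
        }
    )


def generate_copy_numbers(subjects: pd.DataFrame, config: GeneratorConfig, rng,
                          het_pct: np.ndarray | None = None) -> pd.DataFrame:
    """True per-subject copy numbers per tissue (lognormal marginals).

    Urine carries a male log offset; blood a slight positive heteroplasmy
    slope on the log scale.  These are the association structures the
    copy-number regressions should detect.
    """
    n = len(subjects)
    male = (subjects["sex"] == "male").to_numpy()
    if het_pct is None:
        het_pct = subjects["latent"].to_numpy() * 100.0
    out = {"subject_id": subjects["subject_id"]}
    for tissue, (median, sigma) in config.cn_lognorm.items():
        mu = np.full(n, np.log(median))
        if tissue == "urine":
            # keep the female median at the marginal value; males shifted up
            mu = np.log(881.0) + config.urine_cn_male_log_offset * male
        if tissue == "blood":
            mu = mu + config.blood_cn_het_log_slope * (het_pct - het_pct.mean())
        out[f"copies_{tissue}"] = np.exp(rng.normal(mu, sigma))
    return pd.DataFrame(out)


def generate_qpcr_plates(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng,
) -> pd.DataFrame:
    """Plate-structured qPCR readouts for samples with known copy numbers.

    ``truth`` needs sample_id and copies columns.  Each plate carries
    six-point ten-fold dilution series for both targets, triplicate sample
    wells, and the shared control sample.  A per-plate lognormal factor
    multiplies the effective ND1 template of samples and control (not the
    plasmid standards), emulating target-specific inter-plate drift; the
    control-based standardisation removes it by construction.
    """
    if len(truth) == 0:
        raise ValueError("no samples to plate")
    slope = -1.0 / np.log10(1.0 + config.qpcr_efficiency)
    rows = []
    sample_ids = truth["sample_id"].tolist()
    copies = truth["copies"].to_numpy(dtype=float)
    n_plates = int(np.ceil(len(truth) / config.samples_per_plate))

    def ct(target: str, quantity: float, m: int = 3):
        base = config.qpcr_base_ct[target]
        mean = base + slope * np.log10(quantity)
        return mean + rng.normal(0.0, config.qpcr_ct_sd, size=m)

    for p in range(n_plates):
        plate_id = f"P{p:03d}"
        plate_factor = float(np.exp(rng.normal(0.0, config.plate_log_sd)))
        for target in ("ND1", "B2M"):
            for step in range(config.n_dilutions):
                reps = ct(target, 10.0**-step)
                rows.append(
                    {"plate_id": plate_id, "sample_id": f"std{step}", "role": "standard",
                     "target": target, "dilution_step": step,
                     "ct_rep1": reps[0], "ct_rep2": reps[1], "ct_rep3": reps[2]}
                )

        def add_sample(sid: str, true_copies: float, role: str):
            # loading variation around the nominal sample template amount
            q_b2m = config.qpcr_sample_loading * float(np.exp(rng.normal(0.0, 0.2)))
            q_nd1 = true_copies * q_b2m / (2.0 * config.dilution_ratio)
            for target, q in (("ND1", q_nd1 * plate_factor), ("B2M", q_b2m)):
                reps = ct(target, q)
                rows.append(
                    {"plate_id": plate_id, "sample_id": sid, "role": role,
                     "target": target, "dilution_step": np.nan,
                     "ct_rep1": reps[0], "ct_rep2": reps[1], "ct_rep3": reps[2]}
                )

        lo = p * config.samples_per_plate
        for sid, c in zip(sample_ids[lo:lo + config.samples_per_plate], copies[lo:lo + config.samples_per_plate]):
            add_sample(sid, c, "sample")
        add_sample("control", config.control_copies, "control")
    return pd.DataFrame(rows)


def simulate_cohort(config: GeneratorConfig, seed: int, outdir=None) -> dict:
    """Generate a full synthetic cohort (all pipeline inputs + ground truth).

    Returns a dict of DataFrames; if ``outdir`` is given they are also
    written as heteroplasmy.csv, nmdas.csv, qpcr.csv and ground_truth.csv.
    Identical seeds give byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    subjects = generate_subjects(config, rng)
    het = generate_tissue_measurements(subjects, config, rng)
    blood_long, nmdas, truth_long = generate_longitudinal(subjects, config, rng)
    cns = generate_copy_numbers(subjects, config, rng)
    qpcr_truth = pd.DataFrame(
        {"sample_id": subjects["subject_id"] + ":muscle", "copies": cns["copies_muscle"]}
    )
    qpcr = generate_qpcr_plates(qpcr_truth, config, rng)
    truth = subjects.merge(truth_long, on="subject_id").merge(cns, on="subject_id")
    bundle = {
        "subjects": subjects,
        "heteroplasmy": pd.concat([het, blood_long], ignore_index=True),
        "nmdas": nmdas,
        "qpcr": qpcr,
        "ground_truth": truth,
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle["heteroplasmy"].to_csv(outdir / "heteroplasmy.csv", index=False)
        bundle["nmdas"].to_csv(outdir / "nmdas.csv", index=False)
        bundle["qpcr"].to_csv(outdir / "qpcr.csv", index=False)
        bundle["ground_truth"].to_csv(outdir / "ground_truth.csv", index=False)
    return bundle
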