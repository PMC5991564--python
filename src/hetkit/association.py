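"""Cross-sectional disease-burden analysis on the NMDAS scale.

The Newcastle Mitochondrial Disease Adult Scale is a 29-item clinician-rated
instrument (items scored 0-5).  The respiratory item is excluded from
scoring; assessments with fewer than 25 of 29 responses are excluded, and
the remaining total is rescaled to the full instrument:

    scaled = (sum of answered, respiratory excluded) / n_answered * 29

One burden point per subject (maximum scaled score, earliest age reaching
it) enters OLS models of sqrt(scaled NMDAS) on age plus a heteroplasmy
measure (plus mtDNA copy number for the muscle model); competing measures
are compared by bootstrapping the difference in adjusted R² over subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_ITEMS = 29
MIN_ANSWERED = 25
SYMPTOMATIC_THRESHOLD = 5.0
#: Which NMDAS item records respiratory function is configurable; the
#: default is a named choice, not an instrument constant.
DEFAULT_RESPIRATORY_ITEM = 8

ITEM_COLS = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]


@dataclass
class ModelFit:
    outcome: str
    predictors: list
    coef: dict
    conf_int: dict
    p_values: dict
    adjusted_r_squared: float
    n: int
    residual_normality_p: float = float("nan")


@dataclass
class ComparisonResult:
    """Bootstrap comparison of two candidate models.

    ``p_value`` is the probability that the second model beats the first
    (strictly better, ties split evenly), estimated over subject-level
    bootstrap replicates.
    """

    model_a: str
    model_b: str
    statistic: str
    estimate: float
    ci: tuple
    p_value: float
    n_replicates: int
    n_dropped: int = 0


def scale_nmdas(
    nmdas: pd.DataFrame,
    respiratory_item: int = DEFAULT_RESPIRATORY_ITEM,
) -> pd.DataFrame:
    """Scale raw NMDAS item tables to the 0-145 instrument range.

    ``nmdas`` needs subject_id, age_at_assessment and item_01..item_29
    (blank = unanswered).  n_answered counts all 29 responses; the
    respiratory item is excluded from the sum only.  Assessments with
    n_answered < 25 get included=False (and are logged).
    """
    resp_col = f"item_{respiratory_item:02d}"
    if resp_col not in ITEM_COLS:
        raise ValueError(f"respiratory item index out of range: {respiratory_item}")
    items = nmdas[ITEM_COLS].astype(float)
    bad = (items < 0) | (items > 5)
    if bad.any().any():
        rows = sorted(set(np.where(bad.to_numpy())[0].tolist()))
        raise ValueError(f"item scores outside 0-5 at row(s) {rows}")

    n_answered = items.notna().sum(axis=1)
    scored = items.drop(columns=[resp_col])
    total = scored.sum(axis=1, skipna=True)
    scaled = total / n_answered * N_ITEMS

    out = nmdas[["subject_id", "age_at_assessment"]].copy()
    out["n_answered"] = n_answered.astype(int)
    out["scaled_score"] = scaled
    out["included"] = n_answered >= MIN_ANSWERED
    n_excluded = int((~out["included"]).sum())
    if n_excluded:
        logger.info("scale_nmdas: excluded %d assessment(s) with < %d responses",
                    n_excluded, MIN_ANSWERED)
    return out


def burden_points(scaled: pd.DataFrame) -> pd.DataFrame:
    """One independent burden point per subject.

    Maximum scaled score and the earliest age at which that maximum was
    reached; subjects with no included assessment are dropped and logged.
    The symptomatic flag uses the scaled-NMDAS >= 5 convention.
    """
    rows = []
    dropped = 0
    for sid, grp in scaled.groupby("subject_id", sort=False):
        grp = grp[grp["included"]]
        if grp.empty:
            dropped += 1
            continue
        max_score = float(grp["scaled_score"].max())
        at_max = grp[grp["scaled_score"] == max_score]
        age_at_max = float(at_max["age_at_assessment"].min())
        rows.append(
            {
                "subject_id": sid,
                "max_scaled_score": max_score,
                "age_at_max": age_at_max,
                "sqrt_score": float(np.sqrt(max_score)),
                "symptomatic": max_score >= SYMPTOMATIC_THRESHOLD,
            }
        )
    if dropped:
        logger.info("burden_points: dropped %d subject(s) with no included assessment", dropped)
    return pd.DataFrame(
        rows,
        columns=["subject_id", "max_scaled_score", "age_at_max", "sqrt_score", "symptomatic"],
    )


def _ols_adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Fast adjusted R² for an OLS fit with intercept column already in X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    n, p = X.shape
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def fit_burden_model(data: pd.DataFrame, predictors: list, outcome: str = "sqrt_score") -> ModelFit:
    """OLS of sqrt(scaled NMDAS) burden on age + a heteroplasmy measure.

    ``data`` has one row per subject with the outcome and predictor columns.
    The square-root transform is what makes the residuals approximately
    normal; a Shapiro-Wilk P on the residuals is reported as a diagnostic.
    Rank-deficient designs raise, naming the collinear columns.
    """
    import statsmodels.api as sm
    from scipy.stats import shapiro

    y = data[outcome].to_numpy(dtype=float)
    X = data[predictors].astype(float).to_numpy()
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (predictors[i], predictors[j])
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or predictors}")
    fit = sm.OLS(y, Xc).fit()
    names = ["const"] + list(predictors)
    ci = fit.conf_int()
    try:
        norm_p = float(shapiro(fit.resid)[1])
    except ValueError:
        norm_p = float("nan")
    return ModelFit(
        outcome=outcome,
        predictors=list(predictors),
        coef={nm: float(v) for nm, v in zip(names, fit.params)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        p_values={nm: float(v) for nm, v in zip(names, fit.pvalues)},
        adjusted_r_squared=float(fit.rsquared_adj),
        n=int(len(y)),
        residual_normality_p=norm_p,
    )


def bootstrap_r2_compare(
    data: pd.DataFrame,
    predictors_a: list,
    predictors_b: list,
    outcome: str = "sqrt_score",
    replicates: int = 1000,
    seed: int | None = None,
) -> ComparisonResult:
    """Compare two burden models by bootstrapping the adjusted-R² difference.

    Subjects (rows of ``data``) are resampled with replacement; both models
    are refit per replicate and the difference adj_R²(b) - adj_R²(a) is
    recorded.  The P value is the bootstrap probability that model b is the
    better model (ties counted half), so comparing a model with itself gives
    exactly 0.5.  Replicates where either fit fails are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    y = data[outcome].to_numpy(dtype=float)
    Xa = np.column_stack([np.ones(len(y)), data[predictors_a].astype(float).to_numpy()])
    Xb = np.column_stack([np.ones(len(y)), data[predictors_b].astype(float).to_numpy()])
    n = len(y)
    point = _ols_adj_r2(y, Xb) - _ols_adj_r2(y, Xa)

    deltas = []
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        try:
            d = _ols_adj_r2(y[idx], Xb[idx]) - _ols_adj_r2(y[idx], Xa[idx])
        except np.linalg.LinAlgError:
            dropped += 1
            continue
        if not np.isfinite(d):
            dropped += 1
            continue
        deltas.append(d)
    if dropped > 0.05 * replicates:
        warnings.warn(f"{dropped}/{replicates} bootstrap replicates dropped")
    deltas = np.asarray(deltas)
    p = float(np.mean(deltas > 0) + 0.5 * np.mean(deltas == 0))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return ComparisonResult(
        model_a="+".join(predictors_a),
        model_b="+".join(predictors_b),
        statistic="delta_r_squared",
        estimate=float(point),
        ci=(float(lo), float(hi)),
        p_value=p,
        n_replicates=int(len(deltas)),
        n_dropped=dropped,
    )
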