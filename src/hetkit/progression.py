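"""Longitudinal disease-progression modelling.

Linear mixed model of sqrt(scaled NMDAS) with *no intercept anywhere* (the
assumption that carriers are asymptomatic at birth, so every fitted
trajectory passes through the origin):

    sqrt(NMDAS)_ij = (b_age + u_i) * age_ij + (b_int + v_i) * age_ij * het_i + e_ij

Fixed effects: age and the age x heteroplasmy interaction (the heteroplasmy
main effect is available behind a flag, reproducing the step in which it was
dropped as non-significant).  Random effects: by-subject slopes on the same
two terms with an unstructured 2x2 covariance.  Models are fitted by maximum
likelihood so that AICs are comparable across specifications; competing
heteroplasmy measures are compared by bootstrapping the AIC difference over
subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)


@dataclass
class ProgressionModel:
    fixed_effects: dict
    conf_int: dict
    p_values: dict
    random_slope_sd: dict
    random_cov: list  # 2x2 random-slope covariance (age, age_x_het)
    residual_sd: float
    log_likelihood: float
    aic: float
    n_params: int
    n_subjects: int
    n_observations: int
    converged: bool
    singular: bool = False


def _design(long_df: pd.DataFrame, include_het_main: bool):
    age = long_df["age"].to_numpy(dtype=float)
    het = long_df["het"].to_numpy(dtype=float)
    cols = {"age": age, "age_x_het": age * het}
    if include_het_main:
        cols = {"age": age, "het": het, "age_x_het": age * het}
    X = np.column_stack(list(cols.values()))
    return list(cols.keys()), X


def fit_progression(
    long_df: pd.DataFrame,
    include_random: bool = True,
    include_het_main: bool = False,
    reml: bool = False,
) -> ProgressionModel:
    """Fit the no-intercept random-slope progression model.

    Parameters
    ----------
    long_df : DataFrame
        Long format with columns subject_id, age, het (one value per
        subject, repeated down the rows) and scaled_score (NMDAS scale; the
        square root is taken here).
    include_random : bool
        With False the model degenerates to OLS through the origin (used as
        an equivalence oracle and for single-visit data).
    include_het_main : bool
        Add the heteroplasmy main effect to the fixed part (the selection
        step; the final published structure omits it).
    reml : bool
        Restricted ML for single-model inference; keep False (ML) whenever
        AICs are compared across specifications.

    AIC is -2*loglik + 2*p with p = n fixed effects + n free random-effect
    covariance parameters + 1 (residual variance).
    """
    names, X = _design(long_df, include_het_main)
    y = np.sqrt(long_df["scaled_score"].to_numpy(dtype=float))
    groups = long_df["subject_id"].to_numpy()
    n_obs = len(y)
    n_subjects = len(pd.unique(groups))
    k_fe = X.shape[1]

    if include_random:
        import statsmodels.api as sm

        exog_re = np.column_stack([long_df["age"], long_df["age"] * long_df["het"]])
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # Nelder-Mead is the most reliable optimizer for this profiled
            # likelihood near variance boundaries; Powell as fallback.
            fit = model.fit(reml=reml, method=["nm", "powell"], maxiter=1000)
        if not fit.converged:
            raise RuntimeError(
                "mixed-model optimizer failed to converge; "
                f"gradient norm trace: {getattr(fit, 'hist', None)}"
            )
        cov_re = np.asarray(fit.cov_re, dtype=float)
        # a slope SD below ~1e-3 is indistinguishable from the boundary here
        # (slopes multiply ages of order 10-100 against outcome SDs of order 1)
        singular = bool(np.any(np.sqrt(np.diag(cov_re)) < 1e-3)
                        or np.linalg.eigvalsh(cov_re).min() < 1e-12)
        if singular:
            warnings.warn("random-effects covariance is singular (a slope variance is ~0)")
        q = cov_re.shape[0]
        n_params = k_fe + q * (q + 1) // 2 + 1
        llf = float(fit.llf)
        params = dict(zip(names, fit.params[:k_fe]))
        bse = dict(zip(names, fit.bse[:k_fe]))
        df_t = n_obs - k_fe
        pvals = {
            nm: float(2 * t_dist.sf(abs(params[nm] / bse[nm]), df_t)) for nm in names
        }
        tcrit = t_dist.ppf(0.975, df_t)
        ci = {nm: (params[nm] - tcrit * bse[nm], params[nm] + tcrit * bse[nm]) for nm in names}
        re_sd = {
            "age": float(np.sqrt(cov_re[0, 0])),
            "age_x_het": float(np.sqrt(cov_re[1, 1])),
        }
        re_cov = cov_re.tolist()
        resid_sd = float(np.sqrt(fit.scale))
        converged = bool(fit.converged)
    else:
        # Degenerate case: no random slopes -> Gaussian ML == OLS through origin.
        import statsmodels.api as sm

        fit = sm.OLS(y, X).fit()
        llf = float(fit.llf)
        n_params = k_fe + 1
        params = dict(zip(names, fit.params))
        pvals = dict(zip(names, (float(v) for v in fit.pvalues)))
        ci_arr = fit.conf_int()
        ci = {nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci_arr)}
        re_sd = {"age": 0.0, "age_x_het": 0.0}
        re_cov = [[0.0, 0.0], [0.0, 0.0]]
        resid_sd = float(np.sqrt(fit.mse_resid))
        singular = False
        converged = True

    return ProgressionModel(
        fixed_effects={nm: float(v) for nm, v in params.items()},
        conf_int=ci,
        p_values=pvals,
        random_slope_sd=re_sd,
        random_cov=re_cov,
        residual_sd=resid_sd,
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * n_params,
        n_params=n_params,
        n_subjects=n_subjects,
        n_observations=n_obs,
        converged=converged,
        singular=singular,
    )


def marginal_loglik(long_df: pd.DataFrame, model: ProgressionModel) -> float:
    """Marginal Gaussian log-likelihood of the fitted model, built by hand.

    y_i ~ N(X_i beta, Z_i G Z_i' + s2 I) per subject, evaluated at the fitted
    parameters; an independent route to the mixed-model likelihood used to
    validate the fit and the AIC identity.  Only supports the default
    fixed-effect structure.
    """
    names, X = _design(long_df, include_het_main=False)
    beta = np.array([model.fixed_effects[nm] for nm in names])
    y = np.sqrt(long_df["scaled_score"].to_numpy(dtype=float))
    G = np.asarray(model.random_cov, dtype=float)
    s2 = model.residual_sd**2
    ll = 0.0
    for _, grp in long_df.groupby("subject_id", sort=False):
        idx = grp.index
        Xi = X[long_df.index.get_indexer(idx)]
        yi = y[long_df.index.get_indexer(idx)]
        Zi = Xi  # random slopes act on the same two columns
        V = Zi @ G @ Zi.T + s2 * np.eye(len(yi))
        r = yi - Xi @ beta
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (len(yi) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return float(ll)


def bootstrap_aic_compare(
    long_a: pd.DataFrame,
    long_b: pd.DataFrame,
    replicates: int = 1000,
    seed: int | None = None,
    include_random: bool = True,
):
    """Compare two heteroplasmy measures by bootstrapping the AIC difference.

    ``long_a`` and ``long_b`` are long tables for the same subjects and
    assessments, differing only in the ``het`` column.  Subjects are
    resampled with replacement; each replicate refits both models (ML) and
    records AIC(a) - AIC(b).  The P value is the bootstrap probability that
    the second model is the better fit (lower AIC; ties counted half), so a
    self-comparison gives exactly 0.5.  Non-converging replicates are
    dropped and counted.
    """
    from .association import ComparisonResult

    rng = np.random.default_rng(seed)
    subjects = pd.unique(long_a["subject_id"])
    ga = {s: g for s, g in long_a.groupby("subject_id", sort=False)}
    gb = {s: g for s, g in long_b.groupby("subject_id", sort=False)}

    def refit(sample_ids):
        parts_a, parts_b = [], []
        for j, sid in enumerate(sample_ids):
            a = ga[sid].copy()
            b = gb[sid].copy()
            a["subject_id"] = b["subject_id"] = f"bs{j}"
            parts_a.append(a)
            parts_b.append(b)
        da = pd.concat(parts_a, ignore_index=True)
        db = pd.concat(parts_b, ignore_index=True)
        ma = fit_progression(da, include_random=include_random)
        mb = fit_progression(db, include_random=include_random)
        return ma.aic, mb.aic

    aic_a = fit_progression(long_a, include_random=include_random).aic
    aic_b = fit_progression(long_b, include_random=include_random).aic

    deltas = []
    dropped = 0
    for _ in range(replicates):
        ids = rng.choice(subjects, size=len(subjects), replace=True)
        try:
            ra, rb = refit(ids)
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            dropped += 1
            continue
        deltas.append(ra - rb)
    deltas = np.asarray(deltas)
    if dropped:
        logger.info("bootstrap_aic_compare: %d replicate(s) dropped", dropped)
    # delta > 0 <=> model b has the lower AIC, i.e. the second model is better
    p = float(np.mean(deltas > 0) + 0.5 * np.mean(deltas == 0))
    lo, hi = np.percentile(deltas, [2.5, 97.5]) if len(deltas) else (np.nan, np.nan)
    return ComparisonResult(
        model_a="measure_a",
        model_b="measure_b",
        statistic="delta_aic",
        estimate=float(aic_a - aic_b),
        ci=(float(lo), float(hi)),
        p_value=p,
        n_replicates=int(len(deltas)),
        n_dropped=dropped,
    )
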