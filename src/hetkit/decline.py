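"""Longitudinal decline of blood m.3243A>G heteroplasmy.

Three estimators:

* per-subject trajectory summaries and a declining / non-declining /
  short-span classification (threshold 4 years of observation);
* the rate-vs-initial-level regression: under exponential loss
  dp/dt = -r*p the annual change is proportional to the level, so the slope
  of a through-origin regression of annual change on first level is -r;
* the compound-decline fit blood = init * b**(age + k), which yields the
  age-adjustment constants (b, k) used by :mod:`hetkit.adjustment`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .adjustment import DeclineParams

logger = logging.getLogger(__name__)

#: Minimum observation span (years) for a decline classification.
SPAN_THRESHOLD = 4.0

DECLINING = "declining"
NON_DECLINING = "non-declining"
SHORT_SPAN = "short-span"


@dataclass
class LinearDeclineFit:
    """Result of the rate-vs-initial-level regression.

    ``rate_constant`` is the positive continuous decline constant r; the
    fitted regression slope is -r.  ``extended`` holds the model with an
    age-at-first-measurement term: annual_change = -(r0 + r1*age)*first_level.
    """

    rate_constant: float
    conf_int: tuple
    r_squared: float
    n: int
    extended: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        return -self.rate_constant


@dataclass
class CompoundDeclineFit:
    """Fitted compound-decline constants and goodness of fit."""

    params: DeclineParams
    rss: float
    n_pairs: int

    @property
    def annual_percent_decline(self) -> float:
        return self.params.annual_percent_decline


def summarise_trajectories(blood_df: pd.DataFrame) -> pd.DataFrame:
    """Summarise repeated blood measurements per subject.

    ``blood_df`` needs subject_id, age_at_sample, level.  Subjects with a
    single measurement are skipped (and logged).  annual_change is the crude
    (last - first) / span; the class is ``short-span`` below 4 years of
    observation, otherwise ``declining`` iff the last level is below the
    first.
    """
    rows = []
    skipped = 0
    for sid, grp in blood_df.groupby("subject_id", sort=False):
        if len(grp) < 2:
            skipped += 1
            continue
        grp = grp.sort_values("age_at_sample")
        first_age = float(grp["age_at_sample"].iloc[0])
        last_age = float(grp["age_at_sample"].iloc[-1])
        span = last_age - first_age
        first = float(grp["level"].iloc[0])
        last = float(grp["level"].iloc[-1])
        if span <= 0:
            skipped += 1
            continue
        change = (last - first) / span
        if span < SPAN_THRESHOLD:
            cls = SHORT_SPAN
        elif last < first:
            cls = DECLINING
        else:
            cls = NON_DECLINING
        rows.append(
            {
                "subject_id": sid,
                "n_measurements": len(grp),
                "span": span,
                "first_level": first,
                "last_level": last,
                "age_first": first_age,
                "annual_change": change,
                "trajectory_class": cls,
            }
        )
    if skipped:
        logger.info("summarise_trajectories: skipped %d subject(s) without a usable span", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "n_measurements",
            "span",
            "first_level",
            "last_level",
            "age_first",
            "annual_change",
            "trajectory_class",
        ],
    )


def estimate_linear_decline(traj: pd.DataFrame) -> LinearDeclineFit:
    """Regress annual heteroplasmy change on initial level, through the origin.

    Base model: annual_change = slope * first_level, slope = -r.  Extended
    model adds an age interaction, annual_change = -(r0 + r1*age_first) *
    first_level, still with no intercept.  Both R² values are the uncentred
    (no-intercept) adjusted R² reported by statsmodels.
    """
    import statsmodels.api as sm

    if len(traj) < 3:
        raise ValueError("need >= 3 subjects with a computable annual change")
    x = traj["first_level"].to_numpy(dtype=float)
    y = traj["annual_change"].to_numpy(dtype=float)
    if np.allclose(x, 0):
        raise ValueError("degenerate design: all first levels are zero")

    base = sm.OLS(y, x[:, None]).fit()
    ci = base.conf_int()[0]
    fit = LinearDeclineFit(
        rate_constant=float(-base.params[0]),
        conf_int=(float(-ci[1]), float(-ci[0])),
        r_squared=float(base.rsquared_adj),
        n=int(len(traj)),
    )

    age = traj["age_first"].to_numpy(dtype=float)
    X = np.column_stack([x, x * age])
    ext = sm.OLS(y, X).fit()
    fit.extended = {
        "r0": float(-ext.params[0]),
        "r1": float(-ext.params[1]),
        "r_squared": float(ext.rsquared_adj),
    }
    return fit


def _compound_rss(blood, age, init, b, k):
    pred = init * b ** (age + k)
    resid = blood - pred
    return float(resid @ resid)


def fit_compound_decline(
    blood,
    age,
    init,
    b_bounds=(0.90, 1.00),
    k_bounds=(0.0, 30.0),
    grid_shape=(41, 31),
) -> CompoundDeclineFit:
    """Fit blood = init * b**(age + k) by least squares on the proportion scale.

    Parameters
    ----------
    blood, age, init : array_like
        Observed blood proportion, age in years, and an estimate of the
        initial (pre-decline) mutation load, e.g. sex-adjusted urine.
    b_bounds, k_bounds : tuple
        Search box for the retention base and age offset; the defaults
        bracket the published (0.977, 12) with wide margin.
    grid_shape : tuple
        Coarse-grid resolution for (b, k) before local refinement.

    Notes
    -----
    The objective is smooth but mildly ridge-shaped (errors in ``init``
    trade off against k, not b), so a coarse grid scan followed by bounded
    L-BFGS-B refinement is robust and fast.
    """
    blood = np.asarray(blood, dtype=float)
    age = np.asarray(age, dtype=float)
    init = np.asarray(init, dtype=float)
    if len(blood) < 10:
        raise ValueError("need >= 10 (blood, age, init) pairs to identify (b, k)")
    if np.any((init <= 0) | (init >= 1)):
        raise ValueError("initial-level estimates must lie strictly in (0, 1)")
    if np.any(age < 0):
        raise ValueError("age must be >= 0")

    bs = np.linspace(*b_bounds, grid_shape[0])
    ks = np.linspace(*k_bounds, grid_shape[1])
    # SSE over the (b, k) grid in one broadcast: shape (nb, nk, n)
    expo = age[None, None, :] + ks[None, :, None]
    pred = init[None, None, :] * bs[:, None, None] ** expo
    sse = ((blood[None, None, :] - pred) ** 2).sum(axis=2)
    ib, ik = np.unravel_index(np.argmin(sse), sse.shape)

    res = minimize(
        lambda t: _compound_rss(blood, age, init, t[0], t[1]),
        x0=[bs[ib], ks[ik]],
        method="L-BFGS-B",
        bounds=[b_bounds, k_bounds],
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    b_hat, k_hat = res.x
    return CompoundDeclineFit(
        params=DeclineParams(b=float(b_hat), k=float(k_hat)),
        rss=float(res.fun),
        n_pairs=int(len(blood)),
    )


def validate_against_muscle(muscle, adjusted_blood, unadjusted_blood=None) -> dict:
    """Regress (age-adjusted) blood on muscle heteroplasmy.

    Muscle is age-stable, so agreement with muscle is the external check on
    the age adjustment: a slope near 1 means adjusted blood and muscle read
    on the same scale.  If ``unadjusted_blood`` is given, its fit is reported
    alongside for the improvement comparison.
    """
    import statsmodels.api as sm

    muscle = np.asarray(muscle, dtype=float)
    adjusted_blood = np.asarray(adjusted_blood, dtype=float)
    if len(muscle) < 3:
        raise ValueError("need >= 3 paired subjects")
    X = sm.add_constant(muscle)
    fit = sm.OLS(adjusted_blood, X).fit()
    ci = fit.conf_int()[1]
    out = {
        "slope": float(fit.params[1]),
        "slope_ci": (float(ci[0]), float(ci[1])),
        "r_squared": float(fit.rsquared_adj),
        "n": int(len(muscle)),
    }
    if unadjusted_blood is not None:
        raw = sm.OLS(np.asarray(unadjusted_blood, dtype=float), X).fit()
        out["unadjusted"] = {
            "slope": float(raw.params[1]),
            "r_squared": float(raw.rsquared_adj),
        }
    return out
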