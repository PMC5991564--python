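"""qPCR mtDNA copy-number quantification and inter-plate standardisation.

Copy number per (diploid) nucleus is estimated from singleplex TaqMan assays
of a mitochondrial target (MT-ND1) and a nuclear single-copy target (B2M).
Each plate carries a six-point ten-fold plasmid dilution series per target;
sample quantities are read off the standard curve from the mean of triplicate
Ct values, and plates are tied together through a shared control sample:

    standardised = (copy number / on-plate control) * grand-mean control

QC rules: standard curves need R^2 > 0.999 and slope in [-3.6, -3.3]
(amplification efficiency roughly 90-100%); samples fail on Ct SD > 0.3 or
mean Ct > 33 after removal of outlier wells (|Ct - median| > 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

logger = logging.getLogger(__name__)

ND1 = "ND1"
B2M = "B2M"

CURVE_R2_MIN = 0.999
CURVE_SLOPE_RANGE = (-3.6, -3.3)
CT_SD_MAX = 0.3
MEAN_CT_MAX = 33.0
OUTLIER_CT = 0.5
#: (DNA concentration used for B2M) / (DNA concentration used for ND1);
#: the working dilutions are ~10 ng/ul for B2M and ~0.1 ng/ul for ND1.
DEFAULT_DILUTION_RATIO = 100.0
#: B2M is a single-copy nuclear gene, two copies per diploid nucleus.
DIPLOID_FACTOR = 2.0


@dataclass
class StandardCurve:
    target: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def qc_pass(self) -> bool:
        lo, hi = CURVE_SLOPE_RANGE
        return self.r_squared > CURVE_R2_MIN and lo <= self.slope <= hi


@dataclass
class SampleQuant:
    sample_id: str
    target: str
    mean_ct: float
    ct_sd: float
    quantity: float
    qc_pass: bool
    outliers_removed: int = 0
    fail_reason: str = ""


@dataclass
class CopyNumber:
    subject_id: str
    tissue: str
    plate_id: str
    raw_copies_per_nucleus: float
    standardized_copies_per_nucleus: float = float("nan")


def fit_standard_curve(dilution_steps, cts, target: str = ND1) -> StandardCurve:
    """OLS of mean Ct on log10(relative quantity) over a dilution series.

    ``dilution_steps`` are integer ten-fold steps (0 = undiluted stock), so
    the relative quantity of step d is 10**-d.  ``cts`` is a matching list of
    per-step Ct replicates (each an iterable); the mean Ct per step enters
    the regression.  At 100% amplification efficiency the slope is
    -1/log10(2) = -3.3219.
    """
    steps = np.asarray(dilution_steps, dtype=float)
    if len(steps) < 4:
        raise ValueError("need >= 4 usable dilution points to fit a standard curve")
    mean_cts = np.array([np.mean(np.asarray(c, dtype=float)) for c in cts])
    log_q = -steps  # log10(10**-d)
    res = linregress(log_q, mean_cts)
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(steps),
    )


def quantify_sample(cts, curve: StandardCurve, sample_id: str = "") -> SampleQuant:
    """Convert triplicate Cts to a relative quantity via the standard curve.

    Wells further than 0.5 Ct from the within-sample median are dropped as
    outliers; the sample fails QC if fewer than two wells survive, or the
    surviving wells have Ct SD > 0.3 or mean Ct > 33.  quantity =
    10**((mean_ct - intercept)/slope), on the same arbitrary scale as the
    dilution series.
    """
    if not curve.qc_pass:
        raise ValueError(f"standard curve for {curve.target} failed QC; cannot quantify")
    cts = np.asarray(cts, dtype=float)
    cts = cts[np.isfinite(cts)]
    keep = np.abs(cts - np.median(cts)) <= OUTLIER_CT if len(cts) else np.array([], bool)
    removed = int(len(cts) - keep.sum())
    surviving = cts[keep]
    if len(surviving) < 2:
        return SampleQuant(sample_id, curve.target, np.nan, np.nan, np.nan,
                           qc_pass=False, outliers_removed=removed,
                           fail_reason="fewer than 2 wells after outlier removal")
    mean_ct = float(surviving.mean())
    ct_sd = float(surviving.std(ddof=1))
    quantity = float(10.0 ** ((mean_ct - curve.intercept) / curve.slope))
    reason = ""
    if ct_sd > CT_SD_MAX:
        reason = f"Ct SD {ct_sd:.3f} > {CT_SD_MAX}"
    elif mean_ct > MEAN_CT_MAX:
        reason = f"mean Ct {mean_ct:.2f} > {MEAN_CT_MAX}"
    return SampleQuant(sample_id, curve.target, mean_ct, ct_sd, quantity,
                       qc_pass=reason == "", outliers_removed=removed,
                       fail_reason=reason)


def copies_per_nucleus(
    nd1: SampleQuant,
    b2m: SampleQuant,
    dilution_ratio: float = DEFAULT_DILUTION_RATIO,
) -> float:
    """mtDNA copies per nucleus from paired target quantities.

    copies = DIPLOID_FACTOR * (nd1.quantity * dilution_ratio) / b2m.quantity.
    The dilution ratio undoes the different working concentrations of the two
    assays; the diploid factor converts per-B2M-copy to per-nucleus.
    """
    if not (nd1.qc_pass and b2m.qc_pass):
        raise ValueError("both targets must pass QC to derive a copy number")
    return float(DIPLOID_FACTOR * nd1.quantity * dilution_ratio / b2m.quantity)


def standardize_plate(raw_values, plate_control: float, control_grand_mean: float):
    """Scale one plate's copy numbers by (grand-mean control / on-plate control)."""
    if not np.isfinite(plate_control) or plate_control <= 0:
        raise ValueError("plate control copy number missing or non-positive")
    return np.asarray(raw_values, dtype=float) * (control_grand_mean / plate_control)


def process_plates(
    qpcr: pd.DataFrame,
    dilution_ratio: float = DEFAULT_DILUTION_RATIO,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full plate pipeline on a long qPCR table.

    ``qpcr`` columns: plate_id, sample_id, role {sample|standard|control},
    target {ND1|B2M}, dilution_step (standards only), ct_rep1..ct_rep3.
    Returns (copy-number table, QC report).  Plates whose control fails QC on
    either target are excluded from standardisation (their standardised
    values are NaN) and logged.
    """
    ct_cols = ["ct_rep1", "ct_rep2", "ct_rep3"]
    qc_rows = []
    raw_rows = []
    plate_controls: dict[str, float] = {}

    for plate_id, plate in qpcr.groupby("plate_id", sort=False):
        curves = {}
        curve_ok = True
        for target, tgrp in plate[plate["role"] == "standard"].groupby("target"):
            tgrp = tgrp.sort_values("dilution_step")
            curve = fit_standard_curve(
                tgrp["dilution_step"].to_numpy(),
                tgrp[ct_cols].to_numpy(),
                target=target,
            )
            curves[target] = curve
            qc_rows.append(
                {"plate_id": plate_id, "kind": "curve", "id": target,
                 "qc_pass": curve.qc_pass, "detail": f"slope={curve.slope:.3f} r2={curve.r_squared:.5f}"}
            )
            curve_ok = curve_ok and curve.qc_pass
        if not curve_ok or set(curves) != {ND1, B2M}:
            logger.warning("plate %s: unusable standard curves; plate skipped", plate_id)
            continue

        for (sample_id, role), sgrp in plate[plate["role"] != "standard"].groupby(
            ["sample_id", "role"]
        ):
            quants = {}
            for target, tgrp in sgrp.groupby("target"):
                cts = tgrp[ct_cols].to_numpy(dtype=float).ravel()
                q = quantify_sample(cts, curves[target], sample_id=str(sample_id))
                quants[target] = q
                qc_rows.append(
                    {"plate_id": plate_id, "kind": role, "id": f"{sample_id}:{target}",
                     "qc_pass": q.qc_pass, "detail": q.fail_reason}
                )
            if set(quants) != {ND1, B2M} or not all(q.qc_pass for q in quants.values()):
                logger.info("plate %s sample %s: QC fail, no copy number", plate_id, sample_id)
                continue
            copies = copies_per_nucleus(quants[ND1], quants[B2M], dilution_ratio)
            if role == "control":
                plate_controls[plate_id] = copies
            else:
                raw_rows.append(
                    {"plate_id": plate_id, "sample_id": sample_id,
                     "raw_copies_per_nucleus": copies}
                )

    cn = pd.DataFrame(raw_rows, columns=["plate_id", "sample_id", "raw_copies_per_nucleus"])
    qc = pd.DataFrame(qc_rows, columns=["plate_id", "kind", "id", "qc_pass", "detail"])
    if plate_controls:
        grand_mean = float(np.mean(list(plate_controls.values())))
        std_vals = np.full(len(cn), np.nan)
        for plate_id, ctrl in plate_controls.items():
            mask = (cn["plate_id"] == plate_id).to_numpy()
            std_vals[mask] = standardize_plate(
                cn.loc[mask, "raw_copies_per_nucleus"].to_numpy(), ctrl, grand_mean
            )
        cn["standardized_copies_per_nucleus"] = std_vals
        missing = cn["standardized_copies_per_nucleus"].isna()
        if missing.any():
            logger.warning(
                "plates without a passing control excluded from standardisation: %s",
                sorted(cn.loc[missing, "plate_id"].unique()),
            )
    else:
        cn["standardized_copies_per_nucleus"] = np.nan
    return cn, qc


def copynumber_associations(df: pd.DataFrame, tissue: str) -> dict:
    """Per-tissue OLS of copy number on heteroplasmy, age and (urine) sex.

    ``df`` needs columns copies, het, age and, for urine, male (bool).
    Returns coefficient table, adjusted R² and P values.  With n < 10 the fit
    is still attempted but flagged.
    """
    import statsmodels.api as sm

    y = df["copies"].to_numpy(dtype=float)
    cols = ["het", "age"] + (["male"] if tissue == "urine" else [])
    X = sm.add_constant(df[cols].astype(float).to_numpy())
    if len(y) < 10:
        logger.warning("copynumber_associations(%s): only %d rows", tissue, len(y))
    fit = sm.OLS(y, X).fit()
    return {
        "tissue": tissue,
        "terms": ["const"] + cols,
        "coef": [float(v) for v in fit.params],
        "p_values": [float(v) for v in fit.pvalues],
        "r_squared": float(fit.rsquared_adj),
        "n": int(len(y)),
        "low_n": len(y) < 10,
    }
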