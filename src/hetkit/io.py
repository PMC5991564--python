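"""CSV schemas, validation and cohort-level exclusions.

Three long-format inputs (comma-separated, UTF-8, header row):

* ``heteroplasmy.csv`` — subject_id,sex,tissue,age_at_sample,level
* ``nmdas.csv``        — subject_id,age_at_assessment,item_01..item_29
* ``qpcr.csv``         — plate_id,sample_id,role,target,dilution_step,
                         ct_rep1,ct_rep2,ct_rep3

plus a ``subjects.csv`` table (subject_id,sex[,renal_transplant_age]) used
for the post-renal-transplant urine exclusion.  Heteroplasmy levels are
stored internally as proportions in [0, 1]; a column whose values exceed 1
is auto-detected as percentages and divided by 100 (logged), and a column
mixing the two scales is rejected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("blood", "urine", "muscle")
SEXES = ("male", "female")

SCHEMAS = {
    "heteroplasmy": ["subject_id", "sex", "tissue", "age_at_sample", "level"],
    "subjects": ["subject_id", "sex"],
    "nmdas": ["subject_id", "age_at_assessment"] + [f"item_{i:02d}" for i in range(1, 30)],
    "qpcr": ["plate_id", "sample_id", "role", "target", "dilution_step",
             "ct_rep1", "ct_rep2", "ct_rep3"],
}


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


class ValidationError(ValueError):
    """Row values violate a type invariant; the message names the rows."""


def _check_header(df: pd.DataFrame, schema: str) -> None:
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing required column(s) {missing}")


def normalise_levels(values: pd.Series, column: str = "level") -> pd.Series:
    """Return levels as proportions, auto-detecting a percentage column.

    Values above 1 mark the column as percentages; mixing percentages with
    sub-1 nonzero values (which would sit below 1% — under the assay's
    detection limit) is rejected as a scale inconsistency.
    """
    v = values.astype(float)
    if (v < 0).any() or (v > 100).any():
        rows = v.index[(v < 0) | (v > 100)].tolist()
        raise ValidationError(f"{column}: values outside [0, 100] at row(s) {rows}")
    if (v > 1).any():
        fractional = (v > 0) & (v < 1)
        if fractional.any():
            rows = v.index[fractional].tolist()
            raise ValidationError(
                f"{column}: mixed scales — values above 1 (percent) alongside "
                f"nonzero values below 1 (proportion) at row(s) {rows}; "
                "supply a single scale"
            )
        logger.info("%s: values > 1 detected; interpreting column as percentages", column)
        v = v / 100.0
    return v


def read_measurements(path, schema: str = "heteroplasmy",
                      detection_threshold: float = 0.03) -> pd.DataFrame:
    """Read and validate one of the documented CSV schemas.

    Returns a DataFrame with levels as proportions (heteroplasmy schema gets
    a ``below_detection`` flag for levels under the assay threshold).
    Invalid rows raise ValidationError naming the row index.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    _check_header(df, schema)

    if schema in ("heteroplasmy", "subjects"):
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(f"sex must be male/female at row(s) {df.index[bad_sex].tolist()}")
    if schema == "heteroplasmy":
        bad_tissue = ~df["tissue"].isin(TISSUES)
        if bad_tissue.any():
            raise ValidationError(
                f"tissue must be one of {TISSUES} at row(s) {df.index[bad_tissue].tolist()}"
            )
        bad_age = df["age_at_sample"].astype(float) < 0
        if bad_age.any():
            raise ValidationError(f"negative age at row(s) {df.index[bad_age].tolist()}")
        df = df.copy()
        df["level"] = normalise_levels(df["level"])
        df["below_detection"] = df["level"] < detection_threshold
    elif schema == "nmdas":
        items = df[[f"item_{i:02d}" for i in range(1, 30)]].astype(float)
        bad = ((items < 0) | (items > 5)).any(axis=1)
        if bad.any():
            raise ValidationError(f"item scores outside 0-5 at row(s) {df.index[bad].tolist()}")
    elif schema == "qpcr":
        bad_role = ~df["role"].isin(("sample", "standard", "control"))
        if bad_role.any():
            raise ValidationError(f"unknown role at row(s) {df.index[bad_role].tolist()}")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a validated table back to CSV (proportions kept as proportions,
    so read -> write -> read round-trips losslessly)."""
    df.to_csv(path, index=False)


def apply_exclusions(measurements: pd.DataFrame, subjects: pd.DataFrame):
    """Drop post-renal-transplant urine measurements.

    Urine heteroplasmy collapses after renal transplantation, so urine rows
    sampled at or after the transplant age are excluded.  Returns
    (filtered measurements, exclusion log).  Measurement subject_ids missing
    from the subjects table raise.  The operation is idempotent.
    """
    known = set(subjects["subject_id"])
    orphans = sorted(set(measurements["subject_id"]) - known)
    if orphans:
        raise ValidationError(f"measurements reference unknown subject_id(s): {orphans}")

    if "renal_transplant_age" not in subjects.columns:
        return measurements.copy(), pd.DataFrame(
            columns=["subject_id", "tissue", "age_at_sample", "reason"]
        )
    tx = subjects.set_index("subject_id")["renal_transplant_age"]
    tx_age = measurements["subject_id"].map(tx).astype(float)
    drop = (
        (measurements["tissue"] == "urine")
        & tx_age.notna()
        & (measurements["age_at_sample"].astype(float) >= tx_age)
    )
    log = measurements.loc[drop, ["subject_id", "tissue", "age_at_sample"]].copy()
    log["reason"] = "post-renal-transplant urine measurement"
    if len(log):
        logger.info("apply_exclusions: removed %d post-transplant urine row(s)", len(log))
    return measurements.loc[~drop].copy(), log.reset_index(drop=True)
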