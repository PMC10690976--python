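"""Policy-holder claims tables: schema, validation, I/O and sample selection.

The analysis operates on one row per insured individual with a region code,
needs covariates (age category, obesity, childbirth), preference covariates
(sex, SES, income, urbanization), and two binary outcomes: an initial
specialist visit and treatment.  A third flag, ``visit_observed``, records
whether an initial-visit claim actually exists in the observation window;
treated individuals whose visit fell outside the window are *censored*
(``treated=1, visit_observed=0``) and are assumed to have had a visit.
"""

from __future__ import annotations

import io
from typing import Mapping

import pandas as pd

__all__ = [
    "CLAIMS_COLUMNS",
    "CATEGORICAL_LEVELS",
    "NEEDS_COVARIATES",
    "PREFERENCE_COVARIATES",
    "STAGES",
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "read_claims",
    "write_claims",
    "validate_claims",
    "select_sample",
]

#: Canonical column order of a policy-holder table.
CLAIMS_COLUMNS = (
    "person_id",
    "region",
    "age_cat",
    "obesity",
    "childbirth",
    "sex_female",
    "ses_cat",
    "income_cat",
    "urban_cat",
    "initial_visit",
    "treated",
    "visit_observed",
)

#: Declared level sets; the first level of each is the modelling reference.
CATEGORICAL_LEVELS = {
    "age_cat": ("0-40", "41-60", "61-70", "70+"),
    "obesity": (0, 1),
    "childbirth": (0, 1),
    "sex_female": (0, 1),
    "ses_cat": ("high", "low", "middle"),
    "income_cat": ("high", "low", "middle"),
    "urban_cat": ("1", "2", "3", "4"),
}

#: Medically grounded predictors (the "needs" set X).
NEEDS_COVARIATES = ("age_cat", "obesity", "childbirth")
#: Demand-side predictors (the "preferences" set Z).
PREFERENCE_COVARIATES = ("sex_female", "ses_cat", "income_cat", "urban_cat")

COVARIATES = NEEDS_COVARIATES + PREFERENCE_COVARIATES

#: Patient-journey stages: treatment, initial visit, treatment given a visit.
STAGES = ("T", "I", "T_given_I")

_STAGE_ALIASES = {"T": "T", "I": "I", "T_GIVEN_I": "T_given_I", "TI": "T_given_I"}

_BINARY_COLS = ("obesity", "childbirth", "sex_female", "initial_visit", "treated", "visit_observed")

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class ValidationError(ValueError):
    """A cell value falls outside its declared level set, or is missing."""


class IntegrityError(ValueError):
    """A table-level invariant (e.g. unique person_id) is violated."""


def normalize_stage(stage: str) -> str:
    try:
        return _STAGE_ALIASES[str(stage).upper()]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


def _normalize_label(col: str, value) -> str:
    """Map common spelling variants onto canonical level labels."""
    s = str(value).strip().replace("–", "-").replace("—", "-")
    if col == "age_cat":
        s = s.replace(" ", "")
    elif col in ("ses_cat", "income_cat"):
        s = s.lower()
        if s in ("medium", "mid"):
            s = "middle"
    return s


def _coerce_binary(series: pd.Series, col: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="Int64")
    out[s.isin(_TRUTHY)] = 1
    out[s.isin(_FALSY)] = 0
    # numeric "1.0"/"0.0" from round-tripped floats
    numeric = pd.to_numeric(series, errors="coerce")
    out[numeric == 1] = 1
    out[numeric == 0] = 0
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"column {col!r}, row {row}: value {series[bad].iloc[0]!r} is not binary (0/1)"
        )
    return out


def validate_claims(df: pd.DataFrame, *, has_outcomes: bool = True) -> pd.DataFrame:
    """Validate and canonicalize a policy-holder table.

    Checks the declared level sets, rejects missing values, enforces unique
    ``person_id``, and applies the censored-visit convention: every treated
    record is assumed to have had an initial visit (``initial_visit`` is
    coerced to 1 wherever ``treated`` is 1), whether or not a visit claim was
    observed in-window.

    Parameters
    ----------
    df : DataFrame with the columns of :data:`CLAIMS_COLUMNS`.
    has_outcomes : if False, the outcome columns (initial_visit, treated,
        visit_observed) may be absent; used for covariate-only populations.

    Returns
    -------
    A new DataFrame in canonical column order with canonical dtypes.
    """
    required = list(CLAIMS_COLUMNS)
    if not has_outcomes:
        required = [c for c in required if c not in ("initial_visit", "treated", "visit_observed")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = df[required].copy().reset_index(drop=True)

    for col in required:
        na = out[col].isna()
        if na.any():
            raise ValidationError(f"column {col!r}, row {int(na.idxmax())}: missing value")

    if out["person_id"].duplicated().any():
        dup = out["person_id"][out["person_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate person_id {dup!r}")

    out["person_id"] = out["person_id"].astype(str)
    out["region"] = out["region"].astype(str).str.strip()

    for col, levels in CATEGORICAL_LEVELS.items():
        if col in _BINARY_COLS:
            continue
        vals = out[col].map(lambda v, c=col: _normalize_label(c, v))
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"column {col!r}, row {row}: value {out[col][bad].iloc[0]!r} "
                f"not in declared levels {levels}"
            )
        out[col] = pd.Categorical(vals, categories=levels)

    for col in _BINARY_COLS:
        if col not in required:
            continue
        out[col] = _coerce_binary(out[col], col).astype("int8")

    if has_outcomes:
        # Treated individuals are assumed to have had an initial visit even
        # when no in-window visit claim exists (the censored-visit rule).
        out.loc[out["treated"] == 1, "initial_visit"] = 1
        # A visit cannot be "observed" if no visit happened; and an untreated
        # individual's visit is never censored.
        bad = (out["visit_observed"] == 1) & (out["initial_visit"] == 0)
        if bad.any():
            raise IntegrityError(
                f"row {int(bad.idxmax())}: visit_observed=1 but initial_visit=0"
            )
        bad = (out["treated"] == 0) & (out["initial_visit"] == 1) & (out["visit_observed"] == 0)
        if bad.any():
            raise IntegrityError(
                f"row {int(bad.idxmax())}: untreated visit records cannot be censored "
                "(initial_visit=1 requires visit_observed=1 when treated=0)"
            )
    return out


def read_claims(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a claims CSV and return a validated policy-holder table.

    Parameters
    ----------
    path : CSV file with a header row, one row per policy-holder.
    schema : optional mapping ``{canonical_name: column_name_in_file}`` for
        files whose headers differ from :data:`CLAIMS_COLUMNS`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if schema:
        unknown = set(schema) - set(CLAIMS_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical column(s): {sorted(unknown)}")
        missing_src = [src for src in schema.values() if src not in df.columns]
        if missing_src:
            raise SchemaError(f"schema source column(s) not in file: {missing_src}")
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    return validate_claims(df)


def write_claims(table: pd.DataFrame, path) -> None:
    """Write a validated table as canonical CSV (UTF-8, header, fixed order)."""
    cols = [c for c in CLAIMS_COLUMNS if c in table.columns]
    buf = io.StringIO()
    table[cols].to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def n_censored(table: pd.DataFrame) -> int:
    """Number of treated records with no in-window visit claim."""
    return int(((table["treated"] == 1) & (table["visit_observed"] == 0)).sum())


def select_sample(table: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Return the analysis sample for one patient-journey stage.

    * ``"T"`` — probability of treatment in the full population: all rows.
    * ``"I"`` — probability of an initial visit: drops treated records whose
      visit claim is censored (they carry no information on in-window visits).
    * ``"T_given_I"`` — treatment conditional on a visit: rows with an initial
      visit, whether observed or assumed from treatment.
    """
    stage = normalize_stage(stage)
    if stage == "T":
        return table
    if stage == "I":
        keep = ~((table["treated"] == 1) & (table["visit_observed"] == 0))
        return table[keep].reset_index(drop=True)
    return table[table["initial_visit"] == 1].reset_index(drop=True)
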