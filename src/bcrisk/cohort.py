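"""Case-control cohort data model, tabular I/O, and imputation rules.

A cohort is one row per woman: enrollment age, the questionnaire-based
epidemiologic risk factors, an optional polygenic risk score (PRS), and
carrier flags for pathogenic variants (PVs) in nine high- or
moderate-penetrance breast cancer genes.  Missing values are represented
as NaN throughout; imputation replaces each missing epidemiologic value
with the mean of the observed values among participants with the same
case/control status, and recodes missing PV carrier status to 0
(non-carrier), since carrying a PV is much rarer than not.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Genes whose pathogenic-variant carrier status enters the model.
PV_GENES: tuple[str, ...] = (
    "BRCA1", "BRCA2", "PALB2", "ATM", "CHEK2", "BARD1", "RAD51C", "RAD51D", "TP53",
)
PV_COLUMNS: tuple[str, ...] = tuple(f"pv_{g}" for g in PV_GENES)

#: Questionnaire-based epidemiologic risk factors (the "epi" block).
EPI_FIELDS: tuple[str, ...] = (
    "age_menarche",
    "parity",
    "breastfeeding_months",
    "benign_breast_disease",
    "family_history",
    "height_cm",
    "bmi",
    "alcohol",
)
BINARY_FIELDS: tuple[str, ...] = ("benign_breast_disease", "family_history", "alcohol")

MANDATORY_COLUMNS: tuple[str, ...] = ("id", "status", "age")
ALL_COLUMNS: tuple[str, ...] = ("id", "status", "age", *EPI_FIELDS, "prs", *PV_COLUMNS)

# Plausibility ranges; values outside are recorded as missing on read.
_RANGES: dict[str, tuple[float, float]] = {
    "age": (18.0, 120.0),
    "age_menarche": (5.0, 30.0),
    "parity": (0.0, 30.0),
    "breastfeeding_months": (0.0, 600.0),
    "height_cm": (100.0, 250.0),
    "bmi": (10.0, 80.0),
}


class SchemaError(ValueError):
    """A cohort file does not match the documented column schema."""


class CohortError(ValueError):
    """A cohort violates a structural invariant (duplicate ids, bad status...)."""


@dataclass(frozen=True)
class RiskFactorProfile:
    """One woman's risk-factor record.

    Continuous fields use ``nan`` for missing; ``pv_carrier`` maps gene name
    to 0.0/1.0/nan.  ``status`` is 1 for a case, 0 for a control.
    """

    id: str
    status: int
    age: float
    age_menarche: float
    parity: float
    breastfeeding_months: float
    benign_breast_disease: float
    family_history: float
    height_cm: float
    bmi: float
    alcohol: float
    prs: float
    pv_carrier: Mapping[str, float]

    @property
    def is_case(self) -> bool:
        return self.status == 1

    def epi_values(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in EPI_FIELDS}

    def has_missing_epi(self) -> bool:
        return any(np.isnan(v) for v in self.epi_values().values())


@dataclass
class Cohort:
    """An ordered collection of risk-factor profiles backed by a DataFrame.

    Parameters
    ----------
    data
        One row per participant with (at least) the columns in
        :data:`ALL_COLUMNS`; extra columns (e.g. a true linear predictor from
        the generative simulator) are carried along untouched.
    label
        Provenance label, free text.
    imputed
        Whether imputation has been applied (downstream encoding requires it).
    """

    data: pd.DataFrame
    label: str = "cohort"
    imputed: bool = False

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column {col!r} is missing")
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate participant id(s): {sorted(set(dup))}")
        status = df["status"]
        if status.isna().any() or not status.isin([0, 1]).all():
            raise CohortError("status must be 0 (control) or 1 (case) for every row")
        age = df["age"].to_numpy(float)
        if np.any(age[~np.isnan(age)] < 18):
            raise CohortError("age must be >= 18 years")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())

    def statuses(self) -> np.ndarray:
        return self.data["status"].to_numpy(int)

    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(float)

    def controls(self) -> "Cohort":
        sub = self.data[self.data["status"] == 0].reset_index(drop=True)
        return Cohort(sub.copy(), label=f"{self.label}/controls", imputed=self.imputed)

    def profile(self, i: int) -> RiskFactorProfile:
        row = self.data.iloc[i]
        return RiskFactorProfile(
            id=str(row["id"]),
            status=int(row["status"]),
            age=float(row["age"]),
            age_menarche=float(row["age_menarche"]),
            parity=float(row["parity"]),
            breastfeeding_months=float(row["breastfeeding_months"]),
            benign_breast_disease=float(row["benign_breast_disease"]),
            family_history=float(row["family_history"]),
            height_cm=float(row["height_cm"]),
            bmi=float(row["bmi"]),
            alcohol=float(row["alcohol"]),
            prs=float(row["prs"]),
            pv_carrier={g: float(row[f"pv_{g}"]) for g in PV_GENES},
        )

    def profiles(self) -> Iterator[RiskFactorProfile]:
        for i in range(len(self)):
            yield self.profile(i)


def read_cohort(path) -> Cohort:
    """Read a comma-separated cohort file.

    Unparseable or out-of-range cells are recorded as missing; the number of
    such cells is logged as a warning.  Missing mandatory columns raise
    :class:`SchemaError`; duplicate ids raise :class:`CohortError`.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} is missing from {path}")
    n_bad = 0
    for col in df.columns:
        if col == "id":
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        n_bad += int((raw.notna() & num.isna()).sum())
        lo, hi = _RANGES.get(col, (-np.inf, np.inf))
        if col == "status":
            out = num.notna() & ~num.isin([0, 1])
        elif col in BINARY_FIELDS or col in PV_COLUMNS:
            # imputed binaries are fractional group proportions, so accept [0, 1]
            out = num.notna() & ((num < 0) | (num > 1))
        else:
            out = num.notna() & ((num < lo) | (num > hi))
        n_bad += int(out.sum())
        num[out] = np.nan
        df[col] = num
    if n_bad:
        log.warning("read_cohort(%s): %d unparseable/out-of-range cells set missing", path, n_bad)
    if df["status"].isna().any():
        raise CohortError("status missing or invalid for some rows")
    return Cohort(df, label=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (empty cell = missing); round-trips exactly."""
    cols = [c for c in ALL_COLUMNS if c in cohort.data.columns]
    extra = [c for c in cohort.data.columns if c not in cols]
    cohort.data[cols + extra].to_csv(path, index=False, float_format="%.17g")


def impute_missing(cohort: Cohort) -> Cohort:
    """Mean-impute by case/control status; recode missing PV carriers to 0.

    Each missing epidemiologic value (and missing enrollment age) is replaced
    by the mean of the observed values among participants of the same status —
    binary fields therefore take the observed status-group proportion as a
    fractional value, which the linear predictor accepts.  Returns a new
    cohort flagged imputed; the input is untouched.
    """
    if cohort.imputed:
        raise CohortError("cohort is already imputed")
    df = cohort.data.copy()
    status = df["status"]
    for fld in ("age", *EPI_FIELDS):
        col = df[fld]
        for s in (0, 1):
            mask = (status == s).to_numpy()
            if not mask.any():
                continue
            vals = col[mask]
            if vals.isna().all():
                if vals.isna().any():
                    raise CohortError(
                        f"cannot impute {fld!r}: no observed values among "
                        f"{'cases' if s else 'controls'}"
                    )
                continue
            if vals.isna().any():
                df.loc[mask & col.isna().to_numpy(), fld] = float(vals.mean())
    for col in PV_COLUMNS:
        df[col] = df[col].fillna(0.0)
    return Cohort(df, label=cohort.label, imputed=True)


def exclude_missing(cohort: Cohort, scope: str) -> Cohort:
    """Drop profiles with any missing value in the named scope.

    Parameters
    ----------
    scope
        ``"epidemiologic"`` (the questionnaire fields) or ``"pv"`` (the nine
        gene carrier flags).
    """
    if scope == "epidemiologic":
        cols = list(EPI_FIELDS)
    elif scope == "pv":
        cols = list(PV_COLUMNS)
    else:
        raise ValueError(f"scope must be 'epidemiologic' or 'pv', got {scope!r}")
    keep = ~cohort.data[cols].isna().any(axis=1)
    removed = int((~keep).sum())
    if removed:
        log.info("exclude_missing(%s): removed %d of %d profiles", scope, removed, len(cohort))
    if not keep.any():
        log.warning("exclude_missing(%s): no profiles remain", scope)
    return Cohort(
        cohort.data[keep].reset_index(drop=True).copy(),
        label=cohort.label,
        imputed=cohort.imputed,
    )
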