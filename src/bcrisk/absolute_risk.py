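"""Lifetime absolute risk under competing mortality.

The baseline age-specific hazard is calibrated so that the model reproduces
population incidence over a reference set of controls, then each woman's
hazard ``lambda(t) = lambda0(t) * exp(LP)`` is projected from her start age to
age 80 with a discrete annual recursion that allocates each year's event
probability between breast cancer and death from other causes in proportion
to the cause-specific hazards (exact for piecewise-constant hazards):

    h(t) = lambda(t) + m(t)
    P(diagnosed in year t) = S(t) * (lambda(t)/h(t)) * (1 - exp(-h(t)))
    S(t+1) = S(t) * exp(-h(t))

Rates are supplied per 100 000 person-years in files and held per person-year
internally, on half-open age bands covering [18, 80).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError
from .relative_risk import CoefficientSet, ModelVariant, linear_predictors

AGE_MIN = 18
AGE_MAX = 80


class RateTableError(ValueError):
    """Bands do not tile [18, 80) or carry invalid rates."""


@dataclass(frozen=True)
class PerYearRates:
    """Piecewise-constant rates expanded to single years of age 18..79."""

    ages: np.ndarray        # integer years, AGE_MIN..AGE_MAX-1
    incidence: np.ndarray   # events per person-year
    mortality: np.ndarray   # non-breast-cancer deaths per person-year


@dataclass(frozen=True)
class RateTable:
    """Age-banded incidence and competing-mortality rates.

    Bands are half-open ``[age_start, age_end)``, contiguous, and must cover
    [18, 80).  Rates are per person-year.
    """

    age_start: np.ndarray
    age_end: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.age_start, int)
        e = np.asarray(self.age_end, int)
        if len(s) == 0 or s[0] != AGE_MIN or e[-1] != AGE_MAX:
            raise RateTableError(f"bands must cover [{AGE_MIN}, {AGE_MAX})")
        gaps = np.nonzero(s[1:] != e[:-1])[0]
        if len(gaps):
            raise RateTableError(
                f"gap or overlap between ages {e[gaps[0]]} and {s[gaps[0] + 1]}"
            )
        if np.any(np.asarray(self.incidence) < 0) or np.any(np.asarray(self.mortality) < 0):
            raise RateTableError("rates must be non-negative")

    @classmethod
    def from_bands(cls, bands) -> "RateTable":
        """Build from an iterable of (age_start, age_end, incidence, mortality)."""
        a = np.array([b[0] for b in bands], int)
        e = np.array([b[1] for b in bands], int)
        inc = np.array([b[2] for b in bands], float)
        mort = np.array([b[3] for b in bands], float)
        return cls(a, e, inc, mort)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        """Read columns age_start, age_end, incidence_per_100k, mortality_per_100k."""
        df = pd.read_csv(path, comment="#")
        return cls(
            df["age_start"].to_numpy(int),
            df["age_end"].to_numpy(int),
            df["incidence_per_100k"].to_numpy(float) / 1e5,
            df["mortality_per_100k"].to_numpy(float) / 1e5,
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# half-open age bands [age_start, age_end); rates per 100000 person-years\n")
            pd.DataFrame(
                {
                    "age_start": self.age_start,
                    "age_end": self.age_end,
                    "incidence_per_100k": np.asarray(self.incidence) * 1e5,
                    "mortality_per_100k": np.asarray(self.mortality) * 1e5,
                }
            ).to_csv(fh, index=False, float_format="%.17g")

    def expand(self) -> PerYearRates:
        return expand_rate_table(self)


def expand_rate_table(table: RateTable) -> PerYearRates:
    """Expand banded rates to per-year-of-age values (each year inherits its band)."""
    ages = np.arange(AGE_MIN, AGE_MAX)
    idx = np.searchsorted(np.asarray(table.age_end, int), ages, side="right")
    return PerYearRates(
        ages=ages,
        incidence=np.asarray(table.incidence, float)[idx],
        mortality=np.asarray(table.mortality, float)[idx],
    )


@dataclass(frozen=True)
class BaselineHazard:
    """Per-year baseline breast-cancer hazard for the reference woman (LP = 0)."""

    ages: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.hazard, float)
        if np.any(h < 0) or not np.all(np.isfinite(h)):
            raise ValueError("baseline hazard must be finite and non-negative")


@dataclass(frozen=True)
class RiskEstimate:
    """One woman's result under one model variant."""

    id: str
    variant: ModelVariant
    linear_predictor: float
    lifetime_risk: float
    category: int


def calibrate_from_lps(rates: RateTable, reference_lps: np.ndarray) -> BaselineHazard:
    """Divide population incidence by the reference-mean relative risk.

    Guarantees that the mean hazard over the reference distribution equals the
    population incidence at every age:
    ``mean_i lambda0(t) exp(LP_i) = lambda_pop(t)``.
    """
    lps = np.asarray(reference_lps, float)
    if lps.size == 0:
        raise ValueError("reference is empty; cannot calibrate")
    mean_rr = float(np.mean(np.exp(lps)))
    per_year = expand_rate_table(rates)
    return BaselineHazard(ages=per_year.ages, hazard=per_year.incidence / mean_rr)


def calibrate_baseline(
    rates: RateTable,
    reference: Cohort,
    coeffs: CoefficientSet,
    variant: ModelVariant,
) -> BaselineHazard:
    """Calibrate the baseline hazard against a reference control cohort."""
    if len(reference) == 0:
        raise CohortError("reference cohort is empty")
    if (reference.statuses() != 0).any():
        raise CohortError("reference cohort must contain only controls")
    if not reference.imputed:
        raise CohortError("reference cohort must be imputed")
    lps = linear_predictors(reference, coeffs, variant)
    return calibrate_from_lps(rates, lps)


def lifetime_risk(
    lp: float,
    baseline: BaselineHazard,
    mortality: np.ndarray,
    age_start: float,
    age_end: float = AGE_MAX,
) -> float:
    """Absolute risk of breast cancer between two ages under competing mortality.

    Parameters
    ----------
    lp
        Log relative risk of the woman.
    baseline
        Calibrated per-year baseline hazard on ages 18..79.
    mortality
        Per-year competing mortality aligned with ``baseline.ages``.
    age_start, age_end
        Projection window; years are whole grid years ``floor(age_start)`` to
        ``age_end - 1``.  Must satisfy 18 <= age_start < age_end <= 80.
    """
    if not (AGE_MIN <= age_start < age_end <= AGE_MAX):
        raise ValueError(
            f"need {AGE_MIN} <= age_start < age_end <= {AGE_MAX}, "
            f"got ({age_start}, {age_end})"
        )
    a0 = int(np.floor(age_start)) - AGE_MIN
    a1 = int(np.ceil(age_end)) - AGE_MIN
    lam = baseline.hazard[a0:a1] * np.exp(lp)
    m = np.asarray(mortality, float)[a0:a1]
    h = lam + m
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(h > 0, lam / np.where(h > 0, h, 1.0), 0.0)
        year_prob = frac * -np.expm1(-h)
    surv = np.concatenate([[1.0], np.cumprod(np.exp(-h))[:-1]])
    return float(np.sum(surv * year_prob))


def lifetime_risks(
    lps: np.ndarray,
    ages_start: np.ndarray,
    baseline: BaselineHazard,
    mortality: np.ndarray,
    age_end: float = AGE_MAX,
) -> np.ndarray:
    """Vectorized :func:`lifetime_risk` with per-subject start ages.

    Start ages at or beyond ``age_end`` yield risk 0 (the projection window is
    empty) rather than raising, so whole cohorts including women older than 80
    can be scored in one call.
    """
    lps = np.asarray(lps, float)
    starts = np.floor(np.clip(np.asarray(ages_start, float), AGE_MIN, AGE_MAX)).astype(int)
    rr = np.exp(lps)
    m = np.asarray(mortality, float)
    risk = np.zeros_like(lps)
    surv = np.ones_like(lps)
    for t in range(AGE_MIN, int(age_end)):
        active = starts <= t
        if not active.any():
            continue
        lam = baseline.hazard[t - AGE_MIN] * rr
        h = lam + m[t - AGE_MIN]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(h > 0, lam / np.where(h > 0, h, 1.0), 0.0)
        year_prob = frac * -np.expm1(-h)
        risk = np.where(active, risk + surv * year_prob, risk)
        surv = np.where(active, surv * np.exp(-h), surv)
    return risk


def categorize_risk(risk, thresholds) -> np.ndarray | int:
    """Half-open binning: category ``j`` iff ``thr_j <= risk < thr_{j+1}``.

    Risks below the first threshold are category 0; at or above the last,
    category ``len(thresholds)``.
    """
    thr = np.asarray(thresholds, float)
    if len(thr) == 0 or np.any(np.diff(thr) <= 0) or thr[0] <= 0 or thr[-1] >= 1:
        raise ValueError("thresholds must be strictly ascending probabilities in (0, 1)")
    cats = np.searchsorted(thr, np.asarray(risk, float), side="right")
    if np.isscalar(risk) or np.ndim(risk) == 0:
        return int(cats)
    return cats
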