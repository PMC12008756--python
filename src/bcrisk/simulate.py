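"""Synthetic case-control cohorts, rate tables, and missingness.

Two modes are provided.  *Marginal* mode draws every covariate independently
within status from the marginal distributions observed in a West/East African
hospital-based case-control study of breast cancer (ages, reproductive
history, anthropometry, rare pathogenic-variant carriers, PRS), so the full
pipeline can be exercised on realistic-looking data.  *Generative* mode goes
further and provides ground truth: covariates are drawn from the control
distribution for a source population, disease is simulated year by year from
a true linear predictor against a rate-calibrated baseline hazard, incident
subjects become cases, and the true LP is recorded per subject for
parameter-recovery tests.

All generators are deterministic given the mandatory seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .absolute_risk import AGE_MAX, AGE_MIN, RateTable, calibrate_from_lps
from .cohort import EPI_FIELDS, PV_COLUMNS, PV_GENES, Cohort
from .relative_risk import (
    CoefficientSet,
    ModelVariant,
    adjust_family_history,
    default_coefficients,
    linear_predictors,
)

# (mean, sd) per status for the continuous covariates; "case"/"control" keys.
_DEFAULT_CONTINUOUS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"case": (49.5, 12.2), "control": (41.5, 13.8)},
    "age_menarche": {"case": (15.2, 2.0), "control": (15.3, 2.2)},
    "parity": {"case": (3.8, 2.1), "control": (3.9, 2.6)},
    "breastfeeding_months": {"case": (54.3, 39.4), "control": (67.0, 54.3)},
    "height_cm": {"case": (162.0, 7.3), "control": (159.0, 6.6)},
    # BMI means/SDs chosen to reproduce the observed category distribution
    # (~5% under 18.5, ~38% in 18.5-24.9, ~30% in 25-29.9, ~24% at 30+)
    "bmi": {"case": (26.3, 5.6), "control": (26.5, 5.7)},
}

# truncation bounds for the continuous draws
_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 95.0),
    "age_menarche": (8.0, 28.0),
    "parity": (0.0, 20.0),
    "breastfeeding_months": (0.0, 400.0),
    "height_cm": (120.0, 200.0),
    "bmi": (12.0, 60.0),
}

_DEFAULT_BINARY: dict[str, dict[str, float]] = {
    "benign_breast_disease": {"case": 0.051, "control": 0.033},
    "family_history": {"case": 0.036, "control": 0.020},
    "alcohol": {"case": 0.082, "control": 0.048},
}

# Carrier probabilities per gene; the small nonzero control frequencies avoid
# degenerate infinite odds ratios in generated data.
_DEFAULT_PV_FREQ: dict[str, dict[str, float]] = {
    "BRCA1": {"case": 0.027, "control": 0.003},
    "BRCA2": {"case": 0.018, "control": 0.006},
    "PALB2": {"case": 0.007, "control": 0.002},
    "ATM": {"case": 0.002, "control": 0.001},
    "CHEK2": {"case": 0.001, "control": 0.001},
    "BARD1": {"case": 0.003, "control": 0.002},
    "RAD51C": {"case": 0.001, "control": 0.001},
    "RAD51D": {"case": 0.001, "control": 0.001},
    "TP53": {"case": 0.002, "control": 0.0005},
}

_DEFAULT_PRS: dict[str, tuple[float, float]] = {
    "case": (0.268, 0.317),
    "control": (0.182, 0.314),
}

# Overall per-field missingness rates (fractions of 1686 participants).
_DEFAULT_MISSINGNESS: dict[str, float] = {
    "family_history": 1 / 1686,
    "age_menarche": 57 / 1686,
    "parity": 19 / 1686,
    "height_cm": 46 / 1686,
    "alcohol": 6 / 1686,
    "breastfeeding_months": 28 / 1686,
    "bmi": 74 / 1686,
}

# Differential sequencing coverage: PV status missing much more often in cases.
_DEFAULT_PV_MISSINGNESS: dict[str, float] = {"case": 0.572, "control": 0.412}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the marginal distributions, carrier frequencies, PRS
    moments, and missingness patterns of the motivating case-control study
    (996 cases, 690 controls).  ``seed`` is mandatory.
    """

    seed: int
    n_cases: int = 996
    n_controls: int = 690
    continuous: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CONTINUOUS.items()}
    )
    binary_prevalence: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_BINARY.items()}
    )
    pv_frequency: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PV_FREQ.items()}
    )
    prs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PRS)
    )
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    pv_missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PV_MISSINGNESS)
    )
    # rate-table shape: smooth unimodal incidence peaking at peak_per_100k,
    # Gompertz-like monotone competing mortality
    rate_peak_per_100k: float = 64.6
    rate_peak_age: float = 55.0
    rate_width_years: float = 15.0
    mortality_base: float = 5e-4
    mortality_growth: float = 0.07
    # generative mode
    true_coefficients: CoefficientSet | None = None
    population_size: int = 200_000
    horizon_years: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for fld, per in self.binary_prevalence.items():
            for s, p in per.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {fld} for {s} outside [0, 1]")
        for fld, (mean, sd) in self.prs.items():
            if sd <= 0:
                raise ValueError("PRS SD must be positive")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws whose mean equals the configured target.

    Truncation pulls the mean of a plainly truncated normal away from its
    location parameter (e.g. parity truncated at 0 would average 4.25 instead
    of the configured 3.9), so the location is solved such that the truncated
    distribution's mean hits the target.
    """
    loc = _solve_trunc_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


@lru_cache(maxsize=None)
def _solve_trunc_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    def trunc_mean(loc):
        return truncnorm.mean((lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd) - mean

    if abs(trunc_mean(mean)) < 1e-12:
        return mean
    return float(brentq(trunc_mean, mean - 6 * sd, mean + 2 * sd, xtol=1e-10))


def _draw_status_block(config: GeneratorConfig, rng, status_name: str, n: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for fld, per in config.continuous.items():
        mean, sd = per[status_name]
        lo, hi = _BOUNDS[fld]
        vals = _trunc_normal(rng, mean, sd, lo, hi, n)
        if fld == "parity":
            vals = np.clip(np.round(vals), 0, None)
        cols[fld] = vals
    for fld, per in config.binary_prevalence.items():
        cols[fld] = (rng.random(n) < per[status_name]).astype(float)
    for gene in PV_GENES:
        freq = config.pv_frequency.get(gene, {}).get(status_name, 0.0)
        cols[f"pv_{gene}"] = (rng.random(n) < freq).astype(float)
    mean, sd = config.prs[status_name]
    cols["prs"] = rng.normal(mean, sd, n)
    return pd.DataFrame(cols)


def generate_marginal_cohort(config: GeneratorConfig) -> Cohort:
    """Draw cases and controls independently from their marginal distributions.

    Continuous fields are truncated normals (age >= 18, parity rounded and
    non-negative, months >= 0), binaries and PV carriers are Bernoulli, and
    the PRS is normal, each with status-specific parameters.  Missingness is
    then injected at the configured per-field rates.  Covariates are
    independent within status — the source tables report only marginals.
    """
    rng = np.random.default_rng(config.seed)
    blocks = []
    for status_name, status, n in (("case", 1, config.n_cases), ("control", 0, config.n_controls)):
        df = _draw_status_block(config, rng, status_name, n)
        df.insert(0, "status", status)
        df.insert(0, "id", [f"{status_name}_{i:05d}" for i in range(n)])
        blocks.append(df)
    data = pd.concat(blocks, ignore_index=True)
    cohort = Cohort(data, label="synthetic-marginal", imputed=False)
    return _inject(cohort, config.missingness, config.pv_missingness, rng)


def inject_missingness(
    cohort: Cohort,
    rates: Mapping[str, float],
    seed: int,
    pv_rates_by_status: Mapping[str, float] | None = None,
) -> Cohort:
    """Set each field missing independently with its per-field probability.

    ``pv_rates_by_status`` optionally blanks all nine PV flags jointly at a
    status-specific rate, mimicking differential sequencing coverage.
    """
    if cohort.imputed:
        raise ValueError("cannot inject missingness into an imputed cohort")
    for fld, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {fld} outside [0, 1]: {rate}")
    if pv_rates_by_status:
        for s, rate in pv_rates_by_status.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"PV missingness rate for {s} outside [0, 1]: {rate}")
    return _inject(cohort, rates, pv_rates_by_status, np.random.default_rng(seed))


def _inject(cohort, rates, pv_rates_by_status, rng) -> Cohort:
    df = cohort.data.copy()
    n = len(df)
    for fld, rate in rates.items():
        if rate > 0 and fld in df.columns:
            df.loc[rng.random(n) < rate, fld] = np.nan
    if pv_rates_by_status:
        status = df["status"].to_numpy(int)
        blank = np.zeros(n, bool)
        for s_name, s_val in (("case", 1), ("control", 0)):
            rate = pv_rates_by_status.get(s_name, 0.0)
            mask = status == s_val
            blank |= mask & (rng.random(n) < rate)
        df.loc[blank, list(PV_COLUMNS)] = np.nan
    return Cohort(df, label=cohort.label, imputed=False)


def generate_rate_table(config: GeneratorConfig) -> RateTable:
    """Smooth unimodal incidence and monotone competing mortality on 5-year bands.

    Incidence follows a Gaussian bump in age scaled so its largest band equals
    the configured peak (default 64.6 per 100 000); competing mortality grows
    exponentially with age.
    """
    if config.rate_peak_per_100k <= 0:
        raise ValueError("peak incidence must be positive")
    edges = [AGE_MIN, 20] + list(range(25, AGE_MAX + 1, 5))
    starts = np.array(edges[:-1])
    ends = np.array(edges[1:])
    mids = (starts + ends) / 2.0
    shape = np.exp(-(((mids - config.rate_peak_age) / config.rate_width_years) ** 2))
    incidence = shape / shape.max() * config.rate_peak_per_100k / 1e5
    mortality = config.mortality_base * np.exp(config.mortality_growth * (mids - AGE_MIN))
    return RateTable(starts, ends, incidence, mortality)


def generate_generative_cohort(
    config: GeneratorConfig, rates: RateTable | None = None
) -> Cohort:
    """Simulate disease from a true linear predictor; return a labeled cohort.

    A source population of control-like covariate vectors is drawn; each
    subject's true combined-model LP is computed with the configured true
    coefficients; a baseline hazard is calibrated to the rate table against
    that population; disease and competing death are then simulated year by
    year up to each subject's enrollment age plus ``horizon_years``.  Incident
    subjects become cases (enrolled at their onset age), disease-free
    survivors at enrollment become the control pool, and the requested numbers
    of each are sampled.  The true LP is recorded in a ``true_lp`` column.
    """
    rng = np.random.default_rng(config.seed)
    if rates is None:
        rates = generate_rate_table(config)
    coeffs = config.true_coefficients or default_coefficients()
    n_pop = config.population_size

    pop = _draw_status_block(config, rng, "control", n_pop)
    pop.insert(0, "status", 0)
    pop.insert(0, "id", [f"pop_{i:06d}" for i in range(n_pop)])
    population = Cohort(pop, label="synthetic-population", imputed=True)

    prs_var = float(np.var(pop["prs"].to_numpy(float)))
    adj = adjust_family_history(coeffs, ModelVariant.COMBINED, prs_variance=prs_var)
    lps = linear_predictors(population, adj, ModelVariant.COMBINED)
    baseline = calibrate_from_lps(rates, lps)
    per_year = rates.expand()

    enroll = np.floor(pop["age"].to_numpy(float)).astype(int)
    end_year = np.minimum(enroll + config.horizon_years, AGE_MAX)
    rr = np.exp(lps)
    alive = np.ones(n_pop, bool)
    onset = np.full(n_pop, -1, int)
    for t in range(AGE_MIN, AGE_MAX):
        active = alive & (onset < 0) & (t < end_year)
        if not active.any():
            break
        lam = baseline.hazard[t - AGE_MIN] * rr
        m = per_year.mortality[t - AGE_MIN]
        h = lam + m
        u = rng.random(n_pop)
        event = active & (u < -np.expm1(-h))
        if event.any():
            cause = rng.random(n_pop) < np.divide(
                lam, h, out=np.zeros_like(lam), where=h > 0
            )
            disease = event & cause
            death = event & ~cause
            onset[disease] = t
            alive[death] = False

    case_pool = np.nonzero(onset >= 0)[0]
    control_pool = np.nonzero(alive & (onset < 0))[0]
    if len(case_pool) < config.n_cases:
        raise ValueError(
            f"only {len(case_pool)} incident cases simulated for a request of "
            f"{config.n_cases}; increase population_size (currently {n_pop})"
        )
    if len(control_pool) < config.n_controls:
        raise ValueError(
            f"only {len(control_pool)} controls available; increase population_size"
        )
    cases = rng.choice(case_pool, size=config.n_cases, replace=False)
    controls = rng.choice(control_pool, size=config.n_controls, replace=False)

    df = pop.copy()
    df["true_lp"] = lps
    case_df = df.iloc[cases].copy()
    case_df["status"] = 1
    case_df["age"] = onset[cases].astype(float)
    ctrl_df = df.iloc[controls].copy()
    out = pd.concat([case_df, ctrl_df], ignore_index=True)
    out["id"] = [f"subj_{i:05d}" for i in range(len(out))]
    return Cohort(out, label="synthetic-generative", imputed=True)
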