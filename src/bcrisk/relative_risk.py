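"""Relative-risk model: covariate encoding, PRS, and the linear predictor.

The model multiplies a woman's encoded risk-factor values by log odds-ratio
coefficients; ``exp(LP)`` is her risk relative to a reference woman (parity 0,
height 160 cm, BMI in 18.5-24.9, all binary factors 0, continuous factors at
their centering values, PRS 0, no pathogenic variants).

Four model variants are supported: epidemiologic factors only, PRS only,
PRS plus pathogenic variants (PVs), and the combined model.  When genetic
terms are active the family-history coefficient is attenuated to avoid
double-counting heritability already captured by the modeled variants:

    beta_FH_adjusted = max(0, beta_FH - sum_k f_k (1 - f_k) beta_k^2)

summed over the SNVs and PVs in the active variant, since a variant with
per-allele log-OR beta_k and allele frequency f_k induces a family-history
log-OR of about beta_k^2 * f_k(1-f_k) through the genotype correlation of 1/2
between first-degree relatives.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .cohort import BINARY_FIELDS, EPI_FIELDS, PV_GENES, Cohort, RiskFactorProfile


class ModelVariant(str, enum.Enum):
    """Which blocks of the combined model are active."""

    EPI_ONLY = "epi_only"
    PRS_ONLY = "prs_only"
    PRS_PLUS_PV = "prs_plus_pv"
    COMBINED = "combined"

    @property
    def includes_epi(self) -> bool:
        return self in (ModelVariant.EPI_ONLY, ModelVariant.COMBINED)

    @property
    def includes_prs(self) -> bool:
        return self in (ModelVariant.PRS_ONLY, ModelVariant.PRS_PLUS_PV, ModelVariant.COMBINED)

    @property
    def includes_pv(self) -> bool:
        return self in (ModelVariant.PRS_PLUS_PV, ModelVariant.COMBINED)

    @property
    def includes_genetic(self) -> bool:
        return self.includes_prs or self.includes_pv


class GeneticEffect(NamedTuple):
    """Per-variant (or per-gene) log odds ratio and carrier/allele frequency."""

    beta: float
    freq: float


class SnvWeight(NamedTuple):
    beta: float
    freq: float
    effect_allele: str = ""


#: Term names of the epidemiologic block, in canonical order.
EPI_TERMS: tuple[str, ...] = (
    "age_menarche",
    "first_live_birth",
    "additional_live_births",
    "breastfeeding_months",
    "benign_breast_disease",
    "family_history",
    "height_per_10cm",
    "bmi_under_18_5",
    "bmi_25_29_9",
    "bmi_30_plus",
    "alcohol",
)

DEFAULT_CENTERING: dict[str, float] = {
    "age_menarche": 15.0,
    "breastfeeding_months": 0.0,
    "height_cm": 160.0,
}


class NotImputedError(ValueError):
    """Encoding or scoring was attempted on a profile with missing values."""


class CoefficientError(ValueError):
    """A coefficient set is incomplete or inconsistent for the requested use."""


@dataclass(frozen=True)
class CoefficientSet:
    """Named log odds ratios, encodings, and frequencies for the model.

    Attributes
    ----------
    epi
        Log-OR per epidemiologic term (names in :data:`EPI_TERMS`).
    prs_coefficient
        Log-OR per unit of the polygenic risk score.
    pv
        Gene -> (log-OR, carrier frequency) for the pathogenic variants.
    snv_weights
        Variant id -> (per-allele weight, effect-allele frequency); empty when
        the PRS is consumed as a precomputed score.
    centering
        Reference values subtracted from continuous epidemiologic terms so
        that LP = 0 describes the reference woman.
    adjusted_family_history
        The attenuated family-history log-OR; set by
        :func:`adjust_family_history`, ``None`` until then.
    """

    epi: Mapping[str, float]
    prs_coefficient: float = 0.0
    pv: Mapping[str, GeneticEffect] = field(default_factory=dict)
    snv_weights: Mapping[str, SnvWeight] = field(default_factory=dict)
    centering: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CENTERING))
    adjusted_family_history: float | None = None

    def __post_init__(self) -> None:
        for name, eff in {**dict(self.pv), **dict(self.snv_weights)}.items():
            f = eff.freq
            if not (isinstance(f, (int, float)) and 0.0 < f < 1.0) or math.isnan(f):
                raise CoefficientError(
                    f"genetic term {name!r} needs a frequency in (0, 1), got {f!r}"
                )

    @property
    def family_history(self) -> float:
        return float(self.epi["family_history"])

    def to_csv(self, path) -> None:
        """Write as CSV with a header block of centering constants."""
        buf = io.StringIO()
        for k, v in self.centering.items():
            buf.write(f"# center:{k}={v!r}\n")
        buf.write("term,beta,freq\n")
        for term, beta in self.epi.items():
            buf.write(f"{term},{beta!r},\n")
        buf.write(f"prs,{self.prs_coefficient!r},\n")
        for gene, (beta, freq) in self.pv.items():
            buf.write(f"pv_{gene},{beta!r},{freq!r}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "CoefficientSet":
        centering = dict(DEFAULT_CENTERING)
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# center:"):
                k, v = line[len("# center:"):].strip().split("=")
                centering[k] = float(v)
            elif not line.startswith("#"):
                body.append(line)
        df = pd.read_csv(io.StringIO("".join(body)))
        epi: dict[str, float] = {}
        pv: dict[str, GeneticEffect] = {}
        prs_coefficient = 0.0
        for _, row in df.iterrows():
            term, beta = str(row["term"]), float(row["beta"])
            freq = float(row["freq"]) if not pd.isna(row.get("freq")) else None
            if term == "prs":
                prs_coefficient = beta
            elif term.startswith("pv_"):
                if freq is None:
                    raise CoefficientError(f"{term} lacks a carrier frequency")
                pv[term[3:]] = GeneticEffect(beta, freq)
            else:
                epi[term] = beta
        return cls(epi=epi, prs_coefficient=prs_coefficient, pv=pv, centering=centering)


def read_snv_weights(path) -> dict[str, SnvWeight]:
    """Read a PRS weight file: variant_id, effect_allele, weight, effect_allele_freq."""
    df = pd.read_csv(path)
    need = {"variant_id", "weight", "effect_allele_freq"}
    missing = need - set(df.columns)
    if missing:
        raise CoefficientError(f"weight file lacks columns: {sorted(missing)}")
    out: dict[str, SnvWeight] = {}
    for _, row in df.iterrows():
        out[str(row["variant_id"])] = SnvWeight(
            beta=float(row["weight"]),
            freq=float(row["effect_allele_freq"]),
            effect_allele=str(row.get("effect_allele", "")),
        )
    return out


def default_coefficients() -> CoefficientSet:
    """A documented default coefficient set for synthetic work.

    These are plausible placeholder values on the published scale of effect
    sizes for this kind of model — NOT estimates from any study — intended for
    simulation, testing, and demonstration.  PV log-ORs sit near large
    meta-analysis magnitudes for each gene; carrier frequencies are
    population (control) values.
    """
    epi = {
        "age_menarche": -0.05,        # per year, centered at 15
        "first_live_birth": -0.25,
        "additional_live_births": -0.06,  # per child beyond the first
        "breastfeeding_months": -0.003,   # per month
        "benign_breast_disease": 0.55,
        "family_history": 0.47,
        "height_per_10cm": 0.11,
        "bmi_under_18_5": 0.05,
        "bmi_25_29_9": -0.05,
        "bmi_30_plus": -0.10,
        "alcohol": 0.35,
    }
    pv = {
        "BRCA1": GeneticEffect(math.log(7.6), 0.003),
        "BRCA2": GeneticEffect(math.log(5.2), 0.006),
        "PALB2": GeneticEffect(math.log(3.8), 0.002),
        "ATM": GeneticEffect(math.log(2.0), 0.002),
        "CHEK2": GeneticEffect(math.log(2.5), 0.001),
        "BARD1": GeneticEffect(math.log(2.1), 0.002),
        "RAD51C": GeneticEffect(math.log(1.9), 0.001),
        "RAD51D": GeneticEffect(math.log(1.7), 0.001),
        "TP53": GeneticEffect(math.log(3.5), 0.0005),
    }
    return CoefficientSet(epi=epi, prs_coefficient=1.0, pv=pv)


def encode_covariates(
    profile: RiskFactorProfile, centering: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Encode one profile's epidemiologic factors into model terms.

    Parity becomes a linear spline with a knot at one child: ``first_live_birth``
    (0/1) and ``additional_live_births`` (parity - 1, floored at 0).  BMI maps
    to exactly one of three category indicators (<18.5, 25-29.9, >=30) with
    18.5-24.9 as the reference emitting none.  Height is per 10 cm centered at
    160 cm.  Requires a fully imputed profile.
    """
    if centering is None:
        centering = DEFAULT_CENTERING
    if profile.has_missing_epi():
        missing = [f for f, v in profile.epi_values().items() if np.isnan(v)]
        raise NotImputedError(f"profile {profile.id}: missing epidemiologic fields {missing}")
    p = profile.parity
    bmi = profile.bmi
    return {
        "age_menarche": profile.age_menarche - centering.get("age_menarche", 15.0),
        "first_live_birth": 1.0 if p >= 1 else 0.0,
        "additional_live_births": max(p - 1.0, 0.0),
        "breastfeeding_months": profile.breastfeeding_months
        - centering.get("breastfeeding_months", 0.0),
        "benign_breast_disease": profile.benign_breast_disease,
        "family_history": profile.family_history,
        "height_per_10cm": (profile.height_cm - centering.get("height_cm", 160.0)) / 10.0,
        "bmi_under_18_5": 1.0 if bmi < 18.5 else 0.0,
        "bmi_25_29_9": 1.0 if 25.0 <= bmi < 30.0 else 0.0,
        "bmi_30_plus": 1.0 if bmi >= 30.0 else 0.0,
        "alcohol": profile.alcohol,
    }


def encode_cohort(cohort: Cohort, centering: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Vectorized :func:`encode_covariates` over a cohort (same semantics)."""
    if centering is None:
        centering = DEFAULT_CENTERING
    df = cohort.data
    if df[list(EPI_FIELDS)].isna().any().any():
        raise NotImputedError("cohort has missing epidemiologic values; impute first")
    p = df["parity"].to_numpy(float)
    bmi = df["bmi"].to_numpy(float)
    out = pd.DataFrame(
        {
            "age_menarche": df["age_menarche"] - centering.get("age_menarche", 15.0),
            "first_live_birth": (p >= 1).astype(float),
            "additional_live_births": np.maximum(p - 1.0, 0.0),
            "breastfeeding_months": df["breastfeeding_months"]
            - centering.get("breastfeeding_months", 0.0),
            "benign_breast_disease": df["benign_breast_disease"].astype(float),
            "family_history": df["family_history"].astype(float),
            "height_per_10cm": (df["height_cm"] - centering.get("height_cm", 160.0)) / 10.0,
            "bmi_under_18_5": (bmi < 18.5).astype(float),
            "bmi_25_29_9": ((bmi >= 25.0) & (bmi < 30.0)).astype(float),
            "bmi_30_plus": (bmi >= 30.0).astype(float),
            "alcohol": df["alcohol"].astype(float),
        },
        index=df.index,
    )
    return out[list(EPI_TERMS)]


def compute_prs(
    dosages: Mapping[str, float],
    weights: Mapping[str, SnvWeight],
    on_missing: str = "population_mean",
) -> float:
    """Weighted sum of effect-allele dosages: ``sum_k dosage_k * beta_k``.

    Variants in the weight file absent from the dosage map are imputed at the
    population mean dosage ``2 * f_k`` (``on_missing="population_mean"``), or
    rejected (``on_missing="strict"``).
    """
    if on_missing not in ("population_mean", "strict"):
        raise ValueError(f"on_missing must be 'population_mean' or 'strict', got {on_missing!r}")
    absent = [vid for vid in weights if vid not in dosages]
    if absent and on_missing == "strict":
        raise KeyError(f"dosages missing for variants: {absent[:10]}{'...' if len(absent) > 10 else ''}")
    total = 0.0
    for vid, w in weights.items():
        if vid in dosages:
            d = float(dosages[vid])
            if not (0.0 <= d <= 2.0):
                raise ValueError(f"dosage for {vid} outside [0, 2]: {d}")
        else:
            d = 2.0 * w.freq
        total += d * w.beta
    return total


def compute_prs_matrix(
    dosage_df: pd.DataFrame,
    weights: Mapping[str, SnvWeight],
    on_missing: str = "population_mean",
) -> pd.Series:
    """PRS for every row of a wide dosage matrix (columns = variant ids)."""
    scores = np.zeros(len(dosage_df))
    absent = [vid for vid in weights if vid not in dosage_df.columns]
    if absent and on_missing == "strict":
        raise KeyError(f"dosage matrix missing variants: {absent[:10]}")
    for vid, w in weights.items():
        if vid in dosage_df.columns:
            d = dosage_df[vid].to_numpy(float)
            if np.any((d < 0) | (d > 2)):
                raise ValueError(f"dosages for {vid} outside [0, 2]")
        else:
            d = 2.0 * w.freq
        scores = scores + d * w.beta
    return pd.Series(scores, index=dosage_df.index, name="prs")


def combine_hybrid_prs(prs_erpos, prs_erneg, w_erpos: float):
    """Hybrid overall-disease PRS: subtype scores weighted by subtype proportions.

    ``w_erpos`` is the proportion of estrogen-receptor-positive disease.
    Accepts scalars or arrays.
    """
    if not (0.0 <= w_erpos <= 1.0):
        raise ValueError(f"w_erpos must be in [0, 1], got {w_erpos}")
    return w_erpos * np.asarray(prs_erpos) + (1.0 - w_erpos) * np.asarray(prs_erneg)


def polygenic_attenuation(
    coeffs: CoefficientSet,
    variant: ModelVariant = ModelVariant.COMBINED,
    prs_variance: float | None = None,
) -> float:
    """The heritability term ``sum_k f_k (1 - f_k) beta_k^2`` for a variant.

    When the PRS enters as a single score without per-SNV weights, its
    contribution is ``Var(PRS) * beta_PRS^2 / 2`` — the same quantity under
    independent SNVs, since ``Var(PRS) = sum_k 2 f_k (1 - f_k) beta_k^2``.
    """
    att = 0.0
    if variant.includes_prs:
        for vid, w in coeffs.snv_weights.items():
            att += w.freq * (1.0 - w.freq) * w.beta**2
        if prs_variance is not None:
            if prs_variance < 0:
                raise ValueError("prs_variance must be non-negative")
            att += 0.5 * prs_variance * coeffs.prs_coefficient**2
    if variant.includes_pv:
        for gene, eff in coeffs.pv.items():
            att += eff.freq * (1.0 - eff.freq) * eff.beta**2
    return att


def adjust_family_history(
    coeffs: CoefficientSet,
    variant: ModelVariant = ModelVariant.COMBINED,
    prs_variance: float | None = None,
) -> CoefficientSet:
    """Attenuate the family-history log-OR for the genetic terms in a variant.

    Returns a new coefficient set with ``adjusted_family_history`` set to
    ``max(0, beta_FH - sum_k f_k(1-f_k) beta_k^2)`` over the active SNVs and
    PVs; the unadjusted ``beta_FH`` is kept, so the operation is idempotent.
    """
    att = polygenic_attenuation(coeffs, variant, prs_variance)
    adjusted = max(0.0, coeffs.family_history - att)
    return dataclasses.replace(coeffs, adjusted_family_history=adjusted)


def linear_predictor(
    profile: RiskFactorProfile,
    coeffs: CoefficientSet,
    variant: ModelVariant,
) -> float:
    """Log relative risk for one woman under a model variant.

    The family-history term uses the attenuated coefficient whenever genetic
    terms are active (requiring :func:`adjust_family_history` to have run),
    and the unadjusted one in the epidemiologic-factors-only model.
    """
    if variant.includes_genetic and coeffs.adjusted_family_history is None:
        raise CoefficientError(
            f"variant {variant.value} includes genetic terms; "
            "apply adjust_family_history first"
        )
    lp = 0.0
    if variant.includes_epi:
        terms = encode_covariates(profile, coeffs.centering)
        fh_beta = (
            coeffs.adjusted_family_history if variant.includes_genetic else coeffs.family_history
        )
        for term, value in terms.items():
            if term == "family_history":
                lp += value * fh_beta
            elif term in coeffs.epi:
                lp += value * coeffs.epi[term]
            else:
                raise CoefficientError(f"no coefficient for term {term!r}")
    if variant.includes_prs:
        if np.isnan(profile.prs):
            raise NotImputedError(f"profile {profile.id}: PRS required but missing")
        lp += profile.prs * coeffs.prs_coefficient
    if variant.includes_pv:
        for gene, flag in profile.pv_carrier.items():
            if np.isnan(flag):
                raise NotImputedError(f"profile {profile.id}: PV status for {gene} missing")
            if flag:
                if gene not in coeffs.pv:
                    raise CoefficientError(f"no coefficient for carried PV in {gene!r}")
                lp += flag * coeffs.pv[gene].beta
    return lp


def linear_predictors(
    cohort: Cohort, coeffs: CoefficientSet, variant: ModelVariant
) -> np.ndarray:
    """Vectorized :func:`linear_predictor` over a cohort."""
    if variant.includes_genetic and coeffs.adjusted_family_history is None:
        raise CoefficientError(
            f"variant {variant.value} includes genetic terms; apply adjust_family_history first"
        )
    n = len(cohort)
    lp = np.zeros(n)
    if variant.includes_epi:
        enc = encode_cohort(cohort, coeffs.centering)
        fh_beta = (
            coeffs.adjusted_family_history if variant.includes_genetic else coeffs.family_history
        )
        betas = np.array(
            [fh_beta if t == "family_history" else coeffs.epi[t] for t in EPI_TERMS]
        )
        lp += enc.to_numpy(float) @ betas
    if variant.includes_prs:
        prs = cohort.data["prs"].to_numpy(float)
        if np.isnan(prs).any():
            raise NotImputedError("PRS required but missing for some participants")
        lp += prs * coeffs.prs_coefficient
    if variant.includes_pv:
        for gene in PV_GENES:
            flags = cohort.data[f"pv_{gene}"].to_numpy(float)
            if np.isnan(flags).any():
                raise NotImputedError(f"PV status for {gene} missing; impute first")
            if flags.any():
                if gene not in coeffs.pv:
                    raise CoefficientError(f"no coefficient for carried PV in {gene!r}")
                lp += flags * coeffs.pv[gene].beta
    return lp
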