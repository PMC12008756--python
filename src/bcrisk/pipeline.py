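"""End-to-end orchestration: simulate/load, impute, score, project, evaluate.

A run is fully described by a :class:`RunConfig` (loadable from YAML).  For
every requested model variant the pipeline attenuates the family-history
coefficient, computes per-subject linear predictors and lifetime absolute
risks (baseline calibrated against the run's controls), and evaluates
discrimination (unadjusted and age-adjusted AUROC) and threshold summaries;
for the designated reference/comparison pair it builds the reclassification
table and the net reclassification index.  Outputs are deterministic given
the seed: a per-subject risk file, a text and a JSON report, and a manifest
recording seed, config hash, and software version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .absolute_risk import (
    AGE_MAX,
    RateTable,
    calibrate_baseline,
    categorize_risk,
    lifetime_risks,
)
from .cohort import Cohort, impute_missing, read_cohort, write_cohort
from .evaluation import (
    age_adjusted_auroc,
    auroc,
    category_labels,
    net_reclassification_index,
    reclassification_table,
    threshold_summary,
)
from .relative_risk import (
    CoefficientSet,
    ModelVariant,
    adjust_family_history,
    default_coefficients,
    linear_predictors,
)
from .simulate import GeneratorConfig, generate_generative_cohort, generate_marginal_cohort, generate_rate_table

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Exactly one of ``cohort_path`` and ``generator`` must be set.
    """

    seed: int
    out_dir: str = "bcrisk_run"
    cohort_path: str | None = None
    coefficients_path: str | None = None
    rates_path: str | None = None
    generator: GeneratorConfig | None = None
    generator_mode: str = "marginal"  # or "generative"
    variants: list[ModelVariant] = field(
        default_factory=lambda: list(ModelVariant)
    )
    thresholds_summary: list[float] = field(default_factory=lambda: [0.03, 0.05, 0.10])
    thresholds_reclass: list[float] = field(default_factory=lambda: [0.03, 0.10])
    reference_variant: ModelVariant = ModelVariant.EPI_ONLY
    comparison_variant: ModelVariant = ModelVariant.COMBINED
    age_bin_width: float = 10.0
    n_bootstrap: int = 1000
    start_age: str | float = "enrollment"  # or a fixed age

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ValueError("exactly one of cohort_path and generator must be set")
        self.variants = [ModelVariant(v) for v in self.variants]
        self.reference_variant = ModelVariant(self.reference_variant)
        self.comparison_variant = ModelVariant(self.comparison_variant)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        if out_dir is not None:
            raw["out_dir"] = out_dir
        gen = raw.get("generator")
        if gen is not None:
            gen.setdefault("seed", raw.get("seed"))
            raw["generator"] = GeneratorConfig(**gen)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variants"] = [v.value for v in self.variants]
        d["reference_variant"] = self.reference_variant.value
        d["comparison_variant"] = self.comparison_variant.value
        return d


@dataclass
class PipelineResult:
    cohort: Cohort
    risks: pd.DataFrame
    report: dict
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


@_stage("input")
def _load_inputs(config: RunConfig):
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        if config.generator_mode == "generative":
            cohort = generate_generative_cohort(gen)
        else:
            cohort = generate_marginal_cohort(gen)
    if config.rates_path is not None:
        rates = RateTable.from_csv(config.rates_path)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        rates = generate_rate_table(gen)
    if config.coefficients_path is not None:
        coeffs = CoefficientSet.from_csv(config.coefficients_path)
    else:
        coeffs = default_coefficients()
    return cohort, rates, coeffs


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Returns the imputed cohort, the per-subject risk table (one row per
    subject per variant), the evaluation report as a plain dict, and the run
    manifest.  Writes nothing; see :func:`write_outputs`.
    """
    cohort, rates, coeffs = _load_inputs(config)

    if not cohort.imputed:
        cohort = _stage("impute")(impute_missing)(cohort)

    statuses = cohort.statuses()
    ages = cohort.ages()
    controls = cohort.controls()
    prs_col = cohort.data["prs"].to_numpy(float)
    ctrl_prs = prs_col[statuses == 0]
    prs_var = float(np.var(ctrl_prs[~np.isnan(ctrl_prs)])) if (~np.isnan(ctrl_prs)).any() else None

    if isinstance(config.start_age, (int, float)):
        start_ages = np.full(len(cohort), float(config.start_age))
    else:
        start_ages = ages

    per_year = rates.expand()
    labels4 = category_labels(config.thresholds_reclass)
    risk_rows = []
    report: dict = {"variants": {}, "n_cases": cohort.n_cases, "n_controls": cohort.n_controls}
    cats_by_variant: dict[ModelVariant, np.ndarray] = {}

    for variant in config.variants:
        @_stage(f"score/{variant.value}")
        def _score(variant=variant):
            use_prs_var = prs_var if (variant.includes_prs and not coeffs.snv_weights) else None
            adj = adjust_family_history(coeffs, variant, prs_variance=use_prs_var)
            lps = linear_predictors(cohort, adj, variant)
            baseline = calibrate_baseline(rates, controls, adj, variant)
            return lps, baseline

        lps, baseline = _score()

        @_stage(f"project/{variant.value}")
        def _project(lps=lps, baseline=baseline):
            risks = lifetime_risks(lps, start_ages, baseline, per_year.mortality)
            cats = categorize_risk(risks, config.thresholds_reclass)
            return risks, cats

        risks, cats = _project()
        cats_by_variant[variant] = cats

        @_stage(f"evaluate/{variant.value}")
        def _evaluate(risks=risks):
            roc = auroc(risks[statuses == 1], risks[statuses == 0])
            adj_roc = age_adjusted_auroc(
                risks,
                ages,
                statuses,
                age_bin_width=config.age_bin_width,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            summary = threshold_summary(risks, statuses, config.thresholds_summary)
            return roc, adj_roc, summary

        roc, adj_roc, summary = _evaluate()

        for i in range(len(cohort)):
            risk_rows.append(
                {
                    "id": cohort.data["id"].iloc[i],
                    "variant": variant.value,
                    "lp": lps[i],
                    "lifetime_risk": risks[i],
                    "lifetime_risk_pct": 100.0 * risks[i],
                    "category": labels4[cats[i]],
                }
            )
        report["variants"][variant.value] = {
            "auroc": roc.auroc,
            "auroc_ci": [roc.ci_low, roc.ci_high],
            "age_adjusted_auroc": adj_roc.auroc,
            "age_adjusted_auroc_ci": [adj_roc.ci_low, adj_roc.ci_high],
            "mean_lifetime_risk_cases": float(np.mean(risks[statuses == 1])),
            "mean_lifetime_risk_controls": float(np.mean(risks[statuses == 0])),
            "threshold_summary": summary.to_dict(orient="records"),
        }

    ref, cmp_ = config.reference_variant, config.comparison_variant
    if ref in cats_by_variant and cmp_ in cats_by_variant and ref != cmp_:
        @_stage("reclassify")
        def _reclass():
            table = reclassification_table(
                cats_by_variant[ref], cats_by_variant[cmp_], statuses, labels4
            )
            return table, net_reclassification_index(table)

        table, nri = _reclass()
        report["reclassification"] = {
            "reference": ref.value,
            "comparison": cmp_.value,
            "labels": labels4,
            "counts": {g: table.counts[g].tolist() for g in ("control", "case")},
            "row_percentages": {
                g: table.row_percentages(g).tolist() for g in ("control", "case")
            },
            "nri": nri,
        }

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "version": __version__,
        "n_subjects": len(cohort),
    }
    return PipelineResult(
        cohort=cohort,
        risks=pd.DataFrame(risk_rows),
        report=report,
        manifest=manifest,
    )


def format_report(report: dict) -> str:
    """Human-readable text rendering of the evaluation report."""
    lines = [
        f"Subjects: {report['n_cases']} cases / {report['n_controls']} controls",
        "",
        f"{'Model':<14}{'AUROC (95% CI)':<28}{'Age-adjusted AUROC (95% CI)':<30}",
    ]
    for name, v in report["variants"].items():
        ci = v["auroc_ci"]
        aci = v["age_adjusted_auroc_ci"]
        lines.append(
            f"{name:<14}"
            f"{v['auroc']:.3f} ({ci[0]:.3f}-{ci[1]:.3f})      "
            f"{v['age_adjusted_auroc']:.3f} ({aci[0]:.3f}-{aci[1]:.3f})"
        )
    lines.append("")
    for name, v in report["variants"].items():
        lines.append(f"Mean lifetime risk [{name}]: "
                     f"controls {100 * v['mean_lifetime_risk_controls']:.1f}%, "
                     f"cases {100 * v['mean_lifetime_risk_cases']:.1f}%")
    rec = report.get("reclassification")
    if rec:
        lines += ["", f"Reclassification ({rec['reference']} -> {rec['comparison']}):"]
        for group in ("control", "case"):
            lines.append(f"  {group}s (rows = {rec['reference']} category):")
            for lab, row in zip(rec["labels"], rec["counts"][group]):
                lines.append(f"    {lab:<8}" + "".join(f"{c:>8}" for c in row))
        lines.append(f"  Net reclassification index: {rec['nri']:.3f}")
    return "\n".join(lines) + "\n"


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write risks.csv, report.txt, report.json, manifest.json, cohort.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.risks.to_csv(out / "risks.csv", index=False, float_format="%.10g")
    write_cohort(result.cohort, out / "cohort.csv")
    (out / "report.txt").write_text(format_report(result.report))
    (out / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n"
    )
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
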