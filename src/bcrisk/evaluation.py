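"""Discrimination and reclassification analysis.

AUROC is the probability that a randomly chosen case scores above a randomly
chosen control (Mann-Whitney estimator, ties counting one half), with a
DeLong variance for the confidence interval.  Because cases and controls can
have very different age distributions, an age-adjusted AUROC is computed from
nonparametric placement values within age strata: for each case, the
proportion of same-stratum controls scoring above her; one minus the mean
placement value over all cases is the adjusted AUROC, with a seeded
stratified bootstrap for its confidence interval.

Reclassification between two models is summarized per status group as a
K x K cross-tabulation of risk categories, and the categorical net
reclassification index (NRI) is

    NRI = (up_case - down_case)/n_case - (up_ctrl - down_ctrl)/n_ctrl

where "up" counts members assigned a higher category by the new model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

_Z975 = 1.959963984540054


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention used for reported percentages).

    numpy's default rounds half to even; reported tables round 0.05 up.
    """
    x = np.asarray(x, float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ROCResult:
    auroc: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_controls: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def auroc(case_scores, control_scores) -> ROCResult:
    """Mann-Whitney AUROC with a DeLong confidence interval.

    Equals the mean over all case-control pairs of 1 (case higher),
    0.5 (tied), or 0 (control higher).
    """
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both case and control score lists must be non-empty")
    combined = np.concatenate([cases, controls])
    tz = _midrank(combined)
    tx = _midrank(cases)
    ty = _midrank(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = _Z975 * np.sqrt(max(var, 0.0))
    return ROCResult(
        auroc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        method="unadjusted",
        n_cases=m,
        n_controls=n,
    )


def _placement_values(
    scores: np.ndarray, ages: np.ndarray, statuses: np.ndarray, age_bin_width: float
):
    """Per-case placement values against same-age-stratum controls.

    Returns (placements, case_index, strata) over usable strata (those with at
    least one case and one control); unusable strata are dropped with a logged
    warning.
    """
    bins = np.floor(ages / age_bin_width).astype(int)
    placements: list[np.ndarray] = []
    case_idx: list[np.ndarray] = []
    usable: list[int] = []
    dropped = 0
    for b in np.unique(bins):
        in_bin = bins == b
        c_mask = in_bin & (statuses == 1)
        k_mask = in_bin & (statuses == 0)
        if not c_mask.any() or not k_mask.any():
            dropped += int(in_bin.sum())
            continue
        cs = scores[c_mask]
        ks = np.sort(scores[k_mask])
        nk = len(ks)
        # proportion of controls strictly above the case, ties counting half
        above = nk - np.searchsorted(ks, cs, side="right")
        ties = np.searchsorted(ks, cs, side="right") - np.searchsorted(ks, cs, side="left")
        placements.append((above + 0.5 * ties) / nk)
        case_idx.append(np.nonzero(c_mask)[0])
        usable.append(b)
    if not usable:
        raise ValueError("no age stratum contains both cases and controls")
    if dropped:
        log.warning("age-adjusted AUROC: %d participants in unusable strata dropped", dropped)
    return placements, case_idx, usable, bins


def age_adjusted_auroc(
    scores,
    ages,
    statuses,
    age_bin_width: float = 10.0,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> ROCResult:
    """Covariate-adjusted AUROC via stratified placement values.

    The confidence interval comes from a stratified bootstrap (cases and
    controls resampled independently within each usable stratum); ``seed`` is
    required so results are reproducible.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap confidence interval")
    scores = np.asarray(scores, float)
    ages = np.asarray(ages, float)
    statuses = np.asarray(statuses, int)
    if not (len(scores) == len(ages) == len(statuses)):
        raise ValueError("scores, ages and statuses must have equal length")
    placements, case_idx, usable, bins = _placement_values(
        scores, ages, statuses, age_bin_width
    )
    all_pv = np.concatenate(placements)
    auc = 1.0 - float(np.mean(all_pv))
    n_cases = len(all_pv)
    n_controls = int(
        sum(((bins == b) & (statuses == 0)).sum() for b in usable)
    )

    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    strat = []
    for b in usable:
        in_bin = bins == b
        strat.append(
            (np.sort(scores[in_bin & (statuses == 1)]), np.sort(scores[in_bin & (statuses == 0)]))
        )
    for r in range(n_bootstrap):
        pv_sum = 0.0
        m_tot = 0
        for cs, ks in strat:
            bc = rng.choice(cs, size=len(cs), replace=True)
            bk = np.sort(rng.choice(ks, size=len(ks), replace=True))
            nk = len(bk)
            above = nk - np.searchsorted(bk, bc, side="right")
            ties = np.searchsorted(bk, bc, side="right") - np.searchsorted(bk, bc, side="left")
            pv_sum += float(np.sum((above + 0.5 * ties) / nk))
            m_tot += len(bc)
        boot[r] = 1.0 - pv_sum / m_tot
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(
        auroc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        method="age_adjusted",
        n_cases=n_cases,
        n_controls=n_controls,
    )


def category_labels(thresholds: Sequence[float]) -> list[str]:
    """Human-readable band labels from ascending probability thresholds."""
    pct = [f"{100 * t:g}%" for t in thresholds]
    labels = [f"<{pct[0]}"]
    labels += [f"{pct[i]}-{pct[i + 1]}" for i in range(len(pct) - 1)]
    labels.append(f">={pct[-1]}")
    return labels


def threshold_summary(risks, statuses, thresholds) -> pd.DataFrame:
    """Counts and percentages per risk category, separately for cases and controls.

    Percentages are 100 * count / status-group total, reported to one decimal
    (half away from zero).
    """
    from .absolute_risk import categorize_risk

    risks = np.asarray(risks, float)
    statuses = np.asarray(statuses, int)
    if len(risks) != len(statuses):
        raise ValueError("risks and statuses must have equal length")
    cats = categorize_risk(risks, thresholds)
    labels = category_labels(thresholds)
    rows = []
    for s, name in ((0, "control"), (1, "case")):
        grp = cats[statuses == s]
        total = len(grp)
        for j, lab in enumerate(labels):
            count = int((grp == j).sum())
            pct = round_half_away(100.0 * count / total, 1) if total else np.nan
            rows.append({"status": name, "category": lab, "count": count, "percent": pct})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReclassificationTable:
    """Per-status cross-tabulation of risk categories under two models.

    ``counts[group][i, j]`` is the number of members of that group placed in
    old-model category ``i`` and new-model category ``j``.
    """

    counts: Mapping[str, np.ndarray]
    labels: Sequence[str]

    def row_percentages(self, group: str) -> np.ndarray:
        c = self.counts[group].astype(float)
        totals = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * c / np.where(totals > 0, totals, 1.0), 0.0)
        return round_half_away(pct, 1)

    def to_frame(self, group: str) -> pd.DataFrame:
        df = pd.DataFrame(self.counts[group], index=self.labels, columns=self.labels)
        df.index.name = "old_category"
        df.columns.name = "new_category"
        return df


def reclassification_table(old_cats, new_cats, statuses, labels) -> ReclassificationTable:
    """Cross-tabulate old vs new risk categories, stratified by status."""
    old_cats = np.asarray(old_cats, int)
    new_cats = np.asarray(new_cats, int)
    statuses = np.asarray(statuses, int)
    if not (len(old_cats) == len(new_cats) == len(statuses)):
        raise ValueError("inputs must have equal length")
    k = len(labels)
    if old_cats.size and (old_cats.max() >= k or new_cats.max() >= k or old_cats.min() < 0):
        raise ValueError("category index outside label range")
    counts = {}
    for s, name in ((0, "control"), (1, "case")):
        mask = statuses == s
        mat = np.zeros((k, k), dtype=int)
        np.add.at(mat, (old_cats[mask], new_cats[mask]), 1)
        counts[name] = mat
    return ReclassificationTable(counts=counts, labels=list(labels))


def net_reclassification_index(table: ReclassificationTable) -> float:
    """Categorical NRI of the new model versus the old.

    Net proportion of cases moved up minus net proportion of controls moved
    up; positive values favor the new model.
    """
    nets = {}
    for group in ("case", "control"):
        mat = table.counts[group]
        n = int(mat.sum())
        if n == 0:
            raise ValueError(f"status group {group!r} has no members")
        up = int(np.triu(mat, k=1).sum())
        down = int(np.tril(mat, k=-1).sum())
        nets[group] = (up - down) / n
    return nets["case"] - nets["control"]
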