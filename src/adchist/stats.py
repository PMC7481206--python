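"""Cohort association statistics.

The association layer between the imaging phenotype and molecular or
clinical outcomes: Pearson correlation of expression against ADC_L,
two-sample t-tests between phenotype groups, within-tumor z-score
normalization for intratumoral biopsy samples, median-split
stratification of expression, and Kaplan–Meier survival with the
two-group log-rank test.

Conventions: sample SD uses the n−1 denominator throughout; the
unpaired t-test pools variances (classic Student's; Welch available);
median-split ties go to "low" so "high" is strictly above the median,
mirroring the strict ADC_L > threshold rule; the survival median is the
first time the Kaplan–Meier step falls to ≤ 0.5 and is None when the
curve never does. No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .exceptions import ValidationError
from .mixture import DEFAULT_THRESHOLD

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_two_sided: float
    n: int


@dataclass
class SurvivalResult:
    median_high: float | None
    median_low: float | None
    logrank_chi2: float
    p: float
    n_high: int
    n_low: int


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("undefined correlation: constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p_two_sided=float(res.pvalue), n=int(x.size))


def group_ttest(a, b, paired: bool = False, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test: pooled-variance Student's when unpaired
    (Welch with ``equal_var=False``), t on differences when paired.
    Returns (t statistic, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape or a.size < 2:
            raise ValidationError("paired test needs equal-length vectors of length >= 2")
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            raise ValidationError("zero variance in paired differences")
        res = sps.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            raise ValidationError("each group needs >= 2 observations")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def zscore_within(values, grouping) -> np.ndarray:
    """Z-score each group to mean 0, sample SD 1 (n−1 denominator).

    Singleton or constant groups raise an error naming the group.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    if values.shape != grouping.shape:
        raise ValidationError("values and grouping must align")
    out = np.empty_like(values)
    for g in pd.unique(grouping):
        sel = grouping == g
        v = values[sel]
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"group {g!r} has zero variance")
        out[sel] = (v - v.mean()) / sd
    return out


def median_split(values) -> list[str]:
    """Label each value "high" iff it strictly exceeds the median, else "low"."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values")
    med = float(np.median(values))
    labels = ["high" if v > med else "low" for v in values]
    if all(lab == "low" for lab in labels):
        log.warning("median split degenerate: no value exceeds the median")
    return labels


def _km_median(times, events) -> float | None:
    kmf = KaplanMeierFitter().fit(times, events)
    med = kmf.median_survival_time_
    return None if not math.isfinite(med) else float(med)


def km_logrank(
    table: pd.DataFrame,
    group_field: str,
    time_field: str = "surv_months",
    event_field: str = "event",
    high_label: str = "high",
) -> SurvivalResult:
    """Two-group Kaplan–Meier with the log-rank test (1 df chi-square).

    Group medians are the first times the product-limit estimate drops
    to ≤ 0.5, None when it never does.
    """
    groups = table[group_field].astype(str)
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, found {uniq}")
    if int(table[event_field].sum()) < 1:
        raise ValidationError("need at least one event overall")
    hi = groups == high_label if high_label in uniq else groups == uniq[0]
    t_hi, e_hi = table.loc[hi, time_field], table.loc[hi, event_field]
    t_lo, e_lo = table.loc[~hi, time_field], table.loc[~hi, event_field]
    res = logrank_test(t_hi, t_lo, event_observed_A=e_hi, event_observed_B=e_lo)
    return SurvivalResult(
        median_high=_km_median(t_hi, e_hi),
        median_low=_km_median(t_lo, e_lo),
        logrank_chi2=float(res.test_statistic),
        p=float(res.p_value),
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
    )


def run_association_suite(
    table: pd.DataFrame,
    adcl_threshold: float = DEFAULT_THRESHOLD,
    adcl_field: str = "adcl_true",
    expression_field: str = "expression",
    out_dir=None,
) -> dict:
    """Run the full association layer on a cohort table.

    Components: Pearson correlation of expression vs ADC_L; unpaired
    t-test of expression between high/low ADC_L phenotypes; when a
    ``tumor_id`` column is present, the intratumoral analysis on
    within-tumor z-scores (correlation plus paired t-test of per-tumor
    high-site vs low-site means); Kaplan–Meier/log-rank by phenotype
    and by median-split expression when survival columns are present.
    Returns a JSON-serializable report; writes plots and the report to
    ``out_dir`` when given.
    """
    adcl = table[adcl_field].to_numpy(dtype=float)
    expr = table[expression_field].to_numpy(dtype=float)
    phenotype = np.where(adcl > adcl_threshold, "high", "low")

    report: dict = {"n_subjects": int(len(table)), "adcl_threshold": adcl_threshold}

    corr = pearson(adcl, expr)
    report["expression_vs_adcl"] = vars(corr)

    hi, lo = expr[phenotype == "high"], expr[phenotype == "low"]
    if hi.size >= 2 and lo.size >= 2:
        t, p = group_ttest(hi, lo)
        report["expression_by_phenotype"] = {
            "mean_high": float(hi.mean()), "mean_low": float(lo.mean()),
            "t": t, "p": p, "n_high": int(hi.size), "n_low": int(lo.size),
        }

    if "tumor_id" in table.columns:
        report["intratumoral"] = _intratumoral(table, adcl_field, expression_field, adcl_threshold)

    if "surv_months" in table.columns and "event" in table.columns:
        tab = table.assign(phenotype=phenotype)
        km_pheno = km_logrank(tab, "phenotype")
        report["survival_by_phenotype"] = vars(km_pheno)
        tab = tab.assign(expr_group=median_split(expr))
        km_expr = km_logrank(tab, "expr_group")
        report["survival_by_median_expression"] = vars(km_expr)

    if out_dir is not None:
        _write_report(report, table, adcl, expr, phenotype, out_dir)
    return report


def _intratumoral(table, adcl_field, expression_field, threshold) -> dict:
    """Within-tumor analysis of multi-site biopsy samples.

    Site values are z-scored within each tumor before pooling; the
    paired contrast compares each tumor's mean expression at
    high-index sites against low-index sites (within-tumor split at
    the tumor's own median ADC_L).
    """
    z_adcl = zscore_within(table[adcl_field].to_numpy(float), table["tumor_id"].to_numpy())
    z_expr = zscore_within(table[expression_field].to_numpy(float), table["tumor_id"].to_numpy())
    out: dict = {"zscore_correlation": vars(pearson(z_adcl, z_expr))}

    hi_means, lo_means = [], []
    for _, grp in table.assign(z_adcl=z_adcl, z_expr=z_expr).groupby("tumor_id"):
        labels = np.asarray(median_split(grp["z_adcl"]))
        if (labels == "high").any() and (labels == "low").any():
            hi_means.append(grp["z_expr"].to_numpy()[labels == "high"].mean())
            lo_means.append(grp["z_expr"].to_numpy()[labels == "low"].mean())
    if len(hi_means) >= 2:
        t, p = group_ttest(np.array(hi_means), np.array(lo_means), paired=True)
        out["paired_high_vs_low_sites"] = {"t": t, "p": p, "n_tumors": len(hi_means)}
    return out


def _write_report(report, table, adcl, expr, phenotype, out_dir) -> None:
    import json
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "association_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(adcl, expr, s=12, c=np.where(phenotype == "high", "tab:red", "tab:blue"))
    ax.set_xlabel("ADC_L (µm²/ms)")
    ax.set_ylabel("expression")
    r2 = report["expression_vs_adcl"]["r_squared"]
    ax.set_title(f"R² = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(out / "expression_vs_adcl.png", dpi=120)
    plt.close(fig)

    if "survival_by_phenotype" in report:
        fig, ax = plt.subplots(figsize=(4, 4))
        for label, color in (("high", "tab:red"), ("low", "tab:blue")):
            sel = phenotype == label
            if sel.sum():
                KaplanMeierFitter().fit(
                    table.loc[sel, "surv_months"], table.loc[sel, "event"], label=f"{label} ADC_L"
                ).plot_survival_function(ax=ax, color=color)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        fig.tight_layout()
        fig.savefig(out / "km_by_phenotype.png", dpi=120)
        plt.close(fig)
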