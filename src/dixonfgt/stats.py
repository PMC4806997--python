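"""Repeatability and cross-sequence comparison statistics.

Bland-Altman agreement between repeat measurements is summarized by the
mean difference, the sample standard deviation of the paired
differences sigma_d, the limits of agreement (mean +/- 1.96 sigma_d),
the coefficient of repeatability CoR = 1.96 sigma_d, and the
within-subject coefficient of variation CoV = sigma_d / (sqrt(2) xbar)
* 100%, where xbar is the mean of the per-pair means. The sqrt(2)
denominator converts the SD of a difference of two equally noisy
measurements into the SD of a single measurement; it also makes a CoV
and a CoR expressed in the same percent units numerically consistent
(see :func:`implied_cor_from_cov`).

Cross-sequence comparisons use the Pearson product-moment correlation,
the paired Student's t-test and one-way repeated-measures ANOVA with
the dataset as the within-subject factor, with no multiple-comparison
correction. Left and right breasts are treated as independent
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "AgreementStats",
    "bland_altman",
    "bland_altman_plot",
    "pearson_r",
    "paired_t",
    "rm_anova",
    "cohort_compare",
    "implied_cor_from_cov",
]


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired test-retest measurements."""

    mean_difference: float
    sd_differences: float
    limits_of_agreement: tuple[float, float]
    coefficient_of_repeatability: float
    coefficient_of_variation_pct: float
    n: int


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of paired measurements")
    if not np.all(np.isfinite(arr)):
        raise ValueError("paired measurements must be finite")
    return arr


def bland_altman(pairs) -> AgreementStats:
    """Agreement statistics of an ``(n, 2)`` array of paired measures.

    sigma_d uses the n-1 sample formula; CoR = 1.96 sigma_d;
    CoV = sigma_d / (sqrt(2) xbar) * 100 with xbar the mean of the
    per-pair means.
    """
    arr = _as_pairs(pairs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    xbar = float(arr.mean(axis=1).mean())
    if xbar == 0:
        raise ZeroDivisionError("mean of pair means is zero; CoV undefined")
    cor = 1.96 * sd_d
    cov = sd_d / (np.sqrt(2.0) * xbar) * 100.0
    return AgreementStats(
        mean_difference=mean_d,
        sd_differences=sd_d,
        limits_of_agreement=(mean_d - cor, mean_d + cor),
        coefficient_of_repeatability=cor,
        coefficient_of_variation_pct=float(cov),
        n=n,
    )


def implied_cor_from_cov(cov_pct: float, mean_value: float) -> float:
    """Coefficient of repeatability implied by a CoV and a cohort mean:
    ``1.96 * (cov/100) * sqrt(2) * mean`` — the inverse of the CoV
    definition used in :func:`bland_altman`."""
    return 1.96 * (cov_pct / 100.0) * np.sqrt(2.0) * mean_value


def bland_altman_plot(pairs, ax=None, label: str = ""):
    """Mean-vs-difference plot with mean-difference and limits-of-agreement
    lines. Returns the matplotlib axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = _as_pairs(pairs)
    st = bland_altman(arr)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    ax.scatter(means, diffs, s=18, color="tab:blue")
    ax.axhline(st.mean_difference, ls="--", color="k")
    for loa in st.limits_of_agreement:
        ax.axhline(loa, ls="--", color="gray")
    ax.set_xlabel(f"mean of pair {label}".strip())
    ax.set_ylabel(f"difference {label}".strip())
    return ax


def pearson_r(xs, ys) -> float:
    """Pearson product-moment correlation coefficient."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1D arrays of equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 points")
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(sps.pearsonr(xs, ys).statistic)


def paired_t(pairs) -> tuple[float, float]:
    """Two-sided paired Student's t-test. Returns ``(t, p)``."""
    arr = _as_pairs(pairs)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    if d.std(ddof=1) == 0:
        raise ValueError("all paired differences equal; t undefined")
    res = sps.ttest_rel(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)


def rm_anova(matrix) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on a subjects-by-conditions matrix
    (rows: breasts, columns: datasets; within-subject factor = dataset).
    Returns ``(F, p)``."""
    arr = np.asarray(matrix, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 datasets")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains missing or non-finite cells")
    n_sub, n_cond = arr.shape
    if np.allclose(arr, arr[:, :1]):
        return 0.0, 1.0
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_sub), n_cond),
            "dataset": np.tile(np.arange(n_cond), n_sub),
            "value": arr.ravel(),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["dataset"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


# ---------------------------------------------------------------------------
# Cohort-level comparison report
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject", "laterality", "dataset", "fgt_cm3", "total_cm3", "pct_fgt")


def cohort_compare(
    table: pd.DataFrame,
    reference_dataset: str = "hr-gre-pd",
    value: str = "pct_fgt",
) -> dict:
    """Cohort summary and pairwise comparisons of per-breast results.

    ``table`` holds one row per breast per dataset (columns
    ``subject, laterality, dataset, fgt_cm3, total_cm3, pct_fgt``; extra
    columns are carried through). Produces per-dataset mean +/- sd and
    range, pairwise-vs-reference mean differences with paired t and
    Pearson r, a left-vs-right paired t within the reference dataset,
    and a repeated-measures ANOVA of ``value`` across datasets. No
    multiple-comparison correction is applied.
    """
    missing = [c for c in REQUIRED_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns {missing}")
    if value not in table.columns:
        raise ValueError(f"no column {value!r} in results table")
    datasets = list(dict.fromkeys(table["dataset"]))
    if reference_dataset not in datasets:
        raise ValueError(f"reference dataset {reference_dataset!r} not in table")

    wide = table.pivot_table(
        index=["subject", "laterality"], columns="dataset", values=value
    )

    summary = {}
    for ds in datasets:
        sub = table[table["dataset"] == ds]
        entry = {}
        for col in ("fgt_cm3", "total_cm3", "pct_fgt"):
            if col in sub.columns:
                entry[f"{col}_mean"] = float(sub[col].mean())
                entry[f"{col}_sd"] = float(sub[col].std(ddof=1))
        entry[f"{value}_range"] = float(sub[value].max() - sub[value].min())
        entry["n"] = int(len(sub))
        summary[ds] = entry

    comparisons = {}
    ref = wide[reference_dataset]
    for ds in datasets:
        if ds == reference_dataset:
            continue
        both = wide[[ds, reference_dataset]].dropna()
        pairs = both.to_numpy()
        diffs = both[ds] - both[reference_dataset]
        if diffs.std(ddof=1) > 0:
            t, p = paired_t(pairs)
        else:  # identical measurements; t undefined
            t, p = None, None
        r = (pearson_r(both[ds], both[reference_dataset])
             if len(both) >= 3 and both[ds].std() > 0
             and both[reference_dataset].std() > 0 else None)
        comparisons[f"{ds}_vs_{reference_dataset}"] = {
            "mean_difference": float(diffs.mean()),
            "t": t,
            "p": p,
            "pearson_r": r,
            "n": int(len(both)),
        }

    report = {"summary": summary, "comparisons": comparisons, "value": value}

    ref_rows = table[table["dataset"] == reference_dataset]
    lr = ref_rows.pivot_table(index="subject", columns="laterality", values=value)
    if {"L", "R"}.issubset(lr.columns):
        both = lr[["L", "R"]].dropna()
        if len(both) >= 2 and (both["L"] - both["R"]).std(ddof=1) > 0:
            t, p = paired_t(both.to_numpy())
            report["left_vs_right"] = {"t": t, "p": p, "n": int(len(both))}

    complete = wide.dropna()
    if complete.shape[0] >= 2 and complete.shape[1] >= 2:
        F, p = rm_anova(complete.to_numpy())
        report["anova"] = {"F": F, "p": p, "n_breasts": int(complete.shape[0]),
                           "n_datasets": int(complete.shape[1])}
    return report
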