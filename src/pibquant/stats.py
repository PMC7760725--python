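"""Regional summaries, group comparisons, agreement and ROC analysis.

Implements the statistical layer over the parametric images: regional
mean tables, Welch between-group and paired within-subject tests,
Pearson regression between metrics, Bland–Altman agreement (optionally
after mapping one metric onto the other's scale through the fitted
regression line), a Pitman–Morgan test for comparing the variances of
two *paired* difference sets, and empirical ROC analysis with a
Youden-J optimal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .images import MetricImage
from .phantom import CORTICAL_REGIONS

__all__ = [
    "RegionalTable",
    "AgreementResult",
    "RocResult",
    "GroupTestResult",
    "regional_means",
    "cortical_max_and_pcc",
    "pearson_regression",
    "bland_altman",
    "pitman_morgan",
    "group_test",
    "paired_vs_pcc",
    "roc_analysis",
]

#: Tidy per-(subject, region, metric) value table; plain DataFrame with
#: columns subject, group, region, metric, value.
RegionalTable = pd.DataFrame


def regional_means(
    metric: MetricImage,
    labels: np.ndarray,
    region_map: dict[str, int],
    subject: str = "sub-000",
    group: str = "CTL",
) -> RegionalTable:
    """Arithmetic mean of valid voxels per named region.

    Regions with no valid voxels are omitted from the table.
    """
    labels = np.asarray(labels)
    if labels.shape != metric.data.shape:
        raise ValueError("label volume shape does not match metric image")
    rows = []
    for name, label in region_map.items():
        mask = (labels == label) & metric.valid
        if not mask.any():
            continue
        rows.append({
            "subject": subject, "group": group, "region": name,
            "metric": metric.kind, "value": float(metric.data[mask].mean()),
        })
    return pd.DataFrame(rows)


def cortical_max_and_pcc(table: RegionalTable, subject: str, metric: str) -> tuple[float, float]:
    """Highest lobar mean (over the 8 frontal/temporal/parietal/occipital
    regions) and the posterior-cingulate value, for one subject+metric."""
    sub = table[(table["subject"] == subject) & (table["metric"] == metric)]
    lobar = sub[sub["region"].isin(CORTICAL_REGIONS)]
    pcc = sub[sub["region"] == "pcc"]
    if len(lobar) != len(CORTICAL_REGIONS) or pcc.empty:
        missing = set(CORTICAL_REGIONS) - set(lobar["region"]) | ({"pcc"} if pcc.empty else set())
        raise ValueError(f"missing regions for {subject}/{metric}: {sorted(missing)}")
    return float(lobar["value"].max()), float(pcc["value"].iloc[0])


def pearson_regression(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, r_squared, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


@dataclass(frozen=True)
class AgreementResult:
    """Regression + Bland–Altman agreement between two paired metrics."""

    slope: float
    intercept: float
    r_squared: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray = field(repr=False)
    variance_p: float | None = None  # filled by pitman_morgan comparisons


def bland_altman(x, y, regression_correct: bool = True) -> AgreementResult:
    """Bland–Altman agreement of y against x.

    With ``regression_correct`` (the default) y is first mapped onto x's
    scale through the inverse of the fitted y-on-x line, removing the
    systematic linear offset so the limits of agreement reflect residual
    scatter only.  Differences are (corrected y) - x; limits are
    mean +/- 1.96 SD.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    slope, intercept, r2, _ = pearson_regression(x, y)
    if regression_correct:
        if slope == 0:
            raise ValueError("cannot invert a flat regression line")
        y_corr = (y - intercept) / slope
    else:
        y_corr = y
    d = y_corr - x
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return AgreementResult(
        slope=slope, intercept=intercept, r_squared=r2,
        mean_diff=mean_d, sd_diff=sd_d,
        loa_low=mean_d - 1.96 * sd_d, loa_high=mean_d + 1.96 * sd_d,
        differences=d,
    )


def pitman_morgan(d1, d2) -> tuple[float, float]:
    """Pitman–Morgan test for equal variances of two paired samples.

    Tests corr(d1 + d2, d1 - d2) = 0, which holds iff var(d1) = var(d2)
    for paired observations.  Returns (t statistic, two-sided p); the
    sign of t follows var(d1) - var(d2).
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.size != d2.size or d1.size < 3:
        raise ValueError("need paired samples with n >= 3")
    n = d1.size
    r = np.corrcoef(d1 + d2, d1 - d2)[0, 1]
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(t), float(p)


@dataclass(frozen=True)
class GroupTestResult:
    ctl_mean: float
    ctl_sd: float
    ead_mean: float
    ead_sd: float
    p_value: float


def group_test(table: RegionalTable, region: str, metric: str) -> GroupTestResult:
    """Welch two-sample comparison of one region/metric between groups."""
    sub = table[(table["region"] == region) & (table["metric"] == metric)]
    ctl = sub[sub["group"] == "CTL"]["value"].to_numpy()
    ead = sub[sub["group"] == "eAD"]["value"].to_numpy()
    if ctl.size < 2 or ead.size < 2:
        raise ValueError(f"need >= 2 subjects per group for {region}/{metric}")
    if np.allclose(ctl.mean(), ead.mean()) and np.allclose(ctl.std(), ead.std()) and np.array_equal(
        np.sort(ctl), np.sort(ead)
    ):
        p = 1.0
    else:
        p = float(sps.ttest_ind(ctl, ead, equal_var=False).pvalue)
    return GroupTestResult(
        float(ctl.mean()), float(ctl.std(ddof=1)),
        float(ead.mean()), float(ead.std(ddof=1)), p,
    )


def paired_vs_pcc(table: RegionalTable, region: str, metric: str, group: str) -> float:
    """Paired within-subject comparison of a region against the PCC."""
    sub = table[(table["metric"] == metric) & (table["group"] == group)]
    merged = sub[sub["region"] == region].merge(
        sub[sub["region"] == "pcc"], on="subject", suffixes=("", "_pcc")
    )
    if len(merged) < 2:
        raise ValueError(f"need >= 2 paired subjects for {region} vs pcc")
    a = merged["value"].to_numpy()
    b = merged["value_pcc"].to_numpy()
    if np.allclose(a, b):
        return 1.0
    return float(sps.ttest_rel(a, b).pvalue)


@dataclass(frozen=True)
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)


def roc_analysis(values, groups, positive: str = "eAD") -> RocResult:
    """Empirical ROC of a per-subject metric for separating two groups.

    AUC is the trapezoid area of the empirical curve (equivalently the
    all-pairs concordance probability with ties counted half).  The
    optimal threshold maximizes Youden's J = sens + spec - 1 over the
    midpoints between consecutive sorted unique values ("value >=
    threshold" calls positive); ties pick the lower threshold, and the
    chosen threshold always lies within the observed value range.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = (groups == positive).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, values))
    fpr, tpr, _ = roc_curve(labels, values)

    uniq = np.unique(values)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
    pos = values[labels == 1]
    neg = values[labels == 0]
    best = None
    for thr in candidates:  # ascending: first max keeps the lower threshold
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    return RocResult(auc, float(thr), sens, spec, fpr, tpr)
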