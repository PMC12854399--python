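"""Between-group comparisons, age-class subgroup tables, and IPTW adjustment.

Comparisons follow a normality gate: each sample is checked with the
Shapiro–Wilk test; when both pass (p >= .05), the two groups are compared
with a two-tailed two-sample Student t test, otherwise with the Wilcoxon
rank-sum (Mann–Whitney U) test.  Significance is flagged at p < .05.

Because the two care models are not randomised, the module also provides
inverse probability of treatment weighting: a logistic propensity model of
arm membership on chosen covariates, stabilised weights truncated at the
1st/99th percentiles, weighted arm summaries and weighted standardized mean
differences for balance diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from glycea.cohort import AGE_CLASS_BOUNDS, AGE_CLASS_LABELS

__all__ = [
    "ALPHA", "ComparisonResult", "normality_gate", "compare_groups",
    "age_class_of", "partition_age_classes", "subgroup_table",
    "IptwResult", "iptw_adjust",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one normality-gated two-group comparison."""

    test_name: str  # "t" | "wilcoxon_rank_sum"
    statistic: float
    pvalue: float
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float

    def __post_init__(self):
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA


def normality_gate(sample: Sequence[float]) -> Tuple[float, float, bool]:
    """Shapiro–Wilk normality check: (W, p, is_normal at alpha=.05).

    A constant sample has no defined W and is treated as non-normal with a
    warning.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError(f"normality test needs n >= 3, got n={len(x)}")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: Shapiro-Wilk undefined, treated as non-normal")
        return np.nan, np.nan, False
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p >= ALPHA)


def compare_groups(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Compare two independent samples behind the Shapiro–Wilk gate.

    Both gates pass -> two-tailed Student t test (pooled variance);
    otherwise Wilcoxon rank-sum (Mann-Whitney U, two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    _, _, x_normal = normality_gate(x)
    _, _, y_normal = normality_gate(y)
    if x_normal and y_normal:
        stat, p = stats.ttest_ind(x, y, equal_var=True)
        name = "t"
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "wilcoxon_rank_sum"
    return ComparisonResult(
        name, float(stat), float(p),
        float(x.mean()), float(x.std(ddof=1)),
        float(y.mean()), float(y.std(ddof=1)),
    )


def age_class_of(age: float) -> str:
    """Age class with half-open boundaries [16,25), [25,45), [45,65), [65,inf)."""
    if age < AGE_CLASS_BOUNDS[0][0]:
        raise ValueError(f"age below cohort minimum: {age!r}")
    for (lo, hi), label in zip(AGE_CLASS_BOUNDS[:-1], AGE_CLASS_LABELS[:-1]):
        if lo <= age < hi:
            return label
    return AGE_CLASS_LABELS[-1]


def partition_age_classes(cohort: pd.DataFrame) -> Dict[str, List[str]]:
    """Patient ids per age class; classes partition the cohort."""
    per_patient = cohort.drop_duplicates("patient_id")
    out: Dict[str, List[str]] = {label: [] for label in AGE_CLASS_LABELS}
    for _, row in per_patient.iterrows():
        out[age_class_of(row["age"])].append(row["patient_id"])
    return out


def subgroup_table(
    cohort: pd.DataFrame,
    metric: str,
    timepoint: str,
    intervention: str,
    comparator: str,
) -> pd.DataFrame:
    """Per-age-class between-arm comparison of one metric at one timepoint.

    One row per age class plus a "Total" row, mirroring the clinical
    outcome-table layout (per-arm n, mean, SD, p-value, test used).  An age
    class empty in either arm is reported with its n and no test.
    """
    at_tp = cohort[cohort["timepoint"] == timepoint]
    if metric not in at_tp.columns:
        raise ValueError(f"metric {metric!r} not in cohort frame")
    rows = []
    groups = [("Total", at_tp)] + [
        (label, at_tp[at_tp["age_class"] == label]) for label in AGE_CLASS_LABELS
    ]
    for label, g in groups:
        x = g[g["arm"] == intervention][metric].to_numpy()
        y = g[g["arm"] == comparator][metric].to_numpy()
        row = {
            "subgroup": label, "metric": metric, "timepoint": timepoint,
            f"n_{intervention}": len(x), f"n_{comparator}": len(y),
            f"mean_{intervention}": float(np.mean(x)) if len(x) else np.nan,
            f"sd_{intervention}": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
            f"mean_{comparator}": float(np.mean(y)) if len(y) else np.nan,
            f"sd_{comparator}": float(np.std(y, ddof=1)) if len(y) > 1 else np.nan,
        }
        if len(x) >= 3 and len(y) >= 3:
            res = compare_groups(x, y)
            row.update(pvalue=res.pvalue, test=res.test_name)
        else:
            row.update(pvalue=np.nan, test="")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IptwResult:
    """Stabilised-IPTW output: weights, weighted summaries, balance table."""

    weights: pd.Series  # indexed by patient_id
    propensity: pd.Series
    weighted_summaries: pd.DataFrame  # per arm: weighted mean/SD per outcome
    smd_unweighted: Dict[str, float]
    smd_weighted: Dict[str, float]
    dropped_covariates: List[str] = field(default_factory=list)


def _wmean_wsd(x: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    wm = float(np.average(x, weights=w))
    wv = float(np.average((x - wm) ** 2, weights=w))
    # unbiased-style correction for weighted variance
    denom = 1.0 - float((w / w.sum()) @ (w / w.sum()))
    if denom > 0:
        wv /= denom
    return wm, float(np.sqrt(wv))


def _smd(x: np.ndarray, y: np.ndarray,
         wx: Optional[np.ndarray] = None, wy: Optional[np.ndarray] = None) -> float:
    wx = np.ones(len(x)) if wx is None else wx
    wy = np.ones(len(y)) if wy is None else wy
    mx, sx = _wmean_wsd(x, wx)
    my, sy = _wmean_wsd(y, wy)
    pooled = np.sqrt((sx ** 2 + sy ** 2) / 2.0)
    return float((mx - my) / pooled) if pooled > 0 else 0.0


def iptw_adjust(
    cohort: pd.DataFrame,
    covariates: Iterable[str],
    outcomes: Iterable[str] = ("tir", "gri"),
    timepoint: str = "M12",
    intervention: Optional[str] = None,
    clip: float = 1e-6,
) -> IptwResult:
    """Inverse-probability-of-treatment weighting of the two arms.

    Fits a logistic propensity model of intervention membership on the
    covariates (zero-variance covariates are dropped with a warning),
    computes stabilised weights (arm prevalence / propensity and its
    complement), truncates them at the 1st/99th percentiles, and returns
    weighted outcome means/SDs per arm plus standardized mean differences
    per covariate before and after weighting.

    Covariate columns are taken from the baseline (first-timepoint) rows if
    the frame is long-format.  Raises on a single-arm cohort or on
    non-overlap (fitted propensity at 0 or 1).
    """
    covariates = list(covariates)
    wide = cohort.drop_duplicates("patient_id").set_index("patient_id")
    arms = sorted(wide["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"IPTW needs exactly 2 arms, got {arms}")
    if intervention is None:
        intervention = arms[0]
    comparator = [a for a in arms if a != intervention][0]

    # baseline covariate values per patient (long frame carries them per row)
    base_tp = sorted(cohort["timepoint"].unique())[0]
    base = cohort[cohort["timepoint"] == base_tp].set_index("patient_id")
    X = base.loc[wide.index, covariates].astype(float)
    kept, dropped = [], []
    for c in covariates:
        (kept if X[c].nunique() > 1 else dropped).append(c)
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}")

    t = (wide["arm"] == intervention).astype(float)
    prevalence = float(t.mean())
    if kept:
        design = sm.add_constant(X[kept])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = sm.Logit(t, design).fit(disp=0, maxiter=200).predict(design)
    else:
        ps = pd.Series(prevalence, index=wide.index)
    degenerate = ps[(ps <= clip) | (ps >= 1 - clip)]
    if len(degenerate):
        raise ValueError(
            "non-overlap: propensity at 0 or 1 for patients "
            f"{sorted(degenerate.index.tolist())}")

    w = pd.Series(np.where(t == 1, prevalence / ps, (1 - prevalence) / (1 - ps)),
                  index=wide.index, name="weight")
    lo, hi = np.percentile(w, [1, 99])
    w = w.clip(lo, hi)

    # weighted outcome summaries at the analysis timepoint
    out_tp = cohort[cohort["timepoint"] == timepoint].set_index("patient_id")
    rows = []
    for arm in (intervention, comparator):
        idx = wide.index[wide["arm"] == arm]
        warm = w.loc[idx].to_numpy()
        row = {"arm": arm, "n": len(idx), "sum_weight": float(warm.sum())}
        for oc in outcomes:
            vals = out_tp.loc[idx, oc].to_numpy(dtype=float)
            wm, wsd = _wmean_wsd(vals, warm)
            row[f"{oc}_wmean"] = wm
            row[f"{oc}_wsd"] = wsd
        rows.append(row)

    idx_i = wide.index[wide["arm"] == intervention]
    idx_c = wide.index[wide["arm"] == comparator]
    smd_un, smd_w = {}, {}
    for c in kept:
        xi = X.loc[idx_i, c].to_numpy()
        xc = X.loc[idx_c, c].to_numpy()
        smd_un[c] = _smd(xi, xc)
        smd_w[c] = _smd(xi, xc, w.loc[idx_i].to_numpy(), w.loc[idx_c].to_numpy())
    for c in dropped:
        smd_un[c] = 0.0
        smd_w[c] = 0.0

    return IptwResult(
        weights=w,
        propensity=pd.Series(ps, index=wide.index, name="propensity"),
        weighted_summaries=pd.DataFrame(rows),
        smd_unweighted=smd_un,
        smd_weighted=smd_w,
        dropped_covariates=dropped,
    )
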