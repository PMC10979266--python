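"""Group-comparison statistics: normality tests, unpaired t-tests,
Cronbach's alpha, power-based sample size, and the per-feature comparison
table.

The study design compares every texture / strut / morphometric feature
between two independent groups with a pooled-variance two-sample t-test at
per-comparison alpha 0.05 (no multiplicity correction by default, matching
the source protocol; Bonferroni and Benjamini–Hochberg adjustments are
available behind a flag).  Sample size for the design is solved from the
noncentral-t power function of the two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .strut import RATIO_NAMES

__all__ = [
    "ComparisonRow",
    "normality_tests",
    "unpaired_ttest",
    "cronbach_alpha",
    "sample_size_two_group",
    "compare_groups",
    "FEATURE_ORDER",
]

# Table row order: fractal dimension, the four GLCM features, then struts,
# then the morphometric indices when present.
FEATURE_ORDER = (
    "fd",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    *RATIO_NAMES,
    "mi_mm",
    "pmi",
)


def normality_tests(sample: Sequence[float]) -> dict[str, float]:
    """Shapiro–Wilk plus one-sample Kolmogorov–Smirnov against a fitted normal.

    The KS test uses the sample mean and SD as the reference parameters
    (Lilliefors-style; its p-value is therefore anti-conservative and is
    reported for parity with common screening practice).
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if x.std(ddof=1) == 0:
        raise ValueError("sample has zero variance")
    sw = sps.shapiro(x)
    ks = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


@dataclass
class TTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float


def unpaired_ttest(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    xa = np.asarray(a, dtype=np.float64)
    xb = np.asarray(b, dtype=np.float64)
    if xa.size < 2 or xb.size < 2:
        raise ValueError(f"each group needs n >= 2, got {xa.size} and {xb.size}")
    res = sps.ttest_ind(xa, xb, equal_var=equal_var)
    df = float(xa.size + xb.size - 2) if equal_var else float(res.df)
    return TTestResult(
        mean_a=float(xa.mean()), sd_a=float(xa.std(ddof=1)),
        mean_b=float(xb.mean()), sd_b=float(xb.std(ddof=1)),
        n_a=int(xa.size), n_b=int(xb.size),
        t_statistic=float(res.statistic), df=df, p_value=float(res.pvalue),
    )


def cronbach_alpha(ratings: np.ndarray) -> float:
    """Cronbach's alpha of an observers x subjects rating matrix.

    Rows are the parallel measurements (observers), columns the rated
    subjects.  alpha = k/(k-1) * (1 - sum of per-observer variances /
    variance of per-subject totals), with k observers and sample (n-1)
    variances across subjects.
    """
    r = np.asarray(ratings, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be a matrix with >= 2 observers and >= 2 subjects")
    k = r.shape[0]
    total_var = r.sum(axis=0).var(ddof=1)
    if total_var <= 1e-24:
        raise ValueError("degenerate ratings: per-subject totals have zero variance")
    item_var = r.var(axis=1, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _power_two_sample_t(n: int, d: float, alpha: float, tails: int) -> float:
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    if tails == 1:
        tcrit = sps.t.ppf(1 - alpha, df)
        return float(1 - sps.nct.cdf(tcrit, df, ncp))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_group(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.95, tails: int = 1
) -> dict[str, float]:
    """Smallest per-group n for a two-sample t-test to reach the target power.

    Starts from the normal approximation ``n = 2 ((z_alpha + z_power)/d)^2``
    and steps against the exact noncentral-t power until the minimal integer
    n is found.  Returns per-group n, total 2n and the achieved power.
    """
    if effect_size_d <= 0:
        raise ValueError("effect_size_d must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")

    z_a = sps.norm.ppf(1 - alpha / tails)
    z_b = sps.norm.ppf(power)
    n = max(2, math.ceil(2.0 * ((z_a + z_b) / effect_size_d) ** 2))
    while n > 2 and _power_two_sample_t(n - 1, effect_size_d, alpha, tails) >= power:
        n -= 1
    while _power_two_sample_t(n, effect_size_d, alpha, tails) < power:
        n += 1
    return {
        "n_per_group": n,
        "n_total": 2 * n,
        "achieved_power": _power_two_sample_t(n, effect_size_d, alpha, tails),
    }


@dataclass
class ComparisonRow:
    """One line of the per-feature group-comparison table."""

    feature: str
    roi: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}; use 'bonferroni' or 'bh'")


def compare_groups(
    table: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    correction: Optional[str] = None,
) -> pd.DataFrame:
    """Per-feature, per-ROI two-group comparison table.

    ``table`` holds one row per image with a ``group`` column in {'A', 'B'},
    an optional ``roi`` column, and one column per feature.  Every (feature,
    ROI) cell must contain both groups.  Rows follow the conventional table
    order (fractal dimension, GLCM, strut ratios, indices); NaN feature
    values are dropped per cell before testing.
    """
    if "group" not in table.columns:
        raise ValueError("table must have a 'group' column")
    groups = set(table["group"].unique())
    if not {"A", "B"} <= groups:
        raise ValueError(f"both groups A and B must be present, found {sorted(groups)}")
    rois = list(pd.unique(table["roi"])) if "roi" in table.columns else [""]
    meta_cols = {"group", "roi", "image_id"}
    features = [c for c in table.columns if c not in meta_cols]
    ordered = [f for f in FEATURE_ORDER if f in features]
    ordered += [f for f in features if f not in ordered]

    rows: list[ComparisonRow] = []
    for roi in rois:
        sub = table if roi == "" else table[table["roi"] == roi]
        for feat in ordered:
            a = sub.loc[sub["group"] == "A", feat].dropna().to_numpy()
            b = sub.loc[sub["group"] == "B", feat].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(
                    f"feature {feat!r} in ROI {roi!r} is missing a group "
                    f"(n_A={a.size}, n_B={b.size})"
                )
            res = unpaired_ttest(a, b, equal_var=equal_var)
            rows.append(ComparisonRow(
                feature=feat, roi=str(roi),
                mean_a=res.mean_a, sd_a=res.sd_a,
                mean_b=res.mean_b, sd_b=res.sd_b,
                t_statistic=res.t_statistic, p_value=res.p_value,
                significant=False,
            ))

    out = pd.DataFrame([r.__dict__ for r in rows])
    p = out["p_value"].to_numpy()
    if correction is not None:
        p = _adjust_pvalues(p, correction)
        out["p_adjusted"] = p
    out["significant"] = p <= alpha
    return out
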