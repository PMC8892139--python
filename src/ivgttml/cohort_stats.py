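"""Group-level descriptive statistics with normality-gated testing.

For each feature the cohort summary reports, per group, either mean +/- SD
(when both groups pass a Lilliefors normality test at 5%) or median [IQR
width], and compares the groups with a pooled-variance Student t-test or a
Wilcoxon rank-sum test accordingly.  No multiplicity correction is applied.

The Lilliefors p-value is computed by seeded Monte Carlo: the null
distribution of the KS statistic with estimated mean/SD is distribution-free
under normality, so one simulated null table per sample size is cached and
reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["lilliefors", "group_compare", "summary_table", "CohortSummary"]

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _ks_normal_stat(x: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with estimated moments."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _null_table(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_mc, n))
        z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(
            axis=1, keepdims=True, ddof=1
        )
        z.sort(axis=1)
        cdf = stats.norm.cdf(z)
        grid = np.arange(1, n + 1) / n
        up = (grid - cdf).max(axis=1)
        down = (cdf - np.arange(0, n) / n).max(axis=1)
        _NULL_CACHE[key] = np.maximum(up, down)
    return _NULL_CACHE[key]


def lilliefors(sample, n_mc: int = 10000, seed: int = 0) -> float:
    """Monte-Carlo Lilliefors test p-value for composite normality.

    The statistic is the KS distance to a normal distribution with mean and
    SD estimated from the sample; the p-value is the (add-one-corrected)
    fraction of ``n_mc`` simulated normal samples of the same size with an
    equal or larger statistic.  Deterministic given ``seed``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    if np.std(x) == 0:
        warnings.warn("constant sample; normality rejected by convention")
        return 0.0
    stat = _ks_normal_stat(x)
    null = _null_table(x.size, n_mc, seed)
    return float((np.sum(null >= stat) + 1) / (n_mc + 1))


def group_compare(
    values, labels, alpha: float = 0.05, n_mc: int = 2000, seed: int = 0
) -> dict:
    """Two-group comparison with normality-gated test choice.

    Both groups must pass Lilliefors at ``alpha`` for the pooled-variance
    Student t-test; otherwise the Wilcoxon rank-sum (Mann-Whitney) test is
    used.  Two-sided throughout.  Returns ``{"test", "p", "normal"}`` with
    ``p`` NaN on degenerate groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) != 2 or any(g.size < 4 for g in groups):
        return {"test": None, "p": float("nan"), "normal": False}
    normal = all(
        np.std(g) > 0 and lilliefors(g, n_mc=n_mc, seed=seed) >= alpha
        for g in groups
    )
    if normal:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        return {"test": "t", "p": float(res.pvalue), "normal": True}
    if np.std(values[np.isfinite(values)]) == 0:
        return {"test": "wilcoxon", "p": float("nan"), "normal": False}
    res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    return {"test": "wilcoxon", "p": float(res.pvalue), "normal": False}


@dataclass
class CohortSummary:
    """Per-feature group summaries and test results."""

    table: pd.DataFrame  #: one row per feature, in input column order

    def row(self, feature: str) -> pd.Series:
        return self.table.loc[feature]


def _format_group(values: np.ndarray, normal: bool) -> str:
    values = values[np.isfinite(values)]
    if normal:
        return f"{np.mean(values):.3g} ± {np.std(values, ddof=1):.3g}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.3g} [{q3 - q1:.3g}]"


def summary_table(
    matrix: pd.DataFrame, alpha: float = 0.05, n_mc: int = 2000, seed: int = 0
) -> CohortSummary:
    """Cohort description: one row per feature with summaries, test and p.

    ``matrix`` must carry a ``label`` column with two groups.  Skewed features
    (either group failing Lilliefors) are summarized as median [IQR width],
    normal ones as mean +/- SD; the ``significant`` flag marks p < alpha.
    """
    labels = matrix["label"].to_numpy()
    group_names = sorted(pd.unique(labels), reverse=True)  # PROG last
    features = matrix.drop(columns=["label"]).select_dtypes(include=[np.number])
    rows = []
    for col in features.columns:
        values = features[col].to_numpy(dtype=float)
        res = group_compare(values, labels, alpha=alpha, n_mc=n_mc, seed=seed)
        row = {"feature": col, "test": res["test"], "p": res["p"],
               "normal": res["normal"],
               "significant": bool(res["p"] < alpha) if np.isfinite(res["p"]) else False}
        for g in group_names:
            vals = values[labels == g]
            row[f"summary_{g}"] = _format_group(vals, res["normal"])
            row[f"median_{g}"] = float(np.nanmedian(vals))
        rows.append(row)
    return CohortSummary(table=pd.DataFrame(rows).set_index("feature"))
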