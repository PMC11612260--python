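"""Distributional analysis of standardized effect sizes across matrices.

Under the null hypothesis of unstructured assembly the SES values of a
batch of matrices average zero with ~95% of them inside the +/-2 band.
Beyond that one-sample check, rank tests ask whether SES differs across
biological groupings (functional feeding groups or families):
Kruskal-Wallis across all groups and pairwise Wilcoxon rank-sum
(Mann-Whitney U) between group pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("coocc")

__all__ = [
    "build_ses_table",
    "ses_band_summary",
    "kruskal_wallis",
    "GroupTestResult",
    "pairwise_wilcoxon",
    "ses_histogram",
]


def build_ses_table(results: pd.DataFrame) -> pd.DataFrame:
    """Extract the SES table from a batch-results frame.

    Rows with undefined SES (zero null variance) or unusable matrices are
    excluded and counted in the log.
    """
    cols = ["year", "ecoregion", "vegetation", "unit_type", "unit",
            "ses", "classification"]
    table = results[[c for c in cols if c in results.columns]].copy()
    bad = ~np.isfinite(table["ses"])
    if bad.any():
        logger.info("build_ses_table: excluded %d undefined-SES rows", int(bad.sum()))
    return table[~bad].reset_index(drop=True)


def ses_band_summary(ses_values) -> tuple[float, float]:
    """(mean SES, fraction with |SES| > 2) for a batch of matrices."""
    x = np.asarray(ses_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("ses_band_summary requires at least one defined SES")
    return float(x.mean()), float((np.abs(x) > 2).mean())


@dataclass
class GroupTestResult:
    statistic: float  # Kruskal-Wallis H (tie-corrected)
    df: int
    p: float
    group_sizes: list[int]
    tie_correction_applied: bool

    def summary(self) -> str:
        return (
            f"Kruskal-Wallis: H = {self.statistic:.4f}, df = {self.df}, "
            f"p = {self.p:.4f} (groups n = {self.group_sizes})"
        )


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Kruskal-Wallis rank test of a value across >= 2 groups.

    Midranks with the standard tie correction; p from the chi-square
    approximation with df = g - 1.  All-identical values give H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    samples = [values[groups == g] for g in labels]
    sizes = [len(s) for s in samples]
    if min(sizes) < 1:
        raise ValueError("every group needs at least one value")
    ties = len(np.unique(values)) < len(values)
    if len(np.unique(values)) == 1:
        return GroupTestResult(0.0, len(labels) - 1, 1.0, sizes, ties)
    h, p = stats.kruskal(*samples)
    return GroupTestResult(float(h), len(labels) - 1, float(p), sizes, ties)


def pairwise_wilcoxon(
    values, groups, adjust: str = "none"
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) for every group pair.

    Exact enumeration when both samples have n <= 8 and no ties span the
    pair; the normal approximation with continuity and tie correction
    otherwise.  ``adjust='holm'`` adds Holm-adjusted p-values; the default
    is unadjusted.
    """
    if adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    rows = []
    for g1, g2 in combinations(labels, 2):
        a = values[groups == g1]
        b = values[groups == g2]
        pooled = np.concatenate([a, b])
        exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(pooled)) == len(pooled)
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": len(a),
                "n2": len(b),
                "u": float(res.statistic),
                "p": float(min(res.pvalue, 1.0)),
                "method": method,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "holm" and len(out):
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    return out


def ses_histogram(ses_values, bin_width: float = 0.5) -> pd.DataFrame:
    """Binned SES counts for plotting, with the +/-2 null band marked."""
    x = np.asarray(ses_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no defined SES values")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "inside_band": (edges[:-1] >= -2) & (edges[1:] <= 2),
        }
    )
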