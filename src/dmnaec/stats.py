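"""Group statistics: ANOVA + FDR over ROI x band cells, Bonferroni edge
tests, demographics tables and one-tailed Spearman correlation.

The group factor has two levels, so the one-way ANOVA F statistic is
exactly the square of the pooled two-sample t.  Multiple comparisons
over the ROI x band family use Benjamini-Hochberg FDR; the follow-up
edge-level AEC comparisons use a Bonferroni threshold alpha/m with m an
explicit configuration value (the convention reported with these
analyses is m = 11, i.e. p < 0.0045).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_EDGE_COMPARISONS = 11


def bonferroni_threshold(alpha: float = 0.05, m: int = DEFAULT_EDGE_COMPARISONS) -> float:
    if m <= 0:
        raise ValueError("comparison count m must be positive")
    return alpha / m


def compare_cells(table: pd.DataFrame, alpha: float = 0.05,
                  value: str = "strength") -> pd.DataFrame:
    """One-way ANOVA per (roi, band) cell with BH-FDR over the family.

    ``table`` is tidy with columns subject, group, roi, band and the
    value column.  Returns per-cell group means/SDs, F, raw p, q and a
    significance flag (q < alpha).  Cells where a group has fewer than
    two observations or both groups are constant are flagged NA.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    rows = []
    for (roi, band), cell in table.groupby(["roi", "band"], sort=True):
        a = cell.loc[cell["group"] == g0, value].to_numpy(dtype=float)
        b = cell.loc[cell["group"] == g1, value].to_numpy(dtype=float)
        row = {"roi": roi, "band": band,
               f"mean_{g0}": a.mean() if a.size else np.nan,
               f"sd_{g0}": a.std(ddof=1) if a.size > 1 else np.nan,
               f"mean_{g1}": b.mean() if b.size else np.nan,
               f"sd_{g1}": b.std(ddof=1) if b.size > 1 else np.nan}
        if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
            row.update(F=np.nan, p=np.nan)
        else:
            f, p = sps.f_oneway(a, b)
            row.update(F=f, p=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"],
                                            method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


def compare_edges(edge_table: pd.DataFrame, alpha: float = 0.05,
                  m: int = DEFAULT_EDGE_COMPARISONS,
                  value: str = "aec") -> pd.DataFrame:
    """Two-sample t test per (roi_i, roi_j, band) edge, Bonferroni alpha/m.

    ``edge_table`` is tidy with columns subject, group, roi_i, roi_j,
    band and the AEC value column.  Edges are expected to be
    preselected (those incident to nodes with significant strength
    differences); m is declared, not recomputed.
    """
    threshold = bonferroni_threshold(alpha, m)
    groups = sorted(edge_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    rows = []
    for (ri, rj, band), cell in edge_table.groupby(["roi_i", "roi_j", "band"],
                                                   sort=True):
        a = cell.loc[cell["group"] == g0, value].to_numpy(dtype=float)
        b = cell.loc[cell["group"] == g1, value].to_numpy(dtype=float)
        t, p = sps.ttest_ind(a, b)
        rows.append({"roi_i": ri, "roi_j": rj, "band": band,
                     f"mean_{g0}": a.mean(), f"mean_{g1}": b.mean(),
                     "t": t, "p": p, "threshold": threshold,
                     "significant": p < threshold})
    return pd.DataFrame(rows)


def spearman_one_tailed(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with the
    one-tailed p for a positive association."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DemographicRow:
    name: str
    kind: str        # "numeric" or "categorical"
    summary_a: str
    summary_b: str
    p: float


def ttest_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int) -> float:
    """Pooled two-sample t-test p from printed mean +/- SD summaries."""
    return float(sps.ttest_ind_from_stats(mean_a, sd_a, n_a,
                                          mean_b, sd_b, n_b).pvalue)


def chi2_from_counts(counts_a: tuple[int, ...], counts_b: tuple[int, ...],
                     correction: bool = False) -> float:
    """Chi-squared test on a 2 x k contingency table of category counts.

    No continuity correction by default.  Warns (rather than failing)
    when an expected count drops below 1, where an exact test would be
    preferable.
    """
    table = np.array([counts_a, counts_b], dtype=float)
    res = sps.chi2_contingency(table, correction=correction)
    if (res.expected_freq < 1).any():
        warnings.warn("expected cell count < 1; consider an exact test")
    return float(res.pvalue)


def compare_demographics(numeric: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                         categorical: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] | None = None,
                         ) -> pd.DataFrame:
    """Demographics table: t tests for numeric rows, chi-squared for
    categorical count rows, one p value per row."""
    rows: list[DemographicRow] = []
    for name, (a, b) in (numeric or {}).items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = float(sps.ttest_ind(a, b).pvalue)
        rows.append(DemographicRow(
            name, "numeric",
            f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
            f"{b.mean():.2f} ± {b.std(ddof=1):.2f}", p))
    for name, (ca, cb) in (categorical or {}).items():
        p = chi2_from_counts(ca, cb)
        rows.append(DemographicRow(name, "categorical",
                                   "/".join(map(str, ca)),
                                   "/".join(map(str, cb)), p))
    return pd.DataFrame([r.__dict__ for r in rows])
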