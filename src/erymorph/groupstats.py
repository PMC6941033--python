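"""Group comparisons of RBC morphometry between haematological groups.

Sheep are split into two groups per haematological index (HGB, HCT, MCV,
MCH, MCHC, RDW) by a cut-off; per-cell morphometric means are compared by
Box-Cox-transformed MANOVA (Wilks' lambda) with Tukey-adjusted least-square
means, and subpopulation distributions by Pearson chi-square on the 2x3
group-by-subpopulation contingency table.  ``reconstruct_counts`` rebuilds
such a table from printed percentages and per-group cell totals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupingScheme",
    "ContingencyTable",
    "categorize",
    "boxcox_transform",
    "wilks_manova",
    "tukey_lsmeans",
    "subpop_chisq",
    "reconstruct_counts",
]

#: Columns every sheep record table must carry (analyser units).
SHEEP_COLUMNS = ("sheep_id", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW", "age")


@dataclass(frozen=True)
class GroupingScheme:
    """Two-group split of sheep on one haematological parameter.

    ``rule="le"``: Group 1 iff value <= cutoff; ``rule="lt"``: Group 1 iff
    value < cutoff (the MCHC convention).  Everyone else is Group 2.
    """

    parameter: str
    cutoff: float
    rule: str = "le"

    def __post_init__(self) -> None:
        if self.rule not in ("le", "lt"):
            raise ValueError(f"rule must be 'le' or 'lt', got {self.rule!r}")

    def is_group1(self, value: float) -> bool:
        if self.rule == "le":
            return value <= self.cutoff
        return value < self.cutoff


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of cells per (group, subpopulation); rows = groups."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def categorize(records: pd.DataFrame, scheme: GroupingScheme) -> pd.Series:
    """Assign each sheep to group 1 or 2 under ``scheme``.

    Parameters
    ----------
    records
        Sheep table with at least ``sheep_id`` and the scheme's parameter
        column.

    Returns
    -------
    Integer series (1 or 2) indexed like ``records``.
    """
    if scheme.parameter not in records.columns:
        raise KeyError(f"column {scheme.parameter!r} missing from records")
    values = records[scheme.parameter]
    if values.isna().any():
        raise ValueError(f"{scheme.parameter} has missing values")
    in1 = values.map(scheme.is_group1)
    return pd.Series(np.where(in1, 1, 2), index=records.index, name="group")


def boxcox_transform(
    values: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Box-Cox transform at the grid lambda maximizing the profile
    log-likelihood; lambda = 0 means the log transform.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if (values <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    if lambda_grid is None:
        lambda_grid = np.linspace(-2.0, 2.0, 81)
    llf = np.array([stats.boxcox_llf(l, values) for l in lambda_grid])
    lam = float(lambda_grid[np.argmax(llf)])
    transformed = stats.boxcox(values, lmbda=lam)
    return transformed, lam


def wilks_manova(
    features: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Two-group MANOVA on Wilks' lambda with the exact F transform.

    Lambda = |E| / |E + H| where E is the pooled within-group SSCP and H the
    between-group SSCP.  For two groups, (1-L)/L * (n-p-1)/p is exactly
    F(p, n-p-1) under the null of equal mean vectors.

    Returns
    -------
    (wilks_lambda, F, p_value)
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    n, p = X.shape
    if min((groups == g).sum() for g in levels) <= p + 2:
        raise ValueError("need n > p + 2 observations per group")

    grand = X.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in levels:
        Xg = X[groups == g]
        mg = Xg.mean(axis=0)
        R = Xg - mg
        E += R.T @ R
        d = (mg - grand)[:, None]
        H += len(Xg) * (d @ d.T)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    df2 = n - p - 1
    F = (1.0 - lam) / lam * df2 / p
    pval = float(stats.f.sf(F, p, df2))
    return lam, float(F), pval


def tukey_lsmeans(
    feature: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise Tukey-HSD comparisons of group means for one variable.

    With exactly two groups, the studentized-range adjustment reduces to the
    pooled-variance t-test, so the adjusted p equals the unadjusted p.

    Returns a table with one row per group pair: group labels, each group's
    mean +- standard error, the mean difference and the adjusted p-value.
    """
    feature = np.asarray(feature, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    res = pairwise_tukeyhsd(feature, groups, alpha=alpha)
    means = {g: feature[groups == g].mean() for g in levels}
    sems = {g: stats.sem(feature[groups == g]) for g in levels}
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for (g1, g2), diff, p in zip(pairs, res.meandiffs, res.pvalues):
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean1": means[g1],
                "sem1": sems[g1],
                "mean2": means[g2],
                "sem2": sems[g2],
                "meandiff": float(diff),
                "p_adj": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def subpop_chisq(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Returns ``(chi2, df, p)``; df = (rows-1)(cols-1).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; expected counts must be positive")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def reconstruct_counts(
    percentages: np.ndarray,
    row_totals: np.ndarray,
    row_labels: tuple[str, ...] | None = None,
    col_labels: tuple[str, ...] = ("ES1", "ES2", "ES3"),
) -> ContingencyTable:
    """Rebuild integer counts from printed row percentages and row totals.

    Each cell is ``round(pct/100 * total)``; the rounding residual (at most
    one count per row) is absorbed into the row's largest cell (largest
    printed percentage, which also breaks count ties) so row sums equal the
    printed totals exactly.
    """
    pct = np.asarray(percentages, dtype=float)
    totals = np.asarray(row_totals, dtype=np.int64)
    if pct.ndim != 2 or pct.shape[0] != totals.size:
        raise ValueError("percentages must be rows x cols with one total per row")
    if not np.allclose(pct.sum(axis=1), 100.0, atol=0.2):
        raise ValueError("each percentage row must sum to 100 +- 0.2")
    counts = np.rint(pct / 100.0 * totals[:, None]).astype(np.int64)
    for i, total in enumerate(totals):
        counts[i, np.argmax(pct[i])] += total - counts[i].sum()
    if row_labels is None:
        row_labels = tuple(f"Group {i + 1}" for i in range(pct.shape[0]))
    return ContingencyTable(counts, tuple(row_labels), tuple(col_labels))


def group_comparison_report(
    cells: pd.DataFrame,
    sheep: pd.DataFrame,
    scheme: GroupingScheme,
    variables: list[str],
) -> pd.DataFrame:
    """Per-variable group means +- SE with Tukey-adjusted p, one grouping.

    ``cells`` must carry ``sheep_id`` plus the morphometric columns; groups
    are inherited from each cell's sheep.  Cells are treated as independent
    observations, mirroring the original per-RBC analysis.
    """
    glabels = categorize(sheep, scheme)
    sheep_group = dict(zip(sheep["sheep_id"], glabels))
    cell_groups = cells["sheep_id"].map(sheep_group).to_numpy()
    if np.isnan(cell_groups.astype(float)).any():
        raise ValueError("cells reference sheep missing from the sheep table")
    rows = []
    for var in variables:
        tab = tukey_lsmeans(cells[var].to_numpy(), cell_groups)
        r = tab.iloc[0]
        rows.append(
            {
                "parameter": scheme.parameter,
                "variable": var,
                "n1": int((cell_groups == 1).sum()),
                "mean1": r["mean1"],
                "sem1": r["sem1"],
                "n2": int((cell_groups == 2).sum()),
                "mean2": r["mean2"],
                "sem2": r["sem2"],
                "p_adj": r["p_adj"],
            }
        )
    return pd.DataFrame(rows)
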