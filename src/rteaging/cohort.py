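"""Sample stratification and association statistics for cohort analyses.

Samples are split on a per-sample score either into quartile groups — low
(bottom 25%), medium (middle 50%), high (top 25%) — or at the median into
low/high. Associations are measured with Pearson correlation (two-sided t-test
p-values) and group contrasts with the unpaired two-sided Wilcoxon rank-sum
(Mann-Whitney) test using the normal approximation with tie correction,
matching common practice for cohort-scale blood transcriptomics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


def p_stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 / 0.0001 thresholds."""
    stars = sum(p <= t for t in STAR_THRESHOLDS)
    return "*" * stars if stars else "ns"


@dataclass
class SampleGrouping:
    """Partition of samples into labelled groups on the basis of a score."""

    labels: pd.Series  # sample_id -> {low, medium, high} or {low, high}
    basis: str
    mode: str  # "quartile" or "median"

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.labels.index, "basis": self.basis, "label": self.labels.values}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def quartile_split(values: pd.Series, basis: str = "score") -> SampleGrouping:
    """Split samples into low (<= Q1), high (> Q3) and medium (the rest).

    Quartiles use linear-interpolation quantiles; boundary ties fall into the
    more extreme group (<= Q1 is low, > Q3 is high) so the partition is
    deterministic and exhaustive.
    """
    values = pd.Series(values).dropna()
    if len(values) < 8:
        raise ValueError(f"quartile split needs >= 8 samples, got {len(values)}")
    arr = values.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise ValueError("all values identical; no spread to split on")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    labels = pd.Series("medium", index=values.index, dtype=object)
    labels[values <= q1] = "low"
    labels[values > q3] = "high"
    return SampleGrouping(labels, basis=basis, mode="quartile")


def median_split(values: pd.Series, basis: str = "score") -> SampleGrouping:
    """Split samples at the median: high = strictly above, low = the rest."""
    values = pd.Series(values).dropna()
    if len(values) < 4:
        raise ValueError(f"median split needs >= 4 samples, got {len(values)}")
    arr = values.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise ValueError("all values identical; no spread to split on")
    med = np.median(arr)
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index, dtype=object)
    return SampleGrouping(labels, basis=basis, mode="median")


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from the t distribution (n - 2 df).

    Missing values are removed pairwise; the pair count actually used is
    returned alongside (r, p).
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = x.notna().to_numpy() & y.notna().to_numpy()
    xv, yv = x.to_numpy()[keep], y.to_numpy()[keep]
    n = len(xv)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant vector in correlation")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n


def correlation_matrix(variables: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlations as a long-format table.

    ``variables`` holds one column per named variable over a shared sample
    index. Every ordered pair appears once with var1 <= var2 in column order;
    the table includes the diagonal (r = 1) and star annotations.
    """
    cols = list(variables.columns)
    rows = []
    for v in cols:
        rows.append({"var1": v, "var2": v, "r": 1.0, "p": 0.0, "n": int(variables[v].notna().sum()), "stars": "****"})
    for v1, v2 in combinations(cols, 2):
        r, p, n = pearson(variables[v1], variables[v2])
        rows.append({"var1": v1, "var2": v2, "r": r, "p": p, "n": n, "stars": p_stars(p)})
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "n", "stars"])


def correlation_square(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format correlation table to a symmetric square r matrix."""
    names = list(dict.fromkeys(table["var1"]))
    sq = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for row in table.itertuples(index=False):
        sq.loc[row.var1, row.var2] = row.r
        sq.loc[row.var2, row.var1] = row.r
    return sq


def wilcoxon_compare(a, b) -> tuple[float, float]:
    """Two-sided unpaired rank-sum test (normal approximation, tie-corrected).

    Returns the Mann-Whitney U statistic of the first group and the p-value.
    Identical groups give p = 1 under the approximation.
    """
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional helper; raw p-values are the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
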