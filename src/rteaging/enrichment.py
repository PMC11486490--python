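"""Per-sample gene-set variation scoring and high-vs-low differential calls.

The enrichment score (ES) of a gene set in a sample is computed in three steps:

1. For each gene g, a Gaussian-kernel estimate of its expression CDF across
   samples, evaluated at each sample: h(g, s) = (1/n) sum_k Phi((x_gs - x_gk) /
   (sd_g / 4)). Genes with zero spread get h = 0.5 everywhere.
2. Within each sample the h values are ranked descending (rank 1 = largest) and
   each gene receives the symmetric weight w = |G/2 - rank|, emphasising genes
   at either expression extreme.
3. Walking genes in descending-h order, a running sum is incremented by
   w / sum_set(w) at set members and decremented by 1/(G - m) at non-members;
   the ES is the maximum positive deviation plus the minimum negative deviation
   of that walk (the difference-of-extremes statistic), so a set concentrated
   at the top of the ranking scores positive and its complement negative.

Differential enrichment between high and low strata is a Welch t-test on the
per-sample ES, with sets called up/down when |mean difference| > 0.1 at
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .cohort import SampleGrouping
from .matrix import SampleMatrix
from .signatures import GeneSignature, read_gmt

LOGFC_THRESHOLD = 0.1
P_THRESHOLD = 0.05

#: redundant inflammation gene sets conventionally dropped alongside _UP/_DN sets
REDUNDANT_SET_NAMES = (
    "GOBP_POSITIVE_REGULATION_OF_ACUTE_INFLAMMATORY_RESPONSE",
    "GOBP_POSITIVE_REGULATION_OF_CYTOKINE_PRODUCTION_INVOLVED_IN_INFLAMMATORY_RESPONSE",
    "GOBP_POSITIVE_REGULATION_OF_ACUTE_INFLAMMATORY_RESPONSE_TO_ANTIGENIC_STIMULUS",
)


@dataclass
class GeneSetCollection:
    """Named gene sets with a category label per set (inflammatory / dna_repair / other)."""

    sets: list[GeneSignature]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene-set names must be unique")
        for s in self.sets:
            if len(s.genes) < 2:
                raise ValueError(f"gene set {s.name!r} has fewer than 2 genes")
        for name in self.categories:
            if name not in names:
                raise ValueError(f"category given for unknown set {name!r}")
        for name in names:
            self.categories.setdefault(name, "other")

    @classmethod
    def from_gmt(
        cls, gmt_path: str | Path, category_path: str | Path | None = None
    ) -> "GeneSetCollection":
        sets = read_gmt(gmt_path)
        categories: dict[str, str] = {}
        if category_path is not None:
            cat = pd.read_csv(category_path, sep="\t")
            categories = dict(zip(cat["set_name"], cat["category"]))
            categories = {k: v for k, v in categories.items() if k in {s.name for s in sets}}
        return cls(sets, categories)


def filter_gene_set_names(names: Iterable[str]) -> list[str]:
    """Drop direction-suffixed (``_UP``/``_DN``) and known-redundant set names.

    Keyword selection (e.g. 'inflammatory', 'dna_repair' searches) happens
    upstream of this cleanup.
    """
    return [
        n
        for n in names
        if not n.endswith(("_UP", "_DN")) and n not in REDUNDANT_SET_NAMES
    ]


def select_by_keyword(names: Iterable[str], keywords: Sequence[str]) -> list[str]:
    """Case-insensitive keyword filter over gene-set names."""
    lowered = [k.lower() for k in keywords]
    return [n for n in names if any(k in n.lower() for k in lowered)]


def gsva_scores(matrix: SampleMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-sample enrichment scores (sets x samples) for every gene set."""
    X = matrix.data.to_numpy(dtype=float)
    G, n = X.shape
    if n < 3:
        raise ValueError(f"GSVA needs >= 3 samples, got {n}")

    # step 1: Gaussian-kernel CDF estimate per gene across samples
    sd = X.std(axis=1, ddof=1)
    h = np.empty_like(X)
    const = ~np.isfinite(sd) | (sd == 0)
    for g in range(G):
        if const[g]:
            h[g, :] = 0.5
        else:
            bw = sd[g] / 4.0
            h[g, :] = ndtr((X[g, :, None] - X[g, None, :]) / bw).mean(axis=1)

    # step 2: rank h descending within each sample; rank 1 = largest h.
    # ties broken by gene order for determinism.
    order = np.argsort(-h, axis=0, kind="stable")  # order[r, s] = gene at rank r+1
    ranks = np.empty_like(order)
    rr = np.arange(1, G + 1)
    for s in range(n):
        ranks[order[:, s], s] = rr
    weights = np.abs(G / 2.0 - ranks)

    norm_symbols = np.array([GeneSignature.normalise_symbol(g) for g in matrix.data.index])
    es = pd.DataFrame(
        index=[s.name for s in sets.sets], columns=matrix.data.columns, dtype=float
    )
    for sig in sets.sets:
        member = np.isin(norm_symbols, list(sig.genes))
        m = int(member.sum())
        if m == 0:
            raise ValueError(f"gene set {sig.name!r} shares no gene with the matrix")
        if m == G:
            raise ValueError(f"gene set {sig.name!r} covers every gene in the matrix")
        for s in range(n):
            genes_desc = order[:, s]
            memb = member[genes_desc]
            w = weights[genes_desc, s]
            wsum = w[memb].sum()
            steps = np.where(memb, w / wsum if wsum > 0 else 0.0, -1.0 / (G - m))
            walk = np.cumsum(steps)
            es.loc[sig.name, matrix.data.columns[s]] = max(walk.max(), 0.0) + min(
                walk.min(), 0.0
            )
    return es


@dataclass
class DifferentialResult:
    """Per-set high-vs-low differential enrichment table."""

    table: pd.DataFrame  # columns: set, category, logFC, p, call

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_enrichment(
    es: pd.DataFrame,
    grouping: SampleGrouping,
    categories: Mapping[str, str] | None = None,
    logfc_threshold: float = LOGFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> DifferentialResult:
    """Welch t-test of high-vs-low mean ES per gene set with up/down/ns calls.

    logFC is the mean ES in the high group minus the mean in the low group;
    a set is called up when logFC > 0.1 and p < 0.05, down when logFC < -0.1
    and p < 0.05, otherwise ns.
    """
    high = [s for s in grouping.samples("high") if s in es.columns]
    low = [s for s in grouping.samples("low") if s in es.columns]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got high={len(high)}, low={len(low)}"
        )
    categories = dict(categories or {})
    rows = []
    for name in es.index:
        a = es.loc[name, high].to_numpy(dtype=float)
        b = es.loc[name, low].to_numpy(dtype=float)
        logfc = float(a.mean() - b.mean())
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if logfc > logfc_threshold and p < p_threshold:
            call = "up"
        elif logfc < -logfc_threshold and p < p_threshold:
            call = "down"
        else:
            call = "ns"
        rows.append(
            {
                "set": name,
                "category": categories.get(name, "other"),
                "logFC": logfc,
                "p": p,
                "call": call,
            }
        )
    return DifferentialResult(pd.DataFrame(rows, columns=["set", "category", "logFC", "p", "call"]))


def updown_summary(
    results: Mapping[str, DifferentialResult],
    categories: Sequence[str] = ("inflammatory", "dna_repair"),
) -> pd.DataFrame:
    """#up - #down gene sets per (RTE group, category) — the radar-plot table.

    ``results`` maps an RTE class/family label (the stratification basis) to
    its differential table.
    """
    rows = []
    for rte_group, res in results.items():
        t = res.table
        for cat in categories:
            sub = t[t["category"] == cat]
            n_up = int((sub["call"] == "up").sum())
            n_down = int((sub["call"] == "down").sum())
            rows.append(
                {
                    "rte_group": rte_group,
                    "category": cat,
                    "n_up": n_up,
                    "n_down": n_down,
                    "up_minus_down": n_up - n_down,
                }
            )
    return pd.DataFrame(rows, columns=["rte_group", "category", "n_up", "n_down", "up_minus_down"])
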