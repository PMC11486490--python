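"""Pseudo-bulk construction and cell-type-resolved RTE contrasts.

Per-cell counts (genes plus RTE class/family features, e.g. scTE output) are
summed into pseudo-bulk profiles per (cell type, sample). RPM normalisation of
a pseudo-bulk profile uses the combined denominator of gene counts plus RTE
*class* counts for that (cell type, sample) — family rows, when present, are
normalised with the same denominator but excluded from it so classes are not
double-counted. Sample-level signature scores are computed from the gene rows
summed over all cells of a sample; samples are then median-split on a signature
score and each (cell type, RTE feature) is contrasted high vs low with the
rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SampleGrouping, p_stars, wilcoxon_compare
from .matrix import SampleMatrix
from .signatures import GeneSignature, SignatureScoreMatrix, score_all
from .taxonomy import DEFAULT_TAXONOMY, RTETaxonomy

logger = logging.getLogger(__name__)


@dataclass
class CellAnnotation:
    """cell_id -> (sample_id, cell_type)."""

    table: pd.DataFrame  # index cell_id; columns sample_id, cell_type

    def __post_init__(self) -> None:
        if not {"sample_id", "cell_type"} <= set(self.table.columns):
            raise ValueError("annotation needs sample_id and cell_type columns")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate cell_id in annotation")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("cell_id")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_id")


def split_features(
    feature_ids: Sequence[str], taxonomy: RTETaxonomy = DEFAULT_TAXONOMY
) -> tuple[list[str], list[str], list[str]]:
    """Partition features into (gene, RTE class, RTE family) name lists."""
    classes = set(taxonomy.classes)
    families = set(taxonomy.families) - classes
    gene_rows, class_rows, family_rows = [], [], []
    for f in feature_ids:
        if f in classes:
            class_rows.append(f)
        elif f in families:
            family_rows.append(f)
        else:
            gene_rows.append(f)
    return gene_rows, class_rows, family_rows


@dataclass
class PseudoBulk:
    """feature x (cell_type, sample) matrix of summed counts or RPM values."""

    data: pd.DataFrame  # columns: MultiIndex (cell_type, sample_id)
    value_kind: str = "counts"
    taxonomy: RTETaxonomy = DEFAULT_TAXONOMY

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(1)))

    def to_tsv(self, path: str | Path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{ct}|{s}" for ct, s in flat.columns]
        flat.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path, value_kind: str = "counts") -> "PseudoBulk":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in df.columns], names=["cell_type", "sample_id"]
        )
        return cls(df, value_kind)


def pseudo_bulk(counts: pd.DataFrame, annotation: CellAnnotation) -> PseudoBulk:
    """Sum per-cell counts into per-(cell type, sample) pseudo-bulk profiles.

    ``counts`` is feature x cell. Cells missing from the annotation are dropped
    with a logged count; an annotation covering no counted cell is an error.
    """
    if annotation.table.empty:
        raise ValueError("empty cell annotation")
    cells = counts.columns
    annotated = [c for c in cells if c in annotation.table.index]
    dropped = len(cells) - len(annotated)
    if dropped:
        logger.warning("%d cells without annotation dropped from pseudo-bulk", dropped)
    if not annotated:
        raise ValueError("no counted cell is annotated")
    ann = annotation.table.loc[annotated]
    key = pd.MultiIndex.from_arrays(
        [ann["cell_type"].to_numpy(), ann["sample_id"].to_numpy()],
        names=["cell_type", "sample_id"],
    )
    pb = counts[annotated].T.groupby(key).sum().T
    pb = pb.sort_index(axis=1)
    if not isinstance(pb.columns, pd.MultiIndex):
        pb.columns = pd.MultiIndex.from_tuples(pb.columns)
    pb.columns = pb.columns.set_names(["cell_type", "sample_id"])
    return PseudoBulk(pb, value_kind="counts")


def combined_rpm(pb: PseudoBulk, taxonomy: RTETaxonomy = DEFAULT_TAXONOMY) -> PseudoBulk:
    """RPM-normalise each (cell type, sample) with the gene + RTE-class denominator.

    Columns with a zero denominator are dropped with a warning.
    """
    gene_rows, class_rows, family_rows = split_features(pb.data.index, taxonomy)
    denom_rows = gene_rows + class_rows
    if not denom_rows:
        raise ValueError("no gene or RTE class rows to build an RPM denominator")
    totals = pb.data.loc[denom_rows].sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        import warnings

        warnings.warn(f"dropping {len(zero)} (cell_type, sample) columns with zero total")
    keep = totals.index[totals > 0]
    rpm = pb.data[keep].div(totals[keep], axis=1) * 1e6
    return PseudoBulk(rpm, value_kind="rpm", taxonomy=taxonomy)


def sample_level_counts(
    counts: pd.DataFrame, annotation: CellAnnotation, genes_only: bool = True,
    taxonomy: RTETaxonomy = DEFAULT_TAXONOMY,
) -> pd.DataFrame:
    """Sum counts over all cells of each sample (genes only by default)."""
    pb = pseudo_bulk(counts, annotation)
    by_sample = pb.data.T.groupby(level="sample_id").sum().T
    if genes_only:
        gene_rows, _, _ = split_features(by_sample.index, taxonomy)
        by_sample = by_sample.loc[gene_rows]
    return by_sample


def pseudobulk_signature_scores(
    counts: pd.DataFrame,
    annotation: CellAnnotation,
    signatures: Sequence[GeneSignature],
    taxonomy: RTETaxonomy = DEFAULT_TAXONOMY,
) -> SignatureScoreMatrix:
    """Sample-level signature scores from summed per-sample gene RPM profiles.

    RTE rows never enter the gene ranking. Scores are rank-based and thus
    invariant to each sample's total count.
    """
    by_sample = sample_level_counts(counts, annotation, genes_only=True, taxonomy=taxonomy)
    rpm = by_sample.div(by_sample.sum(axis=0), axis=1) * 1e6
    return score_all(SampleMatrix(rpm, "rpm"), list(signatures))


def celltype_contrast(
    pb_rpm: PseudoBulk,
    grouping: SampleGrouping,
    features: Sequence[str] | None = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Rank-sum high-vs-low contrast per (cell type, RTE feature).

    ``features`` defaults to the RTE class rows present in the pseudo-bulk.
    Cell types with fewer than ``min_group`` samples in either group are
    skipped with a warning. Raw two-sided p-values are reported with stars.
    """
    if features is None:
        _, class_rows, _ = split_features(pb_rpm.data.index, pb_rpm.taxonomy)
        features = class_rows
    if not features:
        raise ValueError("no RTE features to contrast")
    high = set(grouping.samples("high"))
    low = set(grouping.samples("low"))
    rows = []
    for ct in pb_rpm.cell_types:
        sub = pb_rpm.data[ct]
        h = [s for s in sub.columns if s in high]
        l = [s for s in sub.columns if s in low]
        if len(h) < min_group or len(l) < min_group:
            logger.warning(
                "cell type %s skipped: high=%d, low=%d samples", ct, len(h), len(l)
            )
            continue
        for feat in features:
            if feat not in sub.index:
                continue
            stat, p = wilcoxon_compare(sub.loc[feat, h], sub.loc[feat, l])
            rows.append(
                {
                    "cell_type": ct,
                    "feature": feat,
                    "n_high": len(h),
                    "n_low": len(l),
                    "statistic": stat,
                    "p": p,
                    "stars": p_stars(p),
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_type", "feature", "n_high", "n_low", "statistic", "p", "stars"]
    )


# ---------------------------------------------------------------------------
# IO helpers for per-cell matrices


def read_cell_counts_mtx(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> pd.DataFrame:
    """Read a features x cells count matrix from MatrixMarket + sidecar TSVs."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(features)} features x {len(barcodes)} barcodes"
        )
    return pd.DataFrame(np.asarray(mat), index=features, columns=barcodes)


def write_cell_counts_mtx(
    counts: pd.DataFrame, mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(barcodes_path, sep="\t", header=False, index=False)
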