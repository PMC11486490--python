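"""Rank-based single-sample scoring of gene signatures.

Each sample is scored against a gene set using only the within-sample ranks of
its genes, which makes the score invariant to any monotone transform of that
sample's expression values (log, scaling, normalisation). With n genes ranked
1..n ascending and m signature genes present, the mean rank of the signature
genes is linearly rescaled to [0, 1]:

    score = (meanRank - (m + 1)/2) / ((2n - m + 1)/2 - (m + 1)/2)

so 0 means the signature genes occupy the bottom m ranks and 1 the top m. The
six biological-age-related (BAR) signatures used throughout blood-aging work —
IFN-I, inflammatory cytokines, inflammatory chemokines, inflammaging, SASP and
cellular senescence — are plain (up-direction) gene lists, so only
unidirectional scoring is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .matrix import SampleMatrix

BAR_SIGNATURE_NAMES = (
    "IFN-I",
    "inflammatory_cytokines",
    "inflammatory_chemokines",
    "inflammaging",
    "SASP",
    "senescence",
)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")

    @staticmethod
    def normalise_symbol(symbol: str) -> str:
        return symbol.strip().upper()

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str]) -> "GeneSignature":
        return cls(name, frozenset(cls.normalise_symbol(g) for g in genes if g.strip()))


@dataclass
class SignatureScoreMatrix:
    scores: pd.DataFrame  # signature x sample, values in [0, 1]
    missing_genes: dict[str, list[str]] = field(default_factory=dict)
    n_used: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="signature")

    def missing_report(self) -> pd.DataFrame:
        rows = [
            {"signature": sig, "missing_gene": g}
            for sig, genes in self.missing_genes.items()
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["signature", "missing_gene"])


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    signatures: list[GeneSignature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            signatures.append(GeneSignature.from_genes(name, fields[2:]))
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def rank_genes(matrix: SampleMatrix) -> pd.DataFrame:
    """Sample-wise ascending ranks (1..n), average ranks on ties."""
    if matrix.data.shape[0] < 2:
        raise ValueError("ranking needs at least 2 features")
    return matrix.data.rank(axis=0, method="average", ascending=True)


def single_sample_score(ranks: pd.Series, signature: GeneSignature) -> tuple[float, int]:
    """Score one ranked sample against a signature; returns (score, n_genes_used)."""
    n = len(ranks)
    norm_index = ranks.index.to_series().map(GeneSignature.normalise_symbol)
    mask = norm_index.isin(signature.genes).to_numpy()
    m = int(mask.sum())
    if m == 0:
        raise ValueError(f"no gene of signature {signature.name!r} is present in the matrix")
    if m == n:
        raise ValueError(
            f"signature {signature.name!r} covers every ranked gene; score undefined"
        )
    mean_rank = float(ranks.to_numpy()[mask].mean())
    lo = (m + 1) / 2
    hi = (2 * n - m + 1) / 2
    return (mean_rank - lo) / (hi - lo), m


def score_all(
    matrix: SampleMatrix,
    signatures: Sequence[GeneSignature],
) -> SignatureScoreMatrix:
    """Score every signature on every sample of an expression matrix.

    Genes absent from the matrix are intersected away but recorded per
    signature in the missing-gene report.
    """
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")
    ranks = rank_genes(matrix)
    norm_present = {GeneSignature.normalise_symbol(g) for g in matrix.data.index}
    missing = {
        s.name: sorted(s.genes - norm_present) for s in signatures if s.genes - norm_present
    }
    scores = pd.DataFrame(index=names, columns=matrix.data.columns, dtype=float)
    n_used: dict[str, int] = {}
    for sig in signatures:
        for sample in matrix.data.columns:
            score, m = single_sample_score(ranks[sample], sig)
            scores.loc[sig.name, sample] = score
            n_used[sig.name] = m
    return SignatureScoreMatrix(scores, missing_genes=missing, n_used=n_used)
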