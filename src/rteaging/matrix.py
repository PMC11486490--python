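"""Feature x sample matrices and their TSV serialisation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALUE_KINDS = ("log2_expression", "beta_methylation", "counts", "rpm")


@dataclass
class SampleMatrix:
    """A features-in-rows, samples-in-columns real matrix.

    ``value_kind`` records what the numbers are: log2 array intensities, DNA
    methylation beta values (constrained to [0, 1]), raw counts, or reads per
    million. Validation is applied on construction.
    """

    data: pd.DataFrame
    value_kind: str = "log2_expression"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "beta_methylation":
            vals = self.data.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta_methylation values must lie in [0, 1]")
        if self.value_kind == "counts":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path, index_label: str = "feature_id") -> None:
        self.data.to_csv(path, sep="\t", index_label=index_label)

    @classmethod
    def from_tsv(cls, path: str | Path, value_kind: str = "log2_expression") -> "SampleMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, value_kind)
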