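"""Aggregation of probe- and read-level measurements into RTE class/family scores.

The per-sample score of a repeat class (or family) is the unweighted mean of the
probe values assigned to it; a class therefore pools probes across its families,
so families contributing more probes weigh more. For sequencing data, reads are
counted once against their best-overlap repeat and normalised to reads per
million (RPM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, ProbeAssignment, RepeatRecord
from .matrix import SampleMatrix

logger = logging.getLogger(__name__)

LEVELS = ("class", "family")


@dataclass(frozen=True)
class ReadInterval:
    """A mapped read: a genomic interval plus read id and sample label."""

    read_id: str
    interval: GenomicInterval
    sample_id: str = "sample"


@dataclass
class RTEScoreMatrix:
    """Per-sample aggregated RTE scores at class or family level."""

    scores: pd.DataFrame  # rte label x sample
    level: str
    value_kind: str

    @property
    def rte_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path, index_label: str = "rte_id") -> None:
        self.scores.to_csv(path, sep="\t", index_label=index_label)


def collapse_duplicate_features(matrix: SampleMatrix) -> SampleMatrix:
    """Replace rows sharing a feature id by their per-sample mean.

    Row order follows first occurrence; matrices without duplicates come back
    unchanged.
    """
    if not matrix.data.index.duplicated().any():
        return matrix
    order = matrix.data.index.drop_duplicates()
    collapsed = matrix.data.groupby(level=0, sort=False).mean().loc[order]
    return SampleMatrix(collapsed, matrix.value_kind)


def _group_label(assignment: ProbeAssignment, level: str) -> str:
    if level == "class":
        return assignment.repeat_class
    if level == "family":
        return assignment.repeat_family
    raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def aggregate_rte_scores(
    matrix: SampleMatrix,
    assignments: Sequence[ProbeAssignment],
    level: str = "class",
    expected_groups: Sequence[str] | None = None,
) -> RTEScoreMatrix:
    """Mean probe value per RTE class or family, per sample.

    Assigned probes absent from the matrix are logged and skipped; expected
    groups (e.g. every taxonomy family) left without any probe are absent from
    the output, with a warning naming them.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    groups: dict[str, list[str]] = {}
    missing: list[str] = []
    for a in assignments:
        if a.probe_id in matrix.data.index:
            groups.setdefault(_group_label(a, level), []).append(a.probe_id)
        else:
            missing.append(a.probe_id)
    if missing:
        logger.warning(
            "%d assigned probes absent from the matrix and skipped (first: %s)",
            len(missing),
            missing[0],
        )
    if not groups:
        raise ValueError("no assigned probe is present in the matrix")
    if expected_groups is not None:
        empty = [g for g in expected_groups if g not in groups]
        if empty:
            warnings.warn(f"RTE groups without probes dropped: {sorted(empty)}")
    rows = {g: matrix.data.loc[probes].mean(axis=0) for g, probes in groups.items() if probes}
    scores = pd.DataFrame(rows).T
    scores = scores.loc[sorted(scores.index)]
    scores.columns = matrix.data.columns
    return RTEScoreMatrix(scores, level=level, value_kind=matrix.value_kind)


def count_reads_in_repeats(
    reads: Sequence[ReadInterval],
    repeats: Sequence[RepeatRecord],
    level: str = "class",
) -> SampleMatrix:
    """Count reads per RTE group per sample, each read at most once.

    A read is credited to its best-overlap repeat with the same tie-break as
    probe assignment (max overlap, then leftmost repeat start, then repeat
    name), so nested or adjacent repeats never double-count a read.
    """
    from .annotation import ProbeRecord, assign_probes_to_repeats

    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    pseudo_probes = [
        ProbeRecord(f"{i}\t{r.read_id}", r.interval, "intergenic") for i, r in enumerate(reads)
    ]
    assigned = assign_probes_to_repeats(pseudo_probes, repeats, contexts_allowed={"intergenic"})
    samples = sorted({r.sample_id for r in reads})
    counts: dict[tuple[str, str], int] = {}
    for a in assigned:
        idx = int(a.probe_id.split("\t", 1)[0])
        sample = reads[idx].sample_id
        counts[(_group_label(a, level), sample)] = counts.get((_group_label(a, level), sample), 0) + 1
    labels = sorted({g for g, _ in counts})
    mat = pd.DataFrame(0, index=labels, columns=samples, dtype=int)
    for (g, s), c in counts.items():
        mat.loc[g, s] = c
    return SampleMatrix(mat, "counts")


def rpm_normalize(
    counts: SampleMatrix,
    totals: pd.Series | dict | None = None,
) -> SampleMatrix:
    """Reads-per-million scaling: value(f, s) = 1e6 * count(f, s) / total(s).

    With the default column-total denominator every sample column sums to 1e6
    exactly; a provided per-sample total (e.g. library size including features
    not in the matrix) is used verbatim.
    """
    if totals is None:
        tot = counts.data.sum(axis=0)
    else:
        tot = pd.Series(totals).reindex(counts.data.columns)
    bad = tot.index[(~np.isfinite(tot.to_numpy(dtype=float))) | (tot.to_numpy(dtype=float) <= 0)]
    if len(bad):
        raise ValueError(f"non-positive RPM denominator for sample(s): {list(bad)}")
    rpm = counts.data.div(tot, axis=1) * 1e6
    return SampleMatrix(rpm, "rpm")
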