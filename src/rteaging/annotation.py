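"""Genome annotation parsing and probe-to-repeat assignment.

Microarray probes are fixed genomic intervals. To quantify retrotransposon (RTE)
expression or methylation from an array, each probe falling in a noncoding
(intergenic or intronic) region is assigned to the single repeat it overlaps best;
per-class and per-family scores are then aggregated downstream from the probe
values. All coordinates are held internally as 0-based half-open intervals;
RepeatMasker ``.out`` (1-based inclusive) and GTF are converted on read, BED is
passed through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Published probe counts for the Illumina HumanHT-12 expression arrays: the V3 and
# V4 manifests share almost the whole V3 probe list, which is why analyses can be
# run against the V4 manifest regardless of which array version a cohort used.
HT12_V3_N_PROBES = 29431
HT12_V4_N_PROBES = 33963
HT12_V3_V4_SHARED = 29311

CONTEXTS = ("intergenic", "intronic", "exonic", "unknown")


def percent_shared(shared: int, reference: int) -> float:
    """Percentage of a reference probe list covered by a shared subset."""
    if reference <= 0:
        raise ValueError("reference count must be positive")
    if not 0 <= shared <= reference:
        raise ValueError("shared count must lie in [0, reference]")
    return 100.0 * shared / reference


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    interval: GenomicInterval
    context: str = "unknown"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")

    def with_context(self, context: str) -> "ProbeRecord":
        return ProbeRecord(self.probe_id, self.interval, context)


@dataclass(frozen=True)
class ProbeAssignment:
    probe_id: str
    repeat_name: str
    repeat_class: str
    repeat_family: str
    overlap_bp: int
    context: str = "unknown"
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene body of {self.gene_id}")


@dataclass
class GeneModel:
    """Collection of gene bodies with exon structure, indexed for overlap queries."""

    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g.gene_id
            )
            for ex in g.exons:
                self._exon_trees.setdefault(ex.chrom, IntervalTree()).addi(
                    ex.start, ex.end, g.gene_id
                )

    def overlaps_exon(self, iv: GenomicInterval) -> bool:
        tree = self._exon_trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def overlaps_gene_body(self, iv: GenomicInterval) -> bool:
        tree = self._gene_trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines, carrying the 1-based line number."""


# ---------------------------------------------------------------------------
# readers


def _split_class_family(class_family: str) -> tuple[str, str]:
    # RepeatMasker writes e.g. "SINE/Alu" or bare "Satellite"; subclasses like
    # "LINE/L1" keep only the leading token of each side.
    if "/" in class_family:
        cls, fam = class_family.split("/", 1)
    else:
        cls, fam = class_family, class_family
    return cls, fam


def parse_repeatmasker(path: str | Path, format: str = "rmsk_out") -> list[RepeatRecord]:
    """Read repeat intervals from RepeatMasker ``.out`` or BED.

    ``rmsk_out`` coordinates are 1-based inclusive and converted to 0-based
    half-open; the three banner/header lines at the top of the file are skipped.
    BED repeats carry the taxonomy either in columns 7-8 (class, family) or in
    the name field as ``name#class/family``.
    """
    path = Path(path)
    if format == "rmsk_out":
        return _parse_rmsk_out(path)
    if format == "bed":
        return _parse_repeat_bed(path)
    raise ValueError(f"unknown repeat annotation format {format!r}")


def _parse_rmsk_out(path: Path) -> list[RepeatRecord]:
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            # the two header lines start with "SW" / "score"
            if fields[0] in ("SW", "score"):
                continue
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else fields[8]
                name = fields[9]
                cls, fam = _split_class_family(fields[10])
                records.append(
                    RepeatRecord(GenomicInterval(chrom, start, end, strand), name, cls, fam)
                )
            except (IndexError, ValueError) as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: malformed RepeatMasker line: {exc}"
                ) from exc
    return records


def _parse_repeat_bed(path: Path) -> list[RepeatRecord]:
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "."
                if len(fields) > 7:
                    cls, fam = fields[6], fields[7]
                elif "#" in name:
                    name, class_family = name.split("#", 1)
                    cls, fam = _split_class_family(class_family)
                else:
                    raise ValueError("no class/family annotation on BED repeat")
                records.append(
                    RepeatRecord(GenomicInterval(chrom, start, end, strand), name, cls, fam)
                )
            except (IndexError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return records


def read_probe_manifest(path: str | Path) -> list[ProbeRecord]:
    """Read a probe manifest TSV (probe_id, chrom, start, end[, strand], BED-style)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationParseError(f"{path}: probe manifest lacks columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise AnnotationParseError(f"{path}: duplicate probe_id {dup!r}")
    probes = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", ".")
        probes.append(
            ProbeRecord(row.probe_id, GenomicInterval(row.chrom, int(row.start), int(row.end), strand))
        )
    return probes


def read_gene_models(path: str | Path) -> GeneModel:
    """Read gene/exon features from a GTF (via pyranges) or BED12 file."""
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12_genes(path)
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    genes: list[GeneRecord] = []
    for gene_id, sub in gr.groupby("gene_id", sort=False):
        exons = sub[sub["Feature"] == "exon"]
        body = sub[sub["Feature"] == "gene"]
        if body.empty:
            start, end = int(exons["Start"].min()), int(exons["End"].max())
            chrom = str(exons["Chromosome"].iloc[0])
            strand = str(exons["Strand"].iloc[0]) if "Strand" in exons else "."
        else:
            start, end = int(body["Start"].iloc[0]), int(body["End"].iloc[0])
            chrom = str(body["Chromosome"].iloc[0])
            strand = str(body["Strand"].iloc[0]) if "Strand" in body else "."
        if exons.empty:  # gene feature only: treat the body as one exon-less intron host
            exon_ivs = (GenomicInterval(chrom, start, end, strand),)
        else:
            exon_ivs = tuple(
                GenomicInterval(chrom, int(r.Start), int(r.End), strand)
                for r in exons.itertuples(index=False)
            )
        genes.append(GeneRecord(str(gene_id), GenomicInterval(chrom, start, end, strand), exon_ivs))
    return GeneModel(genes)


def _read_bed12_genes(path: Path) -> GeneModel:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if len(f) > 5 else "."
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                    exons = tuple(
                        GenomicInterval(chrom, start + off, start + off + size, strand)
                        for off, size in zip(offsets, sizes)
                    )
                else:
                    exons = (GenomicInterval(chrom, start, end, strand),)
                genes.append(GeneRecord(name, GenomicInterval(chrom, start, end, strand), exons))
            except (IndexError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed BED12 line: {exc}") from exc
    return GeneModel(genes)


# ---------------------------------------------------------------------------
# context classification and assignment


def classify_probe_context(probe: ProbeRecord, genes: GeneModel) -> str:
    """Label a probe exonic / intronic / intergenic against a gene model.

    A single bp of exon overlap makes a probe exonic (and hence excluded from
    RTE quantification); probes inside a gene body but clear of exons are
    intronic; everything else — including probes on chromosomes absent from the
    model, or an empty model — is intergenic.
    """
    if genes.overlaps_exon(probe.interval):
        return "exonic"
    if genes.overlaps_gene_body(probe.interval):
        return "intronic"
    return "intergenic"


def annotate_probe_contexts(probes: Iterable[ProbeRecord], genes: GeneModel) -> list[ProbeRecord]:
    return [p.with_context(classify_probe_context(p, genes)) for p in probes]


DEFAULT_CONTEXTS_ALLOWED = frozenset({"intergenic", "intronic"})


def assign_probes_to_repeats(
    probes: Sequence[ProbeRecord],
    repeats: Sequence[RepeatRecord],
    contexts_allowed: Iterable[str] = DEFAULT_CONTEXTS_ALLOWED,
) -> list[ProbeAssignment]:
    """Assign each noncoding probe to the repeat it overlaps best.

    Only probes whose context is in ``contexts_allowed`` and that overlap at
    least one repeat by >= 1 bp are assigned; each probe maps to exactly one
    repeat (largest overlap, ties broken by leftmost repeat start then
    lexicographic repeat name) so downstream class scores never double-count a
    probe. Strand is ignored. The result is sorted by probe_id.
    """
    contexts_allowed = frozenset(contexts_allowed)
    trees: dict[str, IntervalTree] = {}
    for idx, rep in enumerate(repeats):
        trees.setdefault(rep.interval.chrom, IntervalTree()).addi(
            rep.interval.start, rep.interval.end, idx
        )
    assignments: list[ProbeAssignment] = []
    for probe in probes:
        if probe.context not in contexts_allowed:
            continue
        tree = trees.get(probe.interval.chrom)
        if tree is None:
            continue
        hits = tree.overlap(probe.interval.start, probe.interval.end)
        best: tuple[int, int, str] | None = None  # (-overlap, start, name) minimised
        best_idx = -1
        for hit in hits:
            rep = repeats[hit.data]
            ov = probe.interval.overlap(rep.interval)
            if ov < 1:
                continue
            key = (-ov, rep.interval.start, rep.repeat_name)
            if best is None or key < best:
                best, best_idx = key, hit.data
        if best is not None:
            rep = repeats[best_idx]
            assignments.append(
                ProbeAssignment(
                    probe_id=probe.probe_id,
                    repeat_name=rep.repeat_name,
                    repeat_class=rep.repeat_class,
                    repeat_family=rep.repeat_family,
                    overlap_bp=-best[0],
                    context=probe.context,
                    interval=probe.interval,
                )
            )
    assignments.sort(key=lambda a: a.probe_id)
    return assignments


# ---------------------------------------------------------------------------
# writers


def assignments_to_frame(assignments: Sequence[ProbeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in assignments],
            "repeat_name": [a.repeat_name for a in assignments],
            "repeat_class": [a.repeat_class for a in assignments],
            "repeat_family": [a.repeat_family for a in assignments],
            "overlap_bp": [a.overlap_bp for a in assignments],
            "context": [a.context for a in assignments],
        }
    )


def write_assignments_tsv(assignments: Sequence[ProbeAssignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> list[ProbeAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return [
        ProbeAssignment(
            probe_id=r.probe_id,
            repeat_name=r.repeat_name,
            repeat_class=r.repeat_class,
            repeat_family=r.repeat_family,
            overlap_bp=int(r.overlap_bp),
            context=r.context,
        )
        for r in df.itertuples(index=False)
    ]


def write_assigned_probes_bed(assignments: Sequence[ProbeAssignment], path: str | Path) -> None:
    """BED6 of assigned probes; requires assignments built with probe intervals."""
    with open(path, "w") as fh:
        for a in assignments:
            if a.interval is None:
                raise ValueError(f"assignment for {a.probe_id} carries no interval")
            iv = a.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.probe_id}\t{a.overlap_bp}\t{iv.strand}\n")


def read_probes_bed(path: str | Path) -> list[ProbeRecord]:
    probes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "."
            probes.append(ProbeRecord(f[3], GenomicInterval(f[0], int(f[1]), int(f[2]), strand)))
    return probes
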