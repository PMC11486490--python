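"""Seeded synthetic cohorts with the statistical structure of blood-aging data.

The generators emulate the structure the analysis is built to detect, with a
latent "biological age" factor B per sample that is *independent of
chronological age*:

* expression cohorts: signature-gene expression loads on B; RTE probe
  expression loads on B with positive coefficients for LINE/LTR probes and a
  negative one for SINE probes (PBMC mode) or positive (monocyte mode); age
  itself has no expression effect by default;
* methylation cohorts: probe beta values decline linearly with chronological
  age in every repeat class, with expression anti-coupled to methylation for
  LINE/LTR probes and decoupled for SINE probes;
* single-cell cohorts: negative-binomial counts per cell with one planted
  (cell type x RTE class) fold change in high-B samples only (plasma cells by
  default).

Every generator is a pure function of its config (fixed seed => byte-identical
output) and returns a ground-truth record sufficient to predict the planted
correlations analytically: for a score loading b on B with residual sd s, the
expected Pearson r against B is b / sqrt(b^2 + s^2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneRecord, GenomicInterval, ProbeRecord, RepeatRecord
from .matrix import SampleMatrix
from .signatures import BAR_SIGNATURE_NAMES, GeneSignature, write_gmt
from .single_cell import CellAnnotation
from .taxonomy import DEFAULT_TAXONOMY, RTETaxonomy

MODELLED_FAMILIES = ("L1", "L2", "Alu", "MIR", "ERV1", "ERVL", "ERVL-MaLR", "ERVK", "Satellite")

PBMC_BETA_BAR = {"LINE": 0.9, "LTR": 0.9, "SINE": -0.7, "Satellite": 0.0}
MONOCYTE_BETA_BAR = {"LINE": 0.9, "LTR": 0.9, "SINE": 0.7, "Satellite": 0.0}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohorts.

    Defaults describe a PBMC-like microarray cohort of 600 samples aged 15-101
    with a standard-normal latent biological-age factor, unit-sd log-intensity
    noise, four probes per modelled repeat family, and methylation declining by
    0.002 beta units per year of age.
    """

    seed: int = 0
    # cohort-level expression
    n_samples: int = 600
    age_range: tuple[int, int] = (15, 101)
    cohort_mode: str = "pbmc"  # or "monocyte": flips the SINE-B coupling sign
    n_background_genes: int = 1500
    genes_per_signature: int = 15
    signature_loading: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    probes_per_family: int = 4
    beta_bar: dict[str, float] | None = None  # per-class coupling to B
    beta_age_expr: float = 0.0
    # methylation
    meth_baseline: float = 0.6
    beta_age_meth: float = -0.002  # beta units per year, every RTE class
    meth_noise_sd: float = 0.04
    meth_expr_coupling: float = 1.0  # LINE/LTR expression per -1 sd of methylation
    # single cell
    sc_cell_types: tuple[str, ...] = ("Plasma", "NK", "BC", "TC", "M14")
    sc_n_samples: int = 16
    sc_cells_per_type: int = 25
    sc_n_genes: int = 300
    sc_gene_rate_log_mean: float = 2.0  # lognormal mean rate ~ e^2 ~ 7.4 counts/gene/cell
    sc_genes_per_signature: int = 10
    sc_planted_shifts: dict[tuple[str, str], float] | None = None  # (cell_type, class) -> fold
    sc_signature_fold: float = 1.6
    sc_nb_size: float = 10.0
    sc_base_rte_rate: float = 30.0

    def resolved_beta_bar(self) -> dict[str, float]:
        if self.beta_bar is not None:
            return dict(self.beta_bar)
        return dict(PBMC_BETA_BAR if self.cohort_mode == "pbmc" else MONOCYTE_BETA_BAR)

    def resolved_shifts(self) -> dict[tuple[str, str], float]:
        if self.sc_planted_shifts is not None:
            return dict(self.sc_planted_shifts)
        return {("Plasma", "LINE"): 3.0}


@dataclass
class GroundTruth:
    """Planted quantities written alongside every synthetic dataset."""

    seed: int
    ages: dict[str, float] = field(default_factory=dict)
    latent: dict[str, float] = field(default_factory=dict)  # biological-age factor B
    beta_bar: dict[str, float] = field(default_factory=dict)
    beta_age_meth: dict[str, float] = field(default_factory=dict)
    probe_map: dict[str, dict[str, str]] = field(default_factory=dict)  # probe -> truth labels
    sc_group: dict[str, str] = field(default_factory=dict)  # sample -> high/low latent group
    planted_shifts: dict[str, float] = field(default_factory=dict)  # "cell_type|class" -> fold

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def expected_r(self, loading: float, residual_sd: float, sigma_b: float = 1.0) -> float:
        return loading * sigma_b / np.sqrt(loading**2 * sigma_b**2 + residual_sd**2)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class SyntheticAnnotation:
    genes: GeneModel
    repeats: list[RepeatRecord]
    probes: list[ProbeRecord]
    truth: GroundTruth

    def probe_ids_for_family(self, family: str) -> list[str]:
        return [
            pid
            for pid, info in self.truth.probe_map.items()
            if info["repeat_family"] == family and info["assignable"] == "yes"
        ]


def simulate_annotation(
    config: SyntheticConfig, taxonomy: RTETaxonomy = DEFAULT_TAXONOMY
) -> SyntheticAnnotation:
    """Deterministic genome layout with probes of known context and repeat truth.

    Each modelled family receives ``probes_per_family`` assignable probes,
    alternating intronic and intergenic placement, plus one exonic decoy probe
    (overlapping a repeat, but excluded by the noncoding filter) and one
    intergenic probe overlapping no repeat. Regions never overlap, so every
    truth label is unambiguous.
    """
    if config.probes_per_family < 1:
        raise ValueError("probes_per_family must be >= 1 for every modelled family")
    genes: list[GeneRecord] = []
    repeats: list[RepeatRecord] = []
    probes: list[ProbeRecord] = []
    truth = GroundTruth(seed=config.seed)
    chrom = "chr1"
    cursor = 10_000

    def add_probe(pid: str, start: int, end: int, context: str, family: str | None, assignable: bool) -> None:
        probes.append(ProbeRecord(pid, GenomicInterval(chrom, start, end, "+")))
        truth.probe_map[pid] = {
            "context": context,
            "repeat_family": family or "",
            "repeat_class": (taxonomy.family_to_class(family) or "") if family else "",
            "assignable": "yes" if assignable else "no",
        }

    for family in MODELLED_FAMILIES:
        cls = taxonomy.family_to_class(family) or "Other"
        for j in range(config.probes_per_family):
            pid = f"probe_{family}_{j:02d}"
            rep_name = f"{family}sim{j}"
            if j % 2 == 0:  # intronic placement inside a host gene
                g_start, g_end = cursor, cursor + 3000
                exons = (
                    GenomicInterval(chrom, g_start, g_start + 200, "+"),
                    GenomicInterval(chrom, g_end - 200, g_end, "+"),
                )
                genes.append(
                    GeneRecord(f"GENE_{family}_{j}", GenomicInterval(chrom, g_start, g_end, "+"), exons)
                )
                rep_iv = GenomicInterval(chrom, g_start + 1000, g_start + 1300, "+")
                repeats.append(RepeatRecord(rep_iv, rep_name, cls, family))
                add_probe(pid, g_start + 1050, g_start + 1100, "intronic", family, True)
                cursor += 4000
            else:  # intergenic placement
                rep_iv = GenomicInterval(chrom, cursor, cursor + 300, "+")
                repeats.append(RepeatRecord(rep_iv, rep_name, cls, family))
                add_probe(pid, cursor + 50, cursor + 100, "intergenic", family, True)
                cursor += 1000
        # exonic decoy: probe over a repeat inside an exon -> filtered out
        g_start, g_end = cursor, cursor + 1000
        genes.append(
            GeneRecord(
                f"GENE_decoy_{family}",
                GenomicInterval(chrom, g_start, g_end, "+"),
                (GenomicInterval(chrom, g_start, g_end, "+"),),
            )
        )
        repeats.append(
            RepeatRecord(GenomicInterval(chrom, g_start + 100, g_start + 400, "+"), f"{family}simX", cls, family)
        )
        add_probe(f"probe_{family}_exonic", g_start + 150, g_start + 200, "exonic", family, False)
        cursor += 2000
        # intergenic probe with no repeat underneath
        add_probe(f"probe_{family}_norepeat", cursor + 50, cursor + 100, "intergenic", None, False)
        cursor += 1000

    truth.beta_bar = config.resolved_beta_bar()
    return SyntheticAnnotation(GeneModel(genes), repeats, probes, truth)


def write_annotation_files(ann: SyntheticAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Write repeats (BED), genes (GTF), probe manifest (TSV) and truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "repeats_bed": outdir / "repeats.bed",
        "genes_gtf": outdir / "genes.gtf",
        "probes_tsv": outdir / "probes.tsv",
        "truth_json": outdir / "annotation_truth.json",
    }
    with open(paths["repeats_bed"], "w") as fh:
        for r in ann.repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_name}#{r.repeat_class}/{r.repeat_family}\t0\t{iv.strand}\n"
            )
    with open(paths["genes_gtf"], "w") as fh:
        for g in ann.genes.genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\tsynthetic\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tsynthetic\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n"
                )
    with open(paths["probes_tsv"], "w") as fh:
        fh.write("probe_id\tchrom\tstart\tend\tstrand\n")
        for p in ann.probes:
            iv = p.interval
            fh.write(f"{p.probe_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
    ann.truth.to_json(paths["truth_json"])
    return paths


# ---------------------------------------------------------------------------
# expression cohort


def make_bar_signatures(config: SyntheticConfig, n_genes: int | None = None) -> list[GeneSignature]:
    """Six synthetic biological-age signatures with deterministic gene symbols."""
    n = n_genes if n_genes is not None else config.genes_per_signature
    return [
        GeneSignature.from_genes(name, [f"{name.upper().replace('-', '')}_G{i:02d}" for i in range(n)])
        for name in BAR_SIGNATURE_NAMES
    ]


@dataclass
class ExpressionCohort:
    matrix: SampleMatrix
    ages: pd.Series
    signatures: list[GeneSignature]
    truth: GroundTruth


def simulate_expression_cohort(
    config: SyntheticConfig, taxonomy: RTETaxonomy = DEFAULT_TAXONOMY
) -> ExpressionCohort:
    """Microarray-like log-intensity cohort with a planted latent structure.

    The latent biological-age factor B is standard normal and independent of
    chronological age, so RTE-age correlations are null by construction while
    RTE-signature correlations follow the per-class couplings.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    ages = pd.Series(
        rng.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(float),
        index=samples,
        name="age",
    )
    latent = rng.standard_normal(n)
    betas = config.resolved_beta_bar()
    annotation = simulate_annotation(config, taxonomy)

    signatures = make_bar_signatures(config)
    sig_genes = [g for s in signatures for g in sorted(s.genes)]
    bg_genes = [f"BG_G{i:05d}" for i in range(config.n_background_genes)]
    probe_ids = [p.probe_id for p in annotation.probes]
    features = bg_genes + sig_genes + probe_ids

    base = rng.normal(config.baseline_mean, config.baseline_sd, size=len(features))
    X = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(features), n))
    idx = {f: i for i, f in enumerate(features)}
    for g in sig_genes:
        X[idx[g]] += config.signature_loading * latent
    for pid in probe_ids:
        info = annotation.truth.probe_map[pid]
        if info["assignable"] == "yes":
            beta = betas.get(info["repeat_class"], 0.0)
            X[idx[pid]] += beta * latent
    if config.beta_age_expr != 0.0:
        X += config.beta_age_expr * (ages.to_numpy() - ages.mean())[None, :]

    truth = GroundTruth(
        seed=config.seed,
        ages=dict(zip(samples, ages.astype(float))),
        latent=dict(zip(samples, latent.astype(float))),
        beta_bar=betas,
        probe_map=annotation.truth.probe_map,
    )
    matrix = SampleMatrix(pd.DataFrame(X, index=features, columns=samples), "log2_expression")
    return ExpressionCohort(matrix, ages, signatures, truth)


# ---------------------------------------------------------------------------
# methylation cohort


@dataclass
class MethylationCohort:
    betas: SampleMatrix
    matched_expression: SampleMatrix
    ages: pd.Series
    truth: GroundTruth


def simulate_methylation_cohort(
    config: SyntheticConfig, taxonomy: RTETaxonomy = DEFAULT_TAXONOMY
) -> MethylationCohort:
    """Beta-value cohort declining with age, with matched expression.

    beta(probe, s) = clip(b0_probe + slope * age_s + noise, 0, 1); the slope is
    negative for every repeat class by default. Matched expression for LINE and
    LTR probes is anti-coupled to their methylation; SINE and control probes
    get independent expression (the decoupling the methylation-vs-expression
    contrast should recover).
    """
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    ages = pd.Series(
        rng.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(float),
        index=samples,
        name="age",
    )
    age_centered = ages.to_numpy() - np.mean(config.age_range)
    annotation = simulate_annotation(config, taxonomy)
    probe_ids = [
        pid for pid, info in annotation.truth.probe_map.items() if info["assignable"] == "yes"
    ]
    b0 = config.meth_baseline + rng.normal(0.0, 0.05, size=len(probe_ids))
    slopes = np.full(len(probe_ids), config.beta_age_meth)
    noise = rng.normal(0.0, config.meth_noise_sd, size=(len(probe_ids), n))
    raw = b0[:, None] + slopes[:, None] * age_centered[None, :] + noise
    betas = np.clip(raw, 0.0, 1.0)

    # matched expression: anti-coupled to methylation for LINE/LTR, decoupled else
    expr = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=(len(probe_ids), n))
    meth_z = (raw - raw.mean(axis=1, keepdims=True)) / config.meth_noise_sd
    for i, pid in enumerate(probe_ids):
        cls = annotation.truth.probe_map[pid]["repeat_class"]
        if cls in ("LINE", "LTR"):
            expr[i] -= config.meth_expr_coupling * meth_z[i] * 0.5

    truth = GroundTruth(
        seed=config.seed,
        ages=dict(zip(samples, ages.astype(float))),
        beta_age_meth={cls: config.beta_age_meth for cls in taxonomy.classes},
        probe_map=annotation.truth.probe_map,
    )
    return MethylationCohort(
        SampleMatrix(pd.DataFrame(betas, index=probe_ids, columns=samples), "beta_methylation"),
        SampleMatrix(pd.DataFrame(expr, index=probe_ids, columns=samples), "log2_expression"),
        ages,
        truth,
    )


# ---------------------------------------------------------------------------
# single cell


@dataclass
class SingleCellCohort:
    counts: pd.DataFrame  # features x cells, integer counts
    annotation: CellAnnotation
    signatures: list[GeneSignature]
    truth: GroundTruth


def simulate_single_cell(
    config: SyntheticConfig, taxonomy: RTETaxonomy = DEFAULT_TAXONOMY
) -> SingleCellCohort:
    """Negative-binomial per-cell counts with one planted cell-type RTE effect.

    Half the samples carry a high latent biological-age state: their signature
    genes are scaled by ``sc_signature_fold`` in every cell (so the sample-level
    signature median split recovers the groups), and the configured (cell type,
    RTE class) rates are multiplied by the planted fold in those samples only.
    """
    if len(config.sc_cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if config.sc_n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng([config.seed, 3])
    samples = [f"SC{i + 1:03d}" for i in range(config.sc_n_samples)]
    high = set(rng.permutation(samples)[: config.sc_n_samples // 2])
    shifts = config.resolved_shifts()

    signatures = make_bar_signatures(config, n_genes=config.sc_genes_per_signature)
    sig_genes = [g for s in signatures for g in sorted(s.genes)]
    n_bg = max(0, config.sc_n_genes - len(sig_genes))
    genes = [f"SCBG_G{i:04d}" for i in range(n_bg)] + sig_genes
    classes = [c for c in taxonomy.classes if c != "Satellite"]
    features = genes + classes

    base_rate = rng.lognormal(mean=config.sc_gene_rate_log_mean, sigma=0.8, size=len(genes))
    ct_factor = {
        ct: rng.lognormal(mean=0.0, sigma=0.15, size=len(genes)) for ct in config.sc_cell_types
    }

    cell_ids, cell_samples, cell_types = [], [], []
    mu_cols = []
    for s in samples:
        is_high = s in high
        for ct in config.sc_cell_types:
            for k in range(config.sc_cells_per_type):
                cell_ids.append(f"{s}_{ct}_{k:03d}")
                cell_samples.append(s)
                cell_types.append(ct)
                mu_genes = base_rate * ct_factor[ct]
                if is_high:
                    # scale signature genes up but keep the expected total gene
                    # output per cell unchanged, so RTE RPM values are not
                    # confounded by library composition
                    mu_genes = mu_genes.copy()
                    total = mu_genes.sum()
                    sig_slice = slice(n_bg, len(genes))
                    mu_genes[sig_slice] *= config.sc_signature_fold
                    mu_genes *= total / mu_genes.sum()
                mu_rte = np.full(len(classes), config.sc_base_rte_rate, dtype=float)
                if is_high:
                    for ci, cls in enumerate(classes):
                        fold = shifts.get((ct, cls))
                        if fold is not None:
                            mu_rte[ci] *= fold
                mu_cols.append(np.concatenate([mu_genes, mu_rte]))
    mu = np.column_stack(mu_cols)
    r = config.sc_nb_size
    counts = rng.negative_binomial(r, r / (r + mu))

    ann = CellAnnotation(
        pd.DataFrame({"sample_id": cell_samples, "cell_type": cell_types}, index=pd.Index(cell_ids, name="cell_id"))
    )
    truth = GroundTruth(
        seed=config.seed,
        sc_group={s: ("high" if s in high else "low") for s in samples},
        planted_shifts={f"{ct}|{cls}": fold for (ct, cls), fold in shifts.items()},
    )
    return SingleCellCohort(
        pd.DataFrame(counts, index=features, columns=cell_ids), ann, signatures, truth
    )


# ---------------------------------------------------------------------------
# fixture bundles


def make_enrichment_sets(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Inflammatory + DNA-repair gene-set collections over the cohort's genes.

    Inflammatory sets draw from the signature genes (coupled to the latent
    factor), DNA-repair sets from background genes, so high-vs-low contrasts
    have signal to find.
    """
    from .enrichment import GeneSetCollection

    rng = rng or np.random.default_rng([config.seed, 4])
    signatures = make_bar_signatures(config)
    sig_genes = [g for s in signatures for g in sorted(s.genes)]
    bg_genes = [f"BG_G{i:05d}" for i in range(config.n_background_genes)]
    sets, categories = [], {}
    for i in range(6):
        name = f"SYN_INFLAMMATORY_RESPONSE_{i:02d}"
        sets.append(GeneSignature.from_genes(name, rng.choice(sig_genes, size=12, replace=False)))
        categories[name] = "inflammatory"
    for i in range(5):
        name = f"SYN_DNA_REPAIR_{i:02d}"
        sets.append(GeneSignature.from_genes(name, rng.choice(bg_genes, size=12, replace=False)))
        categories[name] = "dna_repair"
    return GeneSetCollection(sets, categories)


def write_fixture_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic fixture (annotation, cohorts, gene sets, truth)."""
    from .single_cell import write_cell_counts_mtx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(config)
    paths = write_annotation_files(ann, outdir)

    expr = simulate_expression_cohort(config)
    paths["expression_tsv"] = outdir / "expression.tsv"
    expr.matrix.to_tsv(paths["expression_tsv"])
    paths["ages_tsv"] = outdir / "samples.tsv"
    expr.ages.rename_axis("sample_id").reset_index().to_csv(paths["ages_tsv"], sep="\t", index=False)
    paths["signatures_gmt"] = outdir / "bar_signatures.gmt"
    write_gmt(expr.signatures, paths["signatures_gmt"])
    paths["expression_truth_json"] = outdir / "expression_truth.json"
    expr.truth.to_json(paths["expression_truth_json"])

    meth = simulate_methylation_cohort(config)
    paths["methylation_tsv"] = outdir / "methylation.tsv"
    meth.betas.to_tsv(paths["methylation_tsv"])
    paths["methylation_expression_tsv"] = outdir / "methylation_matched_expression.tsv"
    meth.matched_expression.to_tsv(paths["methylation_expression_tsv"])
    paths["methylation_ages_tsv"] = outdir / "methylation_samples.tsv"
    meth.ages.rename_axis("sample_id").reset_index().to_csv(
        paths["methylation_ages_tsv"], sep="\t", index=False
    )
    paths["methylation_truth_json"] = outdir / "methylation_truth.json"
    meth.truth.to_json(paths["methylation_truth_json"])

    coll = make_enrichment_sets(config)
    paths["enrichment_gmt"] = outdir / "enrichment_sets.gmt"
    write_gmt(coll.sets, paths["enrichment_gmt"])
    paths["enrichment_categories_tsv"] = outdir / "enrichment_categories.tsv"
    pd.DataFrame(
        [(k, v) for k, v in coll.categories.items()], columns=["set_name", "category"]
    ).to_csv(paths["enrichment_categories_tsv"], sep="\t", index=False)

    sc = simulate_single_cell(config)
    paths["sc_mtx"] = outdir / "sc_counts.mtx"
    paths["sc_features"] = outdir / "sc_features.tsv"
    paths["sc_barcodes"] = outdir / "sc_barcodes.tsv"
    write_cell_counts_mtx(sc.counts, paths["sc_mtx"], paths["sc_features"], paths["sc_barcodes"])
    paths["sc_annotation_tsv"] = outdir / "sc_annotation.tsv"
    sc.annotation.to_tsv(paths["sc_annotation_tsv"])
    paths["sc_signatures_gmt"] = outdir / "sc_bar_signatures.gmt"
    write_gmt(sc.signatures, paths["sc_signatures_gmt"])
    paths["sc_truth_json"] = outdir / "sc_truth.json"
    sc.truth.to_json(paths["sc_truth_json"])
    return paths
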