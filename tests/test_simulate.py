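"""Synthetic-cohort generators: determinism, truth recovery, planted structure."""

import json

import numpy as np
import pandas as pd
import pytest

from rteaging.annotation import (
    annotate_probe_contexts,
    assign_probes_to_repeats,
    parse_repeatmasker,
    read_gene_models,
    read_probe_manifest,
)
from rteaging.cohort import pearson
from rteaging.quantification import aggregate_rte_scores
from rteaging.signatures import score_all
from rteaging.simulate import (
    GroundTruth,
    SyntheticConfig,
    simulate_annotation,
    simulate_expression_cohort,
    simulate_methylation_cohort,
    simulate_single_cell,
    write_annotation_files,
    write_fixture_bundle,
)

SMALL = SyntheticConfig(seed=9, n_samples=120, n_background_genes=300)


class TestAnnotationGenerator:
    def test_every_family_has_at_least_three_probes(self):
        ann = simulate_annotation(SyntheticConfig(seed=0, probes_per_family=3))
        for fam in ("L1", "L2", "Alu", "MIR", "ERV1", "ERVL", "ERVL-MaLR", "ERVK", "Satellite"):
            assert len(ann.probe_ids_for_family(fam)) >= 3

    def test_context_truth_recovered_for_all_probes(self):
        ann = simulate_annotation(SMALL)
        annotated = annotate_probe_contexts(ann.probes, ann.genes)
        for p in annotated:
            assert p.context == ann.truth.probe_map[p.probe_id]["context"]

    def test_assignment_truth_recovered(self):
        ann = simulate_annotation(SMALL)
        annotated = annotate_probe_contexts(ann.probes, ann.genes)
        assignments = {a.probe_id: a for a in assign_probes_to_repeats(annotated, ann.repeats)}
        for pid, info in ann.truth.probe_map.items():
            if info["assignable"] == "yes":
                assert assignments[pid].repeat_family == info["repeat_family"]
            else:
                assert pid not in assignments

    def test_zero_probes_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(SyntheticConfig(probes_per_family=0))

    def test_written_files_round_trip_through_readers(self, tmp_path):
        ann = simulate_annotation(SMALL)
        paths = write_annotation_files(ann, tmp_path)
        repeats = parse_repeatmasker(paths["repeats_bed"], format="bed")
        assert len(repeats) == len(ann.repeats)
        genes = read_gene_models(paths["genes_gtf"])
        assert len(genes.genes) == len(ann.genes.genes)
        probes = annotate_probe_contexts(read_probe_manifest(paths["probes_tsv"]), genes)
        assignments = assign_probes_to_repeats(probes, repeats)
        n_assignable = sum(1 for v in ann.truth.probe_map.values() if v["assignable"] == "yes")
        assert len(assignments) == n_assignable

    def test_same_seed_writes_identical_files(self, tmp_path):
        a = write_annotation_files(simulate_annotation(SMALL), tmp_path / "a")
        b = write_annotation_files(simulate_annotation(SMALL), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()


def class_scores(cohort, matrix):
    ann = simulate_annotation(SMALL)
    probes = annotate_probe_contexts(ann.probes, ann.genes)
    assignments = assign_probes_to_repeats(probes, ann.repeats)
    return aggregate_rte_scores(matrix, assignments, level="class")


@pytest.fixture(scope="module")
def expression_cohort():
    return simulate_expression_cohort(SMALL)


@pytest.fixture(scope="module")
def methylation_cohort():
    return simulate_methylation_cohort(SMALL)


class TestExpressionCohort:
    @pytest.fixture
    def cohort(self, expression_cohort):
        return expression_cohort

    def test_age_and_latent_independent_by_construction(self, cohort):
        r, p, _ = pearson(pd.Series(cohort.truth.ages), pd.Series(cohort.truth.latent))
        assert abs(r) < 0.2  # n=120, null: |r| rarely above 2/sqrt(n)

    def test_rte_signature_coupling_signs(self, cohort):
        scores = class_scores(cohort, cohort.matrix)
        sig = score_all(cohort.matrix, cohort.signatures)
        r_line, p_line, _ = pearson(scores.scores.loc["LINE"], sig.scores.loc["SASP"])
        r_sine, _, _ = pearson(scores.scores.loc["SINE"], sig.scores.loc["SASP"])
        assert r_line > 0.3 and p_line < 1e-6
        assert r_sine < -0.2

    def test_monocyte_mode_flips_sine_sign(self):
        cfg = SyntheticConfig(seed=9, n_samples=120, n_background_genes=300, cohort_mode="monocyte")
        cohort = simulate_expression_cohort(cfg)
        scores = class_scores(cohort, cohort.matrix)
        sig = score_all(cohort.matrix, cohort.signatures)
        r_sine, _, _ = pearson(scores.scores.loc["SINE"], sig.scores.loc["SASP"])
        assert r_sine > 0.2

    def test_null_couplings_kill_correlations(self):
        ns = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=seed, n_samples=120, n_background_genes=300,
                beta_bar={"LINE": 0.0, "SINE": 0.0, "LTR": 0.0, "Satellite": 0.0},
            )
            cohort = simulate_expression_cohort(cfg)
            scores = class_scores(cohort, cohort.matrix)
            sig = score_all(cohort.matrix, cohort.signatures)
            _, p, _ = pearson(scores.scores.loc["LINE"], sig.scores.loc["SASP"])
            ns += p >= 0.05
        assert ns >= 9

    def test_expected_r_formula_matches_observation(self):
        # score = beta*B + noise/sqrt(k probes): observed r within Fisher-z bounds
        cfg = SyntheticConfig(seed=2, n_samples=2000, n_background_genes=200)
        cohort = simulate_expression_cohort(cfg)
        scores = class_scores(cohort, cohort.matrix)
        B = pd.Series(cohort.truth.latent)
        k = 8  # LINE probes: 2 families x 4
        expected = cohort.truth.expected_r(0.9, cfg.noise_sd / np.sqrt(k))
        r, _, n = pearson(scores.scores.loc["LINE"], B)
        z, ze = np.arctanh(r), np.arctanh(expected)
        assert abs(z - ze) < 1.96 / np.sqrt(n - 3)

    def test_determinism(self):
        a = simulate_expression_cohort(SMALL)
        b = simulate_expression_cohort(SMALL)
        assert a.matrix.data.equals(b.matrix.data)
        assert a.truth.latent == b.truth.latent


class TestMethylationCohort:
    @pytest.fixture
    def cohort(self, methylation_cohort):
        return methylation_cohort

    def test_betas_in_unit_interval(self, cohort):
        vals = cohort.betas.data.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_age_decline_in_every_class(self, cohort):
        scores = class_scores(cohort, cohort.betas)
        for cls in scores.scores.index:
            r, p, _ = pearson(cohort.ages, scores.scores.loc[cls])
            assert r < -0.3 and p < 1e-6

    def test_zero_slope_gives_null_age_correlation(self):
        ns = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_samples=120, beta_age_meth=0.0)
            cohort = simulate_methylation_cohort(cfg)
            scores = class_scores(cohort, cohort.betas)
            _, p, _ = pearson(cohort.ages, scores.scores.loc["LINE"])
            ns += p >= 0.05
        assert ns >= 9

    def test_expression_anticoupled_for_line_ltr_only(self, cohort):
        meth = class_scores(cohort, cohort.betas)
        expr = class_scores(cohort, cohort.matched_expression)
        r_line, p_line, _ = pearson(meth.scores.loc["LINE"], expr.scores.loc["LINE"])
        r_sine, p_sine, _ = pearson(meth.scores.loc["SINE"], expr.scores.loc["SINE"])
        assert r_line < -0.3 and p_line < 1e-3
        assert abs(r_sine) < 0.3


class TestSingleCellGenerator:
    def test_counts_conserved_through_pseudobulk(self):
        from rteaging.single_cell import pseudo_bulk

        sc = simulate_single_cell(SyntheticConfig(seed=4, sc_n_samples=6, sc_cells_per_type=8))
        pb = pseudo_bulk(sc.counts, sc.annotation)
        assert pb.data.to_numpy().sum() == sc.counts.to_numpy().sum()

    def test_determinism(self):
        cfg = SyntheticConfig(seed=4, sc_n_samples=6, sc_cells_per_type=8)
        a = simulate_single_cell(cfg)
        b = simulate_single_cell(cfg)
        assert a.counts.equals(b.counts)
        assert a.truth.sc_group == b.truth.sc_group

    def test_unplanted_factor_gives_no_systematic_flags(self):
        from rteaging.cohort import SampleGrouping
        from rteaging.single_cell import celltype_contrast, combined_rpm, pseudo_bulk

        fps = []
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed, sc_planted_shifts={})
            sc = simulate_single_cell(cfg)
            rpm = combined_rpm(pseudo_bulk(sc.counts, sc.annotation))
            labels = pd.Series(sc.truth.sc_group)
            table = celltype_contrast(rpm, SampleGrouping(labels, "truth", "median"))
            fps.append(int((table.p < 0.05).sum()))
        assert sum(fps) <= 5  # ~5% of 15 contrasts x 5 reps under the null

    def test_config_validation(self):
        with pytest.raises(ValueError):
            simulate_single_cell(SyntheticConfig(sc_cell_types=("Plasma",)))
        with pytest.raises(ValueError):
            simulate_single_cell(SyntheticConfig(sc_n_samples=3))


class TestFixtureBundle:
    def test_bundle_written_and_truth_reloadable(self, tmp_path):
        cfg = SyntheticConfig(
            seed=3, n_samples=40, n_background_genes=100,
            sc_n_samples=4, sc_cells_per_type=5, sc_n_genes=80,
        )
        paths = write_fixture_bundle(cfg, tmp_path)
        for p in paths.values():
            assert p.exists()
        truth = GroundTruth.from_json(paths["expression_truth_json"])
        assert len(truth.ages) == 40
        with open(paths["sc_truth_json"]) as fh:
            sc_truth = json.load(fh)
        assert set(sc_truth["sc_group"].values()) == {"high", "low"}
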