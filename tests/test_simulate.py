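import filecmp

import pytest

from qremap.errors import ConfigError
from qremap.io import ExpressionTable, load_transcripts
from qremap.regulation import DOWN, UP, consensus_matrix, dataset_calls_from_tables
from qremap.simulate import (
    DECOY_ROLES,
    SimConfig,
    TruthTable,
    simulate_fixture,
)


class TestConfigValidation:
    def test_zero_peak_coverage_with_planted_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(peak_coverage=0.0, n_planted_proximal=3)

    def test_planted_distance_must_stay_below_twenty(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_distance=(5, 20))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=5)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_fixture(cfg, d1)
        simulate_fixture(cfg, d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        simulate_fixture(SimConfig(seed=1), tmp_path / "a")
        simulate_fixture(SimConfig(seed=2), tmp_path / "b")
        assert (tmp_path / "a/genome.fa").read_text() != (
            tmp_path / "b/genome.fa"
        ).read_text()


class TestEmittedAnnotation:
    def test_gene_count(self, sim_dir):
        models = load_transcripts(sim_dir / "annotation.gtf")
        assert len(models) == 20
        assert len({m.transcript_id for m in models}) == 20

    def test_both_strands_present(self, sim_dir):
        models = load_transcripts(sim_dir / "annotation.gtf")
        assert {m.strand for m in models} == {"+", "-"}

    def test_truth_lists_planted_proximal_genes(self, sim_truth):
        assert len(sim_truth.proximal_genes) == 3
        roles = {g["gene"]: g["role"] for g in sim_truth.genes}
        for role in DECOY_ROLES:
            assert role in roles.values()

    def test_junction_qre_planted(self, sim_truth):
        assert any(q["spans_junction"] for q in sim_truth.planted_qres)


class TestDecoyAudit:
    """Each decoy class is rejected at its intended stage and no other."""

    def test_expression_decoy_fails_only_expression(self, sim_truth):
        (decoy,) = [s for s in sim_truth.sites if s["class"] == "decoy_expression"]
        assert not decoy["expect_expression_pass"]
        assert decoy["expect_score_pass"]
        assert decoy["planned_distance"] < 20

    def test_score_decoy_fails_only_score(self, sim_truth):
        (decoy,) = [s for s in sim_truth.sites if s["class"] == "decoy_score"]
        assert decoy["expect_expression_pass"]
        assert not decoy["expect_score_pass"]
        assert decoy["planned_distance"] < 20

    def test_distance_decoy_passes_filters_but_is_far(self, sim_truth):
        (decoy,) = [s for s in sim_truth.sites if s["class"] == "decoy_distance"]
        assert decoy["expect_expression_pass"] and decoy["expect_score_pass"]
        assert decoy["planned_distance"] >= 20

    def test_nopeak_decoy_qre_not_validated(self, sim_truth):
        (decoy,) = [s for s in sim_truth.sites if s["class"] == "decoy_nopeak"]
        assert decoy["expect_expression_pass"] and decoy["expect_score_pass"]
        (qre,) = [q for q in sim_truth.planted_qres if q["gene"] == decoy["gene"]]
        assert not qre["expect_validated"]

    def test_pipeline_rejects_each_decoy_at_its_stage(self, sim_truth, pipeline_result):
        kept_sites = {(s.gene_symbol, s.mirna_id) for s in pipeline_result["kept_sites"]}
        validated_genes = {v.hit.gene_symbol for v in pipeline_result["validated"]}
        pair_genes = set(pipeline_result["gene_summary"]["gene"])
        by_class = {s["class"]: s for s in sim_truth.sites if s["class"].startswith("decoy")}

        # filter stage rejections
        assert (by_class["decoy_expression"]["gene"], by_class["decoy_expression"]["mirna_id"]) not in kept_sites
        assert (by_class["decoy_score"]["gene"], by_class["decoy_score"]["mirna_id"]) not in kept_sites
        # validation stage rejection
        assert by_class["decoy_nopeak"]["gene"] not in validated_genes
        assert (by_class["decoy_nopeak"]["gene"], by_class["decoy_nopeak"]["mirna_id"]) in kept_sites
        # proximity stage rejection: survives both earlier stages
        dist_gene = by_class["decoy_distance"]["gene"]
        assert (dist_gene, by_class["decoy_distance"]["mirna_id"]) in kept_sites
        assert dist_gene in validated_genes
        assert dist_gene not in pair_genes


class TestExpressionTables:
    def test_noise_free_lfc_recovered_exactly(self, tmp_path):
        cfg = SimConfig(seed=3, noise_sd=0.0)
        truth = simulate_fixture(cfg, tmp_path)
        mono = ExpressionTable.read_tsv(tmp_path / "sim_array1_monocyte.tsv")
        macro = ExpressionTable.read_tsv(tmp_path / "sim_array1_macrophage.tsv")
        from qremap.regulation import RegulationConfig, log2_fold_change

        for gene, lfc in truth.fc_effects.items():
            observed = log2_fold_change(
                float(macro.values_for(gene).mean()),
                float(mono.values_for(gene).mean()),
                pseudocount=0,
            )
            assert observed == pytest.approx(lfc, abs=1e-9)

    def test_planted_up_in_two_of_three_gives_consensus_up(self, tmp_path):
        gene_up2 = "GENE10"
        cfg = SimConfig(
            seed=5,
            noise_sd=0.0,
            fc_effects={gene_up2: {"sim_rnaseq": 1.0, "sim_array1": 1.0}},
        )
        simulate_fixture(cfg, tmp_path)
        from qremap.regulation import RegulationConfig

        reg = RegulationConfig(pseudocount=0.0)
        calls = []
        for ds in ("sim_rnaseq", "sim_array1", "sim_array2"):
            mono = ExpressionTable.read_tsv(tmp_path / f"{ds}_monocyte.tsv")
            macro = ExpressionTable.read_tsv(tmp_path / f"{ds}_macrophage.tsv")
            calls += dataset_calls_from_tables(mono, macro, [gene_up2], ds, reg)
        (consensus,) = consensus_matrix(calls, reg)
        assert consensus.consensus == UP

    def test_planted_effects_recovered_as_consensus(self, sim_dir, sim_truth):
        """Default fixture: planted up/down genes reach the 2-of-3 consensus."""
        from qremap.regulation import RegulationConfig

        reg = RegulationConfig(pseudocount=0.0)
        panel = [g["gene"] for g in sim_truth.genes]
        calls = []
        for ds in ("sim_rnaseq", "sim_array1", "sim_array2"):
            mono = ExpressionTable.read_tsv(sim_dir / f"{ds}_monocyte.tsv")
            macro = ExpressionTable.read_tsv(sim_dir / f"{ds}_macrophage.tsv")
            calls += dataset_calls_from_tables(mono, macro, panel, ds, reg)
        by_gene = {c.gene: c for c in consensus_matrix(calls, reg)}
        for gene, lfc in sim_truth.fc_effects.items():
            if isinstance(lfc, dict):
                continue
            if lfc >= 1.0:
                assert by_gene[gene].consensus == UP, gene
            elif lfc <= -1.0:
                assert by_gene[gene].consensus == DOWN, gene
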