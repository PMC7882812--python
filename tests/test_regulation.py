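import math

import numpy as np
import pandas as pd
import pytest

from qremap.errors import InputError
from qremap.io import ExpressionTable
from qremap.regulation import (
    DOWN,
    NONE,
    UP,
    DatasetCall,
    RegulationConfig,
    call_direction,
    consensus_call,
    consensus_matrix,
    detectable_genes,
    join_counts_fc,
    load_call_matrix,
    log2_fold_change,
    patient_comparison,
    qki_correlation,
)


def table(values: dict, columns=None):
    if columns is None:
        return ExpressionTable(pd.DataFrame({"s1": values}))
    return ExpressionTable(pd.DataFrame(values, index=columns).T)


class TestDetectableGenes:
    def test_non_zero_in_any_sample(self):
        expr = ExpressionTable(
            pd.DataFrame({"s1": [5, 0, 1], "s2": [0, 0, 0]}, index=["A", "B", "C"])
        )
        assert detectable_genes(expr, ["A", "B", "C"]) == {"A", "C"}

    def test_all_zero_empty(self):
        expr = ExpressionTable(pd.DataFrame({"s1": [0, 0]}, index=["A", "B"]))
        assert detectable_genes(expr, ["A", "B"]) == set()

    def test_missing_gene_excluded(self):
        expr = ExpressionTable(pd.DataFrame({"s1": [5]}, index=["A"]))
        assert detectable_genes(expr, ["A", "Z"]) == {"A"}


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "num,den,pc,expected",
        [
            (16, 4, 0, 2.0),
            (8, 0, 1, math.log2(9)),
            (7, 7, 0, 0.0),
            (7, 7, 1, 0.0),
        ],
    )
    def test_examples(self, num, den, pc, expected):
        assert log2_fold_change(num, den, pc) == pytest.approx(expected)

    def test_double_zero_without_pseudocount_rejected(self):
        with pytest.raises(InputError):
            log2_fold_change(0, 0, 0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(0, 100, size=(50, 2)):
            assert log2_fold_change(a, b, 1) == pytest.approx(
                -log2_fold_change(b, a, 1)
            )


class TestCallDirection:
    @pytest.mark.parametrize(
        "lfc,expected",
        [(0.5, UP), (-0.2, NONE), (0.4, UP), (-0.4, DOWN), (0.39, NONE), (-5, DOWN)],
    )
    def test_threshold(self, lfc, expected):
        assert call_direction(lfc) == expected

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        mirror = {UP: DOWN, DOWN: UP, NONE: NONE}
        for x in rng.uniform(-2, 2, 100):
            assert call_direction(-x) == mirror[call_direction(x)]


def calls_for(gene, directions):
    return [
        DatasetCall(gene, f"ds{i}", None, d) for i, d in enumerate(directions)
    ]


class TestConsensusCall:
    @pytest.mark.parametrize(
        "directions,consensus,conflict",
        [
            ((UP, UP, UP), UP, False),
            ((DOWN, DOWN, NONE), DOWN, False),
            ((UP, DOWN, NONE), NONE, True),
            ((UP, NONE, NONE), NONE, False),
            ((UP, UP, DOWN), UP, True),
        ],
    )
    def test_rules(self, directions, consensus, conflict):
        result = consensus_call(calls_for("G", directions))
        assert result.consensus == consensus
        assert result.conflict == conflict

    def test_duplicate_dataset_rejected(self):
        calls = [DatasetCall("G", "ds1", None, UP), DatasetCall("G", "ds1", None, UP)]
        with pytest.raises(InputError):
            consensus_call(calls)

    def test_worked_example_matrix_9_up_8_down(self):
        """The packaged 17-gene panel call matrix yields 9 Up and 8 Down."""
        consensus = consensus_matrix(load_call_matrix())
        ups = {c.gene for c in consensus if c.consensus == UP}
        downs = {c.gene for c in consensus if c.consensus == DOWN}
        assert len(ups) == 9
        assert len(downs) == 8
        assert "SEMA7A" in ups
        assert "NTNG2" in downs


class TestPatientComparison:
    def test_planted_deficit_called_down_in_both_states(self, sim_dir, sim_truth):
        patient = ExpressionTable.read_tsv(sim_dir / "patient.tsv")
        sibling = ExpressionTable.read_tsv(sim_dir / "sibling.tsv")
        panel = [g["gene"] for g in sim_truth.genes]
        calls = patient_comparison(patient, sibling, panel)
        for gene in sim_truth.proximal_genes:
            states = {c.dataset_id: c.call for c in calls if c.gene == gene}
            assert states == {"monocyte": DOWN, "macrophage": DOWN}

    def test_equal_values_none(self):
        t = ExpressionTable(pd.DataFrame({"monocyte": [4.0]}, index=["A"]))
        (call,) = patient_comparison(t, t, ["A"])
        assert call.log2fc == 0.0 and call.call == NONE


class TestQkiCorrelation:
    def test_perfect_positive_and_negative(self):
        r, _ = qki_correlation([(1, 2), (2, 4), (3, 6)])
        assert r == pytest.approx(1.0)
        r, _ = qki_correlation([(1, 6), (2, 4), (3, 2)])
        assert r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            qki_correlation([(1, 1), (2, 1), (3, 1)])

    def test_noisy_linear_relation_recovered(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 50)
        y = x + rng.normal(0, 0.5, 50)
        r, p = qki_correlation(list(zip(x, y)))
        assert r > 0.9
        assert p < 1e-6


class TestJoinCountsFc:
    def test_inner_join(self):
        calls = [DatasetCall("G1", "ds1", 1.0, UP), DatasetCall("G2", "ds1", 0.1, NONE)]
        out = join_counts_fc({"G1": 2}, calls)
        assert out.to_dict("records") == [
            {"gene": "G1", "dataset_id": "ds1", "qre_count": 2, "log2fc": 1.0}
        ]

    def test_disjoint_keys_empty(self):
        assert join_counts_fc({"A": 1}, [DatasetCall("B", "d", 1.0, UP)]).empty
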