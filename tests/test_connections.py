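from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pharmtree.connections import (
    EXPRESSION,
    GENOMIC,
    ConnectionRecord,
    bh_adjust,
    build_network,
    connect_drug,
    expression_connection_test,
    gene_list_enrichment,
    genomic_connection_test,
    passes_pcc,
)
from pharmtree.io_formats import (
    AlterationMatrix,
    ExpressionMatrix,
    ValidationError,
)
from pharmtree.subtype_tree import (
    MIXED,
    RESISTANT,
    SENSITIVE,
    SubtypeTree,
    TreeNode,
    grow_tree,
    sensitivity_labels,
)
from pharmtree.synthetic_cohort import GenomicEffect, SyntheticConfig, generate

from .oracles import bh_by_hand, chi2_pvalue, fisher_greater

pytestmark = pytest.mark.filterwarnings("ignore::scipy.stats.DegenerateDataWarning")


def chain_tree(drug, leaf_specs):
    """Right-deep tree with leaves (cells, response_class) in order."""
    nodes = [TreeNode(cells=tuple(cells), response_class=cls) for cells, cls in leaf_specs]
    while len(nodes) > 1:
        right = nodes.pop()
        left = nodes.pop()
        nodes.append(
            TreeNode(
                cells=left.cells + right.cells, split_p=0.001, left=left, right=right
            )
        )
    return SubtypeTree(drug=drug, root=nodes[0])


def graded_cohort():
    """Four pure leaves of 10 cells, classes S, S, R, R."""
    cells = [f"C{i:02d}" for i in range(40)]
    leaves = [
        (cells[0:10], SENSITIVE),
        (cells[10:20], SENSITIVE),
        (cells[20:30], RESISTANT),
        (cells[30:40], RESISTANT),
    ]
    return cells, chain_tree("D", leaves)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        # (0.01, 0.02, 0.03, 0.04) -> all 0.04 by the step-up formula
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_hand_formula_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_by_hand(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected)

    def test_order_invariance(self, rng):
        p = list(rng.random(25))
        base = dict(zip(range(25), bh_adjust(p)))
        perm = list(rng.permutation(25))
        shuffled = bh_adjust([p[i] for i in perm])
        for pos, orig_idx in enumerate(perm):
            assert shuffled[pos] == pytest.approx(base[orig_idx])


class TestGenomicConnectionTest:
    def test_graded_frequencies_sensitive_direction_and_chi2_oracle(self):
        cells, tree = graded_cohort()
        # alteration frequencies 0.5, 0.3, 0.1, 0.0 across C1..C4
        status = pd.Series(0, index=cells)
        status.iloc[0:5] = 1
        status.iloc[10:13] = 1
        status.iloc[20:21] = 1
        res = genomic_connection_test(status, tree)
        assert res is not None
        p, direction = res
        assert direction == SENSITIVE
        table = [[5, 3, 1, 0], [5, 7, 9, 10]]
        assert p == pytest.approx(chi2_pvalue(table), rel=1e-9)

    def test_uniform_frequency_gives_p_one(self):
        cells, tree = graded_cohort()
        status = pd.Series(0, index=cells)
        for start in (0, 10, 20, 30):  # 3 altered in every leaf
            status.iloc[start : start + 3] = 1
        p, _ = genomic_connection_test(status, tree)
        assert p == pytest.approx(1.0)

    def test_mixed_leaves_are_excluded(self):
        cells = [f"C{i:02d}" for i in range(30)]
        tree = chain_tree(
            "D",
            [
                (cells[0:10], SENSITIVE),
                (cells[10:20], MIXED),
                (cells[20:30], RESISTANT),
            ],
        )
        status = pd.Series(0, index=cells)
        status.iloc[0:6] = 1
        status.iloc[10:20] = 1  # heavy alteration only in the mixed leaf
        res = genomic_connection_test(status, tree)
        assert res is not None
        p, direction = res
        assert direction == SENSITIVE
        assert p == pytest.approx(chi2_pvalue([[6, 0], [4, 10]]), rel=1e-9)

    def test_too_few_altered_cells_not_testable(self):
        cells, tree = graded_cohort()
        status = pd.Series(0, index=cells)
        status.iloc[0:2] = 1
        assert genomic_connection_test(status, tree) is None

    def test_fewer_than_two_pure_leaves_not_testable(self):
        cells = [f"C{i:02d}" for i in range(12)]
        tree = chain_tree("D", [(cells[:6], MIXED), (cells[6:], SENSITIVE)])
        status = pd.Series([1, 0] * 6, index=cells)
        assert genomic_connection_test(status, tree) is None

    def test_direction_antisymmetric_under_pool_swap(self):
        cells, tree = graded_cohort()
        status = pd.Series(0, index=cells)
        status.iloc[0:8] = 1
        _, direction = genomic_connection_test(status, tree)
        # mirror the tree: swap response classes of all leaves
        mirrored = chain_tree(
            "D",
            [
                (cells[0:10], RESISTANT),
                (cells[10:20], RESISTANT),
                (cells[20:30], SENSITIVE),
                (cells[30:40], SENSITIVE),
            ],
        )
        _, mirrored_direction = genomic_connection_test(status, mirrored)
        assert {direction, mirrored_direction} == {SENSITIVE, RESISTANT}


class TestExpressionConnectionTest:
    def _cohort(self):
        cells, tree = graded_cohort()
        gen = np.random.default_rng(3)
        ln = pd.Series(
            np.concatenate([gen.normal(-4, 0.5, 20), gen.normal(3, 0.5, 20)]),
            index=cells,
        )
        return cells, tree, ln

    def test_linear_relation_retained(self):
        cells, tree, ln = self._cohort()
        gen = np.random.default_rng(4)
        expr = pd.Series(-ln + gen.normal(0, 0.01, len(cells)), index=cells)
        res = expression_connection_test(expr, tree, ln)
        assert res is not None
        p, direction, pcc = res
        assert direction == SENSITIVE
        assert pcc < -0.9
        assert passes_pcc(direction, pcc)
        assert p < 1e-6

    def test_constant_expression_not_testable(self):
        cells, tree, ln = self._cohort()
        expr = pd.Series(2.5, index=cells)
        assert expression_connection_test(expr, tree, ln) is None

    def test_weak_within_pool_correlation_filtered(self):
        cells, tree, ln = self._cohort()
        gen = np.random.default_rng(5)
        # clear pool shift but no within-pool relation to ln-IC50
        expr = pd.Series(
            np.concatenate([gen.normal(5, 0.1, 20), gen.normal(0, 0.1, 20)]),
            index=cells,
        )
        res = expression_connection_test(expr, tree, ln)
        assert res is not None
        p, direction, pcc = res
        assert direction == SENSITIVE
        assert abs(pcc) < 0.3
        assert not passes_pcc(direction, pcc)

    def test_sign_consistency_required(self):
        # direction sensitive but PCC positive: inconsistent, filtered
        assert not passes_pcc(SENSITIVE, 0.9)
        assert passes_pcc(RESISTANT, 0.9)
        assert not passes_pcc(RESISTANT, -0.9)
        assert passes_pcc(SENSITIVE, -0.31)
        assert not passes_pcc(SENSITIVE, -0.3)  # strict threshold

    def test_small_pool_not_testable(self):
        cells = [f"C{i:02d}" for i in range(8)]
        tree = chain_tree("D", [(cells[:2], SENSITIVE), (cells[2:], RESISTANT)])
        ln = pd.Series(np.linspace(-2, 2, 8), index=cells)
        expr = pd.Series(np.linspace(3, -3, 8), index=cells)
        assert expression_connection_test(expr, tree, ln) is None


class TestConnectDrug:
    def test_planted_alteration_recovered_with_direction(self):
        config = SyntheticConfig(
            n_cells=60,
            group_means=(-3.0, 3.0),
            group_sds=1.0,
            max_conc=1.0,
            genomic_effects=(GenomicEffect("BRAFlike", "D000", (0.6, 0.05)),),
            n_null_genes=20,
            seed=42,
        )
        responses, alterations, _, truth = generate(config)
        tree = grow_tree("D000", responses)
        records = connect_drug("D000", tree, responses, alterations=alterations)
        hits = {r.gene: r for r in records}
        assert "BRAFlike" in hits
        assert hits["BRAFlike"].direction == SENSITIVE
        assert hits["BRAFlike"].q_fdr < 0.1


class TestBuildNetwork:
    def _records(self):
        return [
            ConnectionRecord("geneA", "D1", GENOMIC, 1e-4, 1e-3, SENSITIVE),
            ConnectionRecord("geneA", "D2", GENOMIC, 1e-4, 1e-3, SENSITIVE),
            ConnectionRecord("geneB", "D1", EXPRESSION, 1e-3, 1e-2, RESISTANT, 0.5),
        ]

    def test_degrees(self):
        net = build_network(self._records())
        assert net.gene_degree["geneA"] == 2
        assert net.gene_degree["geneB"] == 1
        assert net.drug_degree["D1"] == 2

    def test_duplicates_dropped_with_warning(self):
        records = self._records() + [self._records()[0]]
        with pytest.warns(UserWarning, match="duplicate"):
            net = build_network(records)
        assert net.gene_degree["geneA"] == 2

    def test_bipartite(self):
        net = build_network(self._records())
        for a, b in net.graph.edges:
            kinds = {net.graph.nodes[a]["bipartite"], net.graph.nodes[b]["bipartite"]}
            assert kinds == {"gene", "drug"}

    def test_empty_records_empty_network(self):
        net = build_network([])
        assert net.graph.number_of_edges() == 0
        assert len(net.gene_degree) == 0

    def test_gene_list_enrichment_matches_hypergeometric_oracle(self):
        # 10 hub genes, 3 of them in a 700-gene census over 21,972 genes
        records = [
            ConnectionRecord(f"G{i}", f"D{j}", GENOMIC, 1e-4, 1e-3, SENSITIVE)
            for i in range(10)
            for j in range(10 - i)
        ]
        net = build_network(records)
        census = {"G0", "G1", "G2"} | {f"CENSUS{i}" for i in range(697)}
        p = gene_list_enrichment(net, census, top_k=10, universe_size=21972)
        expected = fisher_greater([[3, 7], [697, 21972 - 10 - 697]])
        assert p == pytest.approx(expected, rel=1e-9)
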