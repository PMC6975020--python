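"""Correlation / partial-correlation network reconstruction."""

import logging

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from grnabc import (
    ExpressionTable,
    GRNError,
    Sign,
    UndirectedGRN,
    connected_components,
    filter_genes,
    log2fc,
    partial_correlation_matrix,
    pearson_correlation_matrix,
    threshold_links,
)


def _table(rows: dict[str, np.ndarray], condition_map=None) -> ExpressionTable:
    genes = list(rows)
    df = pd.DataFrame(
        np.vstack([rows[g] for g in genes]),
        index=genes,
        columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))],
    )
    return ExpressionTable(df, condition_map=condition_map or {})


@pytest.fixture
def chain_table() -> ExpressionTable:
    """X drives Y drives Z with tiny noise: X-Z association is indirect."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = x + rng.normal(scale=1e-3, size=200)
    z = y + rng.normal(scale=1e-3, size=200)
    return _table({"X": 100 + x, "Y": 100 + y, "Z": 100 + z})


class TestPearson:
    def test_diagonal_is_one(self, chain_table):
        cor = pearson_correlation_matrix(chain_table)
        np.testing.assert_allclose(np.diag(cor.to_numpy()), 1.0)

    def test_perfect_linear_dependence(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = _table({"A": base, "B": 2 * base, "C": (-base + 10.0)})
        cor = pearson_correlation_matrix(table)
        assert cor.loc["A", "B"] == pytest.approx(1.0)
        assert cor.loc["A", "C"] == pytest.approx(-1.0)

    def test_constant_gene_excluded_with_warning(self, caplog):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        table = _table({"A": base, "B": base * 3, "K": np.full(4, 7.0)})
        with caplog.at_level(logging.WARNING, logger="grnabc.undirected"):
            cor = pearson_correlation_matrix(table)
        assert "K" not in cor.index
        assert any("constant" in r.message for r in caplog.records)


class TestPartialCorrelation:
    def test_two_genes_equals_plain_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        table = _table({"A": 100 + a, "B": 100 + a + rng.normal(scale=0.5, size=50)})
        cor = pearson_correlation_matrix(table)
        pcor = partial_correlation_matrix(table)
        assert pcor.loc["A", "B"] == pytest.approx(cor.loc["A", "B"], abs=1e-12)

    def test_chain_indirect_link_is_suppressed(self, chain_table):
        """Conditioning on the middle gene collapses the X-Z association."""
        cor = pearson_correlation_matrix(chain_table)
        pcor = partial_correlation_matrix(chain_table)
        assert abs(pcor.loc["X", "Z"]) < abs(cor.loc["X", "Z"])
        assert abs(cor.loc["X", "Z"]) > 0.999
        assert abs(pcor.loc["X", "Z"]) < 0.3

    def test_agrees_with_pingouin(self, chain_table):
        """Independent oracle: recursive partial correlation via pingouin."""
        pcor = partial_correlation_matrix(chain_table)
        df = chain_table.values.T
        ref = pg.partial_corr(df, x="X", y="Z", covar=["Y"])["r"].iloc[0]
        assert pcor.loc["X", "Z"] == pytest.approx(float(ref), abs=1e-6)

    def test_independent_genes_have_small_partial_correlations(self):
        rng = np.random.default_rng(1)
        rows = {f"g{i}": 100 + rng.normal(size=500) for i in range(6)}
        pcor = partial_correlation_matrix(_table(rows))
        off = pcor.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_shrinkage_engages_when_samples_fewer_than_genes(self, caplog):
        rng = np.random.default_rng(2)
        rows = {f"g{i}": 100 + rng.normal(size=4) for i in range(8)}
        with caplog.at_level(logging.INFO, logger="grnabc.undirected"):
            pcor = partial_correlation_matrix(_table(rows))
        assert np.all(np.isfinite(pcor.to_numpy()))
        assert any("shrink" in r.message for r in caplog.records)


class TestThresholdLinks:
    def _matrices(self, genes, entries):
        n = len(genes)
        cor = np.eye(n)
        pcor = np.eye(n)
        for (i, j, c, pc) in entries:
            cor[i, j] = cor[j, i] = c
            pcor[i, j] = pcor[j, i] = pc
        idx = pd.Index(genes)
        return (
            pd.DataFrame(cor, index=idx, columns=idx),
            pd.DataFrame(pcor, index=idx, columns=idx),
        )

    def test_identity_matrices_give_no_edges(self):
        cor, pcor = self._matrices(["A", "B"], [])
        assert threshold_links(cor, pcor).n_edges == 0

    def test_positive_pair_becomes_activation(self):
        cor, pcor = self._matrices(["A", "B"], [(0, 1, 0.995, 0.995)])
        grn = threshold_links(cor, pcor)
        assert grn.edges == (("A", "B", Sign.ACTIVATION),)

    def test_negative_pair_becomes_inhibition(self):
        cor, pcor = self._matrices(["A", "B"], [(0, 1, -0.999, -0.999)])
        assert threshold_links(cor, pcor).edges[0][2] is Sign.INHIBITION

    def test_both_criteria_required(self):
        cor, pcor = self._matrices(["A", "B"], [(0, 1, 0.999, 0.5)])
        assert threshold_links(cor, pcor).n_edges == 0

    def test_lowering_threshold_only_adds_edges(self, chain_table):
        cor = pearson_correlation_matrix(chain_table)
        pcor = partial_correlation_matrix(chain_table)
        strict = {e[:2] for e in threshold_links(cor, pcor, 0.99).edges}
        loose = {e[:2] for e in threshold_links(cor, pcor, 0.5).edges}
        assert strict <= loose

    def test_output_independent_of_gene_ordering(self, chain_table):
        cor = pearson_correlation_matrix(chain_table)
        pcor = partial_correlation_matrix(chain_table)
        direct = threshold_links(cor, pcor, 0.9)
        perm = ["Z", "X", "Y"]
        edges_perm = threshold_links(cor.loc[perm, perm], pcor.loc[perm, perm], 0.9)
        as_sets = lambda g: {frozenset((u, v)) for u, v, _ in g.edges}
        assert as_sets(direct) == as_sets(edges_perm)

    def test_chain_partial_correlation_prunes_indirect_edge(self, chain_table):
        """At a moderate threshold, correlation alone would link X-Z;
        the combined rule keeps only the direct chain links."""
        cor = pearson_correlation_matrix(chain_table)
        pcor = partial_correlation_matrix(chain_table)
        assert abs(cor.loc["X", "Z"]) >= 0.9  # plain correlation would add it
        # conditioning on a near-copy also deflates the direct links, so the
        # discriminating threshold sits between pcor(X,Z)~0.20 and the direct
        # pcor values (~0.57 and ~0.69 for Y-Z and X-Y)
        grn = threshold_links(cor, pcor, r_threshold=0.4)
        pairs = {frozenset((u, v)) for u, v, _ in grn.edges}
        assert frozenset(("X", "Z")) not in pairs
        assert frozenset(("X", "Y")) in pairs
        assert frozenset(("Y", "Z")) in pairs


class TestConnectedComponents:
    def test_two_disjoint_edges(self):
        grn = UndirectedGRN(
            ["A", "B", "C", "D"],
            [("A", "B", Sign.ACTIVATION), ("C", "D", Sign.ACTIVATION)],
        )
        comps = connected_components(grn)
        assert [c.n_nodes for c in comps] == [2, 2]

    def test_singletons_dropped(self):
        grn = UndirectedGRN(["A", "B", "C"], [("A", "B", Sign.ACTIVATION)])
        comps = connected_components(grn)
        assert len(comps) == 1
        assert comps[0].nodes == ("A", "B")

    def test_empty_edge_set_gives_no_components(self):
        assert connected_components(UndirectedGRN(["A", "B"], [])) == []

    def test_sorted_by_decreasing_size(self):
        grn = UndirectedGRN(
            ["A", "B", "C", "D", "E"],
            [
                ("D", "E", Sign.ACTIVATION),
                ("A", "B", Sign.ACTIVATION),
                ("B", "C", Sign.ACTIVATION),
            ],
        )
        comps = connected_components(grn)
        assert [c.n_nodes for c in comps] == [3, 2]
        assert comps[0].nodes == ("A", "B", "C")


class TestLog2FC:
    def _two_condition_table(self, a_vals, b_vals):
        rows = {"g": np.array(a_vals + b_vals, dtype=float)}
        cmap = {f"s{i}": ("ctrl" if i < len(a_vals) else "case")
                for i in range(len(a_vals) + len(b_vals))}
        return _table(rows, condition_map=cmap)

    def test_fourfold_change(self):
        table = self._two_condition_table([2.0, 2.0], [8.0, 8.0])
        assert log2fc(table, "ctrl", "case")["g"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        table = self._two_condition_table([3.0, 5.0], [4.0, 4.0])
        assert log2fc(table, "ctrl", "case")["g"] == pytest.approx(0.0)

    def test_pseudocount_rescues_zero_mean(self):
        table = self._two_condition_table([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(GRNError, match="pseudocount"):
            log2fc(table, "ctrl", "case")
        assert log2fc(table, "ctrl", "case", pseudocount=1.0)["g"] == pytest.approx(1.0)

    def test_missing_condition_is_usage_error(self):
        table = self._two_condition_table([1.0], [2.0])
        with pytest.raises(GRNError, match="no samples"):
            log2fc(table, "ctrl", "nope")


class TestFilterGenes:
    def test_pvalue_cut_and_gene_list(self):
        rng = np.random.default_rng(0)
        table = _table({g: 100 + rng.normal(size=5) for g in "ABCD"})
        kept = filter_genes(table, pvalues={"A": 0.01, "B": 0.2, "C": 0.04, "D": 0.5})
        assert kept.genes == ["A", "C"]
        kept2 = filter_genes(table, keep=["B", "D"])
        assert kept2.genes == ["B", "D"]

    def test_empty_result_is_error(self):
        rng = np.random.default_rng(0)
        table = _table({"A": 100 + rng.normal(size=4)})
        with pytest.raises(GRNError):
            filter_genes(table, keep=["Z"])


class TestExpressionTable:
    def test_rejects_missing_values(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["g"], columns=["s0", "s1"])
        with pytest.raises(GRNError, match="missing"):
            ExpressionTable(df)

    def test_rejects_negative_values(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["g"], columns=["s0", "s1"])
        with pytest.raises(GRNError, match="non-negative"):
            ExpressionTable(df)
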