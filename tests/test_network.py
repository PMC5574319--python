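import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metapls.network import (
    Edge,
    assemble_network,
    correlation_edges,
    correlation_p_value,
    node_directions,
    read_similarity_matrix,
    structural_edges,
    write_edge_tsv,
    write_graphml,
    write_node_tsv,
)
from metapls.synthgen import (
    MetaboliteTable,
    StudyDesign,
    generate_metabolite_table,
    generate_similarity_matrix,
)

from oracles import brute_force_correlation_edges


def table_from_values(values, group="G"):
    values = np.asarray(values, dtype=float)
    return MetaboliteTable(
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        group_labels=(group,) * values.shape[0],
        metabolite_names=tuple(f"m{j}" for j in range(values.shape[1])),
        values=values,
    )


class TestCorrelationPValue:
    def test_matches_scipy_pearsonr(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r, p = stats.pearsonr(x, y)
        assert correlation_p_value(r, 12) == pytest.approx(p, rel=1e-9)

    def test_r_07_n8_is_not_significant(self):
        # t = 0.7*sqrt(6)/sqrt(0.51) = 2.40, df=6 -> two-sided p ~ 0.053
        p = correlation_p_value(0.7, 8)
        assert p == pytest.approx(0.0531, abs=2e-3)
        assert p > 0.05

    def test_n8_significance_boundary_near_0707(self):
        # at n=8 the p<0.05 rule needs |r| > ~0.707
        assert correlation_p_value(0.70, 8) > 0.05
        assert correlation_p_value(0.72, 8) < 0.05

    def test_brain_threshold_implies_significance(self):
        # every |r| > 0.85 edge at n=8 automatically satisfies p < 0.05
        for r in np.linspace(0.8501, 0.999, 50):
            assert correlation_p_value(r, 8) < 0.05


class TestCorrelationEdges:
    def test_identical_columns_kept(self, rng):
        x = rng.normal(size=8)
        table = table_from_values(np.column_stack([x, x, rng.normal(size=8)]))
        edges = correlation_edges(table, "G", r_threshold=0.9)
        pairs = {(e.a, e.b) for e in edges}
        assert ("m0", "m1") in pairs
        (edge,) = [e for e in edges if {e.a, e.b} == {"m0", "m1"}]
        assert edge.r == pytest.approx(1.0)
        assert edge.p == pytest.approx(0.0, abs=1e-12)

    def test_r_07_dropped_at_default_alpha(self):
        # deterministic pair with r ~= 0.70: p ~ 0.053 -> dropped
        rng = np.random.default_rng(17)
        for _ in range(200):
            x = rng.normal(size=8)
            y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=8)
            r, _ = stats.pearsonr(x, y)
            if 0.695 < r < 0.705:
                break
        table = table_from_values(np.column_stack([x, y]))
        edges = correlation_edges(table, "G", r_threshold=0.65, p_threshold=0.05)
        assert edges == []

    def test_matches_brute_force_oracle(self, rng):
        for k in range(100):
            n = int(rng.integers(5, 12))
            p = int(rng.integers(3, 9))
            table = table_from_values(rng.normal(size=(n, p)))
            r_thr = float(rng.uniform(0.2, 0.8))
            edges = correlation_edges(table, "G", r_thr, 0.05)
            oracle = brute_force_correlation_edges(
                table.values, table.metabolite_names, r_thr, 0.05
            )
            got = {(e.a, e.b): (e.r, e.p) for e in edges}
            assert set(got) == set(oracle)
            for pair, (r, pval) in oracle.items():
                assert got[pair][0] == pytest.approx(r, abs=1e-10)
                assert got[pair][1] == pytest.approx(pval, abs=1e-10)

    def test_invariant_under_reordering(self, rng):
        values = rng.normal(size=(10, 6))
        table = table_from_values(values)
        base = {frozenset((e.a, e.b)) for e in correlation_edges(table, "G", 0.3)}
        row_perm = rng.permutation(10)
        shuffled = table_from_values(values[row_perm])
        assert {frozenset((e.a, e.b))
                for e in correlation_edges(shuffled, "G", 0.3)} == base

    def test_constant_metabolite_excluded_with_warning(self, caplog):
        values = np.column_stack(
            [np.ones(8), np.random.default_rng(0).normal(size=(8, 2))]
        )
        with caplog.at_level("WARNING"):
            edges = correlation_edges(table_from_values(values), "G", 0.3)
        assert "constant" in caplog.text
        assert all("m0" not in (e.a, e.b) for e in edges)

    def test_rejects_small_group_and_bad_thresholds(self):
        table = table_from_values(np.random.default_rng(1).normal(size=(3, 4)))
        with pytest.raises(ValueError, match="at least 4"):
            correlation_edges(table, "G", 0.5)
        big = table_from_values(np.random.default_rng(1).normal(size=(8, 4)))
        with pytest.raises(ValueError, match="thresholds"):
            correlation_edges(big, "G", 1.5)

    def test_planted_block_recovery(self):
        # correlation block (rho=0.9, size 5) at n=30 is recovered
        mets = tuple(f"m{j}" for j in range(15))
        within_rates, between_rates = [], []
        for seed in range(20):
            design = StudyDesign(
                groups=("G", "H"),
                n_per_group=30,
                metabolites=mets,
                correlation_blocks=((mets[:5], 0.9),),
                seed=seed,
            )
            table = generate_metabolite_table(design)
            edges = {
                frozenset((e.a, e.b))
                for e in correlation_edges(table, "G", 0.65, 0.05)
            }
            within = [frozenset((mets[i], mets[j]))
                      for i in range(5) for j in range(i + 1, 5)]
            between = [frozenset((a, b)) for a in mets[:5] for b in mets[5:]]
            within_rates.append(np.mean([w in edges for w in within]))
            between_rates.append(np.mean([b in edges for b in between]))
        assert np.mean(within_rates) >= 0.95
        assert np.mean(between_rates) < 0.05


class TestNodeDirections:
    def two_group_table(self, seed=0, shift=0.0):
        design = StudyDesign(
            groups=("R", "T"),
            n_per_group=8,
            metabolites=("a", "b", "c"),
            effect_table={("a", "T"): shift} if shift else {},
            seed=seed,
        )
        return generate_metabolite_table(design)

    def test_group_vs_itself_all_unchanged(self):
        table = self.two_group_table(seed=1)
        assert set(node_directions(table, "T", "T").values()) == {"unchanged"}

    def test_planted_shift_detected_up(self):
        hits = 0
        for seed in range(100):
            table = self.two_group_table(seed=seed, shift=2.0)
            if node_directions(table, "T", "R")["a"] == "up":
                hits += 1
        assert hits >= 95

    def test_direction_flips_when_groups_swapped(self):
        table = self.two_group_table(seed=2, shift=2.0)
        fwd = node_directions(table, "T", "R")
        rev = node_directions(table, "R", "T")
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for met in table.metabolite_names:
            assert rev[met] == flip[fwd[met]]

    def test_rejects_missing_group(self):
        table = self.two_group_table()
        with pytest.raises(ValueError, match="missing"):
            node_directions(table, "T", "ZZ")


class TestStructuralEdges:
    def test_threshold_above_max_gives_empty(self):
        sim = generate_similarity_matrix(["a", "b", "c"], [("a", "b")], high=0.9)
        assert structural_edges(sim, 1.0) == []

    def test_generated_pair_recovered(self):
        sim = generate_similarity_matrix(
            ["citrate", "isocitrate", "x"], [("citrate", "isocitrate")], high=0.9
        )
        edges = structural_edges(sim, 0.8)
        assert len(edges) == 1
        assert {edges[0].a, edges[0].b} == {"citrate", "isocitrate"}
        assert edges[0].similarity == pytest.approx(0.9)

    def test_matches_upper_triangle_scan(self, rng):
        mets = [f"m{j}" for j in range(6)]
        sim = generate_similarity_matrix(mets, [(mets[0], mets[3])], seed=3)
        thr = 0.1
        edges = {frozenset((e.a, e.b)) for e in structural_edges(sim, thr)}
        oracle = set()
        mat = sim.to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                if mat[i, j] >= thr:
                    oracle.add(frozenset((mets[i], mets[j])))
        assert edges == oracle

    def test_rejects_asymmetric_matrix(self):
        mat = pd.DataFrame(
            [[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="symmetric"):
            structural_edges(mat, 0.3)


class TestAssembleNetwork:
    def test_no_edges_empty_graph(self):
        g = assemble_network([], [], {"a": "up"}, drop_isolated=True)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_parallel_edges_of_distinct_kinds(self):
        corr = [Edge("a", "b", "correlation", r=0.9, p=0.001)]
        struct = [Edge("a", "b", "structural", similarity=0.95)]
        g = assemble_network(corr, struct)
        assert g.number_of_edges() == 2
        kinds = {d["kind"] for _, _, d in g.edges(data=True)}
        assert kinds == {"correlation", "structural"}

    def test_counts_match_inputs(self, rng):
        for _ in range(20):
            mets = [f"m{j}" for j in range(int(rng.integers(3, 10)))]
            pairs = [(a, b) for i, a in enumerate(mets) for b in mets[i + 1:]]
            rng.shuffle(pairs)
            n_corr = int(rng.integers(0, len(pairs) + 1))
            corr = [Edge(a, b, "correlation", r=0.8, p=0.01)
                    for a, b in pairs[:n_corr]]
            g = assemble_network(corr, [], drop_isolated=True)
            assert g.number_of_edges() == n_corr
            expected_nodes = {m for e in corr for m in (e.a, e.b)}
            assert set(g.nodes) == expected_nodes

    def test_rejects_self_edge_and_duplicates(self):
        with pytest.raises(ValueError, match="self-edge"):
            assemble_network([Edge("a", "a", "correlation", r=1.0, p=0.0)])
        dup = [Edge("a", "b", "correlation", r=0.9, p=0.01),
               Edge("b", "a", "correlation", r=0.9, p=0.01)]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_network(dup)

    def test_direction_attributes_preserved(self):
        corr = [Edge("a", "b", "correlation", r=-0.9, p=0.001)]
        g = assemble_network(corr, [], {"a": "up", "b": "down", "zz": "up"})
        assert g.nodes["a"]["direction"] == "up"
        assert g.nodes["b"]["direction"] == "down"
        assert "zz" not in g  # isolated node dropped
        (data,) = [d for _, _, d in g.edges(data=True)]
        assert data["sign"] == "negative"


class TestExports:
    def build(self):
        corr = [Edge("a", "b", "correlation", r=0.9, p=0.001)]
        struct = [Edge("b", "c", "structural", similarity=0.85)]
        return assemble_network(corr, struct, {"a": "up", "b": "down", "c": "unchanged"})

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        g = self.build()
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.number_of_edges()

    def test_tsv_exports(self, tmp_path):
        g = self.build()
        write_edge_tsv(g, tmp_path / "edges.tsv")
        write_node_tsv(g, tmp_path / "nodes.tsv")
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        assert list(edges.columns) == [
            "metabolite_a", "metabolite_b", "kind", "r", "p", "similarity",
        ]
        assert len(edges) == 2 and len(nodes) == 3

    def test_similarity_round_trip(self, tmp_path):
        sim = generate_similarity_matrix(["a", "b", "c"], [("a", "c")], seed=2)
        sim.to_csv(tmp_path / "sim.tsv", sep="\t")
        back = read_similarity_matrix(tmp_path / "sim.tsv")
        np.testing.assert_allclose(back.to_numpy(), sim.to_numpy(), rtol=1e-9)
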