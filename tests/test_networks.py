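"""Co-expression edges, FDR control, regulatory edges and network intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import edge_rows, network_from_pairs, random_network
from ernatests_oracles import bh_quadratic_oracle

from ernakit.enhancers import EnhancerRegion
from ernakit.identify import ErnaCall
from ernakit.intervals import GenomicInterval, LoopCall, Transcript
from ernakit.networks import (
    Network,
    adjust_bh,
    adjust_pvalues,
    build_coexpression_network,
    coexpression_network,
    intersect_networks,
    loop_edges,
    regulatory_overlaps,
    spearman_edges,
    spearman_exact_p,
)

iv = GenomicInterval


def expr(rows, ids, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=samples)


def erna_call(tid, start, end, chrom="chr1"):
    tx = Transcript(tid, tid, chrom, "+", (iv(chrom, start, end, "+"),))
    return ErnaCall(tx, (EnhancerRegion(iv(chrom, start, end), ("M",)),))


class TestSpearmanEdges:
    def test_monotone_pairs_hit_plus_minus_one(self):
        e = expr([[1, 2, 3, 4, 5]], ["E1"])
        p = expr([[2, 4, 6, 8, 10], [5, 4, 3, 2, 1]], ["G1", "G2"])
        edges = spearman_edges(e, p).set_index("target")
        assert edges.loc["G1", "rho"] == pytest.approx(1.0)
        assert edges.loc["G1", "p"] == 0.0
        assert edges.loc["G2", "rho"] == pytest.approx(-1.0)
        assert edges.loc["G2", "p"] == 0.0

    def test_t_approximation_documented_case(self):
        edges = spearman_edges(expr([[1, 2, 3, 4]], ["E1"]), expr([[1, 3, 2, 4]], ["G1"]))
        assert edges["rho"][0] == pytest.approx(0.8)
        assert edges["p"][0] == pytest.approx(0.2, abs=1e-9)

    def test_exact_permutation_diverges_from_t_at_n4(self):
        """At n=4 the exact two-sided permutation p for rho=0.8 is 8/24 = 1/3,
        while the t approximation reports ~0.20."""
        assert spearman_exact_p([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(1 / 3)
        edges = spearman_edges(
            expr([[1, 2, 3, 4]], ["E1"]), expr([[1, 3, 2, 4]], ["G1"]), p_method="exact"
        )
        assert edges["p"][0] == pytest.approx(1 / 3)

    def test_zero_variance_row_is_nan(self):
        edges = spearman_edges(expr([[3, 3, 3, 3, 3]], ["E1"]), expr([[1, 2, 3, 4, 5]], ["G1"]))
        assert np.isnan(edges["rho"][0]) and np.isnan(edges["p"][0])

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            spearman_edges(
                expr([[1, 2, 3, 4]], ["E1"], list("abcd")),
                expr([[1, 2, 3, 4]], ["G1"], list("abce")),
            )

    def test_ties_use_midranks(self):
        x, y = [1, 2, 2, 3, 5], [2, 1, 4, 4, 9]
        edges = spearman_edges(expr([x], ["E1"]), expr([y], ["G1"]))
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert edges["rho"][0] == pytest.approx(ref_rho, abs=1e-12)
        assert edges["p"][0] == pytest.approx(ref_p, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        e = expr(rng.normal(size=(8, 10)), [f"E{i}" for i in range(8)])
        p = expr(rng.normal(size=(6, 10)), [f"G{i}" for i in range(6)])
        edges = spearman_edges(e, p)
        for _, row in edges.iterrows():
            ref_rho, ref_p = stats.spearmanr(
                e.loc[row["source"]], p.loc[row["target"]]
            )
            assert row["rho"] == pytest.approx(ref_rho, abs=1e-12)
            assert row["p"] == pytest.approx(ref_p, abs=1e-12)


class TestAdjustBh:
    def test_stepup_hand_computed(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert adjust_bh([0.04]) == pytest.approx([0.04])

    def test_equal_ps_unchanged(self):
        assert adjust_bh([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_nan_propagates_and_excluded_from_family(self):
        q = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(adjust_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_bonferroni_option(self):
        assert adjust_pvalues([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        q = adjust_bh(p)
        assert q == pytest.approx(bh_quadratic_oracle(p), abs=1e-12)
        assert np.all(q >= p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestBuildCoexpressionNetwork:
    def _edges(self, rows):
        e = edge_rows([(r[0], r[1]) for r in rows])
        e["rho"] = [r[2] for r in rows]
        e["q"] = [r[3] for r in rows]
        return e

    def test_rho_boundary_dropped_and_negative_kept(self):
        net = build_coexpression_network(
            self._edges([("E1", "G1", 0.29, 0.001), ("E1", "G2", -0.9, 0.01)])
        )
        assert net.edge_pairs() == {frozenset(("E1", "G2"))}
        assert net.nodes == {"E1": "erna", "G2": "pcg"}

    def test_empty_result_is_empty_network_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="ernakit"):
            net = build_coexpression_network(
                self._edges([("E1", "G1", 0.1, 0.9)])
            )
        assert net.nodes == {} and len(net.edges) == 0

    def test_edges_canonicalized_source_before_target(self):
        net = build_coexpression_network(
            self._edges([("Z9", "A1", 0.8, 0.001)])
        )
        assert list(net.edges[["source", "target"]].iloc[0]) == ["A1", "Z9"]

    def test_planted_signal_recovered_small(self):
        from ernakit.fixtures import make_expression, preset

        spec = preset("network-heavy", seed=11)
        fx = make_expression(
            spec, [f"E{i}" for i in range(20)], [f"G{i}" for i in range(26)]
        )
        net = coexpression_network(fx.erna_expr, fx.pcg_expr)
        kept = net.edge_pairs()
        planted = {frozenset(p) for p in fx.planted_pairs}
        assert len(kept & planted) >= 18  # >= 90 % of 20 planted pairs
        assert len(kept - planted) <= max(1, len(kept) // 10)


class TestRegulatoryOverlaps:
    def test_peak_counts_deduplicated_per_regulator(self):
        calls = [erna_call("E1", 1000, 2000)]
        peaks = [
            ("TF1", "tf", [iv("chr1", 1500, 1600)]),
            ("RBP1", "rbp", [iv("chr1", 1100, 1200), iv("chr1", 1300, 1400), iv("chr1", 1900, 2100)]),
            ("TF2", "tf", [iv("chr1", 2000, 2100)]),  # book-ended: no edge
        ]
        edges = regulatory_overlaps(calls, peaks)
        assert len(edges) == 2
        by_target = edges.set_index("target")
        assert by_target.loc["TF1", "evidence"] == "1"
        assert by_target.loc["RBP1", ["kind", "evidence"]].tolist() == ["rbp", "3"]


class TestLoopEdges:
    def test_anchor_to_promoter_makes_edge(self):
        calls = [erna_call("E1", 1000, 2000)]
        loops = [LoopCall(iv("chr1", 1500, 1600), iv("chr1", 49_000, 51_000))]
        edges, mediated = loop_edges(calls, loops, [("G1", "chr1", 50_000)])
        assert len(edges) == 1
        assert edges.iloc[0][["source", "target", "kind"]].tolist() == ["E1", "G1", "loop"]
        assert len(mediated) == 1

    def test_self_loop_recorded_without_gene_edge(self):
        calls = [erna_call("E1", 1000, 2000)]
        loops = [LoopCall(iv("chr1", 1000, 1200), iv("chr1", 1800, 2000))]
        edges, mediated = loop_edges(calls, loops, [("G1", "chr1", 500_000)])
        assert len(edges) == 0
        assert mediated == [("E1", loops[0])]

    def test_promoter_flank_boundary(self):
        calls = [erna_call("E1", 1000, 2000)]
        genes = [("G1", "chr1", 50_000)]
        # anchor [52000, 52100) starts exactly at the half-open promoter end
        loops = [LoopCall(iv("chr1", 1500, 1600), iv("chr1", 52_000, 52_100))]
        edges, _ = loop_edges(calls, loops, genes, promoter_flank=2000)
        assert len(edges) == 0
        loops = [LoopCall(iv("chr1", 1500, 1600), iv("chr1", 51_999, 52_100))]
        edges, _ = loop_edges(calls, loops, genes, promoter_flank=2000)
        assert len(edges) == 1


class TestIntersectNetworks:
    def test_idempotent_on_identical_networks(self):
        net = network_from_pairs([("A", "B"), ("B", "C")])
        out = intersect_networks(net, net)
        assert out.edge_pairs() == net.edge_pairs()
        assert set(out.nodes) == set(net.nodes)

    def test_shared_nodes_disjoint_edges(self):
        a = network_from_pairs([("A", "B")])
        b = network_from_pairs([("B", "C")])
        out = intersect_networks(a, b)
        assert set(out.nodes) == {"B"}
        assert len(out.edges) == 0

    def test_unordered_match_across_kinds(self):
        a = network_from_pairs([("E1", "G1")], kind="coexpr")
        b = network_from_pairs([("G1", "E1")], kind="loop")
        out = intersect_networks(a, b)
        assert len(out.edges) == 1
        row = out.edges.iloc[0]
        assert row["kind"] == "mixed" and row["evidence"] == "coexpr|loop"

    @pytest.mark.parametrize("seed", range(5))
    def test_commutative_and_subset(self, seed):
        rng = np.random.default_rng(seed)
        a = random_network(rng)
        b = random_network(rng)
        ab = intersect_networks(a, b)
        ba = intersect_networks(b, a)
        assert ab.edge_pairs() == ba.edge_pairs()
        assert set(ab.nodes) == set(ba.nodes)
        assert ab.edge_pairs() <= a.edge_pairs()
        assert ab.edge_pairs() <= b.edge_pairs()
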