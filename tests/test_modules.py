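"""Dense-module extraction, hubs, and hypergeometric gene-set enrichment."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import network_from_pairs, random_network, two_bridged_cliques
from ernatests_oracles import hypergeom_tail_exact

from ernakit.modules import (
    GeneSetCollection,
    Module,
    annotate_erna,
    extract_hubs,
    extract_modules,
    hypergeom_enrich,
    read_gmt,
)
from ernakit.networks import Network


class TestExtractModules:
    def test_two_bridged_cliques_split_exactly(self):
        mods = extract_modules(two_bridged_cliques())
        members = sorted(sorted(m.member_ids) for m in mods)
        assert members == [["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]]
        assert all(m.density == 1.0 for m in mods)

    def test_triangle_is_one_module_density_one(self):
        mods = extract_modules(network_from_pairs([("x", "y"), ("y", "z"), ("x", "z")]))
        assert len(mods) == 1
        assert mods[0].member_ids == frozenset({"x", "y", "z"})
        assert mods[0].density == 1.0

    def test_edgeless_network_yields_no_modules(self):
        net = Network({"a": "pcg", "b": "pcg"})
        assert extract_modules(net) == []

    def test_contains_ernas_tracked(self):
        net = network_from_pairs(
            [("E1", "G1"), ("E1", "G2"), ("G1", "G2")], roles={"E1": "erna"}
        )
        (mod,) = extract_modules(net)
        assert mod.contains_ernas == frozenset({"E1"})

    def test_deterministic_across_repeats(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, n_nodes=20, p=0.3)
        first = [sorted(m.member_ids) for m in extract_modules(net)]
        again = [sorted(m.member_ids) for m in extract_modules(net)]
        assert first == again

    @pytest.mark.parametrize("seed", range(20))
    def test_density_floor_and_disjointness_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_nodes=int(rng.integers(8, 25)), p=float(rng.uniform(0.1, 0.5)))
        pairs = net.edge_pairs()
        mods = extract_modules(net)
        seen = set()
        for m in mods:
            # recompute density independently from the edge list
            k = len(m.member_ids)
            within = sum(
                1
                for a, b in itertools.combinations(sorted(m.member_ids), 2)
                if frozenset((a, b)) in pairs
            )
            assert m.density == pytest.approx(2 * within / (k * (k - 1)))
            assert m.density >= 0.5
            assert k >= 2
            assert not (m.member_ids & seen), "modules must be pairwise disjoint"
            seen |= m.member_ids
        assert seen <= set(net.nodes)


class TestExtractHubs:
    def test_star_center_is_the_only_hub(self):
        pairs = [("hub", f"leaf{i}") for i in range(10)]
        assert extract_hubs(network_from_pairs(pairs)) == ["hub"]

    def test_uniform_low_degree_gives_no_hubs(self):
        cycle = [(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)]  # all degree 2
        assert extract_hubs(network_from_pairs(cycle), min_degree=5) == []

    def test_ties_at_cutoff_both_included(self):
        pairs = []
        for center in ("u", "v"):
            pairs += [(center, f"{center}_leaf{i}") for i in range(6)]
        hubs = extract_hubs(network_from_pairs(pairs), top_fraction=0.1, min_degree=5)
        assert hubs == ["u", "v"]


class TestHypergeomEnrich:
    def _collection(self, sets, universe):
        return GeneSetCollection({k: frozenset(v) for k, v in sets.items()}, frozenset(universe))

    def test_tail_value_matches_exact_enumeration(self):
        # N=20, K=6, n=5, k=3: exact tail sum = 0.13132095...
        universe = {f"g{i}" for i in range(20)}
        genes = {f"g{i}" for i in range(6)}
        query = {"g0", "g1", "g2", "g10", "g11"}
        (res,) = hypergeom_enrich(query, self._collection({"S": genes}, universe))
        assert res.k == 3
        assert res.p == pytest.approx(hypergeom_tail_exact(3, 20, 6, 5), abs=1e-12)
        assert res.p == pytest.approx(0.13132095, abs=1e-7)

    def test_zero_overlap_p_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        coll = self._collection({"S": {"g0", "g1"}}, universe)
        (res,) = hypergeom_enrich({"g5", "g6"}, coll)
        assert res.k == 0 and res.p == 1.0

    def test_set_equal_to_universe_p_is_one(self):
        universe = {f"g{i}" for i in range(8)}
        (res,) = hypergeom_enrich({"g0", "g1"}, self._collection({"ALL": universe}, universe))
        assert res.k == res.n and res.p == pytest.approx(1.0)

    def test_p_monotone_nonincreasing_in_k(self):
        N, K, n = 24, 8, 10
        ps = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        for k, p in enumerate(ps):
            assert p == pytest.approx(hypergeom_tail_exact(k, N, K, n), abs=1e-10)

    def test_query_ids_outside_universe_dropped_with_warning(self, caplog):
        universe = {"a", "b", "c", "d"}
        coll = self._collection({"S": {"a", "b"}}, universe)
        with caplog.at_level("WARNING", logger="ernakit"):
            (res,) = hypergeom_enrich({"a", "zzz"}, coll)
        assert res.n == 1
        assert "zzz" in caplog.text

    def test_results_sorted_by_p_and_bh_adjusted(self):
        universe = {f"g{i}" for i in range(30)}
        coll = self._collection(
            {"big_hit": {f"g{i}" for i in range(5)}, "miss": {"g20", "g21"}}, universe
        )
        results = hypergeom_enrich({f"g{i}" for i in range(5)}, coll)
        assert [r.set_name for r in results] == ["big_hit", "miss"]
        assert all(r.q >= r.p - 1e-15 for r in results)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection({"S": frozenset({"a"})}, frozenset())


class TestReadGmt:
    def test_roundtrip_and_default_universe(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("CYCLE\tcell cycle\tCDK4\tSOX4\tCCNE1\nMISC\t-\tTP53\n")
        coll = read_gmt(p)
        assert coll.sets["CYCLE"] == frozenset({"CDK4", "SOX4", "CCNE1"})
        assert coll.universe == frozenset({"CDK4", "SOX4", "CCNE1", "TP53"})

    def test_explicit_universe_restricts_sets(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S\t-\ta\tb\tc\n")
        coll = read_gmt(p, universe={"a", "b", "z"})
        assert coll.sets["S"] == frozenset({"a", "b"})


class TestAnnotateErna:
    def _planted_net(self):
        cycle_genes = [f"CY{i}" for i in range(6)]
        other_genes = [f"OT{i}" for i in range(6)]
        pairs = [("E1", g) for g in cycle_genes]
        pairs += [(a, b) for a, b in itertools.combinations(cycle_genes, 2)]
        pairs += [(a, b) for a, b in itertools.combinations(other_genes, 2)]
        roles = {"E1": "erna"}
        net = network_from_pairs(pairs, roles=roles)
        universe = frozenset(cycle_genes + other_genes + [f"BG{i}" for i in range(20)])
        coll = GeneSetCollection(
            {"CELL_CYCLE": frozenset(cycle_genes), "OTHER": frozenset(other_genes)},
            universe,
        )
        return net, coll

    def test_planted_set_ranks_first_by_neighbor_enrichment(self):
        net, coll = self._planted_net()
        report = annotate_erna("E1", net, extract_modules(net), coll)
        assert report.neighbor_query == {f"CY{i}" for i in range(6)}
        assert report.neighbor_enrichment[0].set_name == "CELL_CYCLE"
        assert report.neighbor_enrichment[0].p < report.neighbor_enrichment[1].p
        # verify against the exact tail oracle
        top = report.neighbor_enrichment[0]
        assert top.p == pytest.approx(
            hypergeom_tail_exact(top.k, top.N, top.K, top.n), abs=1e-10
        )

    def test_module_query_contains_module_pcgs(self):
        net, coll = self._planted_net()
        mods = extract_modules(net)
        report = annotate_erna("E1", net, mods, coll)
        assert report.module_queries, "E1 should fall inside one dense module"
        for mod, query in report.module_queries:
            assert "E1" in mod.member_ids
            assert query <= mod.member_ids

    def test_isolated_erna_warns_and_returns_empty(self, caplog):
        net = Network({"E1": "erna", "G1": "pcg"})
        coll = GeneSetCollection({"S": frozenset({"G1"})}, frozenset({"G1"}))
        with caplog.at_level("WARNING", logger="ernakit"):
            report = annotate_erna("E1", net, [], coll)
        assert report.neighbor_query == set()
        assert all(r.k == 0 for r in report.neighbor_enrichment)

    def test_unknown_erna_rejected(self):
        net = Network({"E1": "erna"})
        coll = GeneSetCollection({"S": frozenset({"a"})}, frozenset({"a"}))
        with pytest.raises(KeyError):
            annotate_erna("NOPE", net, [], coll)


class TestModuleInvariants:
    def test_module_validation(self):
        with pytest.raises(ValueError):
            Module(frozenset({"a"}), 1.0)
        with pytest.raises(ValueError):
            Module(frozenset({"a", "b"}), 1.5)
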