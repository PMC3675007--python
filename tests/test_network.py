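"""PPI connectivity, permutation nulls, expansion, components, hub test."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnvnet import (
    CandidateTable,
    connectivity_permutation_test,
    cross_network_connectivity,
    direct_connectivity,
    expand_network,
    largest_component,
    load_ppi_edges,
    singleton_hub_test,
)


class TestLoadPPIEdges:
    def test_dedup_and_self_loop_dropped(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("a\tb\nb\ta\nc\tc\n")
        net = load_ppi_edges(path)
        assert net.number_of_edges() == 1
        assert net.graph["self_loops_dropped"] == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("")
        net = load_ppi_edges(path)
        assert net.number_of_nodes() == 0

    def test_fixture_audit(self, tmp_path):
        rows = ["a\tb", "a\tc", "b\tc", "c\td", "d\te", "e\ta", "f\tg",
                "g\tf", "h\th", "a\tb"]
        path = tmp_path / "ppi.tsv"
        path.write_text("\n".join(rows) + "\n")
        net = load_ppi_edges(path)
        # hand count: unique undirected edges excluding the self-loop
        assert net.number_of_edges() == 7
        assert net.number_of_nodes() == 7

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("a\tb\nbroken_line\n")
        with pytest.raises(ValueError, match=":2"):
            load_ppi_edges(path)


class TestDirectConnectivity:
    def test_triangle(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert direct_connectivity({"a", "b", "c"}, net) == 3

    def test_singleton_and_absent_genes(self):
        net = nx.Graph([("a", "b")])
        assert direct_connectivity({"a"}, net) == 0
        assert direct_connectivity({"a", "zzz"}, net) == 0

    def test_matches_pair_scan_oracle_and_monotone(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            net = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(2**31)))
            net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
            query = [f"g{i}" for i in rng.choice(25, size=10, replace=False)]
            oracle = sum(
                1
                for u, v in itertools.combinations(set(query), 2)
                if net.has_edge(u, v)
            )
            assert direct_connectivity(query, net) == oracle
            bigger = set(query) | {f"g{int(rng.integers(25))}"}
            assert direct_connectivity(bigger, net) >= oracle


class TestConnectivityPermutation:
    def test_planted_module_hits_the_floor(self, world):
        module = world.truth["planted_module"]
        result = connectivity_permutation_test(
            module, world.ppi, sorted(world.ppi.nodes), n_perms=500, rng=7
        )
        assert result.p_emp == pytest.approx(1 / 501)
        assert result.fold > 10

    def test_pool_smaller_than_query_rejected(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="pool"):
            connectivity_permutation_test(["a", "b"], net, ["a"], n_perms=10)

    def test_bit_reproducible_and_p_never_zero(self, world):
        module = world.truth["planted_module"]
        pool = sorted(world.ppi.nodes)
        a = connectivity_permutation_test(module, world.ppi, pool, 100, rng=3)
        b = connectivity_permutation_test(module, world.ppi, pool, 100, rng=3)
        assert a.p_emp == b.p_emp and (a.null_counts == b.null_counts).all()
        assert a.p_emp >= 1 / 101

    def test_matched_pool_discounts_annotation_effect(self, world):
        """Against the pool of genes sharing the planted category the fold
        stays finite and the estimate remains reproducible."""
        module = world.truth["planted_module"]
        pool = sorted(
            set(world.category_pool(world.truth["planted_term_category"]))
            | set(module)
        )
        r = connectivity_permutation_test(
            module, world.ppi, pool, 200, rng=4, pool_label="matched"
        )
        assert r.pool_label == "matched" and r.p_emp <= 0.05


class TestExpandNetwork:
    def test_single_edge_expansion(self):
        net = nx.Graph([("a", "b"), ("b", "z")])
        table = expand_network(["a"], ["b", "q"], net)
        assert table.genes == {"a", "b"}
        assert table.edges == [("a", "b")]

    def test_gene_without_seed_contact_excluded(self):
        net = nx.Graph([("a", "b"), ("c", "d")])
        table = expand_network(["a"], ["c", "d"], net)
        assert table.genes == {"a"}

    def test_matches_adjacency_oracle(self, world):
        rng = np.random.default_rng(41)
        nodes = sorted(world.ppi.nodes)
        seed = [nodes[i] for i in rng.choice(len(nodes), 30, replace=False)]
        cnv_genes = [nodes[i] for i in rng.choice(len(nodes), 200, replace=False)]
        table = expand_network(seed, cnv_genes, world.ppi)
        expected = set(seed) | {
            g
            for g in set(cnv_genes) - set(seed)
            if any(world.ppi.has_edge(g, s) for s in seed)
        }
        assert table.genes == expected

    def test_degree_counted_within_induced_subgraph(self):
        net = nx.Graph([("a", "b"), ("a", "x1"), ("a", "x2"), ("a", "x3")])
        table = expand_network(["a"], ["b"], net)
        degrees = table.degrees()
        assert degrees["a"] == 1  # x1..x3 are outside the candidate set


class TestLargestComponent:
    def test_path_plus_isolate(self):
        sizes = largest_component([("a", "b"), ("b", "c")], ["a", "b", "c", "d"])
        assert sizes == [3, 1]

    def test_edgeless_graph(self):
        assert largest_component([], list("abcde")) == [1] * 5

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n = int(rng.integers(2, 40))
            g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(2**31)))
            edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
            nodes = [f"n{i}" for i in range(n)]
            # independent union-find implementation
            parent = {x: x for x in nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in edges:
                parent[find(u)] = find(v)
            from collections import Counter

            oracle = sorted(Counter(find(x) for x in nodes).values(), reverse=True)
            assert largest_component(edges, nodes) == oracle


def make_candidates(rows, edges=()):
    """rows: (gene, degree, patients)"""
    df = pd.DataFrame(
        [
            {
                "gene_id": g,
                "evidence": "synaptic-phenotype",
                "directions": frozenset({"gain"}),
                "degree": d,
                "patients": frozenset(ps),
            }
            for g, d, ps in rows
        ]
    )
    return CandidateTable(df=df, edges=list(edges))


class TestSingletonHubTest:
    def test_constructed_medians(self):
        table = make_candidates(
            [("h1", 3, {"p1"}), ("h2", 3, {"p2"}), ("h3", 3, {"p3"}),
             ("m1", 1, {"p4", "p5"}), ("m2", 1, {"p4", "p5"}),
             ("m3", 1, {"p4", "p5"})]
        )
        result = singleton_hub_test(table)
        assert result.median_single == 3 and result.median_multi == 1

    def test_identical_groups_give_p_one(self):
        table = make_candidates(
            [("a", 2, {"p1"}), ("b", 2, {"p2"}),
             ("c", 2, {"p3", "p4"}), ("d", 2, {"p3", "p4"})]
        )
        assert singleton_hub_test(table).p_value == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        table = make_candidates([("a", 2, {"p1"}), ("b", 1, {"p2"})])
        with pytest.raises(ValueError, match="non-empty"):
            singleton_hub_test(table)

    def test_small_groups_match_exact_enumeration(self):
        """Tie-free degrees: two-sided p equals the exact permutation null of
        the U statistic enumerated over all group assignments."""
        rng = np.random.default_rng(47)
        for _ in range(10):
            nA, nB = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            vals = list(rng.choice(200, size=nA + nB, replace=False))
            A, B = vals[:nA], vals[nA:]
            rows = [(f"s{i}", int(v), {f"ps{i}"}) for i, v in enumerate(A)]
            # one patient carries every multi gene -> its count is nB > 1
            rows += [(f"m{i}", int(v), {"pm"}) for i, v in enumerate(B)]
            table = make_candidates(rows)
            got = singleton_hub_test(table)
            obsA, obsB = list(A), list(B)

            def ustat(a, b):
                return sum(
                    (x > y) + 0.5 * (x == y) for x in a for y in b
                )

            u_obs = ustat(obsA, obsB)
            pooled = obsA + obsB
            total = 0
            extreme = 0
            mu = len(obsA) * len(obsB) / 2
            for idx in itertools.combinations(range(len(pooled)), len(obsA)):
                a = [pooled[i] for i in idx]
                b = [pooled[i] for i in range(len(pooled)) if i not in idx]
                total += 1
                if abs(ustat(a, b) - mu) >= abs(u_obs - mu) - 1e-9:
                    extreme += 1
            assert got.p_value == pytest.approx(extreme / total, abs=1e-9)


class TestCrossNetworkConnectivity:
    def test_bipartite_saturation_gives_large_fold(self):
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        isolated = [f"z{i}" for i in range(60)]
        net = nx.Graph([(x, y) for x in a for y in b])
        net.add_nodes_from(isolated)
        result = cross_network_connectivity(
            a, b, net, b + isolated, n_perms=200, rng=2
        )
        assert result.observed_edges == 16
        assert result.fold > 5
        assert result.p_emp == pytest.approx(1 / 201)

    def test_complete_overlap_is_an_error(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="emptied"):
            cross_network_connectivity(["a"], ["a"], net, ["a", "b"])

    def test_observed_counts_cross_edges_only(self):
        net = nx.Graph([("a1", "a2"), ("a1", "b1"), ("b1", "b2"), ("a2", "b2")])
        result = cross_network_connectivity(
            ["a1", "a2"], ["b1", "b2"], net,
            ["b1", "b2", "c1", "c2", "c3"], n_perms=50, rng=1,
        )
        # a1-b1 and a2-b2 cross; a1-a2 and b1-b2 do not
        assert result.observed_edges == 2
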