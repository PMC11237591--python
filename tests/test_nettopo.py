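import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nichevol.containers import CommunityTable
from nichevol.netinfer import greedy_modules
from nichevol.nettopo import (classify_role, functional_complementarity,
                              global_efficiency, interdomain_network,
                              keystone_tally, niche_overlap,
                              removal_experiment, robustness, vulnerability,
                              zi_pi)
from nichevol.synth import generate_correlated_compositions


def brute_efficiency(graph):
    """Independent global-efficiency oracle: BFS shortest paths by hand."""
    nodes = list(graph.nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        total += sum(1.0 / d for v, d in dist.items() if d > 0)
    return total / (n * (n - 1))


class TestZiPi:
    def test_all_links_inside_module_give_zero_pi(self):
        g = nx.complete_graph(4)
        modules = {n: 0 for n in g}
        roles = zi_pi(g, modules)
        assert all(r.pi == 0.0 for r in roles)

    def test_even_split_across_two_modules_gives_half(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        modules = {"x": 0, "a": 0, "b": 1}
        role = {r.taxon: r for r in zi_pi(g, modules)}
        assert role["x"].pi == pytest.approx(0.5)

    def test_node_at_module_mean_has_zero_zi(self):
        g = nx.complete_graph(4)
        roles = zi_pi(g, {n: 0 for n in g})
        assert all(r.zi == 0.0 for r in roles)  # sd 0 convention and mean

    def test_matches_direct_formula_on_random_graph(self):
        g = nx.gnp_random_graph(12, 0.5, seed=2)
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
        modules, _ = greedy_modules(g)
        for r in zi_pi(g, modules):
            node = int(r.taxon)
            k = g.degree(node)
            per = {}
            for nb in g.neighbors(node):
                per[modules[nb]] = per.get(modules[nb], 0) + 1
            assert r.pi == pytest.approx(
                1 - sum((c / k) ** 2 for c in per.values()))

    def test_isolated_node_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(ValueError):
            zi_pi(g, {"a": 0, "b": 0, "c": 1})


class TestClassifyRole:
    @pytest.mark.parametrize("zi,pi,expected", [
        (3.0, 0.10, "module_hub"),
        (1.0, 0.70, "connector"),
        (2.5, 0.62, "network_hub"),   # boundaries inclusive
        (0.0, 0.0, "peripheral"),
        (2.49, 0.61, "peripheral"),
    ])
    def test_thresholds(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_roles_partition_the_plane(self):
        for zi in np.linspace(-2, 4, 13):
            for pi in np.linspace(0, 1, 11):
                assert classify_role(zi, pi) in {
                    "network_hub", "module_hub", "connector", "peripheral"}


class TestKeystoneTally:
    def test_proportion_example(self):
        from nichevol.containers import NodeRole
        roles = [NodeRole("s1", 3, 0.1, "module_hub"),
                 NodeRole("s2", 0, 0.7, "connector"),
                 NodeRole("s3", 0, 0.1, "peripheral")]
        classes = {"s1": "specialist", "s2": "specialist",
                   "s3": "specialist"}
        df = keystone_tally(roles, classes, {"specialist": 10})
        assert df.loc[df.niche_class == "specialist",
                      "proportion"].iloc[0] == pytest.approx(0.2)

    def test_no_keystones(self):
        from nichevol.containers import NodeRole
        roles = [NodeRole("a", 0, 0.1, "peripheral")]
        df = keystone_tally(roles, {"a": "generalist"})
        assert (df.proportion == 0).all()


class TestRemovalExperiment:
    def test_star_hub_removal_isolates_everything(self):
        g = nx.star_graph(6)  # node 0 is the hub
        rep = removal_experiment(g, [0, 1], fraction=0.5, reps=20, seed=1)
        # one node removed per rep; when the hub goes, nothing remains
        assert rep.remaining_mean < 1.0

    def test_star_remove_hub_directly(self):
        g = nx.star_graph(6)
        g2 = g.copy()
        g2.remove_node(0)
        assert sum(1 for n in g2 if g2.degree(n) > 0) == 0

    def test_clique_half_removal_leaves_half(self):
        g = nx.complete_graph(10)
        rep = removal_experiment(g, list(g.nodes), fraction=0.5, reps=10,
                                 seed=2)
        assert rep.remaining_mean == pytest.approx(0.5)
        assert rep.remaining_sd == 0.0

    def test_fraction_zero_returns_all(self):
        g = nx.complete_graph(5)
        rep = removal_experiment(g, list(g.nodes), fraction=0.0, reps=5,
                                 seed=0)
        assert rep.remaining_mean == 1.0

    def test_matches_independent_reimplementation(self):
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        targets = list(range(10))
        rep = removal_experiment(g, targets, fraction=0.5, reps=100,
                                 seed=21)
        rng = np.random.default_rng(21)
        vals = []
        for _ in range(100):
            drop = set(rng.choice(targets, size=5, replace=False))
            keep = [n for n in g if n not in drop]
            sub = g.subgraph(keep)
            vals.append(sum(1 for n in sub if sub.degree(n) > 0)
                        / g.number_of_nodes())
        assert rep.remaining_mean == pytest.approx(np.mean(vals))

    def test_absent_class_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError):
            removal_experiment(g, ["zz"], reps=5, seed=0)


class TestVulnerability:
    def test_complete_graph_is_invulnerable(self):
        assert vulnerability(nx.complete_graph(4)) == pytest.approx(0.0)

    def test_path_of_three_hand_computed(self):
        # E = (4*1 + 2*0.5)/6 = 5/6; removing the middle node kills all
        # paths (E=0), contribution (E-0)/E = 1
        assert vulnerability(nx.path_graph(3)) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1000)))
            if global_efficiency(g) == 0:
                continue
            e = brute_efficiency(g)
            worst = max(
                (e - brute_efficiency(g.subgraph(set(g) - {v}))) / e
                for v in g)
            assert vulnerability(g) == pytest.approx(worst)

    def test_articulation_point_raises_vulnerability(self):
        chain = nx.path_graph(5)
        bypass = chain.copy()
        bypass.add_edge(1, 3)  # bridges around the cut vertex
        assert vulnerability(chain) >= vulnerability(bypass)


class TestRobustness:
    def test_clique_matches_exact_enumeration(self):
        """For K4 every removal order yields the same attack curve, so the
        exact area is computable by hand."""
        g = nx.complete_graph(4)
        # curve after k removals: 1, 3/4, 2/4, 0, 0 (last survivor isolated)
        curve = [1.0, 0.75, 0.5, 0.0, 0.0]
        exact = np.trapezoid(curve, dx=0.25)
        assert robustness(g, reps=5, seed=0) == pytest.approx(exact)

    def test_star_less_robust_than_clique(self):
        star = nx.star_graph(7)
        clique = nx.complete_graph(8)
        assert robustness(star, reps=500, seed=3) < robustness(
            clique, reps=10, seed=3)

    def test_seeded_determinism(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        assert robustness(g, reps=50, seed=7) == robustness(g, reps=50,
                                                            seed=7)

    def test_matches_exhaustive_enumeration_small_graphs(self):
        """Expected attack-curve area by enumerating all removal orders."""
        rng = np.random.default_rng(13)
        for _ in range(5):
            g = nx.gnp_random_graph(5, 0.5, seed=int(rng.integers(1000)))
            if g.number_of_edges() == 0:
                continue
            nodes = list(g.nodes)
            areas = []
            for order in itertools.permutations(nodes):
                h = g.copy()
                curve = [1.0]
                for v in order:
                    h.remove_node(v)
                    curve.append(sum(1 for u in h if h.degree(u) > 0) / 5)
                areas.append(np.trapezoid(curve, dx=0.2))
            exact = np.mean(areas)
            est = robustness(g, reps=3000, seed=4)
            assert abs(est - exact) < 0.02


class TestBipartiteDescriptors:
    def _toy_graph(self):
        g = nx.Graph()
        g.add_edges_from([("p1", "e1"), ("p1", "e2"),
                          ("p2", "e1"), ("p2", "e2"),
                          ("p3", "e3"), ("p4", "e3"), ("p4", "e2")])
        return g

    def test_identical_partner_sets_contribute_zero(self):
        g = self._toy_graph()
        # p1 and p2 share exactly {e1, e2}
        fc = functional_complementarity(g, ["p1", "p2"])
        assert fc == pytest.approx(0.0)

    def test_disjoint_partner_sets_distance_one(self):
        g = self._toy_graph()
        fc = functional_complementarity(g, ["p1", "p3"])
        # single merge at height 1 -> two branches of length 1
        assert fc == pytest.approx(2.0)

    def test_matches_manual_average_linkage(self):
        g = self._toy_graph()
        # distances: d(p1,p2)=0, d(p1,p3)=1, d(p1,p4)=2/3, d(p2,p3)=1,
        # d(p2,p4)=2/3, d(p3,p4)=1/2
        from scipy.cluster.hierarchy import linkage
        z = linkage([0.0, 1.0, 2 / 3, 1.0, 2 / 3, 0.5], method="average")
        heights = {4: 0.0}
        total = 0.0
        node_h = [0.0] * 4 + [0.0] * 3
        for k, (a, b, h, _) in enumerate(z):
            total += (h - node_h[int(a)]) + (h - node_h[int(b)])
            node_h[4 + k] = h
        assert functional_complementarity(
            g, ["p1", "p2", "p3", "p4"]) == pytest.approx(total)

    def test_niche_overlap_identical_is_one(self):
        g = self._toy_graph()
        assert niche_overlap(g, ["p1", "p2"]) == pytest.approx(1.0)

    def test_niche_overlap_disjoint_is_zero(self):
        g = self._toy_graph()
        assert niche_overlap(g, ["p1", "p3"]) == pytest.approx(0.0)

    def test_niche_overlap_matches_direct_formula(self):
        g = self._toy_graph()
        sides = ["p1", "p2", "p3", "p4"]
        got = niche_overlap(g, sides)
        partners = {p: set(g.neighbors(p)) for p in sides}
        vals = []
        for a, b in itertools.combinations(sides, 2):
            x, y = partners[a], partners[b]
            num = 2 * len(x & y)
            den = (1 / len(x) + 1 / len(y)) * len(x) * len(y) / 1
            # Morisita-Horn with binary profiles:
            den = (len(x) / len(x) ** 2 + len(y) / len(y) ** 2) \
                * len(x) * len(y)
            vals.append(num / den)
        assert got == pytest.approx(np.mean(vals))


class TestInterdomainNetwork:
    def test_planted_cross_domain_edge_recovered(self):
        corr = np.eye(12)
        corr[2, 8] = corr[8, 2] = 0.9
        counts = generate_correlated_compositions(corr, n_samples=150,
                                                  depth=4000, seed=21)
        samples = list(counts.columns)
        meta = pd.DataFrame({"habitat": "moss", "park": "P1",
                             "x": 0.0, "y": 0.0}, index=samples)
        prok = CommunityTable(counts.iloc[:6], meta)
        euk_counts = counts.iloc[6:].copy()
        prok_strict = list(prok.counts.index)
        euk_strict = list(euk_counts.index)
        euk = CommunityTable(euk_counts, meta)
        g = interdomain_network(prok, euk, prok_strict, euk_strict,
                                n_bootstrap=50, seed=3)
        assert g.has_edge(counts.index[2], counts.index[8])
        domains = {g.nodes[n]["domain"] for n in g.nodes}
        assert domains <= {"prokaryote", "microeukaryote"}

    def test_sample_mismatch_rejected(self):
        corr = np.eye(8)
        counts = generate_correlated_compositions(corr, 40, 1000, seed=2)
        meta = pd.DataFrame({"habitat": "moss", "park": "P1",
                             "x": 0.0, "y": 0.0}, index=counts.columns)
        table = CommunityTable(counts.iloc[:4], meta)
        other_counts = counts.iloc[4:, :30]
        meta2 = meta.iloc[:30]
        other = CommunityTable(other_counts, meta2)
        with pytest.raises(ValueError, match="sample"):
            interdomain_network(table, other, list(table.counts.index),
                                list(other.counts.index))
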