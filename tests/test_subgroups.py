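import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from copredict.network import CoPredNetwork, build_network
from copredict.rules import RuleModel
from copredict.subgroups import (
    assign_rules_to_subgroups,
    balanced_distance,
    betweenness_distance,
    kendall_distance_matrix,
    permutation_test,
    subtype_support_distribution,
)
from tests.conftest import make_rule, random_rules


def meta_for(subtypes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for subtype, n in subtypes.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{subtype}_{i}",
                    "cohort_id": "c1",
                    "class": "control" if subtype == "control" else "case",
                    "subtype": subtype,
                }
            )
    return pd.DataFrame(rows)


def net_from_edges(edges) -> CoPredNetwork:
    g = nx.Graph()
    for a, b in edges:
        g.add_edge((a, 1), (b, 1), raw=1.0)
    for n in g.nodes:
        g.nodes[n]["raw"] = 1.0
    return CoPredNetwork(graph=g)


class TestAssignment:
    def test_single_subtype_support(self):
        meta = meta_for({"control": 5, "autism": 5, "AS": 5})
        rule = make_rule([("g", 3)], support=["autism_0", "autism_1"])
        model = RuleModel(rules=[rule], class_totals={})
        assert set(assign_rules_to_subgroups(model, meta)) == {"autism"}

    def test_multi_subtype_support(self):
        meta = meta_for({"control": 5, "AS": 5, "PDD-NOS": 5})
        rule = make_rule([("g", 3)], support=["AS_0", "PDD-NOS_2"])
        model = RuleModel(rules=[rule], class_totals={})
        assert set(assign_rules_to_subgroups(model, meta)) == {"AS", "PDD-NOS"}

    def test_empty_support_assigned_nowhere(self):
        meta = meta_for({"control": 5, "autism": 5})
        model = RuleModel(rules=[make_rule([("g", 3)], support=[])], class_totals={})
        assert assign_rules_to_subgroups(model, meta) == {}

    def test_unknown_sample_warns(self):
        meta = meta_for({"control": 2})
        model = RuleModel(rules=[make_rule([("g", 1)], support=["ghost"])], class_totals={})
        with pytest.warns(UserWarning, match="missing subtype"):
            assert assign_rules_to_subgroups(model, meta) == {}

    def test_proportional_mode_suppresses_single_sample_overlap(self):
        meta = meta_for({"control": 10, "autism": 10, "AS": 10})
        support = [f"autism_{i}" for i in range(8)] + ["AS_0"]
        model = RuleModel(rules=[make_rule([("g", 3)], support=support)], class_totals={})
        assign = assign_rules_to_subgroups(model, meta, mode="proportional", min_share=0.3)
        assert set(assign) == {"autism"}

    def test_bad_mode_rejected(self):
        meta = meta_for({"control": 2})
        model = RuleModel(rules=[], class_totals={})
        with pytest.raises(ValueError):
            assign_rules_to_subgroups(model, meta, mode="bogus")


class TestSupportDistribution:
    def test_full_subtype_coverage(self):
        meta = meta_for({"autism": 40, "control": 10})
        rule = make_rule([("g", 3)], support=[f"autism_{i}" for i in range(40)])
        dist = subtype_support_distribution(rule, meta)
        assert dist["autism"] == pytest.approx(100.0)

    def test_partial_coverage(self):
        meta = meta_for({"autism": 40, "AS": 50})
        support = [f"autism_{i}" for i in range(10)] + [f"AS_{i}" for i in range(5)]
        dist = subtype_support_distribution(make_rule([("g", 3)], support=support), meta)
        assert dist["autism"] == pytest.approx(25.0)
        assert dist["AS"] == pytest.approx(10.0)

    def test_empty_support_all_zero(self):
        meta = meta_for({"autism": 4, "control": 4})
        dist = subtype_support_distribution(make_rule([("g", 3)], support=[]), meta)
        assert set(dist.values()) == {0.0}


class TestBetweennessDistance:
    def test_identical_networks(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        assert betweenness_distance(net, net) == 0.0

    def test_path_vs_triangle(self):
        # path a-b-c: betweenness (0,1,0); triangle: (0,0,0); distance 1
        path = net_from_edges([("a", "b"), ("b", "c")])
        triangle = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert betweenness_distance(path, triangle) == pytest.approx(1.0)

    def test_cross_checked_against_igraph(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(0)
        for _ in range(10):
            rules_a = random_rules(rng, 12)
            rules_b = random_rules(rng, 12)
            net_a, net_b = build_network(rules_a), build_network(rules_b)
            union = sorted(set(net_a.graph.nodes) | set(net_b.graph.nodes))
            vecs = []
            for net in (net_a, net_b):
                g = igraph.Graph()
                names = [str(n) for n in net.graph.nodes]
                g.add_vertices(names)
                g.add_edges([(str(a), str(b)) for a, b in net.graph.edges])
                bc = dict(zip(names, g.betweenness()))
                vecs.append(np.array([bc.get(str(n), 0.0) for n in union]))
            expected = float(np.linalg.norm(vecs[0] - vecs[1]))
            assert betweenness_distance(net_a, net_b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = build_network(random_rules(rng, 10))
            b = build_network(random_rules(rng, 10))
            assert betweenness_distance(a, b) == pytest.approx(betweenness_distance(b, a))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            nets = [build_network(random_rules(rng, 8)) for _ in range(3)]
            d01 = betweenness_distance(nets[0], nets[1])
            d12 = betweenness_distance(nets[1], nets[2])
            d02 = betweenness_distance(nets[0], nets[2])
            assert d02 <= d01 + d12 + 1e-9

    def test_both_empty_warn(self):
        empty = CoPredNetwork(graph=nx.Graph())
        with pytest.warns(UserWarning):
            assert betweenness_distance(empty, empty) == 0.0


class TestBalancedDistance:
    def test_equal_sizes_single_resample_equals_plain(self):
        rng = np.random.default_rng(0)
        rules_a, rules_b = random_rules(rng, 8), random_rules(rng, 8)
        plain = betweenness_distance(build_network(rules_a), build_network(rules_b))
        assert balanced_distance(rules_a, rules_b, n_balance=1, seed=5) == pytest.approx(plain)

    def test_identical_rule_lists(self):
        rng = np.random.default_rng(1)
        rules = random_rules(rng, 10)
        assert balanced_distance(rules, rules, n_balance=3, seed=0) == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        a, b = random_rules(rng, 12), random_rules(rng, 7)
        assert balanced_distance(a, b, seed=9) == balanced_distance(a, b, seed=9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balanced_distance([], [make_rule([("a", 1)])])


class TestPermutationTest:
    def test_identical_assignments_give_p_one(self):
        rng = np.random.default_rng(3)
        rules = random_rules(rng, 8)
        meta = meta_for({"control": 4, "autism": 4})
        model = RuleModel(rules=rules, class_totals={})
        results = permutation_test(
            model, meta, n_perm=30, n_balance=2, seed=0,
            assignment={"A": rules, "B": list(rules)},
        )
        assert results[0].observed_distance == 0.0
        assert results[0].permutation_p == 1.0

    def test_p_lower_bound(self):
        rng = np.random.default_rng(4)
        assignment = {"A": random_rules(rng, 10), "B": random_rules(rng, 10)}
        model = RuleModel(rules=assignment["A"] + assignment["B"], class_totals={})
        results = permutation_test(
            model, meta_for({"control": 2, "autism": 2}), n_perm=50, n_balance=2,
            seed=1, assignment=assignment,
        )
        for r in results:
            assert r.permutation_p >= 1.0 / 51.0

    def test_small_subgroup_excluded(self):
        rng = np.random.default_rng(5)
        assignment = {
            "A": random_rules(rng, 6),
            "B": random_rules(rng, 6),
            "C": random_rules(rng, 1),
        }
        model = RuleModel(rules=[], class_totals={})
        with pytest.warns(UserWarning, match="excluded"):
            results = permutation_test(
                model, meta_for({"control": 2}), n_perm=10, n_balance=1, seed=0,
                assignment=assignment,
            )
        assert {(r.subgroup_a, r.subgroup_b) for r in results} == {("A", "B")}

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        assignment = {"A": random_rules(rng, 8), "B": random_rules(rng, 8)}
        model = RuleModel(rules=[], class_totals={})
        kw = dict(n_perm=20, n_balance=2, seed=11, assignment=assignment)
        r1 = permutation_test(model, meta_for({"control": 2}), **kw)
        r2 = permutation_test(model, meta_for({"control": 2}), **kw)
        assert [(x.observed_distance, x.permutation_p) for x in r1] == [
            (x.observed_distance, x.permutation_p) for x in r2
        ]


class TestKendallDistance:
    @staticmethod
    def brute_force_tau_b(x, y):
        """Pair-counting tau-b, the independent oracle."""
        n = len(x)
        concordant = discordant = tx = ty = 0
        for i, j in itertools.combinations(range(n), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
        n0 = n * (n - 1) / 2
        return (concordant - discordant) / np.sqrt((n0 - tx) * (n0 - ty))

    def test_identical_vectors(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        assert kendall_distance_matrix(table).at["a", "b"] == pytest.approx(0.0)

    def test_reversed_rankings(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        assert kendall_distance_matrix(table).at["a", "b"] == pytest.approx(2.0)

    def test_single_swap_against_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
        assert self.brute_force_tau_b(x, y) == pytest.approx(2.0 / 3.0)
        table = pd.DataFrame([x, y], index=["a", "b"])
        assert kendall_distance_matrix(table).at["a", "b"] == pytest.approx(1.0 / 3.0)

    def test_constant_vector_warns(self):
        table = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            assert kendall_distance_matrix(table).at["a", "b"] == 1.0

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        d = kendall_distance_matrix(table)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_single_subgroup_rejected(self):
        with pytest.raises(ValueError):
            kendall_distance_matrix(pd.DataFrame([[1.0, 2.0]], index=["a"]))
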