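"""Huff choice model, accessibility, criticality, isolation, compounding, comparison."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cityaccess import (
    Amenity,
    HazardRule,
    ValidationError,
    accessibility,
    allocate_population,
    apply_rule,
    baseline_scenario,
    choice_matrix,
    compare_scenarios,
    compound_aggregate,
    criticality,
    huff_probabilities,
    isolation,
    travel_times,
)
from cityaccess.metrics import (
    AccessibilityResult,
    CriticalityResult,
    access_share_table,
)
from cityaccess.network_model import Origin, OriginSet, edge_key
from cityaccess.routing import ODMatrix
from tests.conftest import random_road_graph


def od_from(times, origin_ids=None, dest_ids=None, weights=None):
    times = np.asarray(times, dtype=float)
    n, m = times.shape
    return ODMatrix(
        origin_ids=origin_ids or [f"o{i}" for i in range(n)],
        dest_ids=dest_ids or [f"f{j}" for j in range(m)],
        times=times,
        origin_weights=None if weights is None else np.asarray(weights, dtype=float),
    )


class TestHuffProbabilities:
    def test_single_reachable_facility_gets_probability_one(self):
        od = od_from([[7.0, math.inf]])
        p = huff_probabilities(od, [100.0, 100.0], 0)
        assert p.tolist() == [1.0, 0.0]

    def test_equal_areas_equal_times_split_evenly(self):
        od = od_from([[10.0, 10.0]])
        p = huff_probabilities(od, [500.0, 500.0], 0)
        assert p.tolist() == [0.5, 0.5]

    def test_area_ratio_two_to_one_at_equal_times(self):
        od = od_from([[10.0, 10.0]])
        p = huff_probabilities(od, [200.0, 100.0], 0)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], rtol=1e-12)

    def test_negative_area_rejected(self):
        od = od_from([[10.0]])
        with pytest.raises(ValidationError):
            huff_probabilities(od, [-5.0], 0)

    def test_no_reachable_facility_gives_zero_vector(self):
        od = od_from([[math.inf, math.inf]])
        p = huff_probabilities(od, [100.0, 100.0], 0)
        assert p.tolist() == [0.0, 0.0]
        assert od.isolated_mask()[0]

    def test_colocated_origin_uses_time_floor_not_infinity(self):
        od = od_from([[0.0, 10.0]])
        p = huff_probabilities(od, [100.0, 100.0], 0)
        assert 0 < p[1] < p[0] < 1
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rows_normalize_over_reachable_set(self, seed):
        """Sum of Huff probabilities over reachable facilities is 1 (tol 1e-12)."""
        rng = np.random.default_rng(seed)
        t = rng.uniform(1, 120, size=(6, 4))
        t[rng.random(t.shape) < 0.3] = math.inf
        od = od_from(t)
        cm = choice_matrix(od, rng.uniform(100, 10_000, size=4))
        for i in range(6):
            if np.isfinite(t[i]).any():
                assert cm.probabilities[i].sum() == pytest.approx(1.0, abs=1e-12)
            assert (cm.probabilities[i][~np.isfinite(t[i])] == 0).all()

    def test_scale_invariance_of_areas(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 60, size=(4, 3))
        areas = rng.uniform(100, 5000, size=3)
        od = od_from(t)
        p1 = choice_matrix(od, areas).probabilities
        p2 = choice_matrix(od, areas * 137.5).probabilities
        np.testing.assert_allclose(p1, p2, rtol=1e-12)


class TestAccessibility:
    def test_expected_time_hand_computed(self):
        od = od_from([[10.0, 20.0]])
        cm = choice_matrix(od, [100.0, 100.0])
        cm.probabilities = np.array([[0.5, 0.5]])
        res = accessibility(od, cm)
        assert res.expected_min[0] == pytest.approx(15.0)

    def test_single_facility_accessibility_is_its_time(self):
        od = od_from([[42.0]])
        res = accessibility(od, choice_matrix(od, [100.0]))
        assert res.expected_min[0] == pytest.approx(42.0)

    def test_isolated_origin_excluded_from_summary(self):
        od = od_from([[10.0], [math.inf]])
        res = accessibility(od, choice_matrix(od, [100.0]))
        assert res.isolated.tolist() == [False, True]
        assert res.mean == pytest.approx(10.0)
        assert math.isnan(res.expected_min[1])

    def test_bounded_by_min_and_max_reachable_time(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 90, size=(10, 5))
        t[rng.random(t.shape) < 0.2] = math.inf
        od = od_from(t)
        res = accessibility(od, choice_matrix(od, rng.uniform(100, 9000, size=5)))
        for i in range(10):
            finite = t[i][np.isfinite(t[i])]
            if len(finite):
                assert finite.min() - 1e-9 <= res.expected_min[i] <= finite.max() + 1e-9


def brute_force_criticality(net, origins, weights, amenities, areas, alpha=1.0):
    """Independent oracle: enumerate all equal-cost shortest paths with networkx,
    pick the lexicographically smallest node sequence, and accumulate
    alpha * w * P over its edges."""
    g = net.graph
    scores = {edge_key(u, v): 0.0 for u, v in g.edges}
    dest_nodes = [a.node_id for a in amenities]
    for o, w in zip(origins, weights):
        ts = []
        for dn in dest_nodes:
            try:
                ts.append(nx.shortest_path_length(g, o, dn, weight="travel_time"))
            except nx.NetworkXNoPath:
                ts.append(math.inf)
        ts = np.array(ts)
        reach = np.isfinite(ts)
        if not reach.any():
            continue
        attract = np.asarray(areas)[reach] / np.maximum(ts[reach], 0.1)
        probs = np.zeros(len(ts))
        probs[reach] = attract / attract.sum()
        for dn, t, p in zip(dest_nodes, ts, probs):
            if not math.isfinite(t) or p == 0:
                continue
            best = min(tuple(pth) for pth in nx.all_shortest_paths(
                g, o, dn, weight="travel_time"))
            for a, b in zip(best, best[1:]):
                scores[edge_key(a, b)] += alpha * w * p
    return scores


class TestCriticality:
    def _evaluate(self, net, origins, weights, amenities, alpha=1.0):
        od = travel_times(
            net, origins, [a.node_id for a in amenities],
            weights=weights, return_paths=True,
        )
        cm = choice_matrix(od, [a.area_m2 for a in amenities])
        return od, cm, criticality(net, od, cm, weights=weights, alpha=alpha)

    def test_two_trips_sharing_an_edge_sum_their_contributions(self, fig2):
        """Trips A->H and C->H share F-H; its score is c1 + c2."""
        net, _, ams, _ = fig2
        hospital_h = [a for a in ams if a.id == "H"]
        od, cm, crit = self._evaluate(net, ["A", "C"], [100.0, 50.0], hospital_h)
        c1 = 1.0 * 100.0 * cm.probabilities[0, 0]
        c2 = 1.0 * 50.0 * cm.probabilities[1, 0]
        assert crit.scores[("F", "H")] == pytest.approx(c1 + c2)

    def test_doubling_alpha_doubles_every_score(self, fig2):
        net, _, ams, _ = fig2
        _, _, c1 = self._evaluate(net, ["A", "C"], [100.0, 50.0], ams, alpha=1.0)
        _, _, c2 = self._evaluate(net, ["A", "C"], [100.0, 50.0], ams, alpha=2.0)
        for k in c1.scores:
            assert c2.scores[k] == pytest.approx(2 * c1.scores[k])

    def test_unused_edges_score_zero(self, fig2):
        net, _, ams, _ = fig2
        hospital_h = [a for a in ams if a.id == "H"]
        _, _, crit = self._evaluate(net, ["A"], [10.0], hospital_h)
        # the A->H path is A-D-E-F-H; K-J is never traversed
        assert crit.scores[("J", "K")] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_enumeration_oracle(self, seed):
        net = random_road_graph(n_nodes=9, seed=seed)
        nodes = sorted(net.graph.nodes)
        ams = [
            Amenity("f0", "f0", 0, 0, node_id=nodes[0], area_m2=3000.0),
            Amenity("f1", "f1", 0, 0, node_id=nodes[-1], area_m2=1000.0),
        ]
        origins = nodes[1:-1]
        weights = [10.0 * (i + 1) for i in range(len(origins))]
        _, _, crit = self._evaluate(net, origins, weights, ams)
        oracle = brute_force_criticality(
            net, origins, weights, ams, [a.area_m2 for a in ams]
        )
        for k in oracle:
            assert crit.scores[k] == pytest.approx(oracle[k], rel=1e-12), k

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_total_score_accounts_every_trip(self, seed):
        """Sum of edge scores equals sum over trips of contribution x path length."""
        net = random_road_graph(n_nodes=10, seed=seed)
        nodes = sorted(net.graph.nodes)
        ams = [Amenity("f0", "f0", 0, 0, node_id=nodes[0], area_m2=2000.0)]
        origins = nodes[1:]
        weights = [5.0] * len(origins)
        od, cm, crit = self._evaluate(net, origins, weights, ams)
        expected = 0.0
        for i, o in enumerate(origins):
            if not math.isfinite(od.times[i, 0]):
                continue
            n_edges = len(od.paths[(o, nodes[0])]) - 1
            expected += weights[i] * cm.probabilities[i, 0] * n_edges
        assert crit.total() == pytest.approx(expected, rel=1e-12)

    def test_ranking_descending_with_id_tiebreak(self):
        crit = CriticalityResult({("A", "B"): 5.0, ("A", "C"): 5.0, ("B", "C"): 9.0})
        ranked = [k for k, _ in crit.ranked()]
        assert ranked == [("B", "C"), ("A", "B"), ("A", "C")]

    def test_scaled_scores_lie_in_unit_interval(self):
        crit = CriticalityResult({("A", "B"): 2.0, ("B", "C"): 8.0, ("C", "D"): 0.0})
        scaled = crit.scaled()
        assert scaled[("A", "B")] == 0.0 and scaled[("B", "C")] == 1.0
        assert scaled[("C", "D")] == 0.0


class TestIsolation:
    def test_cutting_only_bridge_isolates_population(self, fig2):
        """Disrupting A's single link A-D isolates exactly A's assigned weight."""
        net, _, ams, _ = fig2
        sc = apply_rule(net, {("A", "D"): 0.0}, HazardRule(), kind="fault")
        od = travel_times(sc, ["A", "C"], [a.node_id for a in ams], weights=[75.0, 20.0])
        iso = isolation(od)
        assert iso.total_population == 75.0
        assert iso.isolated_origins == ["A"]

    def test_fully_connected_network_has_no_isolation(self, fig2):
        net, _, ams, _ = fig2
        od = travel_times(net, ["A", "C", "G"], [a.node_id for a in ams],
                          weights=[1.0, 2.0, 3.0])
        assert isolation(od).total_population == 0.0

    def test_all_facilities_disrupted_isolates_everyone(self):
        od = od_from([[math.inf], [math.inf]], weights=[10.0, 20.0])
        assert isolation(od).total_population == 30.0


class TestCompoundAggregate:
    def test_sum_and_max_on_identical_scores(self):
        a = CriticalityResult({("A", "B"): 4.0})
        b = CriticalityResult({("A", "B"): 4.0})
        assert compound_aggregate([a, b], "sum").scores[("A", "B")] == 8.0
        assert compound_aggregate([a, b], "max").scores[("A", "B")] == 4.0

    def test_single_hazard_is_identity_in_both_modes(self):
        a = CriticalityResult({("A", "B"): 4.0, ("B", "C"): 1.5})
        for mode in ("sum", "max"):
            assert compound_aggregate([a], mode).scores == a.scores

    def test_elementwise_max_never_exceeds_sum(self):
        rng = np.random.default_rng(5)
        keys = [("A", str(i)) for i in range(20)]
        rs = [
            CriticalityResult({k: float(rng.uniform(0, 10)) for k in keys})
            for _ in range(3)
        ]
        mx = compound_aggregate(rs, "max").scores
        sm = compound_aggregate(rs, "sum").scores
        assert all(mx[k] <= sm[k] + 1e-12 for k in keys)

    def test_accessibility_compound_is_per_origin_max(self):
        a = AccessibilityResult(["o1", "o2"], np.array([10.0, 30.0]),
                                np.array([False, False]))
        b = AccessibilityResult(["o1", "o2"], np.array([25.0, 20.0]),
                                np.array([False, False]))
        agg = compound_aggregate([a, b], "max")
        assert agg.expected_min.tolist() == [25.0, 30.0]

    def test_accessibility_sum_mode_rejected(self):
        a = AccessibilityResult(["o1"], np.array([10.0]), np.array([False]))
        with pytest.raises(ValidationError):
            compound_aggregate([a, a], "sum")

    def test_isolated_in_any_hazard_stays_isolated(self):
        a = AccessibilityResult(["o1"], np.array([np.nan]), np.array([True]))
        b = AccessibilityResult(["o1"], np.array([12.0]), np.array([False]))
        agg = compound_aggregate([a, b], "max")
        assert agg.isolated.tolist() == [True]


def scenario_results(net, origins, weights, amenities):
    od = travel_times(net, origins, [a.node_id for a in amenities], weights=weights)
    cm = choice_matrix(od, [a.area_m2 for a in amenities])
    return accessibility(od, cm), cm


class TestCompareScenarios:
    def test_identical_scenarios_show_no_difference(self, fig2):
        net, _, ams, _ = fig2
        w = [10.0, 20.0, 5.0]
        acc, cm = scenario_results(net, ["A", "C", "G"], w, ams)
        cmp = compare_scenarios(acc, cm, acc, cm, w)
        assert cmp.js_divergence == 0.0
        assert cmp.pref_change_fraction == 0.0
        assert cmp.shift_graph == {}

    def test_single_switch_appears_in_shift_graph(self, fig2):
        net, _, ams, _ = fig2
        w = [10.0]
        acc_b, cm_b = scenario_results(net, ["C"], w, ams)
        # disrupting F-H forces C's preference away from H
        sc = apply_rule(net, {("F", "H"): 0.0}, HazardRule(), kind="fault")
        acc_d, cm_d = scenario_results(sc.network, ["C"], w, ams)
        assert cm_b.top_choice() == ["H"] and cm_d.top_choice() == ["J"]
        cmp = compare_scenarios(acc_b, cm_b, acc_d, cm_d, w)
        assert cmp.shift_graph == {("H", "J"): 1}
        assert cmp.pref_change_fraction == 1.0

    def test_change_fraction_matches_direct_argmax_comparison(self):
        rng = np.random.default_rng(7)
        n, m = 5, 3
        t_base = rng.uniform(5, 60, size=(n, m))
        t_dis = t_base * rng.uniform(1, 3, size=(n, m))
        areas = rng.uniform(100, 5000, size=m)
        odb, odd = od_from(t_base), od_from(t_dis)
        cmb, cmd = choice_matrix(odb, areas), choice_matrix(odd, areas)
        accb, accd = accessibility(odb, cmb), accessibility(odd, cmd)
        w = np.ones(n)
        cmp = compare_scenarios(accb, cmb, accd, cmd, w)
        direct = np.mean(
            np.argmax(cmb.probabilities, axis=1) != np.argmax(cmd.probabilities, axis=1)
        )
        assert cmp.pref_change_fraction == pytest.approx(direct)

    def test_isolated_origins_counted_separately(self):
        odb = od_from([[10.0], [12.0]], weights=[1.0, 1.0])
        odd = od_from([[15.0], [math.inf]], weights=[1.0, 1.0])
        cmb, cmd = choice_matrix(odb, [100.0]), choice_matrix(odd, [100.0])
        cmp = compare_scenarios(
            accessibility(odb, cmb), cmb, accessibility(odd, cmd), cmd, [1.0, 1.0]
        )
        assert cmp.n_isolated_any == 1 and cmp.n_comparable == 1

    def test_mismatched_origin_sets_rejected(self):
        a = AccessibilityResult(["o1"], np.array([1.0]), np.array([False]))
        b = AccessibilityResult(["o2"], np.array([1.0]), np.array([False]))
        od = od_from([[5.0]])
        cm = choice_matrix(od, [100.0])
        with pytest.raises(ValidationError):
            compare_scenarios(a, cm, b, cm, [1.0])

    def test_access_share_table_sums_to_hundred(self):
        acc = AccessibilityResult(
            ["a", "b", "c", "d"],
            np.array([30.0, 90.0, 200.0, np.nan]),
            np.array([False, False, False, True]),
        )
        table = access_share_table(acc, [100, 200, 300, 400])
        assert sum(table.values()) == pytest.approx(100.0)
        assert table["0 - 1"] == pytest.approx(10.0)
        assert table["Unreachable"] == pytest.approx(40.0)
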