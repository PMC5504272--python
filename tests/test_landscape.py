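import networkx as nx
import numpy as np
import pytest

from conftest import random_params
from energylandscape.landscape import (
    EnergyLandscape,
    assign_basins,
    build_disconnectivity_graph,
    build_landscape,
    define_brain_states,
    find_local_minima,
)
from energylandscape.mem import MEMParams, state_energy, pattern_decode


# --- independent oracles -------------------------------------------------

def minima_oracle(energies, k):
    """Explicit neighbour scan."""
    out = []
    for c in range(2**k):
        if all(energies[c] < energies[c ^ (1 << i)] for i in range(k)):
            out.append(c)
    return out


def descent_oracle(energies, k, start):
    """Hand steepest descent with lowest-code tie break."""
    c = start
    while True:
        nbrs = [c ^ (1 << i) for i in range(k)]
        best = min(energies[n] for n in nbrs)
        if best >= energies[c]:
            return c
        c = min(n for n in nbrs if energies[n] == best)


def merge_oracle(energies, k, m1, m2):
    """Minimax path barrier by Dijkstra-style widest-path search: the
    lowest achievable maximum node energy over hypercube paths m1 -> m2.
    Equals the lowest threshold at which the two minima stay connected in
    the descending-threshold sweep."""
    import heapq

    dist = {m1: energies[m1]}
    pq = [(energies[m1], m1)]
    while pq:
        d, c = heapq.heappop(pq)
        if d > dist.get(c, np.inf):
            continue
        for n in [c ^ (1 << i) for i in range(k)]:
            nd = max(d, energies[n])
            if nd < dist.get(n, np.inf):
                dist[n] = nd
                heapq.heappush(pq, (nd, n))
    return dist[m2]


def connectivity_sweep_oracle(energies, k, m1, m2):
    """Direct reading of the threshold procedure with networkx: the lowest
    E_th among the sorted distinct energies at which m1 and m2 remain in
    one component of the subgraph of nodes with energy < E_th."""
    best = None
    for e_th in np.unique(energies)[::-1]:
        keep = {c for c in range(2**k) if energies[c] < e_th}
        g = nx.Graph()
        g.add_nodes_from(keep)
        g.add_edges_from(
            (c, c ^ (1 << i)) for c in keep for i in range(k) if c ^ (1 << i) in keep
        )
        if m1 in g and m2 in g and nx.has_path(g, m1, m2):
            best = e_th
        else:
            break
    return best


class TestBuildLandscape:
    def test_k7_has_128_energies(self, td_params):
        ls = build_landscape(td_params)
        assert ls.n_patterns == 128

    def test_zero_params_flat(self):
        ls = build_landscape(MEMParams(h=np.zeros(4), J=np.zeros((4, 4))))
        np.testing.assert_allclose(ls.energies, 0.0)

    def test_matches_per_pattern_state_energy(self, td_params, td_landscape):
        for c in (0, 17, 49, 64, 127):
            v = pattern_decode(c, 7)
            assert td_landscape.energies[c] == pytest.approx(
                state_energy(v, td_params)
            )


class TestFindLocalMinima:
    def test_strong_field_single_minimum(self):
        ls = build_landscape(MEMParams(h=np.full(5, 2.0), J=np.zeros((5, 5))))
        assert find_local_minima(ls) == [2**5 - 1]

    def test_flat_landscape_has_none(self):
        ls = EnergyLandscape(k=3, energies=np.zeros(8))
        assert find_local_minima(ls) == []

    def test_matches_neighbour_scan_oracle(self, rng):
        for _ in range(100):
            e = rng.normal(size=128)
            ls = EnergyLandscape(k=7, energies=e)
            assert find_local_minima(ls) == minima_oracle(e, 7)


class TestAssignBasins:
    def test_k2_toy_hand_descent(self, toy_k2):
        basins = assign_basins(toy_k2, [0, 3])
        np.testing.assert_array_equal(basins.basin_of, [0, 3, 3, 3])
        assert basins.basin_sizes == {0: 0.25, 3: 0.75}

    def test_single_minimum_owns_everything(self):
        ls = build_landscape(MEMParams(h=np.full(4, 3.0), J=np.zeros((4, 4))))
        m = find_local_minima(ls)
        basins = assign_basins(ls, m)
        assert basins.basin_sizes[m[0]] == 1.0

    def test_partition_properties_random(self, rng):
        for _ in range(25):
            e = rng.normal(size=64)
            ls = EnergyLandscape(k=6, energies=e)
            minima = find_local_minima(ls)
            basins = assign_basins(ls, minima)
            assert sum(basins.basin_sizes.values()) == pytest.approx(1.0)
            # every minimum maps to itself; every terminal is the oracle's
            for m in minima:
                assert basins.basin_of[m] == m
            for start in range(0, 64, 7):
                assert basins.basin_of[start] == descent_oracle(e, 6, start)

    def test_descent_monotone_energy(self, td_landscape):
        minima = find_local_minima(td_landscape)
        basins = assign_basins(td_landscape, minima)
        # fixed points exactly at minima
        fixed = [c for c in range(128) if basins.basin_of[c] == c]
        assert sorted(fixed) == sorted(minima)
        # basin terminal is never higher in energy than the start
        assert np.all(
            td_landscape.energies[basins.basin_of] <= td_landscape.energies + 1e-12
        )


class TestDisconnectivityGraph:
    def test_single_minimum_tree(self):
        ls = build_landscape(MEMParams(h=np.full(3, 2.0), J=np.zeros((3, 3))))
        tree = build_disconnectivity_graph(ls, find_local_minima(ls))
        assert tree.root.is_leaf
        assert tree.leaves() == [7]

    def test_k2_toy_barrier(self, toy_k2):
        tree = build_disconnectivity_graph(toy_k2, [0, 3])
        assert sorted(tree.leaves()) == [0, 3]
        assert tree.merge_energy(0, 3) == pytest.approx(2.0)

    def test_merge_energies_match_minimax_oracle(self, rng):
        for _ in range(20):
            e = rng.normal(size=128)
            ls = EnergyLandscape(k=7, energies=e)
            minima = find_local_minima(ls)
            tree = build_disconnectivity_graph(ls, minima)
            assert sorted(tree.leaves()) == sorted(minima)
            for i, m1 in enumerate(minima):
                for m2 in minima[i + 1:]:
                    assert tree.merge_energy(m1, m2) == pytest.approx(
                        merge_oracle(e, 7, m1, m2)
                    )

    def test_consistent_with_threshold_sweep(self, rng):
        """The merge energy is the saddle energy: the threshold sweep
        disconnects the pair exactly one distinct energy level above it."""
        for _ in range(5):
            e = rng.normal(size=32)
            ls = EnergyLandscape(k=5, energies=e)
            minima = find_local_minima(ls)
            tree = build_disconnectivity_graph(ls, minima)
            levels = np.unique(e)
            for i, m1 in enumerate(minima):
                for m2 in minima[i + 1:]:
                    barrier = tree.merge_energy(m1, m2)
                    successor = levels[np.searchsorted(levels, barrier) + 1]
                    assert connectivity_sweep_oracle(e, 5, m1, m2) == pytest.approx(
                        successor
                    )

    def test_merge_energy_at_least_own_energies(self, td_landscape):
        minima = find_local_minima(td_landscape)
        tree = build_disconnectivity_graph(td_landscape, minima)
        for i, m1 in enumerate(minima):
            for m2 in minima[i + 1:]:
                assert tree.merge_energy(m1, m2) >= max(
                    td_landscape.energies[m1], td_landscape.energies[m2]
                )

    def test_newick_export_contains_all_leaves(self, td_landscape):
        minima = find_local_minima(td_landscape)
        tree = build_disconnectivity_graph(td_landscape, minima)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for m in minima:
            assert f"m{m}" in nwk

    def test_zero_minima_rejected(self, toy_k2):
        with pytest.raises(ValueError, match="minima"):
            build_disconnectivity_graph(toy_k2, [])


class TestConstantOffsetInvariance:
    def test_offset_changes_nothing(self, rng):
        e = rng.normal(size=64)
        ls1 = EnergyLandscape(k=6, energies=e)
        ls2 = EnergyLandscape(k=6, energies=e + 57.3)
        m1, m2 = find_local_minima(ls1), find_local_minima(ls2)
        assert m1 == m2
        b1, b2 = assign_basins(ls1, m1), assign_basins(ls2, m2)
        np.testing.assert_array_equal(b1.basin_of, b2.basin_of)
        t1 = build_disconnectivity_graph(ls1, m1)
        t2 = build_disconnectivity_graph(ls2, m2)
        for i, a in enumerate(m1):
            for b in m1[i + 1:]:
                assert t2.merge_energy(a, b) - t1.merge_energy(a, b) == pytest.approx(
                    57.3
                )


class TestDefineBrainStates:
    def test_explicit_grouping_bookkeeping(self, td_landscape):
        minima = find_local_minima(td_landscape)
        tree = build_disconnectivity_graph(td_landscape, minima)
        basins = assign_basins(td_landscape, minima)
        grouping = {56: "major1", 62: "major1", 65: "major2", 71: "major2",
                    49: "minor1", 78: "minor2"}
        part = define_brain_states(tree, basins, grouping=grouping)
        assert part.labels == ("major1", "major2", "minor1", "minor2")
        assert part.state_sizes["major1"] == pytest.approx(
            basins.basin_sizes[56] + basins.basin_sizes[62]
        )
        assert sum(part.state_sizes.values()) == pytest.approx(1.0)

    def test_automatic_cut_recovers_planted_grouping(self, td_landscape):
        minima = find_local_minima(td_landscape)
        tree = build_disconnectivity_graph(td_landscape, minima)
        basins = assign_basins(td_landscape, minima)
        part = define_brain_states(tree, basins, n_states=4)
        groups = {}
        for m, lab in part.state_of_minimum.items():
            groups.setdefault(lab, set()).add(m)
        assert groups["major1"] in ({56, 62}, {65, 71})
        assert groups["major2"] in ({56, 62}, {65, 71})
        assert groups["major1"] != groups["major2"]
        assert {frozenset(groups["minor1"]), frozenset(groups["minor2"])} == {
            frozenset({49}), frozenset({78})
        }

    def test_grouping_omitting_minimum_errors(self, toy_k2):
        basins = assign_basins(toy_k2, [0, 3])
        tree = build_disconnectivity_graph(toy_k2, [0, 3])
        with pytest.raises(ValueError, match="omits"):
            define_brain_states(tree, basins, grouping={0: "major1"})

    def test_absorb_unlisted_inherits_nearest_branch(self, td_landscape):
        minima = find_local_minima(td_landscape)
        tree = build_disconnectivity_graph(td_landscape, minima)
        basins = assign_basins(td_landscape, minima)
        grouping = {56: "major1", 65: "major2", 49: "minor1", 78: "minor2"}
        part = define_brain_states(
            tree, basins, grouping=grouping, absorb_unlisted=True
        )
        # 62 merges with 56 at a low barrier, 71 with 65
        assert part.state_of_minimum[62] == "major1"
        assert part.state_of_minimum[71] == "major2"
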