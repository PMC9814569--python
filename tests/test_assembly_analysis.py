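"""Hydrogen-bond detection, association graphs, cluster classification
and strand-order statistics, checked against independent oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catchsim import assembly_analysis as aa
from catchsim.forcefield import default_table
from catchsim.scenario_generator import make_ideal_sheet
from oracle_utils import flood_fill_partition


class TestClassifyClusters:
    def _graph(self, n, joined_edges):
        g = nx.Graph()
        for i in range(n):
            g.add_node(i, species="x", charge=0)
        for u, v in joined_edges:
            g.add_edge(u, v, joined=True, n_hbonds=0, n_hydrophobic_contacts=1)
        return g

    def test_all_isolated(self):
        free, olig, fib = aa.classify_clusters(self._graph(96, []))
        assert len(free) == 96 and not olig and not fib

    def test_boundary_sizes(self):
        # components of sizes 1, 2, 5, 6, 10
        edges = []
        node = 0
        comps = []
        for size in (1, 2, 5, 6, 10):
            members = list(range(node, node + size))
            comps.append(members)
            edges += [(a, b) for a, b in zip(members, members[1:])]
            node += size
        free, olig, fib = aa.classify_clusters(self._graph(node, edges))
        assert free == {comps[0][0]}
        assert sorted(len(c) for c in olig) == [2, 5]
        assert sorted(len(c) for c in fib) == [6, 10]

    def test_non_joined_edges_ignored(self):
        g = self._graph(3, [])
        g.add_edge(0, 1, joined=False, n_hbonds=2, n_hydrophobic_contacts=0)
        free, olig, fib = aa.classify_clusters(g)
        assert len(free) == 3

    @given(
        st.integers(2, 20).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.lists(
                    st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)),
                    max_size=40,
                ),
            )
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_flood_fill_oracle(self, case):
        n, raw_edges = case
        edges = [(u, v) for u, v in raw_edges if u != v]
        free, olig, fib = aa.classify_clusters(self._graph(n, edges))
        got = (
            {frozenset({f}) for f in free}
            | {frozenset(c) for c in olig}
            | {frozenset(c) for c in fib}
        )
        assert got == flood_fill_partition(n, edges)

    def test_relabeling_invariance(self, rng):
        n = 12
        edges = [(0, 1), (1, 2), (3, 4), (5, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
        perm = rng.permutation(n)
        g1 = self._graph(n, edges)
        g2 = self._graph(n, [(perm[u], perm[v]) for u, v in edges])
        sizes1 = sorted(
            len(c) for c in aa.classify_clusters(g1)[1] + aa.classify_clusters(g1)[2]
        )
        sizes2 = sorted(
            len(c) for c in aa.classify_clusters(g2)[1] + aa.classify_clusters(g2)[2]
        )
        assert sizes1 == sizes2


class TestDetectHbonds:
    def test_two_strand_fixture_recovered(self):
        fx = make_ideal_sheet("+-")
        got = set(aa.detect_hbonds(fx.positions, fx.topology, fx.box_side))
        assert got == set(fx.hbonds)
        assert len(got) >= aa.default_hb_majority_threshold(fx.topology)

    def test_isolated_peptide_no_interchain_bonds(self, family):
        fx = make_ideal_sheet([family["CATCH(6+)"]])
        bonds = aa.detect_hbonds(fx.positions, fx.topology, fx.box_side)
        inter = [
            (a, b)
            for a, b in bonds
            if fx.topology.chain_id[a] != fx.topology.chain_id[b]
        ]
        assert inter == []

    def test_scattered_dilute_peptides_no_bonds(self, family):
        from catchsim.dmd_engine import init_system

        state = init_system([(family["CATCH(6+)"], 4)], 300.0, 0.2, seed=3)
        bonds = aa.detect_hbonds(
            state.positions, state.topology, state.box_side
        )
        inter = [
            (a, b)
            for a, b in bonds
            if state.topology.chain_id[a] != state.topology.chain_id[b]
        ]
        assert inter == []

    def test_rotation_translation_invariance(self):
        fx = make_ideal_sheet("+-+-")
        base = aa.detect_hbonds(fx.positions, fx.topology, fx.box_side)
        th = 0.7
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1],
            ]
        )
        centre = fx.positions.mean(axis=0)
        moved = (fx.positions - centre) @ R.T + centre + 3.0
        assert set(
            aa.detect_hbonds(moved, fx.topology, fx.box_side)
        ) == set(base)

    def test_uniqueness_one_bond_per_site(self):
        fx = make_ideal_sheet("+-+-+-")
        bonds = aa.detect_hbonds(fx.positions, fx.topology, fx.box_side)
        nh_sites = [a for a, _ in bonds]
        co_sites = [b for _, b in bonds]
        assert len(nh_sites) == len(set(nh_sites))
        assert len(co_sites) == len(set(co_sites))

    def test_shrinking_well_screens_bonds(self):
        fx = make_ideal_sheet("+-+-")
        table = default_table()
        n_ref = len(aa.detect_hbonds(fx.positions, fx.topology, fx.box_side, table))
        import dataclasses

        for hbd in (4.5, 4.4, 4.0, 3.8):
            shrunk = dataclasses.replace(table, hb_distance=hbd)
            n = len(
                aa.detect_hbonds(fx.positions, fx.topology, fx.box_side, shrunk)
            )
            assert n <= n_ref
            n_ref = n


class TestAssociationGraph:
    def test_sheet_pair_joined_by_majority(self):
        fx = make_ideal_sheet("+-")
        g = aa.build_association_graph(fx.positions, fx.topology, fx.box_side)
        assert g.edges[0, 1]["joined"]
        assert g.edges[0, 1]["n_hbonds"] >= 6

    def test_high_threshold_unjoins_pure_hb_pair(self):
        fx = make_ideal_sheet("+-")
        g = aa.build_association_graph(
            fx.positions, fx.topology, fx.box_side, hb_majority_threshold=99
        )
        if g.has_edge(0, 1):
            d = g.edges[0, 1]
            # may still be joined through a hydrophobic contact (rule 2)
            assert d["joined"] == (d["n_hydrophobic_contacts"] >= 1)

    def test_distant_pair_not_joined(self, family):
        from catchsim.dmd_engine import init_system

        state = init_system([(family["CATCH(6+)"], 2)], 400.0, 0.2, seed=11)
        g = aa.build_association_graph(
            state.positions, state.topology, state.box_side
        )
        assert not any(d["joined"] for _, _, d in g.edges(data=True))


class TestKineticsSeries:
    def test_constant_trajectory_constant_series(self):
        from catchsim.scenario_generator import make_kinetics_toy

        traj, gt = make_kinetics_toy(6, [])
        kin = aa.kinetics_series(traj)
        assert np.all(kin.n_free == 6)
        assert np.all(kin.n_in_oligomers == 0)

    def test_conservation_invariant(self):
        from catchsim.scenario_generator import make_kinetics_toy

        sched = [(1.0, 1, 0), (2.0, 2, 0), (3.0, 4, 3), (4.0, 5, 3)]
        traj, gt = make_kinetics_toy(8, sched)
        kin = aa.kinetics_series(traj)
        total = kin.n_free + kin.n_in_oligomers + kin.n_in_fibrils
        assert np.all(total == 8)

    def test_dimer_formation_counts(self):
        from catchsim.scenario_generator import make_kinetics_toy

        traj, gt = make_kinetics_toy(4, [(1.0, 1, 0)])
        kin = aa.kinetics_series(traj)
        assert kin.n_free.tolist() == gt.n_free.tolist() == [4, 2]
        assert kin.n_in_oligomers.tolist() == [0, 2]


class TestStrandOrderStats:
    def _graph(self, charges, neighbor_pairs, hb=10):
        g = nx.Graph()
        for i, q in enumerate(charges):
            g.add_node(i, species="s", charge=q)
        for u, v in neighbor_pairs:
            g.add_edge(u, v, joined=True, n_hbonds=hb, n_hydrophobic_contacts=0)
        return g

    def test_alternating_six(self):
        g = self._graph([+6, -6, +6, -6, +6, -6], [(i, i + 1) for i in range(5)])
        s = aa.strand_order_stats(range(6), g)
        assert s.n_alternating_neighbors == 5
        assert s.n_like_charge_neighbors == 0
        assert s.cation_fraction == 0.5

    def test_mismatched_chain(self):
        # +,+,-,- -> neighbours (+,+), (+,-), (-,-): 1 alternating, 2 like
        g = self._graph([+6, +6, -6, -6], [(0, 1), (1, 2), (2, 3)])
        s = aa.strand_order_stats(range(4), g)
        assert s.n_alternating_neighbors == 1
        assert s.n_like_charge_neighbors == 2

    @given(st.lists(st.sampled_from([+6, -6]), min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_hand_enumeration(self, charges):
        pairs = [(i, i + 1) for i in range(len(charges) - 1)]
        g = self._graph(charges, pairs)
        s = aa.strand_order_stats(range(len(charges)), g)
        alt = sum(1 for a, b in pairs if charges[a] * charges[b] < 0)
        assert s.n_alternating_neighbors == alt
        assert s.n_like_charge_neighbors == len(pairs) - alt
        assert s.cation_fraction == pytest.approx(
            sum(1 for q in charges if q > 0) / len(charges)
        )

    def test_hydrophobic_only_edges_not_neighbors(self):
        g = self._graph([+6, -6], [(0, 1)], hb=0)
        g.edges[0, 1]["n_hydrophobic_contacts"] = 3
        s = aa.strand_order_stats([0, 1], g)
        assert s.n_alternating_neighbors == 0
        assert s.n_like_charge_neighbors == 0
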