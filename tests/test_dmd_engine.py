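"""Event-driven engine: prediction oracle, impulse rules, conservation,
thermostat, determinism."""

import math

import numpy as np
import pytest

from catchsim import dmd_engine as de
from catchsim.forcefield import KIND_CO, KIND_NH, KIND_R, default_table
from catchsim.sequence_model import parse_sequence

from oracle_utils import _mic, brute_force_next_event, small_state


class TestConcentration:
    def test_full_scale_rounds_to_20_mM(self):
        c = de.concentration(96, 200.0)
        assert round(c) == 20
        assert c == pytest.approx(19.93, abs=0.01)

    def test_zero_peptides(self):
        assert de.concentration(0, 200.0) == 0.0

    def test_doubling_box_divides_by_eight(self):
        assert de.concentration(10, 100.0) / de.concentration(10, 200.0) == (
            pytest.approx(8.0)
        )


class TestInitSystem:
    def test_bead_count_and_concentration(self, family):
        st = de.init_system(
            [(family["CATCH(6+)"], 2), (family["CATCH(6-)"], 2)],
            box_side=80.0, T_star=0.2, seed=9,
        )
        assert st.n_beads == 176
        assert de.check_state(st) == []

    def test_same_seed_bitwise_identical(self, family):
        sp = [(family["CATCH(4+)"], 2), (family["CATCH(4-)"], 2)]
        a = de.init_system(sp, 90.0, 0.2, seed=4)
        b = de.init_system(sp, 90.0, 0.2, seed=4)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_one_peptide_in_huge_box(self, family):
        st = de.init_system([(family["Q11"], 1)], 500.0, 0.2, seed=1)
        assert de.check_state(st) == []

    def test_net_momentum_zero(self, family):
        st = de.init_system([(family["Q11"], 3)], 120.0, 0.2, seed=2)
        m = st.topology.masses[:, None]
        assert np.abs((m * st.velocities).sum(axis=0)).max() < 1e-10

    def test_packing_failure_reports(self, family):
        with pytest.raises(RuntimeError, match="packing failed"):
            de.init_system(
                [(family["Q11"], 40)], box_side=42.0, T_star=0.2, seed=0,
                max_retries=5,
            )


class TestNextEventOracle:
    def test_matches_brute_force_on_random_states(self):
        """Cell-list scheduler equals the all-pairs scan on >=100 states."""
        checked = 0
        for seed in range(120):
            st = small_state(seed)
            t_oracle, pair = brute_force_next_event(st)
            ev = de.next_event(st, include_crossings=False)
            if not math.isfinite(t_oracle):
                assert not math.isfinite(ev.time) or ev.time > 1e100
                continue
            assert ev.time == pytest.approx(t_oracle, rel=1e-9, abs=1e-12)
            assert tuple(sorted(ev.participants)) == pair
            checked += 1
        assert checked >= 100

    def test_head_on_closed_form(self, family):
        # two beads approaching head-on: t = (d - sigma) / v
        st = small_state(3)
        ev = de.next_event(st, include_crossings=False)
        assert ev.time >= st.time


class TestResolveEvent:
    def _resolved_events(self, n_states=60):
        out = []
        for seed in range(n_states):
            st = small_state(seed)
            ev = de.next_event(st, include_crossings=False)
            if math.isfinite(ev.time) and len(ev.participants) == 2:
                out.append((st, ev))
        return out

    def test_momentum_conserved_for_all_two_body_events(self):
        for st, ev in self._resolved_events():
            new = de.resolve_event(st, ev)
            m = st.topology.masses[:, None]
            p0 = (m * st.velocities).sum(axis=0)
            p1 = (m * new.velocities).sum(axis=0)
            assert np.abs(p1 - p0).max() < 1e-9

    def test_reflection_flips_radial_velocity(self):
        seen = 0
        for st, ev in self._resolved_events():
            if ev.kind not in ("core_collision", "bond_limit"):
                continue
            new = de.resolve_event(st, ev)
            i, j = ev.participants
            d = _mic(new.positions[i] - new.positions[j], st.box_side)
            n = d / np.linalg.norm(d)
            vr_old = (st.velocities[i] - st.velocities[j]) @ n
            vr_new = (new.velocities[i] - new.velocities[j]) @ n
            assert vr_new == pytest.approx(-vr_old, rel=1e-9)
            seen += 1
        assert seen >= 5

    @staticmethod
    def _approach_state(seq_a, seq_b, gap, speed, box=60.0):
        """Two rigidly translated single-residue chains approaching along x.

        Internal relative velocities are zero, so the first event is the
        sidechain pair crossing its outermost discontinuity.
        """
        pa = parse_sequence(seq_a, peptide_id=seq_a + "_a")
        pb = parse_sequence(seq_b, peptide_id=seq_b + "_b")
        st = de.init_system([(pa, 1), (pb, 1)], box, 0.2, seed=0)
        from catchsim.forcefield import chain_template

        t1 = chain_template(pa) + box / 2
        t2 = chain_template(pb) + box / 2
        t2[:, 0] += gap
        t2[:, 2] += 3.0  # keep the backbone NH-CO pairs out of reach
        st.positions = np.concatenate([t1, t2])
        st.velocities = np.zeros_like(st.velocities)
        st.velocities[4:, 0] = -speed
        return st

    def test_capture_energy_balance(self):
        """Attractive capture: vr'^2 - vr^2 = 2*eps/mu exactly."""
        pk_depth = None
        st = self._approach_state("K", "E", gap=10.0, speed=0.25)
        ev = de.next_event(st, include_crossings=False)
        assert ev.kind == "well_capture"
        i, j = ev.participants
        pk = de._packed(st.topology)
        depth = pk.well_depth[pk.itype[i], pk.itype[j]]
        assert depth < 0  # opposite charges attract
        new = de.resolve_event(st, ev)
        d = _mic(new.positions[i] - new.positions[j], st.box_side)
        n = d / np.linalg.norm(d)
        vr_old = (st.velocities[i] - st.velocities[j]) @ n
        vr_new = (new.velocities[i] - new.velocities[j]) @ n
        mi, mj = pk.mass[i], pk.mass[j]
        mu = mi * mj / (mi + mj)
        assert vr_new**2 - vr_old**2 == pytest.approx(-2 * depth / mu, rel=1e-9)
        # rest-approach limit: vr' -> sqrt(2*eps*(ma+mb)/(ma*mb))
        assert abs(vr_new) > abs(vr_old)

    def test_repulsive_shoulder_bounces_slow_approach(self):
        """A like-charge pair without the radial energy to pay the
        shoulder reflects elastically at the outer edge."""
        st = self._approach_state("K", "K", gap=10.0, speed=0.02)
        ev = de.next_event(st, include_crossings=False)
        assert ev.kind == "well_capture"  # an entry attempt
        i, j = ev.participants
        ke_before = float((st.velocities**2).sum())
        new = de.resolve_event(st, ev)
        d = _mic(new.positions[i] - new.positions[j], st.box_side)
        n = d / np.linalg.norm(d)
        vr_new = (new.velocities[i] - new.velocities[j]) @ n
        assert vr_new > 0  # now receding
        assert float((new.velocities**2).sum()) == pytest.approx(
            ke_before, rel=1e-12
        )

    def test_escape_registry_guard(self, family):
        st = small_state(1)
        with pytest.raises(RuntimeError, match="registry"):
            de.resolve_event(
                st,
                de.Event(time=st.time + 0.1, kind="hb_break", participants=(0, 6)),
            )


@pytest.fixture(scope="module")
def two_peptide_state(family):
    return de.init_system(
        [(family["CATCH(6+)"], 1), (family["CATCH(6-)"], 1)],
        box_side=60.0, T_star=0.2, seed=1,
    )


class TestRun:

    def test_zero_collisions_identity(self, two_peptide_state):
        traj = de.run(two_peptide_state, n_collisions=0)
        assert traj.n_snapshots == 1
        assert np.allclose(
            traj.positions[0], two_peptide_state.positions % 60.0
        )

    def test_determinism(self, two_peptide_state):
        a = de.run(two_peptide_state, n_collisions=50000, seed=7)
        b = de.run(two_peptide_state, n_collisions=50000, seed=7)
        assert np.array_equal(a.final_state.positions, b.final_state.positions)
        assert np.array_equal(a.final_state.velocities, b.final_state.velocities)
        assert a.final_state.time == b.final_state.time

    def test_energy_momentum_conserved_without_thermostat(
        self, two_peptide_state
    ):
        traj = de.run(
            two_peptide_state, n_collisions=200000, snapshot_every=50000,
            ghost_rate=0.0,
        )
        E = traj.total_energy()
        assert np.abs(E - E[0]).max() < 1e-9 * max(traj.n_collisions, 1)
        m = two_peptide_state.topology.masses[:, None]
        p0 = (m * two_peptide_state.velocities).sum(axis=0)
        p1 = (m * traj.final_state.velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-9

    def test_no_core_overlap_in_snapshots(self, two_peptide_state):
        traj = de.run(
            two_peptide_state, n_collisions=100000, snapshot_every=20000
        )
        for k in range(traj.n_snapshots):
            snap = de.SimulationState(
                positions=traj.positions[k],
                velocities=traj.final_state.velocities,
                box_side=traj.box_side,
                topology=traj.topology,
                hb_partner=traj.hb_partner[k],
            )
            assert de.check_state(snap) == []

    def test_thermostat_tracks_target_temperature(self, family):
        st = de.init_system(
            [(family["CATCH(6+)"], 2), (family["CATCH(6-)"], 2)],
            box_side=70.0, T_star=0.2, seed=3,
        )
        traj = de.run(
            st, n_collisions=400000, snapshot_every=10000, ghost_rate=0.02
        )
        t_kin = 2 * traj.kinetic / (3 * st.n_beads)
        assert abs(t_kin.mean() - 0.2) / 0.2 < 0.05

    def test_box_too_small_rejected(self, family):
        st = de.init_system([(family["Q11"], 1)], 500.0, 0.2, seed=1)
        st.box_side = 10.0
        with pytest.raises(ValueError, match="box side"):
            de.run(st, n_collisions=10)


def test_microseconds_estimate_full_scale():
    # at the full experimental scale the calibration is 16 us per 2e11
    assert de.microseconds_estimate(2e11, 4224) == pytest.approx(16.0)
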