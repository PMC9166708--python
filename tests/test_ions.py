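"""Branch-point bridging sites, event detection, and incidence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hjkit.ions import (
    IncidenceSummary,
    branch_point_sites,
    detect_events,
    incidence,
    site_occupancy_table,
)
from hjkit.structure_io import HJStructure, JunctionSpec, Trajectory, replace_spec
from hjkit.synth import IonPlan, SynthSpec, build_trajectory


class TestSites:
    def test_two_disjoint_sites(self, junction_60):
        s, _ = junction_60
        p1, p2 = branch_point_sites(s)
        assert {p1.label, p2.label} == {"Pos1", "Pos2"}
        assert len(p1.phosphate_indices) >= 1 and len(p1.acceptor_indices) >= 1
        assert len(p1.atom_indices) >= 2 and len(p2.atom_indices) >= 2
        assert not set(p1.atom_indices) & set(p2.atom_indices)

    def test_sites_swap_under_strand_relabeling(self, junction_60):
        # relabeling strands by a two-arm rotation exchanges the two
        # exchanging-strand pairs, so the sites must swap labels exactly
        s, _ = junction_60
        rot = JunctionSpec(
            strands=s.spec.strands[2:] + s.spec.strands[:2],
            stacks=s.spec.stacks,
        )
        p1, p2 = branch_point_sites(s)
        q1, q2 = branch_point_sites(replace_spec(s, rot))
        assert set(q1.atom_indices) == set(p2.atom_indices)
        assert set(q2.atom_indices) == set(p1.atom_indices)

    def test_unannotated_rejected(self, junction_60):
        s, _ = junction_60
        with pytest.raises(Exception):
            branch_point_sites(replace_spec(s, None))


class TestDetection:
    def test_planted_ion_yields_one_event_at_site(self, make_trajectory):
        traj, _ = make_trajectory(n_frames=1, bound_frames={0}, noise=0.0)
        events = detect_events(traj)
        assert len(events) == 1
        ev = events[0]
        assert ev.site == "Pos1"
        assert ev.frame == 0
        assert all(d <= 3.6 for d in ev.distances)
        assert 1 <= len(ev.acceptor_indices) <= 2

    def test_displaced_ion_yields_no_event(self, make_trajectory):
        traj, _ = make_trajectory(n_frames=1, bound_frames=set(), noise=0.0)
        assert detect_events(traj) == []

    def test_phosphate_only_contact_is_not_a_bridge(self, make_trajectory):
        traj, _ = make_trajectory(n_frames=1, bound_frames=set(), noise=0.0)
        topo = traj.topology
        site = branch_point_sites(topo)[0]
        coords = traj.frames[0].copy()
        o = coords[site.phosphate_indices[0]]
        acc = coords[list(site.acceptor_indices)]
        away = o - acc.mean(axis=0)
        away /= np.linalg.norm(away)
        ion_pos = o + 1.5 * away  # 1.5 A from the oxygen, far side from bases
        assert np.linalg.norm(acc - ion_pos, axis=1).min() > 3.6
        coords[int(topo.ion_indices[0])] = ion_pos
        assert detect_events(Trajectory(topo, [coords])) == []

    def test_monotone_in_cutoff(self, make_trajectory):
        traj, _ = make_trajectory(n_frames=40, bound_frames=set(range(0, 40, 3)))
        keys = {}
        for cutoff in (2.0, 3.6, 6.0):
            keys[cutoff] = {
                (e.frame, e.ion_index) for e in detect_events(traj, cutoff)
            }
        assert keys[2.0] <= keys[3.6] <= keys[6.0]

    def test_rigid_motion_invariance(self, make_trajectory):
        traj, _ = make_trajectory(n_frames=20, bound_frames=set(range(7)))
        R = Rotation.from_euler("zxy", [33.0, -71.0, 145.0], degrees=True).as_matrix()
        t = np.array([8.0, -20.0, 3.0])
        topo2 = traj.topology.with_coords(traj.topology.coords @ R.T + t)
        moved = Trajectory(topo2, [f @ R.T + t for f in traj.frames])
        ev0 = [(e.frame, e.ion_index, e.site) for e in detect_events(traj)]
        ev1 = [(e.frame, e.ion_index, e.site) for e in detect_events(moved)]
        assert ev0 == ev1

    def test_no_ions_warns_and_returns_empty(self, make_trajectory):
        traj, _ = make_trajectory(ion=False, n_frames=3)
        with pytest.warns(UserWarning, match="no ions"):
            assert detect_events(traj) == []


class TestIncidence:
    def test_planted_53_of_100(self, make_trajectory):
        traj, truth = make_trajectory(bound_frames=set(range(53)), n_frames=100)
        summ = incidence(traj)
        assert summ.incidence == 0.53
        assert summ.frames_with_event == len(truth.bound_frames["Pos1"]) == 53

    def test_all_frames_bound(self, make_trajectory):
        traj, _ = make_trajectory(bound_frames=set(range(10)), n_frames=10)
        assert incidence(traj).incidence == 1.0

    def test_no_ion_bound_anywhere(self, make_trajectory):
        traj, _ = make_trajectory(bound_frames=set(), n_frames=10)
        assert incidence(traj).incidence == 0.0

    def test_invariant_under_frame_reordering(self, make_trajectory):
        traj, _ = make_trajectory(bound_frames={1, 4, 9}, n_frames=12)
        shuffled = Trajectory(traj.topology, list(reversed(traj.frames)))
        assert incidence(shuffled).incidence == incidence(traj).incidence

    def test_zero_frames_rejected(self, junction_60):
        s, _ = junction_60
        with pytest.raises(ValueError, match="zero frames"):
            incidence(Trajectory(s, []))

    def test_both_sites_pooled(self, quartet):
        plans = (
            IonPlan(frames=frozenset({0, 1}), site="Pos1"),
            IonPlan(frames=frozenset({1, 2}), site="Pos2"),
        )
        spec = SynthSpec.from_quartet(quartet, n_frames=4, ion_plans=plans,
                                      noise_sigma=0.0)
        traj, _ = build_trajectory(spec)
        assert incidence(traj).incidence == pytest.approx(3 / 4)


class TestOccupancyTable:
    def test_group_mean_reproduces_arithmetic(self):
        summaries = [
            IncidenceSummary("Ja", 100, 25),
            IncidenceSummary("Jb", 100, 53),
            IncidenceSummary("Jc", 100, 81),
        ]
        table, mean, sigma = site_occupancy_table(summaries)
        assert len(table) == 3
        assert mean == pytest.approx(0.53)
        assert sigma == pytest.approx(np.std([0.25, 0.53, 0.81], ddof=1))

    def test_single_summary_sigma_absent(self):
        _, mean, sigma = site_occupancy_table([IncidenceSummary("J", 10, 5)])
        assert mean == 0.5 and sigma is None

    def test_subset_selection(self):
        summaries = [
            IncidenceSummary("good", 10, 8),
            IncidenceSummary("fatal", 10, 0),
        ]
        _, mean, _ = site_occupancy_table(summaries, subset=["good"])
        assert mean == pytest.approx(0.8)
        with pytest.raises(ValueError):
            site_occupancy_table(summaries, subset=["absent"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            site_occupancy_table([])
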