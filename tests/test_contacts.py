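import numpy as np
import pytest

from crowdmd import contacts as ct
from crowdmd.io import Atom, Topology, Trajectory

from conftest import brute_force_contact_count


def _chain(chain_id, positions, element="C", resid_start=1, name="CA"):
    atoms, coords = [], []
    for i, pos in enumerate(positions):
        atoms.append(
            Atom(chain_id, resid_start + i, "GLY", f"{name}{i}" if i else name,
                 element, 12.0)
        )
        coords.append(pos)
    return atoms, coords


def _two_chain_topology(pos_a, pos_b, element_a="C", element_b="C"):
    atoms_a, coords_a = _chain("A", pos_a, element_a)
    atoms_b, coords_b = _chain("B", pos_b, element_b)
    top = Topology(atoms_a + atoms_b)
    return top, np.array(coords_a + coords_b, dtype=float)


class TestCountContacts:
    def test_single_pair_below_cutoff_counts_both_atoms(self):
        top, xyz = _two_chain_topology(
            [(0, 0, 0), (50, 50, 50)], [(3.9, 0, 0), (60, 60, 60)]
        )
        assert ct.count_contacts(top, xyz, "A", "B") == 2

    def test_pair_just_outside_cutoff(self):
        top, xyz = _two_chain_topology([(0, 0, 0)], [(4.1, 0, 0)])
        assert ct.count_contacts(top, xyz, "A", "B") == 0

    def test_hydrogens_ignored(self):
        top, xyz = _two_chain_topology(
            [(0, 0, 0), (30, 0, 0)], [(1.0, 0, 0), (60, 0, 0)],
            element_a="H", element_b="H",
        )
        # replace one atom per chain by carbon far away so chains have heavy atoms
        atoms = list(top.atoms)
        atoms[1] = Atom("A", 2, "GLY", "CX", "C", 12.0)
        atoms[3] = Atom("B", 2, "GLY", "CX", "C", 12.0)
        top2 = Topology(atoms)
        assert ct.count_contacts(top2, xyz, "A", "B") == 0

    def test_symmetric_in_chains(self):
        rng = np.random.default_rng(0)
        top, xyz = _two_chain_topology(rng.uniform(0, 10, (20, 3)), rng.uniform(3, 13, (15, 3)))
        assert ct.count_contacts(top, xyz, "A", "B") == ct.count_contacts(top, xyz, "B", "A")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("box_edge", [None, 25.0])
    def test_matches_brute_force_oracle(self, seed, box_edge):
        rng = np.random.default_rng(seed)
        pos_a = rng.uniform(0, 20, (60, 3))
        pos_b = rng.uniform(0, 20, (45, 3))
        top, xyz = _two_chain_topology(pos_a, pos_b)
        got = ct.count_contacts(top, xyz, "A", "B", box_edge=box_edge)
        want = brute_force_contact_count(pos_a, pos_b, 4.0, box_edge)
        assert got == want

    def test_monotonic_in_cutoff(self):
        rng = np.random.default_rng(5)
        top, xyz = _two_chain_topology(
            rng.uniform(0, 15, (30, 3)), rng.uniform(0, 15, (30, 3))
        )
        counts = [
            ct.count_contacts(top, xyz, "A", "B", cutoff=c)
            for c in (2.0, 3.0, 4.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts)

    def test_no_heavy_atoms_errors(self):
        top, xyz = _two_chain_topology([(0, 0, 0)], [(3, 0, 0)], element_a="H")
        with pytest.raises(ValueError):
            ct.count_contacts(top, xyz, "A", "B")


class TestResidueContactProfile:
    def _contact_trajectory(self):
        # residue 44 of chain A touches residue 7 of chain B; rest far away
        atoms = [
            Atom("A", 44, "GLY", "CA", "C", 12.0),
            Atom("A", 45, "GLY", "CA", "C", 12.0),
            Atom("B", 7, "GLY", "CA", "C", 12.0),
            Atom("B", 8, "GLY", "CA", "C", 12.0),
        ]
        coords = np.array(
            [[[0, 0, 0], [30, 0, 0], [3, 0, 0], [60, 0, 0]]], dtype=float
        )
        return Trajectory(Topology(atoms), coords, [0.0])

    def test_single_contact_localized(self):
        traj = self._contact_trajectory()
        prof = ct.residue_contact_profile(traj)
        lookup = dict(zip(prof.residue_indices, prof.counts))
        assert lookup[44] == 1 and lookup[7] == 1
        assert lookup[45] == 0 and lookup[8] == 0

    def test_duplicating_frames_doubles_counts(self):
        traj = self._contact_trajectory()
        doubled = Trajectory(
            traj.topology,
            np.concatenate([traj.coords, traj.coords]),
            [0.0, 0.1],
        )
        p1 = ct.residue_contact_profile(traj)
        p2 = ct.residue_contact_profile(doubled)
        np.testing.assert_allclose(p2.counts, 2 * p1.counts)

    def test_averaging_identical_replicas_is_identity(self):
        p = ct.residue_contact_profile(self._contact_trajectory())
        avg = ct.average_profiles([p, p, p])
        np.testing.assert_allclose(avg.counts, p.counts)

    def test_profile_total_equals_contact_count(self):
        """Per-frame consistency with the atom-counting convention."""
        rng = np.random.default_rng(11)
        atoms, coords = [], []
        for c, off in (("A", 0.0), ("B", 3.0)):
            for i in range(25):
                atoms.append(Atom(c, i + 1, "GLY", "CA", "C", 12.0))
                coords.append(rng.uniform(0, 12, 3) + off)
        traj = Trajectory(Topology(atoms), np.array(coords)[None], [0.0])
        prof = ct.residue_contact_profile(traj)
        total = ct.count_contacts(traj.topology, traj.coords[0], "A", "B")
        assert prof.counts.sum() == total

    def test_unknown_chain_errors(self):
        traj = self._contact_trajectory()
        with pytest.raises(KeyError):
            ct.residue_contact_profile(traj, chain_pairs=[("A", "Z")])


class TestRunningAverage:
    def _profile(self, counts):
        counts = np.asarray(counts, dtype=float)
        return ct.ContactProfile(np.arange(1, len(counts) + 1), counts)

    def test_constant_profile_unchanged(self):
        p = ct.running_residue_average(self._profile([3.0] * 11))
        np.testing.assert_allclose(p.counts, 3.0)

    def test_unit_impulse_spread(self):
        counts = np.zeros(11)
        counts[5] = 1.0
        sm = ct.running_residue_average(self._profile(counts), window=5)
        np.testing.assert_allclose(sm.counts[3:8], 0.2)
        assert sm.counts[2] == 0.0 and sm.counts[8] == 0.0

    def test_window_one_is_identity(self):
        counts = np.arange(8.0)
        sm = ct.running_residue_average(self._profile(counts), window=1)
        np.testing.assert_allclose(sm.counts, counts)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ct.running_residue_average(self._profile([1.0, 2.0]), window=4)


class TestCompareProfiles:
    def _profile(self, counts):
        counts = np.asarray(counts, dtype=float)
        return ct.ContactProfile(np.arange(1, len(counts) + 1), counts)

    def test_self_comparison(self):
        p = self._profile([0, 1, 5, 2, 0, 7, 1])
        res = ct.compare_profiles(p, p)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["peak_overlap"] == pytest.approx(1.0)

    def test_ramp_vs_reversed_ramp_anticorrelated(self):
        ramp = np.arange(20.0)
        res = ct.compare_profiles(self._profile(ramp), self._profile(ramp[::-1]))
        assert res["pearson_r"] == pytest.approx(-1.0)

    def test_disjoint_peaks_zero_overlap(self):
        a = np.zeros(20)
        b = np.zeros(20)
        a[3] = 10.0
        b[15] = 10.0
        res = ct.compare_profiles(self._profile(a), self._profile(b))
        assert res["peak_overlap"] == 0.0

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            res = ct.compare_profiles(self._profile([2.0] * 5), self._profile([0, 1, 2, 3, 4]))
        assert res["r_defined"] == 0.0


class TestInterfacialWater:
    def _system(self, water_pos):
        atoms = [
            Atom("A", 1, "GLY", "CA", "C", 12.0),
            Atom("B", 1, "GLY", "CA", "C", 12.0),
            Atom("W", 1, "HOH", "OW", "O", 16.0),
        ]
        coords = np.array([[0, 0, 0], [6, 0, 0], list(water_pos)], dtype=float)
        return Topology(atoms), coords

    def test_bridging_water_counted(self):
        top, xyz = self._system((3.0, 0.0, 0.0))
        assert ct.interfacial_water_count(top, xyz, "A", "B") == 1

    def test_one_sided_water_not_counted(self):
        top, xyz = self._system((-3.0, 0.0, 0.0))  # 3 Å from A, 9 Å from B
        assert ct.interfacial_water_count(top, xyz, "A", "B") == 0

    def test_no_waters_warns_zero(self):
        atoms = [
            Atom("A", 1, "GLY", "CA", "C", 12.0),
            Atom("B", 1, "GLY", "CA", "C", 12.0),
        ]
        top = Topology(atoms)
        with pytest.warns(UserWarning):
            n = ct.interfacial_water_count(top, np.zeros((2, 3)), "A", "B")
        assert n == 0
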