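import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from crowdmd import geometry as geom
from crowdmd.constants import E_ANGSTROM_TO_DEBYE


def quaternion_rotation_angle_oracle(coords_a, coords_b):
    """Independent superposition-angle oracle via the Kearsley quaternion
    eigenvalue method (no scipy rotation machinery)."""
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    evals, evecs = np.linalg.eigh(k)
    q = evecs[:, np.argmax(evals)]  # (w, x, y, z), optimal rotation
    w = abs(q[0])
    return np.degrees(2.0 * np.arccos(np.clip(w, -1.0, 1.0)))


class TestCenterOfMass:
    @pytest.mark.parametrize(
        "coords,masses,expected",
        [
            ([(0, 0, 0), (2, 0, 0)], [1, 1], (1, 0, 0)),
            ([(0, 0, 0), (4, 0, 0)], [1, 3], (3, 0, 0)),
            ([(1.5, -2, 7)], [12.0], (1.5, -2, 7)),
        ],
    )
    def test_examples(self, coords, masses, expected):
        np.testing.assert_allclose(
            geom.center_of_mass(np.array(coords, float), np.array(masses, float)),
            expected,
        )

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            geom.center_of_mass(np.empty((0, 3)), np.empty(0))


class TestPbcDistance:
    @pytest.mark.parametrize(
        "a,b,edge,expected",
        [
            ((5, 5, 5), (95, 5, 5), 100.0, 10.0),
            ((1, 2, 3), (1, 2, 3), 100.0, 0.0),
            ((10, 10, 10), (40, 10, 10), 100.0, 30.0),
        ],
    )
    def test_examples(self, a, b, edge, expected):
        assert geom.pbc_distance(np.array(a, float), np.array(b, float), edge) == pytest.approx(expected)

    @given(
        st.lists(st.floats(-200, 200), min_size=3, max_size=3),
        st.lists(st.floats(-200, 200), min_size=3, max_size=3),
        st.lists(st.integers(-3, 3), min_size=3, max_size=3),
    )
    def test_periodic_image_invariance(self, a, b, k):
        a, b, k = np.array(a), np.array(b), np.array(k, float)
        L = 100.0
        d1 = geom.pbc_distance(a, b, L)
        d2 = geom.pbc_distance(a + L * k, b, L)
        assert d1 == pytest.approx(d2, abs=1e-8)
        assert d1 <= L * np.sqrt(3) / 2 + 1e-9

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            geom.pbc_distance(np.zeros(3), np.ones(3), -1.0)


class TestGyration:
    def test_single_atom_zero(self):
        assert geom.gyration_diameter(np.array([[1.0, 2.0, 3.0]]), np.array([12.0])) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert geom.gyration_diameter(coords, np.ones(2)) == pytest.approx(2.0)

    def test_template_matches_compact_globular_protein(self, template):
        """The synthetic template is built to match a ubiquitin-sized
        globule, whose gyration diameter is ~23.4 Å."""
        top, xyz = template
        d = geom.gyration_diameter(xyz[top.heavy], top.masses[top.heavy])
        assert d == pytest.approx(23.4, abs=1.0)


class TestOrientationAngle:
    def test_identical_copies_zero(self, small_template):
        _, xyz = small_template
        assert geom.orientation_angle(xyz, xyz) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle_deg", [30.0, 90.0, 150.0, 180.0])
    def test_constructed_rotation_recovered(self, small_template, angle_deg):
        _, xyz = small_template
        rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([0, 0, 1.0]))
        other = rot.apply(xyz) + np.array([40.0, -3.0, 7.0])
        got = geom.orientation_angle(xyz, other)
        assert got == pytest.approx(angle_deg, abs=1e-6)
        assert got == pytest.approx(
            quaternion_rotation_angle_oracle(xyz, rot.apply(xyz)), abs=1e-6
        )

    def test_arbitrary_rotation_matches_quaternion_oracle(self, small_template):
        _, xyz = small_template
        rng = np.random.default_rng(4)
        for _ in range(5):
            rot = Rotation.from_quat(rng.normal(size=4) / 1.0, scalar_first=False)
            other = rot.apply(xyz)
            assert geom.orientation_angle(xyz, other) == pytest.approx(
                quaternion_rotation_angle_oracle(xyz, other), abs=1e-6
            )

    def test_symmetric_in_arguments(self, small_template):
        _, xyz = small_template
        rot = Rotation.from_rotvec([0.3, 0.8, -0.4])
        other = rot.apply(xyz)
        assert geom.orientation_angle(xyz, other) == pytest.approx(
            geom.orientation_angle(other, xyz), abs=1e-8
        )

    def test_collinear_errors(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            geom.orientation_angle(line, line)

    def test_too_few_atoms_errors(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            geom.orientation_angle(pts, pts)


class TestDipoleMoment:
    def test_unit_charge_pair_gives_conversion_constant(self):
        coords = np.array([[1.0, 0, 0], [0.0, 0, 0]])
        mu = geom.dipole_moment(coords, np.array([1.0, -1.0]))
        np.testing.assert_allclose(mu, [E_ANGSTROM_TO_DEBYE, 0, 0], atol=1e-12)
        assert np.linalg.norm(mu) == pytest.approx(4.80320, abs=1e-4)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_neutral_system_translation_invariant(self, shift):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(10, 3))
        q = rng.normal(size=10)
        q -= q.mean()  # exactly neutral
        mu1 = geom.dipole_moment(coords, q)
        mu2 = geom.dipole_moment(coords + np.array(shift), q)
        np.testing.assert_allclose(mu1, mu2, atol=1e-8)

    def test_template_constructed_to_250_debye(self, template):
        top, xyz = template
        mu = geom.dipole_moment(xyz, top.charges)
        assert np.linalg.norm(mu) == pytest.approx(250.0, rel=0.01)

    def test_all_zero_charges_warns_zero_vector(self):
        with pytest.warns(UserWarning):
            mu = geom.dipole_moment(np.ones((3, 3)), np.zeros(3))
        np.testing.assert_array_equal(mu, np.zeros(3))

    def test_net_charge_warns(self):
        with pytest.warns(UserWarning, match="net charge"):
            geom.dipole_moment(np.eye(3), np.array([1.0, 0.0, 0.0]))


class TestVectorAngle:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (2, 0, 0), 0.0),
            ((1, 0, 0), (-3, 0, 0), 180.0),
            ((1, 0, 0), (0, 5, 0), 90.0),
        ],
    )
    def test_examples(self, u, v, expected):
        assert geom.vector_angle(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            geom.vector_angle(np.zeros(3), np.ones(3))


class TestMsdDiffusion:
    def test_static_trajectory_zero(self):
        series = np.ones((200, 3))
        times = np.arange(200) * 0.1
        est = geom.msd_diffusion(series, times)
        assert est.D_trans == 0.0

    def test_brownian_recovery_pooled_walks(self):
        """Pooled MSD over independent walks recovers the input D within 10%."""
        D_ang = 3.0  # Å²/ns ⇔ 3e-11 m²/s
        dt = 0.1
        walks = []
        for seed in range(6):
            rng = np.random.default_rng(200 + seed)
            steps = rng.normal(0, np.sqrt(2 * D_ang * dt), size=(10000, 3))
            walks.append(np.cumsum(steps, axis=0))
        times = np.arange(10000) * dt
        est = geom.msd_diffusion(walks, times)
        assert est.D_trans == pytest.approx(3e-11, rel=0.10)
        assert est.fit_quality > 0.95

    def test_doubling_times_halves_D(self):
        rng = np.random.default_rng(3)
        walk = np.cumsum(rng.normal(size=(500, 3)), axis=0)
        t = np.arange(500) * 0.1
        d1 = geom.msd_diffusion(walk, t).D_trans
        d2 = geom.msd_diffusion(walk, 2 * t).D_trans
        assert d2 == pytest.approx(d1 / 2, rel=1e-9)

    def test_non_monotonic_times_error(self):
        walk = np.zeros((50, 3))
        t = np.zeros(50)
        with pytest.raises(ValueError):
            geom.msd_diffusion(walk, t)

    def test_msd_curve_matches_direct_average(self):
        rng = np.random.default_rng(9)
        r = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        curve = geom.msd(r)
        for lag in (1, 17, 150):
            direct = np.mean(np.sum((r[lag:] - r[:-lag]) ** 2, axis=1))
            assert curve[lag] == pytest.approx(direct, rel=1e-9)


class TestBrownianLength:
    @pytest.mark.parametrize(
        "D,t,expected",
        [(2e-11, 1e-6, 110.0), (5e-11, 1e-6, 173.0), (1e-11, 0.0, 0.0)],
    )
    def test_examples(self, D, t, expected):
        assert round(geom.brownian_length(D, t)) == expected

    def test_squared_length_linear_in_time(self):
        for D in (1e-11, 3e-11):
            for t in (1e-7, 5e-7, 2e-6):
                assert geom.brownian_length(D, t) ** 2 == pytest.approx(
                    6 * D * t * 1e20, rel=1e-12
                )


class TestBoxConcentration:
    def test_study_box_near_5mM(self):
        assert geom.box_concentration(3, 100.0) == pytest.approx(4.98, abs=0.01)

    def test_single_copy(self):
        assert geom.box_concentration(1, 100.0) == pytest.approx(1.66, abs=0.01)

    def test_doubling_edge_divides_by_eight(self):
        c1 = geom.box_concentration(2, 50.0)
        c2 = geom.box_concentration(2, 100.0)
        assert c1 == pytest.approx(8 * c2, rel=1e-12)


class TestUnwrap:
    def test_unwrap_removes_boundary_jumps(self):
        L = 100.0
        true = np.column_stack([np.linspace(0, 250, 500), np.zeros(500), np.zeros(500)])
        wrapped = np.mod(true, L)
        back = geom.unwrap_series(wrapped, L)
        np.testing.assert_allclose(back, true, atol=1e-9)
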