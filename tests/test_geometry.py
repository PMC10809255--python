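import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dyesorb.constants import EA_TO_DEBYE
from dyesorb.geometry import (
    NanoparticleModel,
    center_of_mass,
    core_plane_normal,
    dipole_angle_theta,
    dipole_moment,
    parallelism_angle,
    surface_distance,
)
from dyesorb.trajio import Topology


def topo(masses, charges, groups):
    return Topology(np.asarray(masses, float), np.asarray(charges, float), groups)


vec3 = st.tuples(*[st.floats(-50, 50) for _ in range(3)]).map(np.array)


class TestCenterOfMass:
    def test_single_particle(self):
        t = topo([2.0], [0.0], {"g": [0]})
        np.testing.assert_allclose(
            center_of_mass(t, np.array([[1.0, 2.0, 3.0]]), "g"), [1, 2, 3]
        )

    def test_equal_masses_symmetric(self):
        t = topo([1, 1], [0, 0], {"g": [0, 1]})
        frame = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        np.testing.assert_allclose(center_of_mass(t, frame, "g"), [0, 0, 0])

    def test_weighted_mean_matches_brute_force(self):
        masses = [1.0, 2.0, 3.0]
        t = topo(masses, [0, 0, 0], {"g": [0, 1, 2]})
        frame = np.eye(3)
        expected = sum(m * frame[i] for i, m in enumerate(masses)) / sum(masses)
        np.testing.assert_allclose(center_of_mass(t, frame, "g"), expected)

    def test_empty_group_rejected(self):
        t = topo([1.0], [0.0], {"g": [0], "empty": []})
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(t, np.zeros((1, 3)), "empty")


class TestSurfaceDistance:
    NP = NanoparticleModel(label="SNP1", centers=np.zeros(3), radius=20.0)

    def test_adsorption_threshold_geometry(self):
        # a COM 25 Å from the center of a 40 Å-diameter sphere sits exactly
        # at the 5 Å near-surface threshold
        assert surface_distance(np.array([25.0, 0, 0]), self.NP) == pytest.approx(5.0)

    def test_com_at_center_is_minus_radius(self):
        assert surface_distance(np.zeros(3), self.NP) == pytest.approx(-20.0)

    @given(vec3)
    def test_matches_norm_oracle(self, p):
        expected = np.linalg.norm(p) - 20.0
        assert surface_distance(p, self.NP) == pytest.approx(expected, abs=1e-9)


class TestPlaneNormal:
    def _square(self):
        return np.array(
            [[1.0, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0], [0.5, 0.3, 0]]
        )

    def test_coplanar_points_give_z_normal(self):
        pts = self._square()
        t = topo(np.ones(5), np.zeros(5), {"c": range(5)})
        n = core_plane_normal(t, pts, "c")
        assert abs(abs(n[2]) - 1.0) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rotation_equivariance(self, seed):
        rot = Rotation.random(rng=np.random.default_rng(seed))
        pts = rot.apply(self._square())
        t = topo(np.ones(5), np.zeros(5), {"c": range(5)})
        n = core_plane_normal(t, pts, "c")
        expected = rot.apply([0.0, 0.0, 1.0])
        assert min(np.linalg.norm(n - expected), np.linalg.norm(n + expected)) < 1e-9

    def test_sign_follows_reference_radial(self):
        pts = self._square()
        t = topo(np.ones(5), np.zeros(5), {"c": range(5)})
        n = core_plane_normal(t, pts, "c", reference_radial=np.array([0, 0, -1.0]))
        assert n[2] < 0

    def test_two_points_degenerate(self):
        t = topo(np.ones(2), np.zeros(2), {"c": [0, 1]})
        with pytest.raises(ValueError):
            core_plane_normal(t, np.array([[0.0, 0, 0], [1, 0, 0]]), "c")

    def test_collinear_degenerate(self):
        t = topo(np.ones(4), np.zeros(4), {"c": range(4)})
        pts = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            core_plane_normal(t, pts, "c")


class TestAngles:
    def test_parallel_surface_is_zero(self):
        assert parallelism_angle([0, 0, 1.0], [0, 0, 1.0]) == pytest.approx(0.0)

    def test_perpendicular_is_ninety(self):
        assert parallelism_angle([1.0, 0, 0], [0, 0, 1.0]) == pytest.approx(90.0)

    def test_folding_makes_sign_irrelevant(self):
        assert parallelism_angle([0, 0, -1.0], [0, 0, 1.0]) == pytest.approx(0.0)

    @given(vec3, vec3)
    def test_matches_arccos_oracle(self, a, b):
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        cosang = abs(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
        expected = np.degrees(np.arccos(min(cosang, 1.0)))
        assert parallelism_angle(a, b) == pytest.approx(expected, abs=1e-6)
        assert 0.0 <= parallelism_angle(a, b) <= 90.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            parallelism_angle([0.0, 0, 0], [1.0, 0, 0])


class TestDipole:
    def test_two_charges_about_origin(self):
        t = topo([1, 1], [1.0, -1.0], {"g": [0, 1]})
        frame = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        d = dipole_moment(t, frame, "g", reference=np.zeros(3))
        np.testing.assert_allclose(d.components, [2.0, 0, 0])
        assert d.magnitude_debye == pytest.approx(2 * EA_TO_DEBYE)  # 9.6064 D
        assert d.net_charge == pytest.approx(0.0)

    def test_all_zero_charges(self):
        t = topo([1, 1], [0.0, 0.0], {"g": [0, 1]})
        d = dipole_moment(t, np.random.default_rng(0).normal(size=(2, 3)), "g")
        np.testing.assert_allclose(d.components, 0.0)

    @given(vec3)
    def test_neutral_group_reference_independent(self, shift):
        t = topo([1, 2, 3], [0.4, -0.9, 0.5], {"g": [0, 1, 2]})
        frame = np.array([[1.0, 0, 2], [-3, 1, 0], [0, 4, -2.0]])
        d0 = dipole_moment(t, frame, "g", reference=np.zeros(3))
        d1 = dipole_moment(t, frame, "g", reference=shift)
        np.testing.assert_allclose(d0.components, d1.components, atol=1e-9)

    @given(vec3)
    def test_charged_group_shift_law(self, shift):
        """Moving the reference by t changes the dipole by exactly −q·t."""
        t = topo([1, 2], [1.0, 0.5], {"g": [0, 1]})
        frame = np.array([[2.0, -1, 0], [0, 3, 1.0]])
        d0 = dipole_moment(t, frame, "g", reference=np.zeros(3))
        d1 = dipole_moment(t, frame, "g", reference=shift)
        np.testing.assert_allclose(
            d1.components, d0.components - d0.net_charge * shift, atol=1e-9
        )

    def test_theta_antiparallel_and_orthogonal(self):
        a = np.array([1.0, 0, 0])
        assert dipole_angle_theta(a, -a) == pytest.approx(180.0)
        assert dipole_angle_theta(a, np.array([0, 1.0, 0])) == pytest.approx(90.0)

    def test_theta_zero_dipole_rejected(self):
        with pytest.raises(ValueError):
            dipole_angle_theta(np.zeros(3), np.array([1.0, 0, 0]))


class TestFrameInvariances:
    """Translation invariance and rotation equivariance of the primitives."""

    @given(vec3, st.integers(0, 10))
    def test_translation(self, shift, seed):
        rng = np.random.default_rng(seed)
        t = topo([1, 2, 1, 3], [0.2, -0.2, 0.5, -0.5], {"g": [0, 1, 2, 3]})
        frame = rng.normal(scale=3, size=(4, 3))
        com0 = center_of_mass(t, frame, "g")
        com1 = center_of_mass(t, frame + shift, "g")
        np.testing.assert_allclose(com1, com0 + shift, atol=1e-8)
        d0 = dipole_moment(t, frame, "g")
        d1 = dipole_moment(t, frame + shift, "g")
        np.testing.assert_allclose(d0.components, d1.components, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_rotation(self, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng)
        t = topo(np.ones(5), np.linspace(-1, 1, 5), {"g": range(5)})
        frame = rng.normal(scale=3, size=(5, 3))
        d0 = dipole_moment(t, frame, "g")
        d1 = dipole_moment(t, rot.apply(frame), "g")
        np.testing.assert_allclose(d1.components, rot.apply(d0.components), atol=1e-8)
        np.testing.assert_allclose(
            center_of_mass(t, rot.apply(frame), "g"),
            rot.apply(center_of_mass(t, frame, "g")),
            atol=1e-8,
        )
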