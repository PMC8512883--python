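import math

import numpy as np
import pytest

from dimerfes.colvars import (
    cog_distance,
    dimer_cvs,
    normal_angle,
    read_colvar,
    ring_torsion,
    write_colvar,
)
from dimerfes.toysystems import DimerState, Pose, make_ring_template, random_unit_quaternion

from conftest import random_dimer_state

IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


def dihedral_oracle(p0, p1, p2, p3):
    """Textbook dihedral via the two plane normals: atan2((n1 x n2).b2, n1.n2).

    Sign convention: positive when p3 is rotated right-handed about the
    p1 -> p2 axis relative to p0 (checked on a canonical geometry below).
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = math.atan2(y, x)
    return math.pi if ang == -math.pi else ang


def state_at(translation_b, quat_b=None, quat_a=None, box=5.0):
    return DimerState(
        Pose(np.zeros(3), IDENTITY_Q if quat_a is None else quat_a),
        Pose(np.asarray(translation_b, dtype=float), IDENTITY_Q if quat_b is None else quat_b),
        box_edge=box,
    )


class TestCogDistance:
    def test_plain_translation(self, hexagon):
        state = state_at([0.55, 0.0, 0.0])
        assert cog_distance(state, hexagon, hexagon) == pytest.approx(0.55, abs=1e-12)

    def test_minimum_image_wraps(self, hexagon):
        state = state_at([4.5, 0.0, 0.0], box=5.0)
        assert cog_distance(state, hexagon, hexagon) == pytest.approx(0.5, abs=1e-12)

    def test_matches_raw_coordinate_oracle(self, hexagon, tetra):
        rng = np.random.default_rng(17)
        for _ in range(50):
            state = random_dimer_state(rng)
            ca = state.pose_a.apply(hexagon.coords)[hexagon.ring_atom_indices].mean(axis=0)
            cb = state.pose_b.apply(tetra.coords)[tetra.ring_atom_indices].mean(axis=0)
            d = cb - ca
            d -= state.box_edge * np.round(d / state.box_edge)
            assert cog_distance(state, hexagon, tetra) == pytest.approx(
                float(np.linalg.norm(d)), abs=1e-12
            )


class TestRingTorsion:
    def test_cis_is_zero(self, hexagon):
        # identical orientation: anchors on the same side of the COG-COG axis
        state = state_at([0.0, 0.0, 0.8])
        assert ring_torsion(state, hexagon, hexagon) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_pi(self, hexagon):
        from scipy.spatial.transform import Rotation

        # rotate B by 180 deg about the separation axis -> anchors opposed
        q = Rotation.from_rotvec([0, 0, math.pi]).as_quat()
        state = state_at([0.0, 0.0, 0.8], quat_b=q)
        assert abs(ring_torsion(state, hexagon, hexagon)) == pytest.approx(math.pi, abs=1e-9)

    def test_sign_convention_right_handed_about_cog_axis(self):
        """Rotating the far anchor by +phi right-handed about the COG->COG
        axis yields torsion +phi (both for the oracle and the implementation)."""
        from dimerfes.colvars import _dihedral

        for phi in (0.5, -0.5, 2.0):
            p0 = np.array([1.0, 0.0, 0.0])
            p1 = np.array([0.0, 0.0, 0.0])
            p2 = np.array([0.0, 0.0, 1.0])
            p3 = np.array([math.cos(phi), math.sin(phi), 1.0])
            assert _dihedral(p0, p1, p2, p3) == pytest.approx(phi, abs=1e-12)
            assert dihedral_oracle(p0, p1, p2, p3) == pytest.approx(phi, abs=1e-12)

    def test_matches_textbook_oracle_on_random_states(self, hexagon):
        rng = np.random.default_rng(23)
        for _ in range(60):
            state = random_dimer_state(rng)
            ca = state.pose_a.apply(hexagon.coords)
            cb = state.pose_b.apply(hexagon.coords)
            cog_a = ca[hexagon.ring_atom_indices].mean(axis=0)
            cog_b = cb[hexagon.ring_atom_indices].mean(axis=0)
            expected = dihedral_oracle(ca[0], cog_a, cog_b, cb[0])
            assert ring_torsion(state, hexagon, hexagon) == pytest.approx(expected, abs=1e-9)

    def test_coincident_cogs_rejected(self, hexagon):
        state = state_at([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="torsion"):
            ring_torsion(state, hexagon, hexagon)


class TestNormalAngle:
    def test_parallel_stacked_is_zero(self, hexagon):
        state = state_at([0.0, 0.0, 0.5])
        assert normal_angle(state, hexagon, hexagon) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_t_shaped_is_right_angle(self, hexagon):
        from scipy.spatial.transform import Rotation

        q = Rotation.from_rotvec([math.pi / 2, 0, 0]).as_quat()
        state = state_at([0.0, 0.0, 0.6], quat_b=q)
        assert normal_angle(state, hexagon, hexagon) == pytest.approx(math.pi / 2, abs=1e-9)

    def test_matches_cross_product_oracle_for_planar_rings(self, hexagon):
        rng = np.random.default_rng(31)
        for _ in range(50):
            state = random_dimer_state(rng)
            ca = state.pose_a.apply(hexagon.coords)
            cb = state.pose_b.apply(hexagon.coords)

            def cross_normal(c):
                n = np.cross(c[1] - c[0], c[2] - c[0])
                return n / np.linalg.norm(n)

            cosang = abs(float(np.dot(cross_normal(ca), cross_normal(cb))))
            expected = math.acos(min(cosang, 1.0))
            assert normal_angle(state, hexagon, hexagon) == pytest.approx(expected, abs=1e-9)

    def test_folded_to_first_quadrant(self, hexagon):
        from scipy.spatial.transform import Rotation

        # 150 deg tilt folds to 30 deg
        q = Rotation.from_rotvec([5 * math.pi / 6, 0, 0]).as_quat()
        state = state_at([0.0, 0.0, 0.6], quat_b=q)
        assert normal_angle(state, hexagon, hexagon) == pytest.approx(math.pi / 6, abs=1e-9)


class TestInvariances:
    def test_cvs_invariant_under_global_motion(self, hexagon):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(41)
        state = random_dimer_state(rng)
        ref = dimer_cvs(state, hexagon, hexagon)
        R = Rotation.from_quat(random_unit_quaternion(rng))
        shift = rng.uniform(-1, 1, size=3)
        qa = (R * Rotation.from_quat(state.pose_a.quaternion)).as_quat()
        qb = (R * Rotation.from_quat(state.pose_b.quaternion)).as_quat()
        moved = DimerState(
            Pose(R.apply(state.pose_a.translation) + shift, qa / np.linalg.norm(qa)),
            Pose(R.apply(state.pose_b.translation) + shift, qb / np.linalg.norm(qb)),
            state.box_edge,
        )
        new = dimer_cvs(moved, hexagon, hexagon)
        assert new.distance == pytest.approx(ref.distance, abs=1e-9)
        assert new.torsion == pytest.approx(ref.torsion, abs=1e-9)
        assert new.normal_angle == pytest.approx(ref.normal_angle, abs=1e-9)

    def test_label_exchange_flips_torsion_sign_only(self, hexagon, tetra):
        rng = np.random.default_rng(43)
        state = random_dimer_state(rng)
        ref = dimer_cvs(state, hexagon, tetra)
        swapped = dimer_cvs(
            DimerState(state.pose_b, state.pose_a, state.box_edge), tetra, hexagon
        )
        assert swapped.distance == pytest.approx(ref.distance, abs=1e-9)
        assert swapped.normal_angle == pytest.approx(ref.normal_angle, abs=1e-9)
        assert abs(swapped.torsion) == pytest.approx(abs(ref.torsion), abs=1e-9)


class TestColvarIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        n = 20
        path = tmp_path / "COLVAR"
        t = np.arange(1, n + 1) * 10
        cols = {
            "dist": rng.uniform(0.3, 2.0, n),
            "torsion": rng.uniform(-np.pi, np.pi, n),
            "nangle": rng.uniform(0, np.pi / 2, n),
            "bias": rng.uniform(0, 5, n),
        }
        write_colvar(path, t, cols["dist"], cols["torsion"], cols["nangle"], cols["bias"])
        back = read_colvar(path)
        np.testing.assert_allclose(back["time"], t)
        for k, v in cols.items():
            np.testing.assert_allclose(back[k], v, atol=1e-9)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "COLVAR"
        path.write_text("1 0.5 0.1 0.2 0.0\n")
        with pytest.raises(ValueError, match="FIELDS"):
            read_colvar(path)
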