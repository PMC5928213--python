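"""Patch geometry and directional square-well pair interaction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchygibbs.model import (
    OVERLAP,
    Configuration,
    ModelParams,
    Particle,
    Species,
    is_bonded,
    minimum_image,
    pair_energy,
    patch_cos_half_angle,
    quat_to_matrix,
    random_quaternion,
    reference_patch_directions,
    total_energy,
)
from patchygibbs.fixtures import make_fixture, random_configuration


class TestPatchGeometry:
    @pytest.mark.parametrize(
        "m, chi, expected",
        [(4, 0.7, 0.65), (2, 0.7, 0.30), (2, 1.0, 0.0)],
    )
    def test_cos_half_angle_values(self, m, chi, expected):
        assert patch_cos_half_angle(m, chi) == pytest.approx(expected, abs=1e-12)

    def test_cos_half_angle_domain_errors(self):
        with pytest.raises(ValueError):
            patch_cos_half_angle(0, 0.5)
        with pytest.raises(ValueError):
            patch_cos_half_angle(4, -0.1)
        with pytest.raises(ValueError):
            patch_cos_half_angle(1, 1.0)  # cos = -1: patch beyond a hemisphere

    def test_reference_directions(self):
        p = reference_patch_directions(Species.P)
        r = reference_patch_directions(Species.R)
        assert np.allclose(np.linalg.norm(p, axis=1), 1.0)
        dots = p @ p.T
        off = dots[~np.eye(4, dtype=bool)]
        assert np.allclose(off, -1.0 / 3.0)
        assert np.allclose(r, [[0, 0, 1], [0, 0, -1]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rotation_preserves_pairwise_dots(self, seed):
        rng = np.random.default_rng(seed)
        q = random_quaternion(rng)
        p = reference_patch_directions(Species.P)
        rotated = p @ quat_to_matrix(q).T
        assert np.allclose(rotated @ rotated.T, p @ p.T, atol=1e-12)


class TestModelParams:
    def test_defaults_match_study_conditions(self):
        p = ModelParams()
        assert p.cos_theta_P == pytest.approx(0.65)
        assert p.cos_theta_R == pytest.approx(0.30)
        assert p.well_edge == pytest.approx(1.5)
        assert p.eps_RR == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chi": 0.0},
            {"chi": 1.0},
            {"lam": -0.1},
            {"eps_PR": -0.5},
            {"m_P": 3},
            {"chi": 0.95},  # P patches would overlap
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_patch_overlap_check_optional(self):
        p = ModelParams(chi=0.95, check_patch_overlap=False)
        assert 0 < p.cos_theta_P < 1

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError):
            Particle(Species.P, np.zeros(3), np.array([1.0, 0.1, 0.0, 0.0]))


def _aligned_pair(species_i, species_j, distance, box=20.0):
    """Two particles along x with their first patches facing each other."""
    from patchygibbs.fixtures import _quat_patch0_to

    x = np.array([1.0, 0.0, 0.0])
    pi = Particle(species_i, np.array([5.0, 5.0, 5.0]), _quat_patch0_to(species_i, x))
    pj = Particle(
        species_j, np.array([5.0 + distance, 5.0, 5.0]), _quat_patch0_to(species_j, -x)
    )
    return pi, pj, np.array([distance, 0.0, 0.0])


class TestPairEnergy:
    def test_aligned_RR_bonded_but_zero_energy(self):
        params = ModelParams()
        pi, pj, d = _aligned_pair(Species.R, Species.R, 1.2)
        assert is_bonded(pi, pj, params, d)
        assert pair_energy(pi, pj, params, d) == 0.0

    def test_antialigned_not_bonded(self):
        """First patch pointed directly away from the partner: the remaining
        tetrahedral patches sit 70.5 degrees off the pair axis, outside
        theta_P, so no bond forms."""
        from patchygibbs.fixtures import _quat_patch0_to

        params = ModelParams()
        x = np.array([1.0, 0.0, 0.0])
        pi = Particle(Species.P, np.array([5.0, 5.0, 5.0]), _quat_patch0_to(Species.P, -x))
        pj = Particle(Species.P, np.array([6.2, 5.0, 5.0]), _quat_patch0_to(Species.P, x))
        d = np.array([1.2, 0.0, 0.0])
        assert not is_bonded(pi, pj, params, d)

    def test_aligned_PP_in_well(self):
        params = ModelParams()
        pi, pj, d = _aligned_pair(Species.P, Species.P, 1.2)
        assert pair_energy(pi, pj, params, d) == -1.0

    def test_hard_core_overlap_sentinel(self):
        params = ModelParams()
        pi, pj, d = _aligned_pair(Species.P, Species.P, 0.9)
        assert pair_energy(pi, pj, params, d) is OVERLAP

    def test_outside_well_zero(self):
        params = ModelParams()
        pi, pj, d = _aligned_pair(Species.P, Species.P, 1.6)
        assert pair_energy(pi, pj, params, d) == 0.0

    def test_symmetry_and_range(self, rng):
        """pair_energy(i, j) == pair_energy(j, i), and only three values occur."""
        params = ModelParams(eps_PR=0.7)
        values = {-1.0, -0.7, -0.0, 0.0}
        for _ in range(300):
            ri = rng.uniform(0, 4, 3)
            rj = rng.uniform(0, 4, 3)
            pi = Particle(rng.integers(0, 2), ri, random_quaternion(rng))
            pj = Particle(rng.integers(0, 2), rj, random_quaternion(rng))
            d = rj - ri
            e_ij = pair_energy(pi, pj, params, d)
            e_ji = pair_energy(pj, pi, params, -d)
            assert e_ij is e_ji or e_ij == e_ji
            if e_ij is not OVERLAP:
                assert e_ij in values

    def test_isotropic_limit_reduces_to_square_well(self, rng):
        """chi -> 1 on the polar species: energy independent of orientation."""
        params = ModelParams(chi=0.999999, eps_RR=1.0, check_patch_overlap=False)
        for _ in range(1000):
            r = rng.uniform(0.2, 2.0)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            d = r * direction
            pi = Particle(Species.R, np.zeros(3), random_quaternion(rng))
            pj = Particle(Species.R, d, random_quaternion(rng))
            e = pair_energy(pi, pj, params, d)
            if r <= 1.0:
                assert e is OVERLAP
            elif r <= 1.5:
                assert e == -1.0
            else:
                assert e == 0.0


class TestTotalEnergy:
    def test_single_particle_zero(self):
        cfg = Configuration(
            np.array([[1.0, 1.0, 1.0]]),
            np.array([[1.0, 0.0, 0.0, 0.0]]),
            np.array([0]),
            10.0,
        )
        assert total_energy(cfg, ModelParams()) == 0.0

    def test_trimer_fixture_value(self):
        fx = make_fixture("trimer_PPR")
        assert total_energy(fx.configuration, fx.params) == -1.5

    def test_rotational_invariance(self, rng):
        """One global rotation of positions and orientations about the box
        center leaves the total energy unchanged (cluster far from walls)."""
        from scipy.spatial.transform import Rotation

        params = ModelParams(eps_PR=0.6)
        box = 40.0
        center = np.full(3, box / 2)
        # compact random cluster near the center, away from well edges
        cfg = random_configuration(12, 4.0, rng, x_ratio=0.5, min_distance=1.05)
        pos = cfg.positions - 2.0 + center
        cfg = Configuration(pos, cfg.orientations, cfg.species, box)
        e0 = total_energy(cfg, params)
        rot = Rotation.random(random_state=np.random.RandomState(3))
        new_pos = rot.apply(cfg.positions - center) + center
        q_rot = rot.as_quat()  # x, y, z, w
        q_rot = np.array([q_rot[3], q_rot[0], q_rot[1], q_rot[2]])

        def qmul(a, b):
            w1, x1, y1, z1 = a
            w2, x2, y2, z2 = b
            return np.array(
                [
                    w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                    w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                    w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                    w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                ]
            )

        new_quat = np.array([qmul(q_rot, q) for q in cfg.orientations])
        new_quat /= np.linalg.norm(new_quat, axis=1, keepdims=True)
        rotated = Configuration(new_pos, new_quat, cfg.species, box)
        assert total_energy(rotated, params) == e0

    def test_no_RR_energy_when_eps_RR_zero(self, rng):
        params = ModelParams(eps_PR=0.0, eps_RR=0.0)
        cfg = random_configuration(30, 5.0, rng, x_ratio=5.0, min_distance=1.02)
        cfg_r_only = Configuration(
            cfg.positions, cfg.orientations, np.ones(30, dtype=int), cfg.box_edge
        )
        assert total_energy(cfg_r_only, params) == 0.0


class TestConfiguration:
    def test_positions_wrapped(self):
        cfg = Configuration(
            np.array([[11.0, -1.0, 5.0]]),
            np.array([[1.0, 0.0, 0.0, 0.0]]),
            np.array([0]),
            10.0,
        )
        assert np.all(cfg.positions >= 0) and np.all(cfg.positions < 10.0)

    def test_minimum_image(self):
        d = minimum_image(np.array([9.0, -9.0, 0.5]), 10.0)
        assert np.allclose(d, [-1.0, 1.0, 0.5])
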