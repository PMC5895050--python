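import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torgo.electrostatics import (TERM_LABELS, isotropic_pair_fg, pair_energy,
                                  pair_fg, pair_fg_orientational, pair_terms,
                                  quadrupole_trace_product,
                                  quadrupole_trace_product_basis)
from conftest import random_multipole

ZERO = (0.0, np.zeros(3), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# independent oracle: multipole expansion of the electrostatic potential.
# E = q2 phi(r2) + mu2 . grad phi(r2) + (1/3) Theta2 : hess phi(r2), with
# phi(x) = q1/r + mu1.d/r^3 + d.Theta1.d/r^5, d = x - r1 (numeric derivatives)
def _phi(x, m1, r1):
    q1, mu1, th1 = m1
    d = x - r1
    r = np.linalg.norm(d)
    return q1 / r + mu1 @ d / r**3 + d @ th1 @ d / r**5


def oracle_energy(m1, m2, r1, r2, h=1e-4):
    q2, mu2, th2 = m2
    grad = np.zeros(3)
    hess = np.zeros((3, 3))
    for i in range(3):
        e = np.zeros(3); e[i] = h
        grad[i] = (_phi(r2 + e, m1, r1) - _phi(r2 - e, m1, r1)) / (2 * h)
        for j in range(3):
            f = np.zeros(3); f[j] = h
            hess[i, j] = (_phi(r2 + e + f, m1, r1) - _phi(r2 + e - f, m1, r1)
                          - _phi(r2 - e + f, m1, r1)
                          + _phi(r2 - e - f, m1, r1)) / (4 * h * h)
    return q2 * _phi(r2, m1, r1) + mu2 @ grad + np.sum(th2 * hess) / 3.0


def _fd_pair_gradient(m1, m2, r1, r2, n, p, h_deg=1e-3):
    """Central difference of the pair energy under rotation of atom 1 and its
    frame about the axis (p, n); per radian."""
    def E(ang):
        R = Rotation.from_rotvec(ang * n)
        r1p = R.apply(r1 - p) + p
        m1p = (m1[0], R.apply(m1[1]), R.as_matrix() @ m1[2] @ R.as_matrix().T)
        return pair_energy(m1p, m2, r1p, r2)[0]
    h = np.deg2rad(h_deg)
    return (E(h) - E(-h)) / (2 * h)


class TestPairEnergy:
    def test_point_charges(self):
        E, bd = pair_energy((1.0, *ZERO[1:]), (1.0, *ZERO[1:]),
                            [0, 0, 0], [2, 0, 0])
        assert E == pytest.approx(0.5)
        assert bd["q-q"] == pytest.approx(0.5)

    def test_parallel_dipoles_perpendicular_to_axis(self):
        mu = np.array([0.0, 0.0, 1.0])
        E, _ = pair_energy((0.0, mu, ZERO[2]), (0.0, mu, ZERO[2]),
                           [0, 0, 0], [2, 0, 0])
        assert E == pytest.approx(1.0 / 8.0)

    def test_matches_potential_expansion_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            m1 = random_multipole(rng)
            m2 = random_multipole(rng)
            r1 = rng.uniform(-1, 1, 3)
            r2 = r1 + rng.uniform(-0.5, 0.5, 3) + np.array([3.0, 0.5, -0.5])
            E, _ = pair_energy(m1, m2, r1, r2)
            assert E == pytest.approx(oracle_energy(m1, m2, r1, r2), abs=2e-8)

    def test_symmetric_under_role_swap(self):
        rng = np.random.default_rng(3)
        m1, m2 = random_multipole(rng), random_multipole(rng)
        r1, r2 = np.zeros(3), np.array([2.5, 0.4, -0.7])
        assert pair_energy(m1, m2, r1, r2)[0] == \
            pytest.approx(pair_energy(m2, m1, r2, r1)[0], rel=1e-14)

    def test_breakdown_has_all_term_labels(self):
        _, bd = pair_energy(random_multipole(np.random.default_rng(0)),
                            random_multipole(np.random.default_rng(1)),
                            [0, 0, 0], [3, 0, 0])
        assert list(bd) == TERM_LABELS
        assert len(TERM_LABELS) == 14

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            pair_energy((1.0, *ZERO[1:]), (1.0, *ZERO[1:]), [1, 1, 1], [1, 1, 1])


class TestPairFG:
    def test_zero_multipoles_zero_gradient(self):
        pg = pair_fg(ZERO, ZERO, [0, 0, 0], [2, 0, 0])
        assert not pg.f.any() and not pg.g.any()

    def test_monopole_monopole_closed_form(self):
        pg = pair_fg((1.0, *ZERO[1:]), (1.0, *ZERO[1:]), [0, 0, 0], [2, 0, 0])
        np.testing.assert_allclose(pg.f, [0, 0, 0], atol=1e-15)
        np.testing.assert_allclose(pg.g, [-0.25, 0, 0], atol=1e-15)

    def test_matches_finite_difference(self):
        rng = np.random.default_rng(21)
        for _ in range(6):
            m1, m2 = random_multipole(rng), random_multipole(rng)
            r1 = rng.uniform(-1, 1, 3)
            r2 = r1 + np.array([2.6, 0.4, -0.5])
            n = rng.normal(size=3); n /= np.linalg.norm(n)
            p = rng.uniform(-2, 2, 3)
            pg = pair_fg(m1, m2, r1, r2)
            ana = pg.f @ n + pg.g @ np.cross(n, p)
            assert ana == pytest.approx(
                _fd_pair_gradient(m1, m2, r1, r2, n, p), abs=1e-9)

    def test_go_form_universality_one_fg_many_axes(self):
        """A single (f, g) pair must serve any separating rotation axis."""
        rng = np.random.default_rng(5)
        m1, m2 = random_multipole(rng), random_multipole(rng)
        r1 = np.array([0.3, -0.2, 0.1])
        r2 = r1 + np.array([2.2, 1.0, -0.6])
        pg = pair_fg(m1, m2, r1, r2)
        for _ in range(5):
            n = rng.normal(size=3); n /= np.linalg.norm(n)
            p = rng.uniform(-3, 3, 3)
            ana = pg.f @ n + pg.g @ np.cross(n, p)
            assert ana == pytest.approx(
                _fd_pair_gradient(m1, m2, r1, r2, n, p), abs=5e-9)

    def test_antisymmetry_under_role_swap(self):
        rng = np.random.default_rng(9)
        m1, m2 = random_multipole(rng), random_multipole(rng)
        r1, r2 = np.array([0.1, 0.2, 0.3]), np.array([2.0, -0.5, 1.0])
        a = pair_fg(m1, m2, r1, r2)
        b = pair_fg(m2, m1, r2, r1)
        np.testing.assert_allclose(b.f, -a.f, atol=1e-13)
        np.testing.assert_allclose(b.g, -a.g, atol=1e-13)

    def test_rotation_invariance_identity(self):
        """u x G + O1 + O2 = 0: the algebraic core of Gō-form universality."""
        rng = np.random.default_rng(17)
        for _ in range(6):
            m1, m2 = random_multipole(rng), random_multipole(rng)
            u = rng.uniform(-1, 1, 3) + np.array([2.5, 0, 0])
            _, G, O1, O2 = pair_terms(m1[0], m1[1], m1[2],
                                      m2[0], m2[1], m2[2], u[None])
            resid = np.cross(u, G[0]) + O1[0] + O2[0]
            assert np.abs(resid).max() < 1e-13


class TestOrientational:
    def test_zero_for_atom_without_moments(self):
        rng = np.random.default_rng(2)
        m2 = random_multipole(rng)
        o = pair_fg_orientational((0.5, *ZERO[1:]), m2, [0, 0, 0], [2.5, 0, 0],
                                  which_atom=0)
        assert not o.any()

    def test_matches_frame_only_finite_difference(self):
        """Rotate only the designated atom's frame, positions frozen."""
        rng = np.random.default_rng(31)
        m1, m2 = random_multipole(rng), random_multipole(rng)
        r1, r2 = np.zeros(3), np.array([2.4, 0.8, -0.3])
        n = rng.normal(size=3); n /= np.linalg.norm(n)
        o1 = pair_fg_orientational(m1, m2, r1, r2, which_atom=0)

        def E(ang):
            R = Rotation.from_rotvec(ang * n)
            m1p = (m1[0], R.apply(m1[1]),
                   R.as_matrix() @ m1[2] @ R.as_matrix().T)
            return pair_energy(m1p, m2, r1, r2)[0]

        h = 1e-6
        assert o1 @ n == pytest.approx((E(h) - E(-h)) / (2 * h), abs=1e-9)

    def test_f_decomposes_into_positional_and_orientational(self):
        rng = np.random.default_rng(41)
        m1, m2 = random_multipole(rng), random_multipole(rng)
        r1, r2 = np.array([0.4, 0.1, -0.2]), np.array([2.0, 1.2, 0.5])
        pg = pair_fg(m1, m2, r1, r2)
        u = r2 - r1
        _, G, O1, O2 = pair_terms(m1[0], m1[1], m1[2], m2[0], m2[1], m2[2],
                                  u[None])
        np.testing.assert_allclose(pg.f, np.cross(G[0], r1) + O1[0],
                                   atol=1e-13)
        # equivalent closed form through the other atom (rotation invariance)
        np.testing.assert_allclose(pg.f, -(np.cross(r2, G[0]) + O2[0]),
                                   atol=1e-12)


class TestTraceProduct:
    def test_elementwise_equals_basis_vector_form(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            th1 = random_multipole(rng)[2]
            th2 = random_multipole(rng)[2]
            assert quadrupole_trace_product(th1, th2) == pytest.approx(
                quadrupole_trace_product_basis(th1, th2), abs=1e-12)


class TestIsotropic:
    def test_zero_slope(self):
        pg = isotropic_pair_fg(0.0, [0, 0, 0], [1, 1, 1])
        assert not pg.f.any() and not pg.g.any()

    def test_harmonic_restraint_magnitude(self):
        # E = k d^2, d = 1, k = 10 -> |dE/dd| = 20 along the bond
        pg = isotropic_pair_fg(20.0, [0, 0, 0], [1, 0, 0])
        np.testing.assert_allclose(pg.g, [20.0, 0, 0], atol=1e-14)

    def test_matches_finite_difference_over_torsion(self):
        rng = np.random.default_rng(8)
        r1 = rng.uniform(-1, 1, 3)
        r2 = r1 + np.array([1.7, 0.6, -0.2])
        k = 3.5
        d0 = np.linalg.norm(r2 - r1)
        pg = isotropic_pair_fg(2 * k * d0, r1, r2)
        n = rng.normal(size=3); n /= np.linalg.norm(n)
        p = rng.uniform(-2, 2, 3)
        ana = pg.f @ n + pg.g @ np.cross(n, p)

        def E(ang):
            R = Rotation.from_rotvec(ang * n)
            r1p = R.apply(r1 - p) + p
            return k * np.linalg.norm(r2 - r1p) ** 2

        h = 1e-6
        assert ana == pytest.approx((E(h) - E(-h)) / (2 * h), abs=1e-8)
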