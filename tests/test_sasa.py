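import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torgo.sasa import (DegenerateGeometryError, compute_arcs, sasa_from_arcs,
                        sasa_gradient_data, sasa_pair_fg, total_sasa)

FOURPI = 4 * np.pi


def dot_density_sasa(pos, rad, probe, ndots=20000, seed=3):
    """Independent surface-point sampling estimate of per-atom areas."""
    r = np.random.default_rng(seed)
    v = r.normal(size=(ndots, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    rho = rad + probe
    per = []
    for i in range(len(pos)):
        pts = pos[i] + rho[i] * v
        cov = np.zeros(ndots, bool)
        for j in range(len(pos)):
            if j != i:
                cov |= np.linalg.norm(pts - pos[j], axis=1) < rho[j]
        per.append(FOURPI * rho[i] ** 2 * (1 - cov.mean()))
    return np.array(per)


def _clean_cluster(rng, n=7):
    while True:
        pos = rng.uniform(0, 4.0, (n, 3))
        rad = rng.uniform(1.2, 1.9, n)
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(pos[i] - pos[j])
                if d < 0.9 or abs(d - (rad[i] + rad[j])) < 5e-3 \
                        or d < abs(rad[i] - rad[j]) + 5e-3:
                    ok = False
        if ok:
            return pos, rad


class TestAreas:
    def test_isolated_sphere(self):
        per, tot = sasa_from_arcs(compute_arcs(np.zeros((1, 3)),
                                               np.array([1.4]), probe=0.0))
        assert tot == pytest.approx(FOURPI * 1.4 ** 2, rel=1e-12)
        assert per[0].exposed_fraction == 1.0
        assert not per[0].buried

    def test_probe_extends_radius(self):
        tot = total_sasa(np.zeros((1, 3)), np.array([1.5]), probe=1.4)
        assert tot == pytest.approx(FOURPI * 2.9 ** 2, rel=1e-12)

    @pytest.mark.parametrize("rho1,rho2,d", [(1.7, 1.7, 1.9), (1.8, 1.5, 2.0),
                                             (1.4, 1.9, 1.2)])
    def test_two_spheres_cap_closed_form(self, rho1, rho2, d):
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        per, tot = sasa_from_arcs(compute_arcs(pos, np.array([rho1, rho2]),
                                               probe=0.0))
        h1 = rho1 - (d ** 2 + rho1 ** 2 - rho2 ** 2) / (2 * d)
        h2 = rho2 - (d ** 2 + rho2 ** 2 - rho1 ** 2) / (2 * d)
        assert per[0].area == pytest.approx(
            FOURPI * rho1 ** 2 - 2 * np.pi * rho1 * h1, rel=1e-10)
        assert per[1].area == pytest.approx(
            FOURPI * rho2 ** 2 - 2 * np.pi * rho2 * h2, rel=1e-10)
        # conservation: exposed + buried caps account for both full spheres
        buried = 2 * np.pi * (rho1 * h1 + rho2 * h2)
        assert tot + buried == pytest.approx(FOURPI * (rho1**2 + rho2**2),
                                             rel=1e-10)

    def test_contained_sphere_is_buried(self):
        pos = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        per, tot = sasa_from_arcs(compute_arcs(pos, np.array([0.5, 2.0]),
                                               probe=0.0))
        assert per[0].buried and per[0].area == 0.0
        assert per[1].area == pytest.approx(FOURPI * 4.0, rel=1e-12)

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            compute_arcs(np.zeros((2, 3)), np.array([1.5, 1.5]), probe=0.0)

    def test_three_sphere_arc_endpoints_match_trigonometry(self):
        """Arc vertices equal the brute-force circle-circle intersections."""
        pos = np.array([[0.0, 0, 0], [2.2, 0, 0], [1.1, 1.7, 0.3]])
        rad = np.array([1.6, 1.5, 1.55])
        arcs = compute_arcs(pos, rad, probe=0.0)
        # vertex between circles (0,1) and (0,2) on sphere 0, by hand:
        # solve |x| = r0, |x - p1| = r1, |x - p2| = r2
        endpoints = [a.start for a in arcs[0].arcs] + \
                    [a.end for a in arcs[0].arcs]
        for p in endpoints:
            assert np.linalg.norm(p - pos[0]) == pytest.approx(rad[0], abs=1e-8)
            dists = sorted(abs(np.linalg.norm(p - pos[j]) - rad[j])
                           for j in (1, 2))
            assert dists[0] < 1e-8   # on at least one neighbor sphere too

    def test_matches_dot_density_oracle(self):
        rng = np.random.default_rng(10)
        pos, rad = _clean_cluster(rng)
        per, tot = sasa_from_arcs(compute_arcs(pos, rad, probe=0.0))
        per_a = np.array([p.area for p in per])
        per_o = dot_density_sasa(pos, rad, 0.0)
        assert tot == pytest.approx(per_o.sum(), rel=5e-3)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pos, rad = _clean_cluster(rng)
        t0 = total_sasa(pos, rad, probe=1.0)
        R = Rotation.from_rotvec([1.0, -0.4, 0.2]).as_matrix()
        t1 = total_sasa(pos @ R.T + np.array([3.0, 1.0, -2.0]), rad, probe=1.0)
        assert t1 == pytest.approx(t0, rel=1e-10)

    def test_tangency_warning(self):
        pos = np.array([[0.0, 0, 0], [3.0000001, 0, 0]])
        with pytest.warns(UserWarning, match="tangency"):
            compute_arcs(pos, np.array([1.5, 1.5]), probe=0.0)


class TestGradients:
    def test_two_sphere_parallel_part_equals_cap_derivative(self):
        rho1, rho2, d = 1.8, 1.5, 2.0
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        rad = np.array([rho1, rho2])
        arcs = compute_arcs(pos, rad, probe=0.0)
        pairs, W = sasa_gradient_data(arcs, pos)
        # full circle: perpendicular (V) part closes to zero
        for (i, j), w in zip(pairs, W):
            assert abs(w[1]) < 1e-12 and abs(w[2]) < 1e-12
        w01 = W[[tuple(p) for p in pairs].index((0, 1))]
        # d(exposed area of sphere 1)/dd from the cap closed form
        dA1_dd = np.pi * rho1 * (1 - (rho1 ** 2 - rho2 ** 2) / d ** 2)
        assert w01[0] == pytest.approx(dA1_dd, rel=1e-10)

    def test_no_contact_pair_zero(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        arcs = compute_arcs(pos, np.array([1.5, 1.5]), probe=0.0)
        pg = sasa_pair_fg(arcs, pos, 0, 1)
        assert not pg.f.any() and not pg.g.any()

    def test_cartesian_finite_difference(self):
        rng = np.random.default_rng(11)
        pos, rad = _clean_cluster(rng, n=6)
        arcs = compute_arcs(pos, rad, probe=0.0)
        pairs, W = sasa_gradient_data(arcs, pos)
        h = 1e-6
        for (i, j), w in list(zip(pairs, W))[:6]:
            fd = np.zeros(3)
            for k in range(3):
                pp = pos.copy(); pp[j, k] += h
                a1 = sasa_from_arcs(compute_arcs(pp, rad, 0.0))[0][i].area
                pp = pos.copy(); pp[j, k] -= h
                a2 = sasa_from_arcs(compute_arcs(pp, rad, 0.0))[0][i].area
                fd[k] = (a1 - a2) / (2 * h)
            np.testing.assert_allclose(w, fd, atol=5e-7)

    def test_pair_fg_matches_torsional_finite_difference(self):
        """(f, g) of a contact pair vs rotating atom 1 about a random axis."""
        rng = np.random.default_rng(12)
        pos, rad = _clean_cluster(rng, n=5)
        arcs = compute_arcs(pos, rad, probe=0.0)
        pairs, _ = sasa_gradient_data(arcs, pos)
        i, j = (int(pairs[0][0]), int(pairs[0][1]))
        pg = sasa_pair_fg(arcs, pos, i, j)
        n = rng.normal(size=3); n /= np.linalg.norm(n)
        p = rng.uniform(-2, 2, 3)

        def pair_area(ang):
            pp = pos.copy()
            R = Rotation.from_rotvec(ang * n)
            pp[i] = R.apply(pos[i] - p) + p
            aset = compute_arcs(pp, rad, probe=0.0)
            prs, Ws = sasa_gradient_data(aset, pp)
            # joint i-j terms only: integrate via the per-atom areas is not
            # pairwise separable; instead check the full dA against all pairs
            per, _ = sasa_from_arcs(aset)
            return per[i].area + per[j].area

        # chain rule over the directed contacts of atoms i and j must match
        # the finite difference of their joint area when atom i rotates
        h = np.deg2rad(1e-3)
        fd = (pair_area(h) - pair_area(-h)) / (2 * h)
        prs, Ws = sasa_gradient_data(arcs, pos)
        dri = np.cross(n, pos[i] - p)
        expected = 0.0
        for (a, b), w in zip(prs, Ws):
            if a not in (i, j):
                continue
            du = np.zeros(3)
            if b == i:
                du += dri
            if a == i:
                du -= dri
            expected += w @ du
        assert fd == pytest.approx(expected, abs=1e-6)
        # and the Gō-form contraction reproduces the i-j part of that sum
        go = pg.f @ n + pg.g @ np.cross(n, p)
        manual_ij = 0.0
        for (a, b), w in zip(prs, Ws):
            if {a, b} == {i, j}:
                du = (dri if b == i else 0) - (dri if a == i else 0)
                manual_ij += w @ du
        assert go == pytest.approx(manual_ij, rel=1e-9, abs=1e-12)

    def test_torsional_gradcheck_on_polymer(self, chain_fixture, sasa_cfg):
        from torgo.validation import gradcheck_per_dof
        rep = gradcheck_per_dof(chain_fixture.tree, chain_fixture.params,
                                sasa_cfg)
        assert rep.mean_abs_diff < 1e-8
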