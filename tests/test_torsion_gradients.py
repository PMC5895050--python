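import copy

import numpy as np
import pytest

from torgo.fixtures import FixtureSpec, make_chain
from torgo.frames import LocalMultipole
from torgo.minimizer import (PotentialConfig, electrostatic_terms,
                             restraint_terms, sasa_terms,
                             total_energy_and_gradient)
from torgo.torsion_gradients import (PairEntryList, accumulate_naive,
                                     accumulate_recursive, split_frame_atoms)
from torgo.validation import gradcheck_per_dof


def _all_entries(fx, cfg):
    _, e1, _ = electrostatic_terms(fx.tree, fx.params, cfg)
    _, e2 = restraint_terms(fx.tree, cfg)
    cfg_s = PotentialConfig(elec_weight=0.0, gamma=0.31, probe=1.4)
    _, e3, _ = sasa_terms(fx.tree, cfg_s)
    return PairEntryList.concat([e1, e2, e3])


class TestAccumulators:
    @pytest.mark.parametrize("seed", [0, 1, 5, 9])
    def test_recursive_equals_naive(self, seed, reduced_cfg):
        fx = make_chain(FixtureSpec(n_units=9, seed=seed))
        entries = _all_entries(fx, reduced_cfg)
        gn = accumulate_naive(fx.tree, entries)
        gr = accumulate_recursive(fx.tree, entries)
        scale = max(1e-30, np.abs(gn.dE_dalpha).max())
        np.testing.assert_allclose(gr.dE_dalpha, gn.dE_dalpha,
                                   atol=1e-10 * scale)

    def test_empty_entries_zero_gradient(self, chain_fixture):
        g = accumulate_naive(chain_fixture.tree, PairEntryList.empty())
        assert not g.dE_dalpha.any()
        g = accumulate_recursive(chain_fixture.tree, PairEntryList.empty())
        assert not g.dE_dalpha.any()

    def test_single_pair_single_dof_equals_direct_contraction(self):
        from torgo.electrostatics import pair_fg
        fx = make_chain(FixtureSpec(n_units=2, seed=8))
        tree, params = fx.tree, fx.params
        # pair_fg assumes the moving atom's frame co-rotates and the fixed
        # atom's frame is frozen, i.e. the pre-correction bookkeeping
        cfg = PotentialConfig(prefactor=1.0, use_reference_correction=False)
        _, entries, (ii, jj, _, G, O1, O2, gm) = \
            electrostatic_terms(tree, params, cfg)
        grad = accumulate_naive(tree, entries)
        # contract each pair by hand with the atom-1-moving convention
        origin, axis = tree.dof_axis(0)
        mov = tree.moving_atoms(0)
        total = 0.0
        pos = tree.positions()
        for k in range(len(ii)):
            i, j = int(ii[k]), int(jj[k])
            if (i in mov) == (j in mov):
                continue
            mover, fixed = (i, j) if i in mov else (j, i)
            pg = pair_fg((gm.q[mover], gm.mu[mover], gm.theta[mover]),
                         (gm.q[fixed], gm.mu[fixed], gm.theta[fixed]),
                         pos[mover], pos[fixed])
            total += pg.f @ axis + pg.g @ np.cross(axis, origin)
        assert grad.dE_dalpha[0] == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_recursive_never_queries_per_dof_moving_sets(self, chain_fixture,
                                                         reduced_cfg,
                                                         monkeypatch):
        """The single-pass form must not loop pairs per DOF."""
        fx = chain_fixture
        entries = _all_entries(fx, reduced_cfg)
        calls = {"n": 0}
        orig = type(fx.tree).moving_atoms

        def counting(self, d):
            calls["n"] += 1
            return orig(self, d)

        monkeypatch.setattr(type(fx.tree), "moving_atoms", counting)
        accumulate_recursive(fx.tree, entries)
        assert calls["n"] == 0
        accumulate_naive(fx.tree, entries)
        assert calls["n"] == fx.tree.n_dofs

    def test_linearity_of_accumulation(self, chain_fixture, reduced_cfg):
        fx = chain_fixture
        _, e1, _ = electrostatic_terms(fx.tree, fx.params, reduced_cfg)
        cfg_s = PotentialConfig(elec_weight=0.0, gamma=1.0)
        _, e2, _ = sasa_terms(fx.tree, cfg_s)
        g1 = accumulate_recursive(fx.tree, e1).dE_dalpha
        g2 = accumulate_recursive(fx.tree, e2).dE_dalpha
        g12 = accumulate_recursive(fx.tree,
                                   PairEntryList.concat([e1, e2])).dE_dalpha
        np.testing.assert_allclose(g12, g1 + g2, rtol=1e-12, atol=1e-12)


class TestReferenceCorrection:
    def test_rigid_molecule_has_zero_gradient(self):
        """No DOF separates any pair: every entry contributes nothing."""
        fx = make_chain(FixtureSpec(n_units=4, seed=2))
        cfg = PotentialConfig(prefactor=1.0)
        _, entries, _ = electrostatic_terms(fx.tree, fx.params, cfg)
        # a tree with no DOFs at all
        from torgo.kinematics import build_tree
        rigid = build_tree(fx.tree.atoms[:],
                           fx.tree.bonds, [], root=0)
        g = accumulate_naive(rigid, entries)
        assert g.dE_dalpha.shape == (0,)

    def test_frame_rotation_needs_correction(self, frame_rotation_fixture):
        """A torsion that rotates an atom's frame at constant pair distance:
        plain distance-based bookkeeping misses the gradient entirely; the
        reference-atom correction restores it to finite-difference accuracy."""
        fx = frame_rotation_fixture
        cfg_on = PotentialConfig(prefactor=1.0)
        cfg_off = PotentialConfig(prefactor=1.0, use_reference_correction=False)
        rep_on = gradcheck_per_dof(fx.tree, fx.params, cfg_on)
        rep_off = gradcheck_per_dof(fx.tree, fx.params, cfg_off)
        assert rep_on.mean_abs_diff <= 1e-7
        assert rep_off.mean_abs_diff > 100 * rep_on.mean_abs_diff

    def test_hinge_partner_pair_is_exact(self, reduced_cfg):
        """Regression: pair (hinge atom, moving partner) carries the hinge's
        frame-rotation term through the correction entries."""
        fx = make_chain(FixtureSpec(n_units=3, seed=3))
        params = copy.deepcopy(fx.params)
        for k, v in params.local.items():
            params.local[k] = LocalMultipole(q=0.0, mu=v.mu)
        rep = gradcheck_per_dof(fx.tree, params, reduced_cfg)
        assert rep.max_abs_diff <= 1e-9


class TestSplitFrameDiagnostic:
    def test_clean_fixture_unflagged(self, chain_fixture):
        assert split_frame_atoms(chain_fixture.tree, chain_fixture.params) \
            == set()

    def test_split_frame_atom_flagged_and_error_bounded(self):
        from torgo.fixtures import make_ring_fixture
        fx = make_ring_fixture(FixtureSpec(n_units=7, seed=2, include_ring=True,
                                           include_split_frame=True))
        flagged = split_frame_atoms(fx.tree, fx.params)
        assert flagged == {2}
        # the split frame produces a real (bounded, restraint-controlled)
        # gradient error, unlike the exact clean-fixture case
        fx.tree.set_torsion(3, 20.0)
        cfg = PotentialConfig(prefactor=1.0)
        rep = gradcheck_per_dof(fx.tree, fx.params, cfg)
        assert rep.mean_abs_diff > 1e-6
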