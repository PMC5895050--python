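"""Composite torsion-space potential and local minimization.

The potential is a weighted sum of permanent multipole electrostatics, a
surface-tension term gamma * SASA, and harmonic ring-closure restraints
E = k |r_virtual - r_real|^2.  Gradients with respect to every torsion are
assembled analytically through the pair-entry accumulator; minimization uses
L-BFGS-B over the torsion angles (quasi-Newton with a monotone line search,
which also copes with the small gradient discontinuities at SASA contact
changes by backtracking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import electrostatics as es
from .frames import MultipoleParams, refresh_global_multipoles
from .sasa import compute_arcs, sasa_entries, sasa_from_arcs
from .torsion_gradients import (PairEntryList, accumulate_naive,
                                accumulate_recursive,
                                entries_from_pair_arrays,
                                reference_correction_entries)

__all__ = ["PotentialConfig", "MinimizationTrace", "EnergyReport",
           "total_energy_and_gradient", "minimize_torsions"]


@dataclass
class PotentialConfig:
    """Term weights and evaluation options.

    ``prefactor`` is the electrostatic conversion constant; use 1.0 for
    reduced units or ``electrostatics.COULOMB`` (the default) for kcal/mol
    with charges in e and distances in Angstrom.  ``gamma`` is the surface
    tension in energy/A^2 (0 disables the SASA term); ``elec_weight`` scales
    the whole electrostatic term.  ``exclusion_scales`` maps bond separation
    (1-2, 1-3, 1-4) to a scale factor; unlisted separations count at full
    strength.
    """

    elec_weight: float = 1.0
    gamma: float = 0.0
    probe: float = 1.4
    prefactor: float = es.COULOMB
    restraint_scale: float = 1.0
    exclusion_scales: dict[int, float] = field(default_factory=dict)
    cutoff: float | None = None
    use_reference_correction: bool = True
    accumulator: str = "recursive"       # or "naive"
    tolerance: float = 1e-6              # kcal/mol/rad max-norm
    max_iterations: int = 500

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for w in (self.elec_weight, self.gamma, self.prefactor):
            if not np.isfinite(w):
                raise ValueError("weights must be finite")


@dataclass
class EnergyReport:
    total: float
    electrostatics: float
    sasa_energy: float
    restraints: float
    total_sasa: float
    breakdown: dict[str, float]


@dataclass
class MinimizationTrace:
    energies: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    converged: bool = False
    message: str = ""


def _bond_separation_scales(tree, ii, jj, scales: dict[int, float]) -> np.ndarray:
    out = np.ones(len(ii))
    if not scales:
        return out
    import networkx as nx
    g = nx.Graph(tree.bonds)
    g.add_edges_from((c.real_atom, c.virtual_atom) for c in tree.ring_closures)
    maxsep = max(scales)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=maxsep))
    for k in range(len(ii)):
        sep = lengths.get(int(ii[k]), {}).get(int(jj[k]))
        if sep is not None and sep in scales:
            out[k] = scales[sep]
    return out


def electrostatic_pairs(tree, gm) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i < j) of real atoms that both carry multipoles."""
    act = np.array([
        (not a.is_virtual) and (gm.q[a.atom_id] != 0 or gm.mu[a.atom_id].any()
                               or gm.theta[a.atom_id].any())
        for a in tree.atoms
    ])
    idx = np.where(act)[0]
    ii, jj = np.triu_indices(len(idx), k=1)
    return idx[ii], idx[jj]


def electrostatic_terms(tree, params: MultipoleParams, config: PotentialConfig):
    """(energy, entries, per-pair data) for the multipole term.

    Returns the scaled total energy, accumulator entries (base pairs plus
    reference-atom corrections), and ``(ii, jj, E_pair, G, O1, O2)`` for
    fine-grained validation.
    """
    gm = refresh_global_multipoles(tree, params)
    ii, jj = electrostatic_pairs(tree, gm)
    pos = tree.positions()
    if len(ii) == 0:
        return 0.0, PairEntryList.empty(), (ii, jj, np.zeros(0), np.zeros((0, 3)),
                                            np.zeros((0, 3)), np.zeros((0, 3)), gm)
    u = pos[jj] - pos[ii]
    if config.cutoff is not None:
        keep = np.einsum("mi,mi->m", u, u) <= config.cutoff ** 2
        ii, jj, u = ii[keep], jj[keep], u[keep]
    Et, G, O1, O2 = es.pair_terms(gm.q[ii], gm.mu[ii], gm.theta[ii],
                                  gm.q[jj], gm.mu[jj], gm.theta[jj], u)
    w = config.elec_weight * config.prefactor \
        * _bond_separation_scales(tree, ii, jj, config.exclusion_scales)
    E_pair = Et.sum(axis=1) * w
    G = G * w[:, None]
    O1 = O1 * w[:, None]
    O2 = O2 * w[:, None]
    entries = entries_from_pair_arrays(ii, jj, pos, G, O1, O2)
    if config.use_reference_correction:
        folding = tree.folding_path_atoms()
        entries = PairEntryList.concat([
            entries,
            reference_correction_entries(ii, jj, O1, O2, tree.reference_atom,
                                         folding),
        ])
    return float(E_pair.sum()), entries, (ii, jj, E_pair, G, O1, O2, gm)


def restraint_terms(tree, config: PotentialConfig):
    """Harmonic virtual-real closure restraints: E = k d^2."""
    E = 0.0
    parts: list[PairEntryList] = []
    pos = tree.positions()
    for c in tree.ring_closures:
        k = c.spring_k * config.restraint_scale
        i, j = c.virtual_atom, c.real_atom
        u = pos[j] - pos[i]
        E += k * float(u @ u)
        G = (2.0 * k) * u
        parts.append(entries_from_pair_arrays(
            np.array([i]), np.array([j]), pos, G[None, :],
            np.zeros((1, 3)), np.zeros((1, 3))))
    return E, PairEntryList.concat(parts)


def sasa_terms(tree, config: PotentialConfig):
    pos = tree.positions()
    radii = np.array([a.radius for a in tree.atoms])
    active = np.array([(not a.is_virtual) and a.radius > 0 for a in tree.atoms])
    arcs = compute_arcs(pos, radii, config.probe, active)
    _, total = sasa_from_arcs(arcs)
    entries = sasa_entries(arcs, pos, gamma=config.gamma)
    return config.gamma * total, entries, total


def total_energy_and_gradient(tree, params: MultipoleParams,
                              config: PotentialConfig,
                              return_report: bool = False):
    """Composite energy and per-DOF analytic gradient (per radian)."""
    E_el, ent_el, _ = electrostatic_terms(tree, params, config) \
        if config.elec_weight != 0 else (0.0, PairEntryList.empty(), None)
    E_rs, ent_rs = restraint_terms(tree, config) \
        if tree.ring_closures and config.restraint_scale != 0 \
        else (0.0, PairEntryList.empty())
    if config.gamma != 0.0:
        E_sa, ent_sa, tot_sasa = sasa_terms(tree, config)
    else:
        E_sa, ent_sa, tot_sasa = 0.0, PairEntryList.empty(), 0.0
    entries = PairEntryList.concat([ent_el, ent_rs, ent_sa])
    acc = accumulate_naive if config.accumulator == "naive" else accumulate_recursive
    grad = acc(tree, entries)
    E = E_el + E_rs + E_sa
    if return_report:
        rep = EnergyReport(total=E, electrostatics=E_el, sasa_energy=E_sa,
                           restraints=E_rs, total_sasa=tot_sasa, breakdown={})
        return E, grad.dE_dalpha, rep
    return E, grad.dE_dalpha


def minimize_torsions(tree, params: MultipoleParams, config: PotentialConfig):
    """Quasi-Newton minimization over all torsion angles.

    Returns ``(final_angles_deg, trace)``; the tree is left at the minimized
    conformation.  The trace records energy and gradient max-norm after each
    accepted iterate.
    """
    trace = MinimizationTrace()
    x0 = np.deg2rad(tree.torsion_angles())
    last_x = [x0.copy()]

    def fun(x):
        tree.set_all_torsions(np.rad2deg(x))
        E, g = total_energy_and_gradient(tree, params, config)
        return E, g

    def cb(x):
        E, g = fun(x)
        trace.energies.append(float(E))
        trace.grad_norms.append(float(np.abs(g).max()) if len(g) else 0.0)
        trace.step_sizes.append(float(np.abs(x - last_x[0]).max()))
        last_x[0] = x.copy()

    E0, g0 = fun(x0)
    trace.energies.append(float(E0))
    trace.grad_norms.append(float(np.abs(g0).max()) if len(g0) else 0.0)
    trace.step_sizes.append(0.0)
    if len(x0) == 0 or trace.grad_norms[0] <= config.tolerance:
        trace.converged = True
        trace.message = "already stationary"
        return tree.torsion_angles(), trace

    res = _scipy_minimize(
        fun, x0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": config.max_iterations,
                 "gtol": config.tolerance, "ftol": 1e-14},
    )
    tree.set_all_torsions(np.rad2deg(res.x))
    trace.converged = bool(res.success) or \
        float(np.abs(res.jac).max()) <= config.tolerance
    trace.message = str(res.message)
    Ef, _ = total_energy_and_gradient(tree, params, config)
    if Ef > E0 + 1e-12:
        # L-BFGS should never accept an uphill iterate; fall back to start
        tree.set_all_torsions(np.rad2deg(x0))
        trace.message += " (final energy above start; restored start)"
    return tree.torsion_angles(), trace
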