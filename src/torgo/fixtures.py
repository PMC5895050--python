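"""Deterministic synthetic molecular fixtures.

Branched polymers of "heavy" atoms with one or two hydrogen-like satellites
each, idealized geometry (1.5 A bonds, near-tetrahedral angles), randomized
multipole parameters of protein-like magnitude (q in [-1, 1] e, |mu| <= 0.5
e*A, quadrupole components <= 1 e*A^2, traceless and symmetric by
construction) and randomized starting torsions.  Every heavy atom carries a
hydrogen, so a reference atom is always available; local frames are z-then-x
with the tree parent as z anchor and the first hydrogen as x anchor, so frames
co-rotate exactly with the kinematics (no accidental split frames).

A ring variant closes a five-membered ring through a virtual atom, optionally
defining one frame anchor across the ring break to reproduce the split-frame
pathology on purpose.

Identical (spec, seed) pairs generate bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import LocalFrameDef, LocalMultipole, MultipoleParams
from .kinematics import Atom, KinematicTree, build_tree

__all__ = ["FixtureSpec", "Fixture", "make_chain", "make_ring_fixture",
           "make_frame_rotation_fixture"]

BOND_LENGTH = 1.5
H_BOND_LENGTH = 1.1
HEAVY_RADIUS = 1.7
H_RADIUS = 1.2
MIN_CLEARANCE = 1e-3


@dataclass
class FixtureSpec:
    n_units: int = 10
    branch_prob: float = 0.25
    bond_length: float = BOND_LENGTH
    q_scale: float = 1.0
    mu_scale: float = 0.5
    theta_scale: float = 1.0
    include_ring: bool = False
    include_split_frame: bool = False
    spring_k: float = 100.0
    seed: int = 0


@dataclass
class Fixture:
    tree: KinematicTree
    params: MultipoleParams
    spec: FixtureSpec


def _random_quadrupole(rng: np.random.Generator, scale: float) -> np.ndarray:
    A = rng.uniform(-scale, scale, (3, 3))
    th = 0.5 * (A + A.T)
    th -= np.eye(3) * np.trace(th) / 3.0
    m = np.abs(th).max()
    if m > scale:                      # keep components within the stated band
        th *= scale / m
    return th


def _random_multipole(rng: np.random.Generator, spec: FixtureSpec) -> LocalMultipole:
    mu = rng.uniform(-1, 1, 3)
    nrm = np.linalg.norm(mu)
    mu = mu / nrm * rng.uniform(0.05, spec.mu_scale) if nrm > 0 else mu
    return LocalMultipole(
        q=float(rng.uniform(-spec.q_scale, spec.q_scale)),
        mu=mu,
        theta=_random_quadrupole(rng, spec.theta_scale),
    )


def _tetrahedral_directions(rng: np.random.Generator, back: np.ndarray,
                            n: int) -> list[np.ndarray]:
    """n directions at ~109.5 deg from ``back`` (the bond to the parent),
    evenly rolled around it from a random phase."""
    z = back / np.linalg.norm(back)
    ref = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0.0, 1, 0])
    a = np.cross(z, ref)
    a /= np.linalg.norm(a)
    b = np.cross(z, a)
    phi0 = rng.uniform(0, 2 * np.pi)
    ang = np.deg2rad(109.47)
    out = []
    for k in range(n):
        phi = phi0 + 2 * np.pi * k / max(n, 1)
        d = np.cos(ang) * z + np.sin(ang) * (np.cos(phi) * a + np.sin(phi) * b)
        out.append(d / np.linalg.norm(d))
    return out


def _place_substituents(rng: np.random.Generator, back: np.ndarray,
                        existing_dirs: list[np.ndarray], n_new: int) -> list[np.ndarray]:
    """Directions on the tetrahedral cone around ``back`` avoiding existing bonds."""
    z = back / np.linalg.norm(back)
    ref = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0.0, 1, 0])
    a = np.cross(z, ref)
    a /= np.linalg.norm(a)
    b = np.cross(z, a)
    taken = []
    for d in existing_dirs:
        taken.append(np.arctan2(float(d @ b), float(d @ a)))
    cand = list(np.linspace(0, 2 * np.pi, 36, endpoint=False) + rng.uniform(0, 0.2))
    ang = np.deg2rad(109.47)
    out = []
    for _ in range(n_new):
        def score(phi):
            if not taken:
                return 1.0
            return min(abs((phi - t + np.pi) % (2 * np.pi) - np.pi) for t in taken)
        phi = max(cand, key=score)
        taken.append(phi)
        d = np.cos(ang) * z + np.sin(ang) * (np.cos(phi) * a + np.sin(phi) * b)
        out.append(d / np.linalg.norm(d))
    return out


def _grow_polymer(spec: FixtureSpec, rng: np.random.Generator):
    """Self-avoiding heavy-atom skeleton as (positions, parent list).

    Grows from live chain tips with tetrahedral geometry, re-rolling the
    dihedral phase of each placement until the new atom keeps >= 1.8 A from
    all non-bonded atoms; tips with no room are abandoned.  Returns None when
    growth stalls before reaching the requested size (caller retries).
    """
    n = spec.n_units
    pos = [np.zeros(3)]
    parent = [-1]
    tips = [0]
    arr = lambda: np.array(pos)
    while len(pos) < n and tips:
        pick = 0 if rng.uniform() > spec.branch_prob or len(tips) == 1 \
            else int(rng.integers(len(tips)))
        src = tips.pop(pick)
        back = pos[parent[src]] - pos[src] if parent[src] >= 0 \
            else np.array([-1.0, 0, 0])
        n_child = 1 + int(rng.uniform() < spec.branch_prob)
        placed_dirs: list[np.ndarray] = []
        for _ in range(n_child):
            if len(pos) >= n:
                break
            ok = None
            for _try in range(30):
                d = _place_substituents(rng, back, placed_dirs, 1)[0] \
                    if placed_dirs else \
                    _tetrahedral_directions(rng, back, 1)[0]
                cand = pos[src] + spec.bond_length * d
                dist = np.linalg.norm(arr() - cand, axis=1)
                dist[src] = np.inf
                if np.all(dist >= 1.8):
                    ok = (cand, d)
                    break
            if ok is None:
                continue
            pos.append(ok[0])
            parent.append(src)
            placed_dirs.append(ok[1])
            tips.append(len(pos) - 1)
    if len(pos) < n:
        return None
    return pos, parent


def _bonded_mask(n: int, bonded: set[tuple[int, int]]) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    return np.array([(int(a), int(b)) in bonded for a, b in zip(iu, ju)])


def _violations(positions: np.ndarray, is_bonded: np.ndarray,
                radii: np.ndarray, min_nonbonded: float = 1.2,
                probes: tuple[float, ...] = (1.4,)) -> int:
    """Count clash and near-tangency violations (see ``_clearance_ok``)."""
    n = len(positions)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    v = int(np.sum(d[is_bonded] < 0.5)) + int(np.sum(d[~is_bonded] < min_nonbonded))
    for probe in probes:
        ri = radii[iu] + probe
        rj = radii[ju] + probe
        v += int(np.sum(np.abs(d - (ri + rj)) < MIN_CLEARANCE))
        v += int(np.sum(np.abs(d - np.abs(ri - rj)) < MIN_CLEARANCE))
    return v


def _clearance_ok(positions: np.ndarray, is_bonded: np.ndarray,
                  radii: np.ndarray, min_nonbonded: float = 1.2,
                  probes: tuple[float, ...] = (1.4,)) -> bool:
    """Reject steric pile-ups and sphere tangencies.

    Contacts of the extended spheres (at the probe radius the surface-area
    term uses, 1.4 A) must be at least ``MIN_CLEARANCE`` away from exact
    tangency, since arc topology is perturbation-sensitive there.  Short
    geminal/vicinal separations sit nowhere near the extended-sphere contact
    radii, so the constraint is satisfiable for long chains.
    """
    n = len(positions)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    if np.any(d[is_bonded] < 0.5) or np.any(d[~is_bonded] < min_nonbonded):
        return False
    for probe in probes:
        ri = radii[iu] + probe
        rj = radii[ju] + probe
        if np.any(np.abs(d - (ri + rj)) < MIN_CLEARANCE):
            return False
        if np.any(np.abs(d - np.abs(ri - rj)) < MIN_CLEARANCE):
            return False
    return True


def make_chain(spec: FixtureSpec) -> Fixture:
    """Branched polymer fixture with every heavy-heavy bond rotatable."""
    if spec.n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(spec.seed)
    for attempt in range(200):
        fx = _try_make_chain(spec, rng)
        if fx is not None:
            return fx
    raise RuntimeError("could not generate a clash-free fixture")


def _try_make_chain(spec: FixtureSpec, rng: np.random.Generator) -> Fixture | None:
    grown = _grow_polymer(spec, rng)
    if grown is None:
        return None
    heavy_pos, heavy_parent = grown
    nH = spec.n_units

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    rotatable: list[tuple[int, int]] = []
    h_of: dict[int, list[int]] = {}
    heavy_ids: list[int] = []

    for h in range(nH):
        aid = len(atoms)
        heavy_ids.append(aid)
        atoms.append(Atom(aid, "C", f"C{h}", heavy_pos[h], HEAVY_RADIUS))
    for h in range(nH):
        if heavy_parent[h] >= 0:
            b = (heavy_ids[heavy_parent[h]], heavy_ids[h])
            bonds.append(b)
            rotatable.append(b)
    children: dict[int, list[int]] = {h: [] for h in range(nH)}
    for h in range(nH):
        if heavy_parent[h] >= 0:
            children[heavy_parent[h]].append(h)
    ang = np.deg2rad(109.47)
    for h in range(nH):
        back = heavy_pos[heavy_parent[h]] - heavy_pos[h] if heavy_parent[h] >= 0 \
            else np.array([-1.0, 0, 0])
        z = back / np.linalg.norm(back)
        ref = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0.0, 1, 0])
        ax = np.cross(z, ref)
        ax /= np.linalg.norm(ax)
        bx = np.cross(z, ax)
        taken = [np.asarray(heavy_pos[c]) - heavy_pos[h] for c in children[h]]
        taken = [e / np.linalg.norm(e) for e in taken]
        n_h = 1 + int(rng.uniform() < 0.6)
        h_of[heavy_ids[h]] = []
        occupied = np.array([a.position for a in atoms])
        for hk in range(n_h):
            best, best_score = None, -np.inf
            for _try in range(24):
                phi = rng.uniform(0, 2 * np.pi)
                d = np.cos(ang) * z + np.sin(ang) * (np.cos(phi) * ax
                                                     + np.sin(phi) * bx)
                crowded = taken and max(float(d @ t) for t in taken) > np.cos(0.7)
                cand = heavy_pos[h] + H_BOND_LENGTH * d
                dist = np.linalg.norm(occupied - cand, axis=1)
                dist[heavy_ids[h]] = np.inf
                score = float(dist.min()) - (10.0 if crowded else 0.0)
                if score > best_score:
                    best, best_score = (cand, d), score
                if score >= 1.5:
                    break
            cand, d = best
            aid = len(atoms)
            atoms.append(Atom(aid, "H", f"H{h}{'ab'[hk]}", cand, H_RADIUS))
            bonds.append((heavy_ids[h], aid))
            h_of[heavy_ids[h]].append(aid)
            taken.append(d)
            occupied = np.vstack([occupied, cand[None, :]])

    tree = build_tree(atoms, bonds, rotatable, root=heavy_ids[0],
                      spring_k=spec.spring_k)

    # randomize torsions one DOF at a time, rejecting clashing rotations so
    # arbitrarily long chains stay clash- and tangency-free
    bonded = {tuple(sorted(b)) for b in bonds}
    mask = _bonded_mask(tree.n_atoms, bonded)
    radii = np.array([a.radius for a in tree.atoms])

    # randomize torsions, then greedily re-roll DOFs until no clash or
    # near-tangency remains (long-range violations are always separated by
    # some DOF; rigid-unit internal distances sit far from the contact radii)
    order = tree._root_to_leaf_dof_order()
    for d in order:
        tree.set_torsion(d, float(rng.uniform(-180.0, 180.0)))
    v = _violations(tree.positions(), mask, radii)
    for _sweep in range(8):
        if v == 0:
            break
        for d in order:
            if v == 0:
                break
            best_angle = tree.dofs[d].angle
            for _ in range(12):
                angle = float(rng.uniform(-180.0, 180.0))
                tree.set_torsion(d, angle)
                v2 = _violations(tree.positions(), mask, radii)
                if v2 < v:
                    v, best_angle = v2, angle
                    if v == 0:
                        break
            tree.set_torsion(d, best_angle)
    if v != 0:
        return None
    for a in tree.atoms:
        a.position = a.position.copy()
    tree._base_positions = tree.positions()
    for d in tree.dofs:
        d.angle = 0.0

    local: dict[int, LocalMultipole] = {}
    frames: dict[int, LocalFrameDef] = {}
    for h, aid in enumerate(heavy_ids):
        local[aid] = _random_multipole(rng, spec)
        z_anchor = heavy_ids[heavy_parent[h]] if heavy_parent[h] >= 0 \
            else h_of[aid][-1] if len(h_of[aid]) > 1 else _first_child(tree, aid)
        frames[aid] = LocalFrameDef("z-then-x", z_anchor, h_of[aid][0])
        for hid in h_of[aid]:
            local[hid] = LocalMultipole(q=float(rng.uniform(-0.3, 0.3)))
    return Fixture(tree=tree, params=MultipoleParams(local=local, frames=frames),
                   spec=spec)


def _first_child(tree: KinematicTree, aid: int) -> int:
    for d in tree.dofs:
        if d.upstream_end_atom == aid:
            return d.downstream_end_atom
    for b in tree._adj[aid]:
        return b
    raise ValueError("isolated atom")


def make_ring_fixture(spec: FixtureSpec) -> Fixture:
    """Five-membered ring closed through a virtual atom, plus a short tail.

    Topology: T0-T1-N-C1-C2-C3-C4 with the ring bond N-C4 declared as a
    closure; a virtual copy of N rides on C4's unit.  Every backbone and ring
    bond is rotatable.  With ``include_split_frame``, N's x anchor is C4 (a
    ring-break-crossing anchor); otherwise N's frame uses its hydrogen.
    """
    if not spec.include_ring:
        raise ValueError("spec.include_ring must be set")
    rng = np.random.default_rng(spec.seed)

    # planar regular pentagon for the ring, tail off N
    r_ring = BOND_LENGTH / (2 * np.sin(np.pi / 5))
    ring_pos = [r_ring * np.array([np.cos(2 * np.pi * k / 5),
                                   np.sin(2 * np.pi * k / 5), 0.0])
                for k in range(5)]  # N, C1, C2, C3, C4
    t1 = ring_pos[0] + np.array([BOND_LENGTH, 0, 0.4])
    t0 = t1 + np.array([BOND_LENGTH, 0.3, -0.2])

    names = ["T0", "T1", "N", "C1", "C2", "C3", "C4"]
    coords = [t0, t1] + ring_pos
    elements = ["C", "C", "N", "C", "C", "C", "C"]
    atoms = [Atom(i, elements[i], names[i], coords[i], HEAVY_RADIUS)
             for i in range(7)]
    heavy = list(range(7))
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 2)]
    closures = [(2, 6)]   # virtual copy of N appended to C4's unit
    rotatable = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]

    h_of: dict[int, list[int]] = {}
    full_bonds = list(bonds)
    for a in heavy:
        incoming = atoms[a].position - atoms[max(a - 1, 0)].position
        if not incoming.any():
            incoming = np.array([0.5, 0.2, 1.0])
        d = _tetrahedral_directions(rng, -incoming, 2)[0]
        d = d if abs(d[2]) > 0.3 else np.array([0, 0, 1.0])
        aid = len(atoms)
        atoms.append(Atom(aid, "H", f"H{a}", atoms[a].position + H_BOND_LENGTH * d,
                          H_RADIUS))
        full_bonds.append((a, aid))
        h_of[a] = [aid]

    tree = build_tree(atoms, full_bonds, rotatable, root=0, closures=closures,
                      spring_k=spec.spring_k)

    local: dict[int, LocalMultipole] = {}
    frames: dict[int, LocalFrameDef] = {}
    parent_of = {1: 0, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5}
    for a in heavy:
        local[a] = _random_multipole(rng, spec)
        z_anchor = parent_of.get(a, 1)
        if a == 2 and spec.include_split_frame:
            frames[a] = LocalFrameDef("z-then-x", 1, 6)   # x anchor across break
        else:
            frames[a] = LocalFrameDef("z-then-x", z_anchor, h_of[a][0])
        local[h_of[a][0]] = LocalMultipole(q=float(rng.uniform(-0.3, 0.3)))
    return Fixture(tree=tree, params=MultipoleParams(local=local, frames=frames),
                   spec=spec)


def make_frame_rotation_fixture(seed: int = 0) -> Fixture:
    """Minimal geometry in which a torsion rotates an atom's local frame
    without changing its distance to an interaction partner.

    Chain A-B-C with rotatable bond B-C: atom C is the downstream hinge (on
    the axis, stationary), its hydrogen rotates, and C's frame (z along the
    bond to B, x toward its hydrogen) rotates exactly with the torsion.  The
    A..C distance is constant, so without the reference-atom correction the
    pair (A, C) contributes nothing to this DOF even though dE/dalpha != 0.
    """
    rng = np.random.default_rng(seed)
    pA = np.array([0.0, 0.0, 0.0])
    pB = pA + np.array([BOND_LENGTH, 0, 0])
    pC = pB + BOND_LENGTH * np.array([np.cos(np.deg2rad(70.5)),
                                      np.sin(np.deg2rad(70.5)), 0])
    hdir = np.array([0.3, -0.5, 0.9])
    atoms = [
        Atom(0, "C", "A", pA, HEAVY_RADIUS),
        Atom(1, "C", "B", pB, HEAVY_RADIUS),
        Atom(2, "N", "C", pC, HEAVY_RADIUS),
        Atom(3, "H", "HA", pA + H_BOND_LENGTH * np.array([-0.4, 0.7, 0.59]) /
             np.linalg.norm([-0.4, 0.7, 0.59]), H_RADIUS),
        Atom(4, "H", "HC", pC + H_BOND_LENGTH * hdir / np.linalg.norm(hdir),
             H_RADIUS),
    ]
    bonds = [(0, 1), (1, 2), (0, 3), (2, 4)]
    tree = build_tree(atoms, bonds, rotatable=[(1, 2)], root=0)
    local = {
        0: _random_multipole(rng, FixtureSpec()),
        2: _random_multipole(rng, FixtureSpec()),
    }
    frames = {
        0: LocalFrameDef("z-then-x", 1, 3),
        2: LocalFrameDef("z-then-x", 1, 4),
    }
    return Fixture(tree=tree, params=MultipoleParams(local=local, frames=frames),
                   spec=FixtureSpec(n_units=3, seed=seed))
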