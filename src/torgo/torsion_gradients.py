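"""Accumulation of per-pair gradient contributions into per-DOF torsion gradients.

Every energy term between two atoms i and j contributes to the gradient of each
rotatable bond that separates them, via the Gō form

    dE/dalpha = f . n_alpha + g . (n_alpha x r_alpha)

with (f, g) independent of which separating torsion is queried.  Entries are
stored side-symmetrically: with s = [j in moving set] - [i in moving set] and
m = [j in moving set] + [i in moving set], an entry (i, j, f, g, c) contributes

    s * (f.n + g.(n x r_alpha)) + m * c.n

For an energy term E(u) with u = r_j - r_i and Cartesian gradient W = dE/du,
f = (r_i + r_j) x W / 2, g = -W and c = u x W / 2 reproduce the chain rule for
every mobility combination, including both atoms co-rotating (the relative
vector still rotates: W.(n x u) = 2 c.n).  For multipole electrostatics c
vanishes identically once the orientational parts are added (rotation
invariance: u x G + O_i + O_j = 0), which is exactly the Gō-form property that
one (f, g) pair serves every separating torsion; for the
solvent-accessible-surface-area terms c is genuinely nonzero because one
atom's area depends on the directions to several neighbors at once.

The *moving set* of a DOF is its downstream unit subtree minus the downstream
hinge atom, which lies on the rotation axis: its position is invariant although
its local frame co-rotates.  That frame rotation is exactly what the
reference-atom correction routes through a mobile proxy atom.

Two accumulators are provided: a naive per-(DOF, entry) loop, and a recursive
single pass over the tree that aggregates per-atom totals and subtree sums
(linear storage).  They agree to floating-point roundoff; the naive form is the
oracle for the recursive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairEntryList",
    "TorsionGradient",
    "entries_from_pair_arrays",
    "reference_correction_entries",
    "accumulate_naive",
    "accumulate_recursive",
    "split_frame_atoms",
]


@dataclass
class PairEntryList:
    """Flat arrays of gradient entries (all vectors per-radian, energy units)."""

    ii: np.ndarray                 # (m,) int
    jj: np.ndarray                 # (m,) int
    f: np.ndarray                  # (m, 3)
    g: np.ndarray                  # (m, 3)
    c: np.ndarray                  # (m, 3)

    def __len__(self) -> int:
        return len(self.ii)

    @classmethod
    def empty(cls) -> "PairEntryList":
        z = np.zeros((0, 3))
        return cls(np.zeros(0, int), np.zeros(0, int), z, z.copy(), z.copy())

    @classmethod
    def concat(cls, parts: list["PairEntryList"]) -> "PairEntryList":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([p.ii for p in parts]),
            np.concatenate([p.jj for p in parts]),
            np.vstack([p.f for p in parts]),
            np.vstack([p.g for p in parts]),
            np.vstack([p.c for p in parts]),
        )


@dataclass
class TorsionGradient:
    """Per-DOF gradient with its accumulated vectors.

    ``dE_dalpha`` is per radian; ``per_degree()`` converts to the reporting
    units (energy per degree).
    """

    dE_dalpha: np.ndarray          # (n_dofs,) per radian
    F: np.ndarray                  # (n_dofs, 3)
    G: np.ndarray                  # (n_dofs, 3)

    def per_degree(self) -> np.ndarray:
        return self.dE_dalpha * (np.pi / 180.0)


def entries_from_pair_arrays(ii, jj, pos, G, O1, O2) -> PairEntryList:
    """Build side-symmetric entries from per-pair Cartesian data.

    ``G`` is dE/du with u = r[jj] - r[ii]; ``O1``/``O2`` are the orientational
    f-parts of atoms ``ii``/``jj`` (own-frame-rotating-positively convention).
    The antisymmetric part is f = [(r_i + r_j) x G + O2 - O1]/2, g = -G; the
    side-independent part c = [u x G + O1 + O2]/2 vanishes identically here but
    is kept so roundoff never biases one mover side.
    """
    ri = pos[ii]
    rj = pos[jj]
    f = 0.5 * (np.cross(ri + rj, G) + O2 - O1)
    g = -G
    c = 0.5 * (np.cross(rj - ri, G) + O1 + O2)
    return PairEntryList(np.asarray(ii), np.asarray(jj), f, g, c)


def reference_correction_entries(ii, jj, O1, O2, reference_atom: dict[int, int],
                                 folding_atoms: set[int],
                                 return_source: bool = False):
    """Entries that route orientational gradients through reference atoms.

    For each pair (i, j) and each folding-path member a of the pair with
    partner b: the orientational f-part O_a is subtracted from the (b, a) pair
    and added to the pair (b, ref(a)).  When a and ref(a) move together across
    a torsion the two edits cancel; when a is stationary but ref(a) moves, the
    frame-rotation gradient that the plain pair bookkeeping cannot see is
    reinstated.  The entries are purely antisymmetric f-vectors (g = c = 0):
    the subtract/add pair always travels together, and their sum yields O_a.n
    exactly when a's frame rotates relative to the pair and zero otherwise
    (including the hinge-atom case, where a is stationary on the axis, its
    frame co-rotates with the downstream side, and the partner also moves).
    """
    out_i: list[int] = []
    out_j: list[int] = []
    out_f: list[np.ndarray] = []
    out_src: list[int] = []

    def emit(b: int, a: int, f: np.ndarray, k: int) -> None:
        out_i.append(b)
        out_j.append(a)
        out_f.append(f)
        out_src.append(k)

    for k in range(len(ii)):
        i, j = int(ii[k]), int(jj[k])
        if i in folding_atoms:
            emit(j, i, -O1[k], k)
            emit(j, reference_atom[i], +O1[k], k)
        if j in folding_atoms:
            emit(i, j, -O2[k], k)
            emit(i, reference_atom[j], +O2[k], k)
    if not out_i:
        ent = PairEntryList.empty()
        return (ent, np.zeros(0, int)) if return_source else ent
    f = np.array(out_f)
    ent = PairEntryList(np.array(out_i), np.array(out_j), f,
                        np.zeros_like(f), np.zeros_like(f))
    return (ent, np.array(out_src)) if return_source else ent


def _axes(tree):
    origins = np.empty((tree.n_dofs, 3))
    axes = np.empty((tree.n_dofs, 3))
    for d in range(tree.n_dofs):
        origins[d], axes[d] = tree.dof_axis(d)
    return origins, axes


def accumulate_naive(tree, entries: PairEntryList) -> TorsionGradient:
    """Per-(DOF, entry) loop; the correctness oracle for the recursive pass."""
    nd = tree.n_dofs
    out = np.zeros(nd)
    F = np.zeros((nd, 3))
    G = np.zeros((nd, 3))
    if nd == 0 or len(entries) == 0:
        return TorsionGradient(out, F, G)
    origins, axes = _axes(tree)
    for d in range(nd):
        mov = np.zeros(tree.n_atoms, bool)
        mov[list(tree.moving_atoms(d))] = True
        si = mov[entries.ii]
        sj = mov[entries.jj]
        sign = sj.astype(float) - si.astype(float)
        cnt = sj.astype(float) + si.astype(float)
        Fd = (sign[:, None] * entries.f + cnt[:, None] * entries.c).sum(axis=0)
        Gd = (sign[:, None] * entries.g).sum(axis=0)
        F[d] = Fd
        G[d] = Gd
        out[d] = Fd @ axes[d] + Gd @ np.cross(axes[d], origins[d])
    return TorsionGradient(out, F, G)


def accumulate_recursive(tree, entries: PairEntryList) -> TorsionGradient:
    """Single leaf-to-root pass with linear storage.

    Antisymmetric parts: each entry adds (f, g) to its j atom and -(f, g) to
    its i atom; per-DOF totals are subtree sums over units minus the hinge
    atom's own total (contributions of pairs interior to the moving set cancel
    pairwise).  Side-independent parts count once per member in the moving
    set, so c attaches to both endpoint atoms and flows through the same
    per-atom subtree sums.
    """
    nd = tree.n_dofs
    if nd == 0:
        return TorsionGradient(np.zeros(0), np.zeros((0, 3)), np.zeros((0, 3)))
    na = tree.n_atoms
    nu = len(tree.rigid_units)

    tf = np.zeros((na, 3))
    tg = np.zeros((na, 3))
    tc = np.zeros((na, 3))
    if len(entries):
        np.add.at(tf, entries.jj, entries.f)
        np.add.at(tf, entries.ii, -entries.f)
        np.add.at(tg, entries.jj, entries.g)
        np.add.at(tg, entries.ii, -entries.g)
        np.add.at(tc, entries.jj, entries.c)
        np.add.at(tc, entries.ii, entries.c)

    # leaf-to-root order over units
    children = tree._unit_children
    order: list[int] = []
    stack = [tree.root_unit]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(children[u])

    unit_f = np.zeros((nu, 3))
    unit_g = np.zeros((nu, 3))
    unit_c = np.zeros((nu, 3))
    for u, members in enumerate(tree.rigid_units):
        unit_f[u] = tf[members].sum(axis=0)
        unit_g[u] = tg[members].sum(axis=0)
        unit_c[u] = tc[members].sum(axis=0)
    sub_f = unit_f.copy()
    sub_g = unit_g.copy()
    sub_c = unit_c.copy()
    for u in reversed(order):
        p = tree.unit_parent[u]
        if p >= 0:
            sub_f[p] += sub_f[u]
            sub_g[p] += sub_g[u]
            sub_c[p] += sub_c[u]

    out = np.zeros(nd)
    F = np.zeros((nd, 3))
    G = np.zeros((nd, 3))
    origins, axes = _axes(tree)
    for u in range(nu):
        d = tree.unit_dof[u]
        if d < 0:
            continue
        hinge = tree.dofs[d].downstream_end_atom
        F[d] = sub_f[u] - tf[hinge]
        G[d] = sub_g[u] - tg[hinge]
        Cd = sub_c[u] - tc[hinge]
        out[d] = (F[d] + Cd) @ axes[d] + G[d] @ np.cross(axes[d], origins[d])
    return TorsionGradient(out, F, G)


def split_frame_atoms(tree, params) -> set[int]:
    """Atoms whose frame anchors lie across a ring break.

    For such atoms a torsion can rotate the local frame of an atom on the same
    side of the bond, violating the distance-only assumption of the recursion;
    the harmonic ring-closure restraint bounds the residual error.  Returned
    for diagnostics; no special gradient handling is applied.
    """
    closure_real = {c.real_atom for c in tree.ring_closures}
    closure_virt = {c.virtual_atom: c.real_atom for c in tree.ring_closures}
    flagged: set[int] = set()
    for aid, fd in params.frames.items():
        lm = params.local.get(aid)
        if lm is None or lm.is_zero:
            continue
        for anchor in (fd.z_anchor, fd.x_anchor):
            # anchor reachable only through a closure bond -> frame is split
            if anchor in closure_virt or (aid in closure_real and
                                          anchor not in tree._adj.get(aid, [])):
                flagged.add(aid)
    return flagged
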