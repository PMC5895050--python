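"""Tree-based representation of molecular conformation over torsional degrees of freedom.

A molecule whose bond lengths and angles are held fixed is parameterized by the
dihedral angles of its rotatable bonds.  Atoms that necessarily move together are
grouped into rigid units; the units, linked by rotatable bonds, form a tree rooted
at a chosen atom.  Rotating a bond rigidly rotates the entire subtree below it.

Cycles in the bond graph are incompatible with a tree; declared ring-closure bonds
are cut and replaced by a *virtual atom*: a duplicate of the atom on one side of
the cut, carried rigidly by the unit on the other side and tied to its real
counterpart by a harmonic restraint.  Virtual atoms carry no multipoles and no
surface area; they exist only to penalize ring opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "TorsionDOF",
    "VirtualAtomConstraint",
    "KinematicTree",
    "TopologyError",
    "build_tree",
]


class TopologyError(ValueError):
    """Raised for disconnected graphs, undeclared cycles and bad references."""


@dataclass
class Atom:
    atom_id: int
    element: str
    name: str
    position: np.ndarray
    radius: float = 0.0
    is_virtual: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite position")
        if self.radius < 0:
            raise ValueError(f"atom {self.atom_id}: negative radius")


@dataclass
class TorsionDOF:
    """One rotatable bond.

    The axis runs from the upstream bond atom to the downstream bond atom;
    positive rotation is right-handed about that direction.  ``origin`` is the
    position of the upstream bond atom (a point on the axis).  Angles are stored
    in degrees; they are offsets from the conformation the tree was built with.
    """

    dof_id: int
    upstream_end_atom: int
    downstream_end_atom: int
    angle: float = 0.0  # degrees, relative to build conformation


@dataclass
class VirtualAtomConstraint:
    virtual_atom: int
    real_atom: int
    spring_k: float = 100.0  # kcal/mol/A^2

    def __post_init__(self):
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")


@dataclass
class KinematicTree:
    """Rigid units linked by torsion DOFs, plus bookkeeping for gradients.

    ``unit_of[a]`` maps an atom to its rigid-unit index; ``unit_parent[u]`` and
    ``unit_dof[u]`` give, for each non-root unit, the parent unit and the DOF on
    the bond into it.  ``_downstream[d]`` caches the atom ids of the full unit
    subtree below DOF ``d``; the *moving* set of a DOF additionally excludes the
    downstream hinge atom, which lies on the rotation axis.
    """

    atoms: list[Atom]
    rigid_units: list[list[int]]
    dofs: list[TorsionDOF]
    unit_of: dict[int, int]
    unit_parent: list[int]           # -1 for root
    unit_dof: list[int]              # DOF id on bond into unit; -1 for root
    root_unit: int
    bonds: list[tuple[int, int]]     # tree bonds (closures excluded)
    ring_closures: list[VirtualAtomConstraint] = field(default_factory=list)
    reference_atom: dict[int, int] = field(default_factory=dict)
    _downstream: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)
    _adj: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _base_positions: np.ndarray | None = field(default=None, repr=False)

    # -- geometry ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, float)
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    def real_atom_ids(self) -> list[int]:
        return [a.atom_id for a in self.atoms if not a.is_virtual]

    def dof_axis(self, dof_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Current (origin r_alpha, unit direction n_alpha) of a DOF."""
        d = self.dofs[dof_id]
        r_up = self.atoms[d.upstream_end_atom].position
        r_dn = self.atoms[d.downstream_end_atom].position
        axis = r_dn - r_up
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError(f"dof {dof_id}: coincident bond atoms")
        return r_up, axis / norm

    def downstream_atoms(self, dof_id: int) -> frozenset[int]:
        """All atoms in the unit subtree below the DOF (includes the hinge atom)."""
        return self._downstream[dof_id]

    def moving_atoms(self, dof_id: int) -> frozenset[int]:
        """Atoms whose positions actually change under the DOF.

        The downstream hinge atom sits on the rotation axis, so although it
        belongs to the downstream unit its position is invariant.  Gradient
        accumulation keys off this set.
        """
        d = self.dofs[dof_id]
        return self._downstream[dof_id] - {d.downstream_end_atom}

    def separates(self, dof_id: int, i: int, j: int) -> bool:
        """True iff exactly one of atoms i, j is downstream of the DOF."""
        dn = self._downstream[dof_id]
        return (i in dn) != (j in dn)

    def set_torsion(self, dof_id: int, angle_deg: float) -> None:
        """Rotate the downstream subtree so the DOF's angle becomes ``angle_deg``.

        Right-hand rule about the axis from the upstream to the downstream bond
        atom.  Upstream atoms are untouched; all intra-unit geometry is
        preserved exactly (a rigid rotation is applied).
        """
        d = self.dofs[dof_id]
        delta = angle_deg - d.angle
        if delta != 0.0:
            origin, axis = self.dof_axis(dof_id)
            rot = Rotation.from_rotvec(np.deg2rad(delta) * axis)
            ids = sorted(self._downstream[dof_id])
            pos = np.array([self.atoms[a].position for a in ids])
            pos = rot.apply(pos - origin) + origin
            for a, p in zip(ids, pos):
                self.atoms[a].position = p
        d.angle = float(angle_deg % 360.0 if abs(angle_deg) >= 360.0 else angle_deg)

    def perturb_torsion(self, dof_id: int, delta_deg: float) -> None:
        self.set_torsion(dof_id, self.dofs[dof_id].angle + delta_deg)

    def torsion_angles(self) -> np.ndarray:
        return np.array([d.angle for d in self.dofs])

    def set_all_torsions(self, angles_deg: np.ndarray) -> None:
        """Set every DOF angle, applying rotations from the root outward."""
        order = self._root_to_leaf_dof_order()
        for d in order:
            self.set_torsion(d, float(angles_deg[d]))

    def rebuild_from_base(self) -> None:
        """Full root-to-leaf rebuild from the stored build conformation.

        Provided to test equivalence with incremental updates: coordinates are
        reset to the build conformation and every DOF's current angle is
        reapplied in root-to-leaf order.
        """
        angles = self.torsion_angles()
        self.set_positions(self._base_positions)
        for d in self.dofs:
            d.angle = 0.0
        self.set_all_torsions(angles)

    def _root_to_leaf_dof_order(self) -> list[int]:
        order: list[int] = []
        stack = [self.root_unit]
        while stack:
            u = stack.pop()
            for v in self._unit_children[u]:
                order.append(self.unit_dof[v])
                stack.append(v)
        return order

    @property
    def _unit_children(self) -> list[list[int]]:
        if not hasattr(self, "_children_cache"):
            ch: list[list[int]] = [[] for _ in self.rigid_units]
            for u, p in enumerate(self.unit_parent):
                if p >= 0:
                    ch[p].append(u)
            self._children_cache = ch
        return self._children_cache

    # -- reference atoms --------------------------------------------------

    def folding_path_atoms(self) -> set[int]:
        """Atoms bounding a rotatable bond (these need reference atoms)."""
        out: set[int] = set()
        for d in self.dofs:
            out.add(d.upstream_end_atom)
            out.add(d.downstream_end_atom)
        return out

    def assign_reference_atoms(self) -> dict[int, int]:
        """Pick a reference atom for every folding-path atom.

        The reference atom is a mobility proxy for the atom's local coordinate
        frame: the frame of a stationary atom rotates iff its reference atom
        moves.  Preference order: an attached hydrogen; then a bonded heavy
        neighbor off the folding path; then the next downstream folding-path
        atom (flagged for re-assignment when the fold direction changes).  Ties
        break on lowest atom id.
        """
        path = self.folding_path_atoms()
        ref: dict[int, int] = {}
        self.needs_reassignment: set[int] = set()
        for a in sorted(path):
            nbrs = sorted(self._adj.get(a, []))
            if not nbrs:
                raise TopologyError(f"atom {a} has no bonded neighbor")
            hydro = [b for b in nbrs if self.atoms[b].element.upper() == "H"]
            if hydro:
                ref[a] = hydro[0]
                continue
            off_path = [
                b for b in nbrs
                if b not in path and not self.atoms[b].is_virtual
            ]
            if off_path:
                ref[a] = off_path[0]
                continue
            down = [b for b in nbrs if b in path and self._is_descendant(b, a)]
            if down:
                ref[a] = down[0]
            else:
                # terminal path atom: fall back to the upstream bond partner
                ref[a] = nbrs[0]
            self.needs_reassignment.add(a)
        self.reference_atom = ref
        return ref

    def _is_descendant(self, b: int, a: int) -> bool:
        """True if unit(b) lies in the subtree at or below unit(a)."""
        u = self.unit_of[b]
        target = self.unit_of[a]
        while u != -1:
            if u == target:
                return True
            u = self.unit_parent[u]
        return False

    def unit_subtree_sets(self) -> None:
        pass


def build_tree(
    atoms: list[Atom],
    bonds: list[tuple[int, int]],
    rotatable: list[tuple[int, int]],
    root: int,
    closures: list[tuple[int, int]] | None = None,
    spring_k: float = 100.0,
) -> KinematicTree:
    """Build a kinematic tree from a bond topology.

    ``closures`` lists ring-closure bonds as ordered pairs (a, b): the bond is
    cut and a virtual copy of ``a`` is appended to ``b``'s rigid unit, with a
    harmonic restraint tying the copy to the real atom.  The bond graph with
    closure bonds removed must be connected and acyclic; rigid units are the
    connected components after additionally removing rotatable bonds.
    """
    closures = closures or []
    ids = [a.atom_id for a in atoms]
    if ids != list(range(len(atoms))):
        raise TopologyError("atom ids must be 0..n-1 in order")

    norm = lambda b: tuple(sorted(b))
    closure_set = {norm(b) for b in closures}
    rot_set = {norm(b) for b in rotatable}
    tree_bonds = [tuple(b) for b in bonds if norm(b) not in closure_set]
    for b in rot_set:
        if b not in {norm(x) for x in tree_bonds}:
            raise TopologyError(f"rotatable bond {b} not in bond list")

    g = nx.Graph(tree_bonds)
    g.add_nodes_from(ids)
    if not nx.is_connected(g):
        raise TopologyError("bond graph (closures removed) is disconnected")
    if g.number_of_edges() != len(atoms) - 1:
        raise TopologyError("cycle present without a declared ring closure")

    # rigid units: components after removing rotatable bonds
    g_rigid = nx.Graph([b for b in tree_bonds if norm(b) not in rot_set])
    g_rigid.add_nodes_from(ids)
    comps = [sorted(c) for c in nx.connected_components(g_rigid)]
    comps.sort(key=lambda c: c[0])
    unit_of = {a: i for i, c in enumerate(comps) for a in c}

    # orient the unit tree away from the root unit
    root_unit = unit_of[root]
    unit_parent = [-1] * len(comps)
    unit_dof = [-1] * len(comps)
    dofs: list[TorsionDOF] = []
    unit_adj: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(len(comps))}
    for (x, y) in (tuple(b) for b in rotatable):
        ux, uy = unit_of[x], unit_of[y]
        if ux == uy:
            raise TopologyError(f"rotatable bond {(x, y)} is internal to a rigid unit")
        unit_adj[ux].append((uy, x, y))
        unit_adj[uy].append((ux, y, x))

    seen = {root_unit}
    stack = [root_unit]
    while stack:
        u = stack.pop()
        for (v, a_up, a_dn) in unit_adj[u]:
            if v in seen:
                continue
            seen.add(v)
            d = TorsionDOF(dof_id=len(dofs), upstream_end_atom=a_up,
                           downstream_end_atom=a_dn)
            dofs.append(d)
            unit_parent[v] = u
            unit_dof[v] = d.dof_id
            stack.append(v)
    if len(seen) != len(comps):
        raise TopologyError("unit graph is not a tree")

    atoms = [Atom(a.atom_id, a.element, a.name, a.position, a.radius, a.is_virtual)
             for a in atoms]

    # virtual atoms for ring closures
    constraints: list[VirtualAtomConstraint] = []
    adj: dict[int, list[int]] = {i: [] for i in ids}
    for (x, y) in tree_bonds:
        adj[x].append(y)
        adj[y].append(x)
    for (a, b) in closures:
        vid = len(atoms)
        real = atoms[a]
        atoms.append(Atom(vid, real.element, real.name + "v", real.position.copy(),
                          radius=0.0, is_virtual=True))
        comps[unit_of[b]].append(vid)
        unit_of[vid] = unit_of[b]
        adj[vid] = [b]
        adj[b].append(vid)
        constraints.append(VirtualAtomConstraint(vid, a, spring_k))

    tree = KinematicTree(
        atoms=atoms, rigid_units=comps, dofs=dofs, unit_of=unit_of,
        unit_parent=unit_parent, unit_dof=unit_dof, root_unit=root_unit,
        bonds=tree_bonds, ring_closures=constraints, _adj=adj,
    )
    # downstream atom sets per DOF (unit subtrees)
    children = tree._unit_children
    subtree_atoms: dict[int, set[int]] = {}

    def collect(u: int) -> set[int]:
        s = set(comps[u])
        for v in children[u]:
            s |= collect(v)
        subtree_atoms[u] = s
        return s

    collect(root_unit)
    for u, d in enumerate(unit_dof):
        if d >= 0:
            tree._downstream[d] = frozenset(subtree_atoms[u])
    tree._base_positions = tree.positions()
    tree.assign_reference_atoms()
    return tree
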