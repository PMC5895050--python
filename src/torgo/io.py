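"""Readers and writers: PDB coordinates, YAML topology / multipole parameter
sidecar files, radii tables and TSV reports.

PDB carries positions only; bonds, rotatable-bond declarations and multipole
parameters do not fit the format and travel in YAML sidecars.  Virtual atoms
are written as ATOM records with element ``X`` plus a REMARK naming their real
counterpart, and are recognized on reading.
"""

from __future__ import annotations

import warnings

import numpy as np
import yaml

from .frames import LocalFrameDef, LocalMultipole, MultipoleParams
from .kinematics import Atom, KinematicTree, build_tree

__all__ = ["read_pdb", "write_pdb", "read_topology", "write_topology",
           "read_params", "write_params", "read_radii_table", "load_system"]


class PDBFormatError(ValueError):
    pass


def read_pdb(path) -> list[dict]:
    """ATOM/HETATM records as dicts (serial, name, element, position ...).

    Only the first alternate location of each atom is kept (with a warning).
    """
    records = []
    seen_altloc: set[str] = set()
    warned = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                serial = int(line[6:11].strip())
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26].strip() or 0)
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                element = line[76:78].strip() or name[:1]
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"{path}:{ln}: unparseable record") from exc
            key = f"{chain}{resseq}{name}"
            if altloc not in (" ", "", "A") or (altloc != " " and key in seen_altloc):
                if altloc not in (" ", ""):
                    if not warned:
                        warnings.warn(f"{path}: taking first altloc only")
                        warned = True
                    if key in seen_altloc:
                        continue
            seen_altloc.add(key)
            records.append(dict(serial=serial, name=name, element=element,
                                resname=resname, chain=chain, resseq=resseq,
                                position=xyz, line=ln))
    return records


def write_pdb(atoms: list[Atom], path) -> None:
    with open(path, "w") as fh:
        for a in atoms:
            if a.is_virtual:
                fh.write(f"REMARK 999 VIRTUAL ATOM {a.atom_id} "
                         f"DUPLICATES {a.name[:-1]}\n")
        for a in atoms:
            el = "X" if a.is_virtual else a.element
            x, y, z = a.position
            fh.write(
                f"ATOM  {a.atom_id + 1:5d} {a.name[:4]:<4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n")
        fh.write("END\n")


def write_topology(tree: KinematicTree, path) -> None:
    doc = {
        "atoms": [
            {"id": a.atom_id, "name": a.name, "element": a.element,
             "radius": float(a.radius)}
            for a in tree.atoms if not a.is_virtual
        ],
        "bonds": [[int(x), int(y)] for x, y in tree.bonds],
        "rotatable": [[d.upstream_end_atom, d.downstream_end_atom]
                      for d in tree.dofs],
        "closures": [[c.real_atom, _closure_partner(tree, c)]
                     for c in tree.ring_closures],
        "root": int(next(a for a in tree.rigid_units[tree.root_unit]
                         if not tree.atoms[a].is_virtual)),
        "spring_k": tree.ring_closures[0].spring_k if tree.ring_closures else 100.0,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _closure_partner(tree: KinematicTree, c) -> int:
    # the real atom the virtual copy is bonded to
    return int(tree._adj[c.virtual_atom][0])


def read_topology(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("atoms", "bonds", "root"):
        if key not in doc:
            raise ValueError(f"topology file {path} lacks '{key}'")
    return doc


def write_params(params: MultipoleParams, path) -> None:
    doc: dict = {"units": {"charge": "e", "dipole": "e*A",
                           "quadrupole": "e*A^2 (traceless, no extra factor)"},
                 "atoms": {}}
    for aid, lm in sorted(params.local.items()):
        th = lm.theta
        rec = {"q": float(lm.q),
               "mu": [float(v) for v in lm.mu],
               "theta": [float(th[0, 0]), float(th[0, 1]), float(th[0, 2]),
                         float(th[1, 1]), float(th[1, 2]), float(th[2, 2])]}
        fd = params.frames.get(aid)
        if fd is not None:
            rec["frame"] = {"type": fd.frame_type, "z_anchor": fd.z_anchor,
                            "x_anchor": fd.x_anchor}
        doc["atoms"][int(aid)] = rec
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params(path, trace_tol: float = 1e-6) -> MultipoleParams:
    """Strict reader: symmetric input by construction; traceless within tolerance.

    ``theta`` lists the six components xx xy xz yy yz zz; zz may be given as
    null to be implied by tracelessness.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    local: dict[int, LocalMultipole] = {}
    frames: dict[int, LocalFrameDef] = {}
    for aid, rec in (doc.get("atoms") or {}).items():
        aid = int(aid)
        xx, xy, xz, yy, yz, zz = rec.get("theta", [0.0] * 6)
        if zz is None:
            zz = -(xx + yy)
        th = np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]], float)
        if abs(np.trace(th)) > trace_tol:
            raise ValueError(
                f"atom {aid}: quadrupole trace {np.trace(th):g} exceeds "
                f"tolerance {trace_tol:g}")
        local[aid] = LocalMultipole(q=float(rec.get("q", 0.0)),
                                    mu=np.array(rec.get("mu", [0, 0, 0]), float),
                                    theta=th)
        if "frame" in rec:
            f = rec["frame"]
            frames[aid] = LocalFrameDef(f["type"], int(f["z_anchor"]),
                                        int(f["x_anchor"]))
    return MultipoleParams(local=local, frames=frames)


def read_radii_table(path) -> dict[str, float]:
    """Two-column text: atom name or element -> radius in Angstrom."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, val = line.split()[:2]
            out[key] = float(val)
    return out


def load_system(structure_path, topology_path, params_path=None,
                radii: dict[str, float] | None = None):
    """Assemble a kinematic tree (and optionally parameters) from files."""
    top = read_topology(topology_path)
    records = read_pdb(structure_path)
    by_serial = {r["serial"]: r for r in records}
    by_name = {r["name"]: r for r in records}
    atoms = []
    for rec in top["atoms"]:
        name = rec["name"]
        # serial = atom_id + 1 by convention; fall back to name matching
        match = by_serial.get(int(rec["id"]) + 1)
        if match is None or match["name"] != name:
            match = by_name.get(name)
        if match is None:
            raise ValueError(
                f"topology atom {rec['id']} ({name}) not found in "
                f"{structure_path}")
        radius = rec.get("radius", 0.0)
        if radii:
            radius = radii.get(name, radii.get(rec.get("element", ""), radius))
        atoms.append(Atom(int(rec["id"]), rec.get("element", "C"), name,
                          match["position"], float(radius)))
    atoms.sort(key=lambda a: a.atom_id)
    tree = build_tree(
        atoms,
        [tuple(b) for b in top["bonds"]],
        [tuple(b) for b in top.get("rotatable", [])],
        root=int(top["root"]),
        closures=[tuple(b) for b in top.get("closures", [])],
        spring_k=float(top.get("spring_k", 100.0)),
    )
    params = read_params(params_path) if params_path else None
    return tree, params
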