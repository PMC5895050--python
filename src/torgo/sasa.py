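"""Exact solvent-accessible surface area from intersection arcs, with
torsion-space derivatives.

Each atom is an extended sphere of radius rho = r_atom + r_probe.  The exposed
part of a sphere's surface is bounded by cycles of circular arcs, each arc a
piece of the intersection circle with one neighbor.  The exposed area follows
from Gauss-Bonnet on the sphere:

    A = rho^2 [ 2 pi chi + sum_arcs phi_k cos(theta_k) - sum_vertices tau_v ]

where theta_k is the angular radius of the occluding cap, phi_k the arc's
subtended angle, tau_v the signed exterior angle at each vertex (boundary
traversed with the exposed region on the left), and chi the Euler
characteristic of the exposed region.  chi is 2*(components) - (cycles); the
number of components is not tracked explicitly, so the formula is evaluated
with chi = 2 - n_cycles and reduced mod 4 pi rho^2 into (0, 4 pi rho^2],
which is unambiguous whenever any occlusion exists.

Derivatives: moving neighbor j relative to atom i changes A_i in two ways.
Radial motion shrinks or grows the buried cap (law of cosines), each arc
counting its fraction phi/(2 pi) of the full circle; perpendicular motion
(rotation of the cap about atom i) sweeps area at the arc endpoints, and the
swept-area integral collapses to the endpoint chords.  With u = r_j - r_i,
d = |u|:

    dA_i/du = Phi_par * u + Phi_perp * V
    Phi_par  = sum_arcs phi_k rho_i (1 - (rho_i^2 - rho_j^2)/d^2) / (2 d)
    Phi_perp = rho_i / d^2
    V        = sum_arcs (v_end - v_start) x u

with arc endpoints in exposed-on-left traversal order.  These per-direction
gradients feed the same Gō-form accumulator as the electrostestatic terms; the
perpendicular part is not exactly side-symmetric, so its side-independent
residual rides in the entry's ``c`` channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .electrostatics import PairGradient
from .torsion_gradients import PairEntryList

__all__ = [
    "Arc",
    "AtomArcs",
    "AtomSASA",
    "compute_arcs",
    "sasa_from_arcs",
    "sasa_gradient_data",
    "sasa_entries",
    "sasa_pair_fg",
    "total_sasa",
]

TANGENCY_WARN = 1e-6
FOURPI = 4.0 * np.pi


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class Arc:
    """One exposed boundary arc on a sphere, caused by one neighbor.

    ``t0``/``t1`` bound the arc in the right-handed angle parameter about the
    cap axis; the exposed-on-left traversal runs from t1 down to t0, so
    ``start`` is the point at t1 and ``end`` the point at t0.  ``phi`` is the
    subtended angle t1 - t0 (2 pi for a full circle).
    """

    neighbor: int
    t0: float
    t1: float
    start: np.ndarray
    end: np.ndarray
    phi: float
    cos_theta: float
    center: np.ndarray      # circle center (absolute)
    axis: np.ndarray        # unit vector from atom to neighbor
    radius: float           # circle radius


@dataclass
class AtomArcs:
    atom: int
    rho: float
    buried: bool = False
    has_neighbors: bool = False
    arcs: list[Arc] = field(default_factory=list)
    n_cycles: int = 0
    turn_sum: float = 0.0


@dataclass
class AtomSASA:
    atom: int
    area: float
    exposed_fraction: float
    buried: bool


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has high dispatch overhead for single 3-vectors
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _unit_perp(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(e[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    a = _cross3(e, ref)
    a /= np.sqrt(a @ a)
    return a, _cross3(e, a)


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge intervals on the circle [0, 2pi) given as (lo, hi) with lo<=hi
    after unwrapping (intervals crossing 0 are passed split)."""
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1] + 1e-14:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(a, b) for a, b in out]


def compute_arcs(positions: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                 active: np.ndarray | None = None) -> list[AtomArcs]:
    """Boundary arcs of every atom's exposed region.

    ``active`` masks atoms that participate (virtual atoms are excluded by the
    callers).  Atoms with zero radius never occlude and are reported fully
    buried with zero extended radius.
    """
    positions = np.asarray(positions, float)
    n = len(positions)
    radii = np.asarray(radii, float)
    if np.any(radii < 0):
        raise ValueError("negative radius")
    if probe < 0:
        raise ValueError("negative probe radius")
    if active is None:
        active = radii > 0
    rho = np.where(active, radii + probe, 0.0)

    out: list[AtomArcs] = []
    idx = np.where(active)[0]
    pos_a = positions[idx]
    rho_a = rho[idx]
    # all-pairs distances among active atoms
    diff = pos_a[:, None, :] - pos_a[None, :, :]
    dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(dmat, np.inf)
    if np.any(dmat == 0.0):
        a, b = np.argwhere(dmat == 0.0)[0]
        raise DegenerateGeometryError(
            f"atoms {idx[a]} and {idx[b]} have coincident centers")
    pos_of = {int(a): k for k, a in enumerate(idx)}

    for i in range(n):
        aa = AtomArcs(atom=i, rho=rho[i])
        if not active[i]:
            aa.buried = True
            out.append(aa)
            continue
        ia = pos_of[i]
        drow = dmat[ia]
        ssum = rho[i] + rho_a
        near = drow < ssum
        if np.any((drow >= ssum) & (drow - ssum < TANGENCY_WARN)):
            warnings.warn(f"atom {i}: contact within {TANGENCY_WARN} of tangency")
        if np.any(near & (drow + rho[i] <= rho_a)):
            aa.buried = True            # sphere i entirely inside another
            aa.has_neighbors = True
            out.append(aa)
            continue
        near &= drow + rho_a > rho[i]   # drop spheres entirely inside i
        ks = np.where(near)[0]
        if len(ks) == 0:
            out.append(aa)
            continue
        aa.has_neighbors = True
        dns = drow[ks]
        ens = (pos_a[ks] - positions[i]) / dns[:, None]       # cap axes
        cths = (dns ** 2 + rho[i] ** 2 - rho_a[ks] ** 2) / (2.0 * dns * rho[i])
        njs = idx[ks]

        any_arc = False
        EdotE = ens @ ens.T
        for jloc in range(len(ks)):
            j = int(njs[jloc])
            ej = ens[jloc]
            cth_j = float(cths[jloc])
            sth_j = np.sqrt(max(0.0, 1.0 - cth_j * cth_j))
            cj = positions[i] + rho[i] * cth_j * ej
            rc = rho[i] * sth_j
            a_hat, b_hat = _unit_perp(ej)
            # coverage of circle j by every other cap k, vectorized:
            # point p(t) covered by cap k  <=>  (p - r_i).e_k > rho_i cos th_k
            A = rho[i] * cth_j * EdotE[jloc]
            B = rc * (ens @ a_hat)
            C = rc * (ens @ b_hat)
            D = rho[i] * cths
            R = np.hypot(B, C)
            lhs = D - A
            lhs[jloc] = np.inf          # never covered by itself
            if np.any(lhs <= -R):
                continue                # whole circle inside some cap
            sel = np.where(lhs < R)[0]
            covered: list[tuple[float, float]] = []
            if len(sel):
                w = np.arccos(lhs[sel] / R[sel])
                mid = np.arctan2(C[sel], B[sel])
                t0s = (mid - w) % (2 * np.pi)
                t1s = t0s + 2 * w
                for t0, t1 in zip(t0s, t1s):
                    if t1 <= 2 * np.pi:
                        covered.append((t0, t1))
                    else:
                        covered.append((t0, 2 * np.pi))
                        covered.append((0.0, t1 - 2 * np.pi))
            point = lambda t: cj + rc * (np.cos(t) * a_hat + np.sin(t) * b_hat)
            if not covered:
                p0 = point(0.0)
                aa.arcs.append(Arc(j, 0.0, 2 * np.pi, p0.copy(), p0.copy(),
                                   2 * np.pi, cth_j, cj, ej, rc))
                any_arc = True
                continue
            merged = _merge_intervals(covered)
            # complement of the union on [0, 2pi)
            exposed: list[tuple[float, float]] = []
            if len(merged) == 1 and merged[0][0] <= 1e-14 and merged[0][1] >= 2 * np.pi - 1e-14:
                continue
            prev_hi = merged[-1][1] - 2 * np.pi
            for (lo, hi) in merged:
                if lo - prev_hi > 1e-12:
                    exposed.append((prev_hi, lo))
                prev_hi = hi
            for (t0, t1) in exposed:
                aa.arcs.append(Arc(j, t0, t1, point(t1), point(t0),
                                   t1 - t0, cth_j, cj, ej, rc))
                any_arc = True
        if not any_arc:
            # caps exist but no exposed boundary: the union covers the sphere
            aa.buried = True
            aa.arcs = []
        out.append(aa)
    _stitch_cycles(out, positions)
    return out


def _stitch_cycles(arcsets: list[AtomArcs], positions: np.ndarray) -> None:
    """Chain arcs head-to-tail, count cycles, accumulate signed turn angles."""
    for aa in arcsets:
        if aa.buried or not aa.arcs:
            aa.n_cycles = 1 if (aa.arcs and not aa.buried) else 0
            continue
        full = [a for a in aa.arcs if a.phi >= 2 * np.pi - 1e-12]
        partial = [a for a in aa.arcs if a.phi < 2 * np.pi - 1e-12]
        n_cycles = len(full)
        turn = 0.0
        if partial:
            starts = np.array([a.start for a in partial])
            used = np.zeros(len(partial), bool)
            nxt = np.full(len(partial), -1)
            for m, a in enumerate(partial):
                d2 = np.einsum("ij,ij->i", starts - a.end, starts - a.end)
                nxt[m] = int(np.argmin(d2))
            center = positions[aa.atom]
            for m, a in enumerate(partial):
                b = partial[nxt[m]]
                p = a.end
                v_in = _cross3(p - a.center, a.axis)
                v_out = _cross3(b.start - b.center, b.axis)
                v_in = v_in / np.sqrt(v_in @ v_in)
                v_out = v_out / np.sqrt(v_out @ v_out)
                nrm = (p - center) / aa.rho
                turn += np.arctan2(nrm @ _cross3(v_in, v_out),
                                   float(v_in @ v_out))
            # cycles of the successor permutation
            for m in range(len(partial)):
                if used[m]:
                    continue
                n_cycles += 1
                k = m
                while not used[k]:
                    used[k] = True
                    k = int(nxt[k])
        aa.n_cycles = n_cycles
        aa.turn_sum = turn


def sasa_from_arcs(arcsets: list[AtomArcs]) -> tuple[list[AtomSASA], float]:
    """Exact per-atom exposed areas and the total, from boundary arcs."""
    out: list[AtomSASA] = []
    total = 0.0
    for aa in arcsets:
        full_area = FOURPI * aa.rho ** 2
        if aa.rho == 0.0 or aa.buried:
            out.append(AtomSASA(aa.atom, 0.0, 0.0, True))
            continue
        if not aa.arcs:
            out.append(AtomSASA(aa.atom, full_area, 1.0, False))
            total += full_area
            continue
        s = 2 * np.pi * (2 - aa.n_cycles) \
            + sum(a.phi * a.cos_theta for a in aa.arcs) - aa.turn_sum
        s = s % FOURPI
        if s <= 0.0:
            s += FOURPI
        area = aa.rho ** 2 * s
        out.append(AtomSASA(aa.atom, area, area / full_area, False))
        total += area
    return out, total


def total_sasa(positions, radii, probe=1.4, active=None) -> float:
    _, tot = sasa_from_arcs(compute_arcs(positions, radii, probe, active))
    return tot


def sasa_gradient_data(arcsets: list[AtomArcs], positions: np.ndarray):
    """Directed per-contact gradients W_ij = dA_i/d(r_j - r_i).

    Returns (pairs, W): ``pairs[k] = (i, j)`` and ``W[k]`` the Cartesian
    gradient of atom i's exposed area with respect to the relative position of
    neighbor j, summed over their shared exposed arcs.
    """
    pairs: list[tuple[int, int]] = []
    Ws: list[np.ndarray] = []
    for aa in arcsets:
        if aa.buried or not aa.arcs:
            continue
        i = aa.atom
        per_j: dict[int, list[Arc]] = {}
        for a in aa.arcs:
            per_j.setdefault(a.neighbor, []).append(a)
        for j, arcs in per_j.items():
            u = positions[j] - positions[i]
            d = np.linalg.norm(u)
            rho_i = aa.rho
            rho_j2 = rho_i ** 2 + d ** 2 - 2 * d * rho_i * arcs[0].cos_theta
            phi_sum = sum(a.phi for a in arcs)
            phi_par = phi_sum * rho_i * (1.0 - (rho_i ** 2 - rho_j2) / d ** 2) / (2 * d)
            V = np.zeros(3)
            for a in arcs:
                V += _cross3(a.end - a.start, u)
            W = phi_par * u + (rho_i / d ** 2) * V
            pairs.append((i, j))
            Ws.append(W)
    if not pairs:
        return np.zeros((0, 2), int), np.zeros((0, 3))
    return np.array(pairs, int), np.array(Ws)


def sasa_entries(arcsets: list[AtomArcs], positions: np.ndarray,
                 gamma: float = 1.0) -> PairEntryList:
    """Accumulator entries for the surface-tension energy E = gamma * SASA."""
    pairs, W = sasa_gradient_data(arcsets, positions)
    if len(pairs) == 0:
        return PairEntryList.empty()
    W = gamma * W
    ii = pairs[:, 0]
    jj = pairs[:, 1]
    ri = positions[ii]
    rj = positions[jj]
    f = 0.5 * np.cross(ri + rj, W)
    g = -W
    c = 0.5 * np.cross(rj - ri, W)
    return PairEntryList(ii.copy(), jj.copy(), f, g, c)


def sasa_pair_fg(arcsets: list[AtomArcs], positions: np.ndarray,
                 atom_1: int, atom_2: int) -> PairGradient:
    """Gō-form (f, g) for one atom pair's joint SASA terms.

    Convention matches ``electrostatics.pair_fg`` (valid with atom 1
    downstream).  The perpendicular part carries a small side-dependence; the
    returned vectors are exact for the atom-1-moving side.
    """
    W = np.zeros(3)
    pairs, Ws = sasa_gradient_data(arcsets, positions)
    for (i, j), w in zip(pairs, Ws):
        if i == atom_1 and j == atom_2:
            W += w
        elif i == atom_2 and j == atom_1:
            W -= w
    r1 = positions[atom_1]
    z = np.zeros(3)
    return PairGradient(atom_i=atom_1, atom_j=atom_2,
                        f=-np.cross(r1, W), g=W, o1=z, o2=z, moving_atom=atom_1)
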