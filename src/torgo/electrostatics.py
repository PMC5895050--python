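"""Permanent multipole electrostatics (through quadrupole-quadrupole) and the
per-pair gradient vectors of the torsional (Gō) framework.

Energies
--------
For two atoms with charges q, dipoles mu (e*A) and traceless symmetric
quadrupoles Theta (e*A^2), separated by u = r2 - r1, r = |u|, the interaction
is the sum of 14 terms of the multipole expansion:

    q-q:      q1 q2 / r
    q-mu:     -q1 (mu2.u)/r^3 + q2 (mu1.u)/r^3
    mu-mu:    (mu1.mu2)/r^3 - 3 (mu1.u)(mu2.u)/r^5
    q-Th:     q1 (u.Th2.u)/r^5 + q2 (u.Th1.u)/r^5
    mu-Th:    -2 (u.Th2.mu1)/r^5 + 2 (u.Th1.mu2)/r^5
              + 5 (mu1.u)(u.Th2.u)/r^7 - 5 (mu2.u)(u.Th1.u)/r^7
    Th-Th:    20 (u.Th1 Th2.u)/(3 r^7) + 35 (u.Th1.u)(u.Th2.u)/(3 r^9)
              + 2 sum_ij Th1^ij Th2^ij /(3 r^5)

All formulas are in reduced units; multiply by ``COULOMB`` for kcal/mol with
e/Angstrom parameters.

Gradients
---------
The contribution of a pair to the gradient of any torsion that separates it is
``dE/dalpha = f.n_alpha + g.(n_alpha x r_alpha)`` with (f, g) independent of
the torsion.  Writing G = dE/du (the Cartesian gradient with multipoles held
fixed) and O_a = the orientational part for atom a (mu x dE/dmu plus the
auxiliary-vector quadrupole terms, i.e. the response to a rigid rotation of
that atom's local frame), the mover-side forms are

    atom 2 downstream:  f = r2 x G + O2,             g = -G
    atom 1 downstream:  f = G x r1 + O1 = -(r2 x G + O2),   g = +G

the two being exact negatives by rotation invariance (u x G + O1 + O2 = 0).
``pair_fg`` returns the atom-1-downstream form, which reproduces the standard
tabulated vector-form derivatives; ``PairGradient.moving_atom`` records the
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COULOMB",
    "TERM_LABELS",
    "PairGradient",
    "pair_terms",
    "pair_energy",
    "pair_fg",
    "pair_fg_orientational",
    "isotropic_pair_fg",
    "quadrupole_trace_product",
    "quadrupole_trace_product_basis",
]

#: Electrostatic prefactor, kcal*A/mol/e^2 (set to 1 for reduced units).
COULOMB = 332.063714

TERM_LABELS = [
    "q-q",
    "q-mu2", "mu1-q",
    "mu1-mu2(dot)", "mu1-mu2(rr)",
    "q-Theta2", "Theta1-q",
    "mu1-Theta2(a)", "Theta1-mu2(a)",
    "mu1-Theta2(b)", "Theta1-mu2(b)",
    "Theta-Theta(cross)", "Theta-Theta(rr)", "Theta-Theta(trace)",
]


class SingularGeometryError(ValueError):
    """Coincident atom centers."""


@dataclass
class PairGradient:
    """(f, g) pair in Gō form plus its orientation-only parts.

    ``f`` and ``g`` contract to dE/dalpha for torsions with ``moving_atom``
    downstream; negate both for torsions with the partner downstream.
    ``o1``/``o2`` are each atom's orientation-only f-parts (their paired
    g-part is identically zero); ``f_orient`` is ``o1`` for the returned
    convention (moving atom 1).
    """

    atom_i: int
    atom_j: int
    f: np.ndarray
    g: np.ndarray
    o1: np.ndarray
    o2: np.ndarray
    moving_atom: int = 0

    @property
    def f_orient(self) -> np.ndarray:
        return self.o1


def _colcross(M: np.ndarray) -> np.ndarray:
    """sum_e (M e) x e over the global basis e in {x,y,z} (vectorized over
    leading axes)."""
    return np.stack([
        M[..., 1, 2] - M[..., 2, 1],
        M[..., 2, 0] - M[..., 0, 2],
        M[..., 0, 1] - M[..., 1, 0],
    ], axis=-1)


def quadrupole_trace_product(th1: np.ndarray, th2: np.ndarray) -> float:
    """Element-wise sum T = sum_ij Th1^ij Th2^ij."""
    return float(np.sum(th1 * th2))


def quadrupole_trace_product_basis(th1: np.ndarray, th2: np.ndarray) -> float:
    """The same sum written as sum_e e.Th1.Th2.e over the global basis."""
    e = np.eye(3)
    return float(sum(e[k] @ th1 @ th2 @ e[k] for k in range(3)))


def pair_terms(q1, mu1, th1, q2, mu2, th2, u):
    """Vectorized energies/gradients for m pairs.

    Parameters are arrays broadcast over a leading pair axis: q (m,),
    mu (m, 3), th (m, 3, 3), u = r2 - r1 (m, 3).  Returns
    ``(E, G, O1, O2)``: per-term energies (m, 14), the Cartesian gradient
    dE/du (m, 3) and the orientational f-parts for each atom (m, 3), all in
    reduced units.
    """
    u = np.atleast_2d(np.asarray(u, float))
    m = u.shape[0]
    q1 = np.broadcast_to(np.asarray(q1, float), (m,))
    q2 = np.broadcast_to(np.asarray(q2, float), (m,))
    mu1 = np.broadcast_to(np.asarray(mu1, float), (m, 3))
    mu2 = np.broadcast_to(np.asarray(mu2, float), (m, 3))
    th1 = np.broadcast_to(np.asarray(th1, float), (m, 3, 3))
    th2 = np.broadcast_to(np.asarray(th2, float), (m, 3, 3))

    r2_ = np.einsum("mi,mi->m", u, u)
    if np.any(r2_ == 0.0):
        raise SingularGeometryError("coincident atoms in multipole pair")
    r = np.sqrt(r2_)
    r3 = r * r2_
    r5 = r3 * r2_
    r7 = r5 * r2_
    r9 = r7 * r2_
    r11 = r9 * r2_

    dot = lambda a, b: np.einsum("mi,mi->m", a, b)
    mv = lambda M, v: np.einsum("mij,mj->mi", M, v)
    col = lambda s: s[:, None]

    m1u = dot(mu1, u)
    m2u = dot(mu2, u)
    m1m2 = dot(mu1, mu2)
    I1 = mv(th1, u)            # Theta1 . u
    I2 = mv(th2, u)
    S1 = dot(u, I1)            # u . Theta1 . u
    S2 = dot(u, I2)
    J1 = mv(th1, mu2)          # Theta1 . mu2
    J2 = mv(th2, mu1)          # Theta2 . mu1
    K1 = mv(th1, I2)           # Theta1 Theta2 . u
    K2 = mv(th2, I1)           # Theta2 Theta1 . u
    P = dot(I1, I2)            # u . Theta1 Theta2 . u
    Tsc = np.einsum("mij,mij->m", th1, th2)

    E = np.empty((m, 14))
    G = np.zeros((m, 3))
    O1 = np.zeros((m, 3))
    O2 = np.zeros((m, 3))
    X = np.cross

    # 1: q-q
    E[:, 0] = q1 * q2 / r
    G += col(-q1 * q2 / r3) * u
    # 2: -q1 (mu2.u)/r^3
    E[:, 1] = -q1 * m2u / r3
    G += col(-q1 / r3) * mu2 + col(3 * q1 * m2u / r5) * u
    O2 += X(mu2, col(-q1 / r3) * u)
    # 3: +q2 (mu1.u)/r^3
    E[:, 2] = q2 * m1u / r3
    G += col(q2 / r3) * mu1 + col(-3 * q2 * m1u / r5) * u
    O1 += X(mu1, col(q2 / r3) * u)
    # 4: (mu1.mu2)/r^3
    E[:, 3] = m1m2 / r3
    G += col(-3 * m1m2 / r5) * u
    O1 += X(mu1, mu2 / col(r3))
    O2 += X(mu2, mu1 / col(r3))
    # 5: -3 (mu1.u)(mu2.u)/r^5
    E[:, 4] = -3 * m1u * m2u / r5
    G += col(-3 / r5) * (col(m1u) * mu2 + col(m2u) * mu1) \
        + col(15 * m1u * m2u / r7) * u
    O1 += X(mu1, col(-3 * m2u / r5) * u)
    O2 += X(mu2, col(-3 * m1u / r5) * u)
    # 6: q1 (u.Th2.u)/r^5
    E[:, 5] = q1 * S2 / r5
    G += col(2 * q1 / r5) * I2 + col(-5 * q1 * S2 / r7) * u
    O2 += col(2 * q1 / r5) * X(I2, u)
    # 7: q2 (u.Th1.u)/r^5
    E[:, 6] = q2 * S1 / r5
    G += col(2 * q2 / r5) * I1 + col(-5 * q2 * S1 / r7) * u
    O1 += col(2 * q2 / r5) * X(I1, u)
    # 8: -2 (u.Th2.mu1)/r^5
    I2m1 = dot(I2, mu1)
    E[:, 7] = -2 * I2m1 / r5
    G += col(-2 / r5) * J2 + col(10 * I2m1 / r7) * u
    O1 += X(mu1, col(-2 / r5) * I2)
    O2 += col(-2 / r5) * (X(J2, u) + X(I2, mu1))
    # 9: +2 (u.Th1.mu2)/r^5
    I1m2 = dot(I1, mu2)
    E[:, 8] = 2 * I1m2 / r5
    G += col(2 / r5) * J1 + col(-10 * I1m2 / r7) * u
    O2 += X(mu2, col(2 / r5) * I1)
    O1 += col(2 / r5) * (X(J1, u) + X(I1, mu2))
    # 10: +5 (mu1.u)(u.Th2.u)/r^7
    E[:, 9] = 5 * m1u * S2 / r7
    G += col(5 / r7) * (col(S2) * mu1 + 2 * col(m1u) * I2) \
        + col(-35 * m1u * S2 / r9) * u
    O1 += X(mu1, col(5 * S2 / r7) * u)
    O2 += col(10 * m1u / r7) * X(I2, u)
    # 11: -5 (mu2.u)(u.Th1.u)/r^7
    E[:, 10] = -5 * m2u * S1 / r7
    G += col(-5 / r7) * (col(S1) * mu2 + 2 * col(m2u) * I1) \
        + col(35 * m2u * S1 / r9) * u
    O2 += X(mu2, col(-5 * S1 / r7) * u)
    O1 += col(-10 * m2u / r7) * X(I1, u)
    # 12: -20 (u.Th1 Th2.u)/(3 r^7)
    E[:, 11] = -20 * P / (3 * r7)
    G += col(-20 / (3 * r7)) * (K1 + K2) + col(140 * P / (3 * r9)) * u
    O1 += col(-20 / (3 * r7)) * (X(K1, u) + X(I1, I2))
    O2 += col(-20 / (3 * r7)) * (X(K2, u) + X(I2, I1))
    # 13: 35 (u.Th1.u)(u.Th2.u)/(3 r^9)
    E[:, 12] = 35 * S1 * S2 / (3 * r9)
    G += col(70 / (3 * r9)) * (col(S2) * I1 + col(S1) * I2) \
        + col(-105 * S1 * S2 / r11) * u
    O1 += col(70 * S2 / (3 * r9)) * X(I1, u)
    O2 += col(70 * S1 / (3 * r9)) * X(I2, u)
    # 14: 2 T/(3 r^5), T = sum_ij Th1^ij Th2^ij
    E[:, 13] = 2 * Tsc / (3 * r5)
    G += col(-10 * Tsc / (3 * r7)) * u
    M12 = np.einsum("mij,mjk->mik", th1, th2)
    crosscols = np.cross(np.swapaxes(th1, 1, 2), np.swapaxes(th2, 1, 2)).sum(axis=1)
    O1 += col(2 / (3 * r5)) * (_colcross(M12) + crosscols)
    O2 += col(2 / (3 * r5)) * (_colcross(np.swapaxes(M12, 1, 2)) - crosscols)

    return E, G, O1, O2


def pair_energy(m1, m2, r1, r2, prefactor: float = 1.0):
    """Total interaction energy of one pair, with per-term breakdown.

    ``m1``/``m2`` are (q, mu, theta) triples; positions in Angstrom; the
    convention for the displacement is u = r2 - r1.  Returns
    ``(energy, breakdown)`` with the breakdown keyed by ``TERM_LABELS``.
    """
    u = np.asarray(r2, float) - np.asarray(r1, float)
    E, _, _, _ = pair_terms(m1[0], m1[1], m1[2], m2[0], m2[1], m2[2], u[None, :])
    terms = prefactor * E[0]
    return float(terms.sum()), dict(zip(TERM_LABELS, terms))


def pair_fg(m1, m2, r1, r2, atom_i: int = 0, atom_j: int = 1,
            prefactor: float = 1.0) -> PairGradient:
    """Gō-form gradient vectors for one pair (atom-1-downstream convention)."""
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    u = r2 - r1
    _, G, O1, O2 = pair_terms(m1[0], m1[1], m1[2], m2[0], m2[1], m2[2], u[None, :])
    G, O1, O2 = prefactor * G[0], prefactor * O1[0], prefactor * O2[0]
    # atom-1-downstream: f = G x r1 + O1, g = G  (G = dE/du, u = r2 - r1)
    f = np.cross(G, r1) + O1
    g = G
    return PairGradient(atom_i=atom_i, atom_j=atom_j, f=f, g=g,
                        o1=O1, o2=O2, moving_atom=atom_i)


def pair_fg_orientational(m1, m2, r1, r2, which_atom: int,
                          prefactor: float = 1.0) -> np.ndarray:
    """Orientation-only f-part for the designated atom (0 or 1).

    These are the terms arising from d(mu)/dalpha = n x mu and the analogous
    quadrupole rotation, evaluated as if only the designated atom's local frame
    rotated (all positions frozen).  They contract with n_alpha only; the
    paired g-part is exactly zero.
    """
    u = np.asarray(r2, float) - np.asarray(r1, float)
    _, _, O1, O2 = pair_terms(m1[0], m1[1], m1[2], m2[0], m2[1], m2[2], u[None, :])
    return prefactor * (O1[0] if which_atom == 0 else O2[0])


def isotropic_pair_fg(dEdr: float, r1, r2, atom_i: int = 0,
                      atom_j: int = 1) -> PairGradient:
    """(f, g) for a potential that depends only on the pair distance.

    f = (dEdr/r12)(r2 x r1), g = (dEdr/r12) r12_vec, in the same
    atom-1-downstream convention as ``pair_fg``.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    u = r2 - r1
    r = np.linalg.norm(u)
    if r == 0:
        f = np.zeros(3)
        g = np.zeros(3)
    else:
        f = (dEdr / r) * np.cross(r2, r1)
        g = (dEdr / r) * u
    z = np.zeros(3)
    return PairGradient(atom_i=atom_i, atom_j=atom_j, f=f, g=g, o1=z, o2=z,
                        moving_atom=atom_i)
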