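"""Per-atom local coordinate frames and rotation of multipole parameters.

Multipole parameters (charge q, dipole mu, traceless symmetric quadrupole Theta)
are defined in a local frame anchored on bonded neighbors, in the style of
anchor-based multipole force fields:

* ``z-then-x``: the z axis points from the owner to the z anchor; the x axis is
  the Gram-Schmidt residual of the owner->x-anchor direction against z.
* ``bisector``: the z axis is the normalized sum of the two owner->anchor
  directions; the x axis is the residual of the first anchor direction.

Rotating into the global frame: mu_g = R mu_l, Theta_g = R Theta_l R^T, which
preserves symmetry, trace and eigenvalues.  Because parameters co-rotate with
the anchors, global-frame energies are invariant under rigid motion of the
whole system.

Units are e, Angstrom and kcal/mol throughout; quadrupoles are e*A^2 with no
additional normalization factor (the tensor enters the energy exactly as
parameterized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameError",
    "LocalFrameDef",
    "LocalMultipole",
    "GlobalMultipoles",
    "MultipoleParams",
    "build_rotation",
    "rotate_multipoles",
    "refresh_global_multipoles",
]

COLLINEARITY_TOL = 1e-8


class FrameError(ValueError):
    """Degenerate frame anchors (zero or collinear directions)."""


@dataclass
class LocalFrameDef:
    frame_type: str  # "z-then-x" | "bisector"
    z_anchor: int
    x_anchor: int    # second z anchor for "bisector"

    def __post_init__(self):
        if self.frame_type not in ("z-then-x", "bisector"):
            raise ValueError(f"unknown frame type {self.frame_type!r}")


@dataclass
class LocalMultipole:
    q: float = 0.0
    mu: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.theta = np.asarray(self.theta, float)
        if not np.allclose(self.theta, self.theta.T, atol=1e-12):
            raise ValueError("quadrupole must be symmetric")
        if abs(np.trace(self.theta)) > 1e-8:
            raise ValueError(f"quadrupole trace {np.trace(self.theta):g} exceeds tolerance")

    @property
    def is_zero(self) -> bool:
        return self.q == 0.0 and not self.mu.any() and not self.theta.any()


@dataclass
class MultipoleParams:
    """Per-atom local multipoles and frame definitions (missing atoms: all zero)."""

    local: dict[int, LocalMultipole]
    frames: dict[int, LocalFrameDef]


@dataclass
class GlobalMultipoles:
    """Global-frame multipoles as dense arrays over all atoms."""

    q: np.ndarray        # (n,)
    mu: np.ndarray       # (n, 3)
    theta: np.ndarray    # (n, 3, 3)


def build_rotation(owner_pos: np.ndarray, frame_def: LocalFrameDef,
                   anchor_positions: dict[int, np.ndarray],
                   owner_id: int | None = None) -> np.ndarray:
    """Rotation matrix whose columns are the local x, y, z axes in global coords."""
    za = anchor_positions[frame_def.z_anchor] - owner_pos
    xa = anchor_positions[frame_def.x_anchor] - owner_pos
    nz = np.linalg.norm(za)
    nx = np.linalg.norm(xa)
    who = f"atom {owner_id}" if owner_id is not None else "atom"
    if nz == 0 or nx == 0:
        raise FrameError(f"{who}: coincident frame anchor")
    if frame_def.frame_type == "bisector":
        z = za / nz + xa / nx
        zn = np.linalg.norm(z)
        if zn < COLLINEARITY_TOL:
            raise FrameError(f"{who}: bisector anchors are anti-parallel")
        z = z / zn
        xref = za / nz
    else:
        z = za / nz
        xref = xa / nx
    if np.linalg.norm(np.cross(z, xref)) < COLLINEARITY_TOL:
        raise FrameError(f"{who}: frame anchors are collinear")
    x = xref - np.dot(xref, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def rotate_multipoles(local: LocalMultipole, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mu_global, theta_global) = (R mu, R Theta R^T)."""
    return R @ local.mu, R @ local.theta @ R.T


def refresh_global_multipoles(tree, params: MultipoleParams) -> GlobalMultipoles:
    """Recompute global multipoles from current coordinates.

    Must be called after any coordinate change.  Atoms absent from ``params``
    or with all-zero parameters are skipped (their frame is never evaluated, so
    degenerate anchors on uncharged atoms are harmless).  Virtual atoms always
    carry zero multipoles.
    """
    n = tree.n_atoms
    q = np.zeros(n)
    mu = np.zeros((n, 3))
    theta = np.zeros((n, 3, 3))
    pos = {a.atom_id: a.position for a in tree.atoms}
    for aid, local in params.local.items():
        if tree.atoms[aid].is_virtual or local.is_zero:
            continue
        q[aid] = local.q
        if local.mu.any() or local.theta.any():
            fd = params.frames.get(aid)
            if fd is None:
                raise FrameError(f"atom {aid}: oriented multipoles but no frame definition")
            R = build_rotation(pos[aid], fd, pos, owner_id=aid)
            mu[aid], theta[aid] = rotate_multipoles(local, R)
    return GlobalMultipoles(q=q, mu=mu, theta=theta)
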