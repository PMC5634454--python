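"""Atomic local frames (ALF) and internal-coordinate features.

Every atom carries its own right-handed local axis system: the x-axis points
from the origin atom A1 to its heaviest bonded neighbour A2, and the xy-plane
sweeps from the x-axis toward the second-heaviest atom A3 bonded to the
origin. The feature vector of an origin atom has length 3N−6 and starts with

    d(A1A2) [Å],  d(A1A3) [Å],  angle A2-A1-A3 [rad],

followed (N > 3 only) by the spherical-polar coordinates (r, θ, φ) of each
remaining atom expressed in the ALF. Distances are in Å and angles in
radians throughout; features are invariant under rigid motions, which is
what makes them usable as Gaussian-process inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ATOMIC_MASSES, MolecularGeometry

__all__ = [
    "ALFDefinition",
    "build_alf",
    "build_all_alfs",
    "compute_features",
    "compute_feature_jacobian",
    "compute_features_batch",
    "compute_feature_jacobian_batch",
    "n_features",
]

_COLLINEAR_TOL = 1e-8  # |sin(angle)| below this → ALF plane undefined


@dataclass(frozen=True)
class ALFDefinition:
    """Origin atom plus its x-axis atom (A2) and xy-plane atom (A3).

    All indices are 0-based positions into the geometry. The three indices
    are distinct; A2/A3 follow the heaviest / second-heaviest precedence with
    mass ties broken by the lower original atom index.
    """

    origin_index: int
    x_axis_index: int
    xy_plane_index: int

    def __post_init__(self) -> None:
        if len({self.origin_index, self.x_axis_index, self.xy_plane_index}) != 3:
            raise ValueError("ALF indices must be distinct")


def n_features(n_atoms: int) -> int:
    """Feature dimensionality 3N−6 for N ≥ 3."""
    if n_atoms < 3:
        raise ValueError("feature construction needs at least 3 atoms")
    return 3 * n_atoms - 6


def _pick(candidates: list[int], elements) -> int:
    """Heaviest candidate; mass ties broken by the lower atom index."""
    return min(candidates, key=lambda i: (-ATOMIC_MASSES[elements[i]], i))


def build_alf(
    geometry: MolecularGeometry,
    origin_index: int,
    connectivity: list[tuple[int, int]],
) -> ALFDefinition:
    """Choose A2 and A3 for the given origin atom.

    A2 is the heaviest atom bonded to the origin. A3 is the second-heaviest
    bonded atom, or — when the origin has exactly one bonded neighbour, as
    for H in water — the heaviest remaining atom excluding A2. Mass ties are
    broken by the lower atom index.
    """
    if geometry.n_atoms < 3:
        raise ValueError("ALF construction needs at least 3 atoms")
    neighbours = sorted(
        {j for i, j in connectivity if i == origin_index}
        | {i for i, j in connectivity if j == origin_index}
    )
    if not neighbours:
        raise ValueError(
            f"atom {geometry.identifiers[origin_index]} has no bonded neighbour; "
            "cannot anchor an ALF"
        )
    a2 = _pick(neighbours, geometry.elements)
    rest = [i for i in neighbours if i != a2]
    if not rest:  # one-bond origin: fall back to the heaviest non-ALF atom
        rest = [
            i for i in range(geometry.n_atoms) if i not in (origin_index, a2)
        ]
    a3 = _pick(rest, geometry.elements)
    return ALFDefinition(origin_index, a2, a3)


def build_all_alfs(
    geometry: MolecularGeometry, connectivity: list[tuple[int, int]]
) -> list[ALFDefinition]:
    """One ALF per atom, in atom order."""
    return [build_alf(geometry, i, connectivity) for i in range(geometry.n_atoms)]


def _alf_axes(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed (x̂, ŷ, ẑ) from the A1→A2 and A1→A3 vectors."""
    xhat = u / np.linalg.norm(u)
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nw < _COLLINEAR_TOL * np.linalg.norm(u) * np.linalg.norm(v):
        raise ValueError("A2-A1-A3 collinear: ALF plane undefined")
    zhat = w / nw
    yhat = np.cross(zhat, xhat)
    return xhat, yhat, zhat


def compute_features(
    geometry: MolecularGeometry, alf: ALFDefinition
) -> np.ndarray:
    """Feature vector of length 3N−6 for one origin atom (see module docs)."""
    coords = geometry.coordinates
    o, a2, a3 = alf.origin_index, alf.x_axis_index, alf.xy_plane_index
    u = coords[a2] - coords[o]
    v = coords[a3] - coords[o]
    ru, rv = np.linalg.norm(u), np.linalg.norm(v)
    if ru <= 0 or rv <= 0:
        raise ValueError("coincident ALF atoms")
    cosang = np.clip(np.dot(u, v) / (ru * rv), -1.0, 1.0)
    if 1.0 - cosang * cosang < _COLLINEAR_TOL**2:
        raise ValueError("A2-A1-A3 collinear: ALF plane undefined")
    feats = [ru, rv, float(np.arccos(cosang))]
    if geometry.n_atoms > 3:
        xhat, yhat, zhat = _alf_axes(u, v)
        for j in range(geometry.n_atoms):
            if j in (o, a2, a3):
                continue
            w = coords[j] - coords[o]
            wl = np.array([np.dot(w, xhat), np.dot(w, yhat), np.dot(w, zhat)])
            r = np.linalg.norm(wl)
            theta = float(np.arccos(np.clip(wl[2] / r, -1.0, 1.0)))
            phi = float(np.arctan2(wl[1], wl[0]))
            feats.extend([r, theta, phi])
    return np.array(feats)


def _angle_jacobian_rows(coords, o, a2, a3):
    """∂angle/∂(p_o, p_a2, p_a3) for the A2-A1-A3 angle, each a 3-vector."""
    u = coords[a2] - coords[o]
    v = coords[a3] - coords[o]
    ru, rv = np.linalg.norm(u), np.linalg.norm(v)
    uhat, vhat = u / ru, v / rv
    cosang = np.clip(np.dot(uhat, vhat), -1.0, 1.0)
    sinang = np.sqrt(max(1.0 - cosang * cosang, 0.0))
    if sinang < _COLLINEAR_TOL:
        raise ValueError("angle at a pole: Jacobian undefined")
    d_a2 = (cosang * uhat - vhat) / (ru * sinang)
    d_a3 = (cosang * vhat - uhat) / (rv * sinang)
    d_o = -(d_a2 + d_a3)
    return d_o, d_a2, d_a3


def compute_feature_jacobian(
    geometry: MolecularGeometry, alf: ALFDefinition
) -> np.ndarray:
    """Analytic d × 3N Jacobian ∂x_h/∂α_i of the feature vector.

    The three ALF features (two distances and the A2-A1-A3 angle) are
    differentiated in closed form. For N > 3 the spherical-polar columns are
    filled by central finite differences (step 1e-7 Å) — the water pipeline
    never exercises them. Rows of features that do not involve atom k carry
    exact zeros in atom k's columns, and the matrix annihilates rigid-body
    displacements.
    """
    coords = geometry.coordinates
    n = geometry.n_atoms
    d = n_features(n)
    o, a2, a3 = alf.origin_index, alf.x_axis_index, alf.xy_plane_index
    jac = np.zeros((d, 3 * n))

    u = coords[a2] - coords[o]
    v = coords[a3] - coords[o]
    uhat = u / np.linalg.norm(u)
    vhat = v / np.linalg.norm(v)
    jac[0, 3 * a2 : 3 * a2 + 3] = uhat
    jac[0, 3 * o : 3 * o + 3] = -uhat
    jac[1, 3 * a3 : 3 * a3 + 3] = vhat
    jac[1, 3 * o : 3 * o + 3] = -vhat
    d_o, d_a2, d_a3 = _angle_jacobian_rows(coords, o, a2, a3)
    jac[2, 3 * o : 3 * o + 3] = d_o
    jac[2, 3 * a2 : 3 * a2 + 3] = d_a2
    jac[2, 3 * a3 : 3 * a3 + 3] = d_a3

    if n > 3:  # numerical fallback for the spherical-polar block
        step = 1e-7
        for atom in range(n):
            for comp in range(3):
                cp = coords.copy()
                cp[atom, comp] += step
                fp = compute_features(geometry.with_coordinates(cp), alf)
                cp[atom, comp] -= 2 * step
                fm = compute_features(geometry.with_coordinates(cp), alf)
                jac[3:, 3 * atom + comp] = (fp[3:] - fm[3:]) / (2 * step)
    return jac


# ---------------------------------------------------------------------------
# Batched fast paths (vectorized over a stack of geometries sharing one ALF).
# These power the optimizers and the landscape scan; they are exercised
# against the scalar versions in the tests.
# ---------------------------------------------------------------------------


def compute_features_batch(coords: np.ndarray, alf: ALFDefinition) -> np.ndarray:
    """Features for a (M, N, 3) coordinate stack → (M, 3). N = 3 only."""
    if coords.shape[1] != 3:
        raise ValueError("batched features are implemented for N = 3")
    o, a2, a3 = alf.origin_index, alf.x_axis_index, alf.xy_plane_index
    u = coords[:, a2] - coords[:, o]
    v = coords[:, a3] - coords[:, o]
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (ru * rv), -1.0, 1.0)
    return np.stack([ru, rv, np.arccos(cosang)], axis=1)


def compute_feature_jacobian_batch(
    coords: np.ndarray, alf: ALFDefinition
) -> np.ndarray:
    """Jacobians for a (M, N, 3) stack → (M, 3, 3N). N = 3 only."""
    if coords.shape[1] != 3:
        raise ValueError("batched Jacobians are implemented for N = 3")
    m = coords.shape[0]
    o, a2, a3 = alf.origin_index, alf.x_axis_index, alf.xy_plane_index
    u = coords[:, a2] - coords[:, o]
    v = coords[:, a3] - coords[:, o]
    ru = np.linalg.norm(u, axis=1, keepdims=True)
    rv = np.linalg.norm(v, axis=1, keepdims=True)
    uhat, vhat = u / ru, v / rv
    cosang = np.clip(np.einsum("ij,ij->i", uhat, vhat), -1.0, 1.0)
    sinang = np.sqrt(np.maximum(1.0 - cosang**2, 0.0))
    if np.any(sinang < _COLLINEAR_TOL):
        raise ValueError("angle at a pole: Jacobian undefined")
    c = cosang[:, None]
    s = sinang[:, None]
    d_a2 = (c * uhat - vhat) / (ru * s)
    d_a3 = (c * vhat - uhat) / (rv * s)
    d_o = -(d_a2 + d_a3)

    jac = np.zeros((m, 3, 9))
    jac[:, 0, 3 * a2 : 3 * a2 + 3] = uhat
    jac[:, 0, 3 * o : 3 * o + 3] = -uhat
    jac[:, 1, 3 * a3 : 3 * a3 + 3] = vhat
    jac[:, 1, 3 * o : 3 * o + 3] = -vhat
    jac[:, 2, 3 * o : 3 * o + 3] = d_o
    jac[:, 2, 3 * a2 : 3 * a2 + 3] = d_a2
    jac[:, 2, 3 * a3 : 3 * a3 + 3] = d_a3
    return jac
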