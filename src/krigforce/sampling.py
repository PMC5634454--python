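"""Normal-mode stochastic sampling of molecular geometries.

A seed geometry (in practice the synthetic-PES minimum) is distorted along
its internal normal modes: a finite-difference Hessian is mass-weighted and
diagonalized, the six near-zero rigid-body modes are excluded, and each
sample displaces the seed by a random combination of the 3N−6 internal
modes. Stiffer modes are displaced less — per-mode coefficients are uniform
on ±s/√λ_m, so the maximum potential energy per mode is about s²/2.

Samples violating the geometric constraint — every bonded distance and every
valence angle within ±`max_distortion` (default 20%) of its seed value,
closed intervals — are rejected and redrawn, so the accepted ensemble covers
the conformational box the models are trained on and nothing beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularGeometry, detect_connectivity

__all__ = [
    "NormalModeBasis",
    "SamplingConfig",
    "compute_hessian",
    "normal_mode_basis",
    "valence_angles",
    "constraint_filter",
    "sample_geometries",
]


@dataclass(frozen=True)
class NormalModeBasis:
    """Mass-weighted Hessian eigen-decomposition of a seed geometry.

    ``eigenvectors[:, m]`` is the m-th mass-weighted mode; ``internal``
    indexes the 3N−6 vibrational modes (the rest are rigid-body modes whose
    eigenvalues sit below ``rigid_cutoff``). Eigenvalues are in
    kJ/mol/Å²/amu.
    """

    eigenvalues: np.ndarray  # (3N,)
    eigenvectors: np.ndarray  # (3N, 3N), orthonormal columns
    internal: np.ndarray  # indices of internal modes
    masses: np.ndarray  # (N,) amu


@dataclass(frozen=True)
class SamplingConfig:
    n_samples: int
    max_distortion: float = 0.20  # fractional, dimensionless
    amplitude: float = 12.0  # s, sqrt(kJ/mol); per-mode bound is s/√λ_m
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_distortion < 1.0:
            raise ValueError("max_distortion must lie in (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")


def compute_hessian(energy_fn, geometry: MolecularGeometry, step: float = 1e-3):
    """Central finite-difference 3N×3N Hessian of a scalar energy function.

    ``energy_fn`` maps a :class:`MolecularGeometry` to kJ/mol. The raw
    stencil matrix is symmetrized; the pre-symmetrization asymmetry is tiny
    (stencil error) and asserted in the tests. Raises on non-finite energies.
    """
    x0 = geometry.coordinates.ravel().copy()
    n = x0.size

    def e(vec):
        val = energy_fn(geometry.with_coordinates(vec.reshape(-1, 3)))
        if not np.isfinite(val):
            raise ValueError("non-finite energy during Hessian stencil evaluation")
        return val

    e0 = e(x0)
    hess = np.empty((n, n))
    for i in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += step
        xm[i] -= step
        hess[i, i] = (e(xp) + e(xm) - 2 * e0) / step**2
    for i in range(n):
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
            xpp[[i, j]] += step
            xmm[[i, j]] -= step
            xpm[i] += step
            xpm[j] -= step
            xmp[i] -= step
            xmp[j] += step
            val = (e(xpp) + e(xmm) - e(xpm) - e(xmp)) / (4 * step**2)
            hess[i, j] = val
            hess[j, i] = val
    return 0.5 * (hess + hess.T)


def normal_mode_basis(
    hessian: np.ndarray,
    masses: np.ndarray,
    rigid_cutoff: float = 1.0,
) -> NormalModeBasis:
    """Mass-weight, diagonalize, and separate internal from rigid modes.

    ``rigid_cutoff`` (kJ/mol/Å²/amu) bounds the |eigenvalue| of the six
    excluded modes; exactly 3N−6 modes must exceed it.
    """
    m3 = np.repeat(masses, 3)
    inv_sqrt = 1.0 / np.sqrt(m3)
    hw = hessian * np.outer(inv_sqrt, inv_sqrt)
    eigvals, eigvecs = np.linalg.eigh(hw)
    internal = np.flatnonzero(np.abs(eigvals) > rigid_cutoff)
    n_expected = hessian.shape[0] - 6
    if internal.size != n_expected:
        raise ValueError(
            f"expected {n_expected} internal modes above cutoff {rigid_cutoff}, "
            f"found {internal.size}"
        )
    return NormalModeBasis(eigvals, eigvecs, internal, np.asarray(masses, float))


def valence_angles(connectivity: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All (i, j, k) triples with i–j and j–k bonded: angles at vertex j."""
    neigh: dict[int, list[int]] = {}
    for i, j in connectivity:
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)
    angles = []
    for j, nb in sorted(neigh.items()):
        nb = sorted(nb)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles


def constraint_filter(
    samples: list[MolecularGeometry],
    seed_geometry: MolecularGeometry,
    max_distortion: float,
    connectivity: list[tuple[int, int]] | None = None,
) -> list[MolecularGeometry]:
    """Keep samples whose bonds and valence angles stay within ±f of the seed.

    Intervals are closed: a bond of exactly (1±f)·b_seed is kept. Bonds and
    angles are defined once, from the seed's connectivity.
    """
    if connectivity is None:
        connectivity = detect_connectivity(seed_geometry)
    angles = valence_angles(connectivity)
    f = max_distortion
    ref_bonds = {b: seed_geometry.distance(*b) for b in connectivity}
    ref_angles = {a: seed_geometry.angle(*a) for a in angles}
    kept = []
    for geom in samples:
        ok = all(
            (1 - f) * ref <= geom.distance(*b) <= (1 + f) * ref
            for b, ref in ref_bonds.items()
        ) and all(
            (1 - f) * ref <= geom.angle(*a) <= (1 + f) * ref
            for a, ref in ref_angles.items()
        )
        if ok:
            kept.append(geom)
    return kept


def _rigid_body_basis(geometry: MolecularGeometry) -> np.ndarray:
    """Orthonormal basis (3N × 6) of translations and infinitesimal rotations."""
    coords = geometry.coordinates
    n = geometry.n_atoms
    com = coords.mean(axis=0)
    vecs = []
    for t in range(3):
        v = np.zeros((n, 3))
        v[:, t] = 1.0
        vecs.append(v.ravel())
    for axis in np.eye(3):
        v = np.cross(np.broadcast_to(axis, (n, 3)), coords - com)
        vecs.append(v.ravel())
    q, _ = np.linalg.qr(np.stack(vecs, axis=1))
    return q


def sample_geometries(
    seed_geometry: MolecularGeometry,
    basis: NormalModeBasis,
    config: SamplingConfig,
    connectivity: list[tuple[int, int]] | None = None,
) -> list[MolecularGeometry]:
    """Draw exactly ``config.n_samples`` constraint-satisfying distortions.

    Each sample is seed + Σ_m c_m·(mass-unweighted mode m), c_m i.i.d.
    uniform on ±s/√λ_m (s = ``config.amplitude``), with rigid-body
    contamination projected out. Oversample-and-reject against
    :func:`constraint_filter`; raises if the rejection rate exceeds 99%.
    """
    if connectivity is None:
        connectivity = detect_connectivity(seed_geometry)
    rng = np.random.default_rng(config.seed)
    n3 = 3 * seed_geometry.n_atoms
    modes = basis.eigenvectors[:, basis.internal]  # (3N, 3N-6)
    lam = basis.eigenvalues[basis.internal]
    bounds = config.amplitude / np.sqrt(lam)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(basis.masses, 3))
    rigid = _rigid_body_basis(seed_geometry)

    accepted: list[MolecularGeometry] = []
    drawn = 0
    while len(accepted) < config.n_samples:
        batch = max(4 * (config.n_samples - len(accepted)), 256)
        c = rng.uniform(-bounds, bounds, size=(batch, bounds.size))
        disp = (c @ modes.T) * inv_sqrt_m  # (batch, 3N), Cartesian
        disp -= (disp @ rigid) @ rigid.T  # strip rigid-body contamination
        candidates = [
            seed_geometry.with_coordinates(
                seed_geometry.coordinates + d.reshape(-1, 3)
            )
            for d in disp
        ]
        accepted.extend(
            constraint_filter(
                candidates, seed_geometry, config.max_distortion, connectivity
            )
        )
        drawn += batch
        if drawn >= 4096 and len(accepted) < 0.01 * drawn:
            raise RuntimeError(
                "sampling rejection rate exceeds 99%; "
                "reduce the per-mode amplitude"
            )
    return accepted[: config.n_samples]
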