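"""Molecular geometries, XYZ I/O and covalent-radius connectivity.

Coordinates are Cartesian and in Ångström throughout; element symbols follow
the usual capitalisation (``"O"``, ``"H"``). Atom identifiers are stable,
1-based indices assigned on construction and preserved by every operation
that moves atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularGeometry",
    "ATOMIC_MASSES",
    "COVALENT_RADII",
    "detect_connectivity",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "write_xyz_frames",
]

#: Standard atomic weights (amu).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
}

#: Covalent radii in Å (Cordero-style single-bond values).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
}

_MIN_PAIR_DISTANCE = 1e-6  # Å; below this two atoms are considered coincident


@dataclass(frozen=True)
class MolecularGeometry:
    """Element symbols plus an N×3 coordinate block (Å).

    The object the optimizers move. Immutable; use :meth:`with_coordinates`
    to obtain a displaced copy sharing the element list.
    """

    elements: tuple[str, ...]
    coordinates: np.ndarray
    identifiers: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be N×3, got shape {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coordinates disagree on atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.identifiers:
            object.__setattr__(
                self, "identifiers", tuple(range(1, coords.shape[0] + 1))
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[el] for el in self.elements])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no atomic mass tabulated for element {exc}") from None

    def distance(self, i: int, j: int) -> float:
        """Distance between atoms ``i`` and ``j`` (0-based), in Å."""
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def angle(self, i: int, j: int, k: int) -> float:
        """Angle i–j–k at vertex ``j``, in radians."""
        u = self.coordinates[i] - self.coordinates[j]
        v = self.coordinates[k] - self.coordinates[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def check_no_coincident(self) -> None:
        """Raise if any two atoms sit closer than 1e-6 Å."""
        n = self.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if self.distance(i, j) <= _MIN_PAIR_DISTANCE:
                    raise ValueError(
                        f"atoms {self.identifiers[i]} and {self.identifiers[j]} "
                        "are coincident"
                    )

    def with_coordinates(self, coordinates: np.ndarray) -> "MolecularGeometry":
        return MolecularGeometry(self.elements, coordinates, self.identifiers)


def detect_connectivity(
    geometry: MolecularGeometry,
    radii: dict[str, float] | None = None,
    tolerance: float = 0.3,
) -> list[tuple[int, int]]:
    """Bonded pairs from summed covalent radii.

    A pair (i, j) is bonded iff d(i, j) ≤ (r_i + r_j)·(1 + tolerance), with a
    closed threshold. Indices in the returned pairs are 0-based and i < j.
    """
    if radii is None:
        radii = COVALENT_RADII
    for el in set(geometry.elements):
        if el not in radii:
            raise KeyError(f"no covalent radius defined for element '{el}'")
    bonds: list[tuple[int, int]] = []
    for i in range(geometry.n_atoms):
        for j in range(i + 1, geometry.n_atoms):
            cutoff = (radii[geometry.elements[i]] + radii[geometry.elements[j]]) * (
                1.0 + tolerance
            )
            if geometry.distance(i, j) <= cutoff:
                bonds.append((i, j))
    return bonds


# ---------------------------------------------------------------------------
# XYZ I/O.  Standard format: atom count / comment / "El x y z" lines in Å.
# The reader tolerates trailing blank lines; the writer emits 10-decimal
# coordinates.
# ---------------------------------------------------------------------------


def _parse_frame(lines: list[str], start: int) -> tuple[MolecularGeometry, str, int]:
    n = int(lines[start].split()[0])
    comment = lines[start + 1].rstrip("\n") if start + 1 < len(lines) else ""
    elements, coords = [], []
    for line in lines[start + 2 : start + 2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return MolecularGeometry(tuple(elements), np.array(coords)), comment, start + 2 + n


def read_xyz(path) -> MolecularGeometry:
    """Read the first frame of an XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    geom, _, _ = _parse_frame(lines, 0)
    return geom


def read_xyz_frames(path) -> list[MolecularGeometry]:
    """Read every frame of a (possibly multi-frame) XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        geom, _, pos = _parse_frame(lines, pos)
        frames.append(geom)
    return frames


def _format_frame(geometry: MolecularGeometry, comment: str) -> str:
    out = [str(geometry.n_atoms), comment]
    for el, (x, y, z) in zip(geometry.elements, geometry.coordinates):
        out.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    return "\n".join(out) + "\n"


def write_xyz(path, geometry: MolecularGeometry, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_format_frame(geometry, comment))


def write_xyz_frames(path, geometries, comments=None) -> None:
    with open(path, "w") as fh:
        for k, geom in enumerate(geometries):
            comment = comments[k] if comments is not None else f"frame {k}"
            fh.write(_format_frame(geom, comment))
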