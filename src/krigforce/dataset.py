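"""Per-atom training tables: assembly, scrubbing, splitting, model designs.

A *sample set* holds, for every geometry, each atom's feature vector, its
energy components, and its integration-error surrogate L(Ω). Scrubbing
removes any (geometry, atom) whose L(Ω) exceeds a threshold quoted in
hartree — and, because a geometry missing one atom is useless for a
molecular model, the whole geometry is then dropped from every atom's set.

Five model designs are predefined: "100", "300" and "500" train per-atom
component models (E_intra, V_cl^AA', V_x^AA') on 100/300/500 geometries
scrubbed at 0.001 a.u.; "T500" uses a twenty-times tighter threshold
(0.00005 a.u.); "TE500" uses the tight threshold but replaces the three
components with the single per-atom total E_IQA^A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alf import ALFDefinition, compute_features
from .geometry import MolecularGeometry
from .pes import HARTREE_KJMOL, LabelledExample

__all__ = [
    "COMPONENT_OUTPUTS",
    "SampleSet",
    "ModelDesign",
    "DESIGNS",
    "assemble_sample_set",
    "scrub",
    "split",
    "build_design",
]

COMPONENT_OUTPUTS = ("E_intra", "V_cl", "V_x")
TOTAL_OUTPUT = "E_IQA"


@dataclass(frozen=True)
class SampleSet:
    """Aligned per-atom training examples for a list of geometries.

    ``features[atom]`` is (G, d); ``outputs[(atom, name)]`` is (G,);
    ``lomega`` is (G, N) in a.u. All atoms index the identical geometry
    list — every operation preserves this alignment.
    """

    geometry_ids: np.ndarray  # (G,) stable integer ids
    geometries: tuple[MolecularGeometry, ...]
    features: dict[int, np.ndarray]
    outputs: dict[tuple[int, str], np.ndarray]
    lomega: np.ndarray  # (G, N)
    alfs: tuple[ALFDefinition, ...]
    n_dropped_by_scrub: int = field(default=0, compare=False)

    @property
    def n_geometries(self) -> int:
        return len(self.geometry_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.alfs)

    def molecular_energies(self) -> np.ndarray:
        """Σ_A E_IQA^A per geometry (kJ/mol)."""
        return np.sum(
            [self.outputs[(a, TOTAL_OUTPUT)] for a in range(self.n_atoms)], axis=0
        )

    def take(self, idx: np.ndarray) -> "SampleSet":
        """Row-subset by geometry positions, keeping all atoms aligned."""
        return SampleSet(
            geometry_ids=self.geometry_ids[idx],
            geometries=tuple(self.geometries[i] for i in idx),
            features={a: f[idx] for a, f in self.features.items()},
            outputs={k: v[idx] for k, v in self.outputs.items()},
            lomega=self.lomega[idx],
            alfs=self.alfs,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per (geometry, atom): id, features, components, L(Ω)."""
        rows = []
        d = self.features[0].shape[1]
        for g in range(self.n_geometries):
            for a in range(self.n_atoms):
                row = {
                    "geometry_id": int(self.geometry_ids[g]),
                    "atom": a + 1,
                    "element": self.geometries[g].elements[a],
                }
                for h in range(d):
                    row[f"f{h + 1}"] = self.features[a][g, h]
                for name in COMPONENT_OUTPUTS + (TOTAL_OUTPUT,):
                    row[name] = self.outputs[(a, name)][g]
                row["lomega_au"] = self.lomega[g, a]
                rows.append(row)
        return pd.DataFrame(rows)


def assemble_sample_set(
    examples: list[LabelledExample],
    alfs: list[ALFDefinition],
    use_noisy: bool = True,
    geometry_ids: np.ndarray | None = None,
) -> SampleSet:
    """Turn labelled geometries into aligned per-atom training tables.

    ``use_noisy`` selects the noisy decomposition as the training label
    (the noise-free one remains available on the examples). E_IQA is always
    the per-atom total of the selected components, so the component and
    total schemes describe the identical data.
    """
    n_atoms = examples[0].geometry.n_atoms
    if geometry_ids is None:
        geometry_ids = np.arange(1, len(examples) + 1)
    features = {
        a: np.array(
            [compute_features(ex.geometry, alfs[a]) for ex in examples]
        )
        for a in range(n_atoms)
    }
    outputs: dict[tuple[int, str], np.ndarray] = {}
    for a in range(n_atoms):
        decomps = [ex.noisy if use_noisy else ex.clean for ex in examples]
        for name in COMPONENT_OUTPUTS + (TOTAL_OUTPUT,):
            outputs[(a, name)] = np.array([d.component(name)[a] for d in decomps])
    lomega = np.array([ex.lomega for ex in examples])
    return SampleSet(
        geometry_ids=np.asarray(geometry_ids),
        geometries=tuple(ex.geometry for ex in examples),
        features=features,
        outputs=outputs,
        lomega=lomega,
        alfs=tuple(alfs),
    )


def scrub(sample_set: SampleSet, threshold_au: float) -> SampleSet:
    """Drop every geometry containing an atom with L(Ω) above the threshold.

    The threshold is in hartree. The returned set records how many
    geometries were removed (``n_dropped_by_scrub``); an empty post-scrub
    set raises.
    """
    if threshold_au <= 0:
        raise ValueError("scrub threshold must be > 0")
    keep = np.all(sample_set.lomega <= threshold_au, axis=1)
    if not np.any(keep):
        raise ValueError(
            f"scrubbing at {threshold_au} a.u. "
            f"({threshold_au * HARTREE_KJMOL:.3g} kJ/mol) removed every geometry"
        )
    dropped = int(np.sum(~keep))
    return replace(sample_set.take(np.flatnonzero(keep)), n_dropped_by_scrub=dropped)


def split(
    sample_set: SampleSet, n_train: int, rng_seed: int
) -> tuple[SampleSet, SampleSet]:
    """Disjoint geometry-level train/test split, reproducible from the seed."""
    g = sample_set.n_geometries
    if n_train >= g:
        raise ValueError(f"n_train={n_train} must be < {g} available geometries")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(g)
    return sample_set.take(np.sort(perm[:n_train])), sample_set.take(
        np.sort(perm[n_train:])
    )


@dataclass(frozen=True)
class ModelDesign:
    """Name, training-set size, scrub threshold (a.u.) and output scheme."""

    name: str
    n_train: int
    threshold_au: float
    scheme: str  # "component" | "total"

    def __post_init__(self) -> None:
        if self.scheme not in ("component", "total"):
            raise ValueError(f"unknown output scheme '{self.scheme}'")
        if self.threshold_au <= 0:
            raise ValueError("threshold must be > 0")


DESIGNS: dict[str, ModelDesign] = {
    "100": ModelDesign("100", 100, 1e-3, "component"),
    "300": ModelDesign("300", 300, 1e-3, "component"),
    "500": ModelDesign("500", 500, 1e-3, "component"),
    "T500": ModelDesign("T500", 500, 5e-5, "component"),
    "TE500": ModelDesign("TE500", 500, 5e-5, "total"),
}


def build_design(
    sample_set: SampleSet, design: ModelDesign
) -> dict[tuple[int, str], tuple[np.ndarray, np.ndarray]]:
    """Per-model (X, y) training tables from an already-split training set.

    The component scheme yields 3 outputs × N atoms tables (9 for water);
    the total scheme yields N tables whose values equal
    E_intra^A + ½(V_cl^AA' + V_x^AA') of the same examples.
    """
    if design.n_train > sample_set.n_geometries:
        raise ValueError(
            f"design '{design.name}' needs {design.n_train} geometries, "
            f"only {sample_set.n_geometries} available post-scrub"
        )
    outputs = COMPONENT_OUTPUTS if design.scheme == "component" else (TOTAL_OUTPUT,)
    tables = {}
    for a in range(sample_set.n_atoms):
        for name in outputs:
            tables[(a, name)] = (
                sample_set.features[a][: design.n_train],
                sample_set.outputs[(a, name)][: design.n_train],
            )
    return tables
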