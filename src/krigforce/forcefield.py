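"""Assembling molecular energies and Cartesian forces from kriging models.

A force field is a set of trained models keyed by (atom, output). The
molecular energy is

    E = Σ_A [Ê_intra^A + ½(V̂_cl^AA' + V̂_x^AA')]        (component scheme)
    E = Σ_A Ê_IQA^A                                      (total scheme)

and the force on nucleus Ω along Cartesian coordinate α_i is the negative
sum over *all* models of (model gradient in feature space) · (feature
Jacobian column for α_i^Ω) — atom A's model depends on every atom entering
A's features, so cross-terms are included automatically by the chain rule.
Because features are rigid-motion invariant, the assembled forces carry
zero net force and zero net torque to machine precision.

Component models can be switched off individually (masking), which exposes
the drift each energy term prefers on its own; no such analysis exists for
the total scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alf import (
    ALFDefinition,
    compute_feature_jacobian,
    compute_feature_jacobian_batch,
    compute_features,
    compute_features_batch,
)
from .dataset import COMPONENT_OUTPUTS, TOTAL_OUTPUT
from .geometry import MolecularGeometry
from .kriging import KrigingModel

__all__ = ["ForceField", "mask_components"]

_COMPONENT_WEIGHTS = {"E_intra": 1.0, "V_cl": 0.5, "V_x": 0.5}
_TOTAL_WEIGHTS = {TOTAL_OUTPUT: 1.0}


@dataclass(frozen=True)
class ForceField:
    """Kriging models keyed by (atom index, output name) plus per-atom ALFs."""

    models: dict[tuple[int, str], KrigingModel]
    alfs: tuple[ALFDefinition, ...]
    scheme: str  # "component" | "total"
    active: frozenset[str] | None = None  # None ⇒ all outputs active

    def __post_init__(self) -> None:
        if self.scheme not in ("component", "total"):
            raise ValueError(f"unknown scheme '{self.scheme}'")
        outputs = COMPONENT_OUTPUTS if self.scheme == "component" else (TOTAL_OUTPUT,)
        for a in range(len(self.alfs)):
            for name in outputs:
                if (a, name) not in self.models:
                    raise ValueError(
                        f"missing kriging model for atom {a + 1}, output {name}"
                    )
        if self.active is None:
            object.__setattr__(self, "active", frozenset(outputs))
        object.__setattr__(self, "alfs", tuple(self.alfs))

    @property
    def n_atoms(self) -> int:
        return len(self.alfs)

    def _terms(self):
        weights = (
            _COMPONENT_WEIGHTS if self.scheme == "component" else _TOTAL_WEIGHTS
        )
        for (a, name), model in sorted(self.models.items()):
            if name in self.active:
                yield a, weights[name], model

    def _features(self, geometry: MolecularGeometry) -> dict[int, np.ndarray]:
        return {
            a: compute_features(geometry, alf) for a, alf in enumerate(self.alfs)
        }

    def molecular_energy(self, geometry: MolecularGeometry) -> float:
        feats = self._features(geometry)
        return float(
            sum(w * model.predict(feats[a]) for a, w, model in self._terms())
        )

    def atomic_forces(self, geometry: MolecularGeometry) -> np.ndarray:
        """N×3 forces in kJ/mol/Å (negative total-energy gradient)."""
        feats = self._features(geometry)
        jacs = {
            a: compute_feature_jacobian(geometry, alf)
            for a, alf in enumerate(self.alfs)
        }
        grad = np.zeros(3 * self.n_atoms)
        for a, w, model in self._terms():
            grad += w * (model.predict_gradient(feats[a]) @ jacs[a])
        return -grad.reshape(-1, 3)

    def energy_and_forces(self, geometry: MolecularGeometry):
        e, f = self.energies_and_forces_batch(geometry.coordinates[None])
        return float(e[0]), f[0]

    # -- batched fast paths (stacks of geometries, shared ALFs) -------------

    def energies_batch(self, coords: np.ndarray) -> np.ndarray:
        """(M, N, 3) coordinate stack → (M,) molecular energies."""
        feats = {
            a: compute_features_batch(coords, alf)
            for a, alf in enumerate(self.alfs)
        }
        e = np.zeros(coords.shape[0])
        for a, w, model in self._terms():
            e += w * model.predict_batch(feats[a])
        return e

    def energies_and_forces_batch(self, coords: np.ndarray):
        """(M, N, 3) → ((M,) energies, (M, N, 3) forces)."""
        m = coords.shape[0]
        feats = {
            a: compute_features_batch(coords, alf)
            for a, alf in enumerate(self.alfs)
        }
        jacs = {
            a: compute_feature_jacobian_batch(coords, alf)
            for a, alf in enumerate(self.alfs)
        }
        e = np.zeros(m)
        grad = np.zeros((m, 3 * self.n_atoms))
        for a, w, model in self._terms():
            e += w * model.predict_batch(feats[a])
            g_feat = model.predict_gradient_batch(feats[a])  # (M, d)
            grad += w * np.einsum("mh,mhi->mi", g_feat, jacs[a])
        return e, -grad.reshape(m, -1, 3)

    def max_correlation(self, geometry: MolecularGeometry) -> float:
        """Largest kernel correlation of any model with its training set.

        Near zero ⇔ the geometry sits in the mean-reverted "no man's land"
        where every prediction collapses to μ̂ and forces vanish.
        """
        feats = self._features(geometry)
        return max(
            float(np.max(model.correlations(feats[a])))
            for a, _, model in self._terms()
        )


def mask_components(ff: ForceField, keep) -> ForceField:
    """Force field whose energy/forces include only the kept components.

    Only meaningful for the component scheme; the total scheme has a single
    inseparable output and raises.
    """
    if ff.scheme != "component":
        raise ValueError(
            "component switch-off is not possible for a total-energy model"
        )
    keep = frozenset(keep)
    unknown = keep - set(COMPONENT_OUTPUTS)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    return replace(ff, active=keep)
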