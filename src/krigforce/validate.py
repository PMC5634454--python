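"""Model-quality diagnostics: S-curves, summary statistics, landscape scans.

The S-curve is the empirical cumulative distribution of absolute prediction
errors over a test set: errors sorted ascending on the x-axis, cumulative
percentage (increments of 100/n %) on the y-axis. A good model's curve is
steep, far to the left, and short-tailed near 100%.

Summary statistics per model: test/training molecular-energy ranges, the
maximum absolute error, the mean absolute error (MAE), and the prediction
percentage error defined as 100·MAE / (test-set energy range) — the
definition that reproduces the published statistics tables from their MAE
and range rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularGeometry
from .optimize import zero_kelvin_batch
from .sampling import valence_angles

__all__ = [
    "SCurve",
    "ModelStats",
    "ScanSummary",
    "s_curve",
    "model_stats",
    "prediction_pct_error",
    "geometry_deviation",
    "landscape_scan",
]


@dataclass(frozen=True)
class SCurve:
    """Sorted absolute errors (kJ/mol) with cumulative percentages."""

    errors: np.ndarray  # non-decreasing
    cumulative_pct: np.ndarray  # 100·i/n, reaching exactly 100 at the end

    @property
    def increment_pct(self) -> float:
        """Per-test-point y-axis increment, 100%/n."""
        return 100.0 / self.errors.size

    def quantile(self, q: float) -> float:
        """Error below which a fraction q of test points fall."""
        return float(np.quantile(self.errors, q))


def s_curve(predictions: np.ndarray, truths: np.ndarray) -> SCurve:
    predictions = np.asarray(predictions, float)
    truths = np.asarray(truths, float)
    if predictions.shape != truths.shape or predictions.size < 1:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    errors = np.sort(np.abs(predictions - truths))
    n = errors.size
    return SCurve(errors, 100.0 * np.arange(1, n + 1) / n)


def prediction_pct_error(mae: float, test_range: float) -> float:
    """Prediction % error = 100 × MAE / test-set energy range."""
    return 100.0 * mae / test_range


@dataclass(frozen=True)
class ModelStats:
    """Summary statistics for one model (all kJ/mol except the percentage)."""

    test_range: float
    train_range: float
    max_error: float
    mae: float

    @property
    def pct_error(self) -> float:
        return prediction_pct_error(self.mae, self.test_range)


def model_stats(
    predictions: np.ndarray, truths: np.ndarray, train_truths: np.ndarray
) -> ModelStats:
    predictions = np.asarray(predictions, float)
    truths = np.asarray(truths, float)
    errors = np.abs(predictions - truths)
    return ModelStats(
        test_range=float(np.ptp(truths)),
        train_range=float(np.ptp(train_truths)),
        max_error=float(np.max(errors)),
        mae=float(np.mean(errors)),
    )


def geometry_deviation(
    final: MolecularGeometry,
    reference: MolecularGeometry,
    connectivity: list[tuple[int, int]],
):
    """Signed per-bond Δ (Å) and per-angle Δ (degrees), reference-subtracted."""
    if final.n_atoms != reference.n_atoms:
        raise ValueError("geometries have different atom counts")
    bonds = {
        b: final.distance(*b) - reference.distance(*b) for b in connectivity
    }
    angles = {
        a: float(np.degrees(final.angle(*a) - reference.angle(*a)))
        for a in valence_angles(connectivity)
    }
    return bonds, angles


@dataclass(frozen=True)
class ScanSummary:
    """Aggregate of an all-starts optimization scan.

    ``delta_e`` holds every start's final energy minus the reference-minimum
    energy (kJ/mol); ``fractions`` maps each threshold to the fraction of
    starts whose |ΔE| falls within it (monotone in the threshold).
    """

    delta_e: np.ndarray
    fractions: dict[float, float]
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.delta_e))

    @property
    def std(self) -> float:
        return float(np.std(self.delta_e))

    @property
    def min(self) -> float:
        return float(np.min(self.delta_e))

    @property
    def max(self) -> float:
        return float(np.max(self.delta_e))


def landscape_scan(
    ff,
    starts: list[MolecularGeometry],
    reference_energy: float,
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.25),
    timestep_fs: float = 0.5,
    max_steps: int = 2000,
) -> ScanSummary:
    """Zero-Kelvin-optimize every start and aggregate final ΔE statistics.

    Runs the vectorized zero-Kelvin stepper (identical per-start updates) for
    ``max_steps`` steps of ``timestep_fs``; any start producing a non-finite
    energy is recorded as failed and excluded from the aggregate.
    """
    if not starts:
        raise ValueError("need at least one starting geometry")
    coords = np.stack([g.coordinates for g in starts])
    masses = starts[0].masses()
    _, energies, _ = zero_kelvin_batch(ff, coords, timestep_fs, max_steps, masses)
    ok = np.isfinite(energies)
    delta = energies[ok] - reference_energy
    fractions = {
        float(t): float(np.mean(np.abs(delta) <= t)) for t in sorted(thresholds)
    }
    return ScanSummary(delta, fractions, n_failed=int(np.sum(~ok)))
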