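"""Geometry optimizers driving a kriged potential-energy surface.

Two minimizers are provided, mirroring the two schemes a molecular-dynamics
host offers for energy minimization:

* **zero-Kelvin** — an MD step with the velocities reset to zero after every
  step, so each atom drifts strictly along its force:
  Δα = ½·(F/m)·dt². It always runs for exactly ``max_steps`` steps.
* **conjugate gradient (CG)** — walks along the current direction in fixed
  dt-scaled increments until the energy rises, then restarts along a
  Polak–Ribière conjugate of the new force. It stops when the largest
  per-atom displacement over a full cycle falls below a distance threshold.
  The recorded trajectory always ends with the forced uphill step; the
  penultimate geometry is the reported solution.

Units: forces kJ/mol/Å, masses amu, timestep fs, displacements Å. The
conversion constant ½·dt²·(1e-7/(N_A·u)) ≈ ½·dt²·1e-4 is assembled from SI
constants.

Both optimizers accept any object exposing ``molecular_energy(geometry)``
and ``atomic_forces(geometry)`` (a :class:`~krigforce.forcefield.ForceField`
or any test surrogate). A final geometry whose kernel correlation with every
training point has vanished is flagged as *mean-reverted*: the model has
defaulted to its global mean and the near-zero forces carry no information,
so the run is reported as not converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import N_A, physical_constants

from .geometry import MolecularGeometry

__all__ = [
    "STEP_CONSTANT",
    "OptimizerConfig",
    "PRESETS",
    "TrajectoryRecord",
    "Trajectory",
    "optimize_zero_kelvin",
    "optimize_cg",
    "zero_kelvin_batch",
]

_U = physical_constants["atomic mass constant"][0]
#: Å displacement per (kJ/mol/Å force, amu mass, fs² time²): 1e-7/(N_A·u).
STEP_CONSTANT = 1e-7 / (N_A * _U)

_MEAN_REVERTED_CORRELATION = 1e-8


@dataclass(frozen=True)
class OptimizerConfig:
    """Method, timestep and termination settings for one optimization run."""

    method: str = "zero_kelvin"  # "zero_kelvin" | "cg"
    timestep_fs: float = 1.0
    max_steps: int = 5000
    distance_tolerance: float = 1e-5  # Å, CG convergence threshold

    def __post_init__(self) -> None:
        if self.method not in ("zero_kelvin", "cg"):
            raise ValueError(f"unknown optimizer method '{self.method}'")
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be > 0")
        if self.method == "cg" and self.distance_tolerance <= 0:
            raise ValueError("distance tolerance must be > 0")


#: The four named parameter presets used throughout the optimization study.
PRESETS: dict[str, OptimizerConfig] = {
    "set1": OptimizerConfig("zero_kelvin", 1.0, 5000),
    "set2": OptimizerConfig("zero_kelvin", 0.5, 5000),
    "set3": OptimizerConfig("cg", 1.0, 20000, 1e-5),
    "set4": OptimizerConfig("cg", 1.0, 20000, 1e-6),
}


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    geometry: MolecularGeometry
    energy: float  # kJ/mol
    forces: np.ndarray  # (N, 3) kJ/mol/Å
    uphill: bool = False  # CG: forced energy-raising step


@dataclass
class Trajectory:
    """Ordered optimization records plus the termination verdict."""

    records: list[TrajectoryRecord] = field(default_factory=list)
    termination_reason: str = "unfinished"
    mean_reverted: bool = False

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    @property
    def solution(self) -> TrajectoryRecord:
        """The optimized result: the last record not flagged uphill."""
        for rec in reversed(self.records):
            if not rec.uphill:
                return rec
        return self.records[-1]

    @property
    def converged(self) -> bool:
        if self.mean_reverted:
            return False
        return self.termination_reason in ("max_steps_completed", "displacement")


def _displacement(forces, masses, dt):
    return 0.5 * (forces / masses[:, None]) * dt**2 * STEP_CONSTANT


def _flag_mean_reversion(ff, trajectory: Trajectory) -> None:
    probe = getattr(ff, "max_correlation", None)
    if probe is not None:
        final = trajectory.records[-1].geometry
        trajectory.mean_reverted = probe(final) < _MEAN_REVERTED_CORRELATION


def optimize_zero_kelvin(
    ff, start: MolecularGeometry, config: OptimizerConfig
) -> Trajectory:
    """Velocity-reset minimization: exactly ``config.max_steps`` force steps.

    Records the state at the start of every step plus the final state
    (``max_steps`` + 1 records). Aborts with a partial trajectory on a
    non-finite force.
    """
    masses = start.masses()
    dt = config.timestep_fs
    geom = start
    traj = Trajectory()
    for step in range(config.max_steps + 1):
        energy = ff.molecular_energy(geom)
        forces = ff.atomic_forces(geom)
        if not (np.isfinite(energy) and np.all(np.isfinite(forces))):
            traj.termination_reason = "non_finite_force"
            return traj
        traj.records.append(TrajectoryRecord(step, geom, energy, forces))
        if step == config.max_steps:
            break
        geom = geom.with_coordinates(
            geom.coordinates + _displacement(forces, masses, dt)
        )
    traj.termination_reason = "max_steps_completed"
    _flag_mean_reversion(ff, traj)
    return traj


def optimize_cg(
    ff, start: MolecularGeometry, config: OptimizerConfig
) -> Trajectory:
    """Conjugate-gradient line-walk minimization (see module docs).

    Terminates with reason ``"displacement"`` when the largest per-atom
    displacement over one cycle drops below the distance tolerance, or
    ``"step_limit"`` (not converged) when ``max_steps`` energy evaluations
    pass without meeting it.
    """
    masses = start.masses()
    dt = config.timestep_fs
    geom = start
    energy = ff.molecular_energy(geom)
    forces = ff.atomic_forces(geom)
    traj = Trajectory()
    traj.records.append(TrajectoryRecord(0, geom, energy, forces))
    direction = forces.copy()
    step = 0

    while step < config.max_steps:
        cycle_start = geom.coordinates
        # Line walk: fixed dt-scaled increments along the current direction
        # until the energy rises; the uphill probe is recorded and undone.
        while step < config.max_steps:
            trial = geom.with_coordinates(
                geom.coordinates + _displacement(direction, masses, dt)
            )
            trial_energy = ff.molecular_energy(trial)
            step += 1
            if not np.isfinite(trial_energy):
                traj.termination_reason = "non_finite_force"
                return traj
            uphill = trial_energy > energy
            traj.records.append(
                TrajectoryRecord(
                    step, trial, trial_energy, np.zeros_like(forces), uphill
                )
            )
            if uphill:
                break  # geom stays at the penultimate (best) point
            geom, energy = trial, trial_energy
        max_disp = float(
            np.max(np.linalg.norm(geom.coordinates - cycle_start, axis=1))
        )
        if max_disp < config.distance_tolerance:
            traj.termination_reason = "displacement"
            _flag_mean_reversion(ff, traj)
            return traj
        new_forces = ff.atomic_forces(geom)
        beta = float(
            np.sum(new_forces * (new_forces - forces)) / np.sum(forces * forces)
        )
        direction = new_forces + max(beta, 0.0) * direction
        if np.sum(direction * new_forces) <= 0:  # restart on non-descent
            direction = new_forces.copy()
        forces = new_forces

    traj.termination_reason = "step_limit"
    _flag_mean_reversion(ff, traj)
    return traj


def zero_kelvin_batch(
    ff,
    coords: np.ndarray,
    timestep_fs: float,
    max_steps: int,
    masses: np.ndarray,
    record_every: int | None = None,
):
    """Vectorized zero-Kelvin stepper for a stack of starts.

    Mathematically identical to running :func:`optimize_zero_kelvin` on each
    start (the update has no cross-coupling between geometries); used by the
    landscape scan for throughput. Returns (final coords (M, N, 3), final
    energies (M,), history) where history is a list of (step, energies)
    snapshots if ``record_every`` is set.
    """
    coords = np.array(coords, float)
    dt = timestep_fs
    history = []
    for step in range(max_steps):
        energies, forces = ff.energies_and_forces_batch(coords)
        if record_every and step % record_every == 0:
            history.append((step, energies.copy()))
        coords = coords + 0.5 * (forces / masses[None, :, None]) * dt**2 * STEP_CONSTANT
    energies = ff.energies_batch(coords)
    if record_every:
        history.append((max_steps, energies.copy()))
    return coords, energies, history
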