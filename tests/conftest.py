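"""Shared fixtures: the synthetic reference minimum, sampled datasets, and
trained force fields at several sizes.

The expensive force fields (500 training geometries) are session-scoped and
shared between the validation and acceptance tests; the small ones keep the
unit tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import krigforce as kf
from krigforce.dataset import DESIGNS, assemble_sample_set, build_design, scrub, split
from krigforce.forcefield import ForceField
from krigforce.kriging import Hyperparameters, KrigingModel, PSOConfig, fit_weights, train


@pytest.fixture(scope="session")
def ref_min():
    """(geometry, energy) of the synthetic reference minimum."""
    return kf.reference_minimum()


@pytest.fixture(scope="session")
def seed_geom(ref_min):
    return ref_min[0]


@pytest.fixture(scope="session")
def connectivity(seed_geom):
    return kf.detect_connectivity(seed_geom)


@pytest.fixture(scope="session")
def alfs(seed_geom, connectivity):
    return kf.build_all_alfs(seed_geom, connectivity)


@pytest.fixture(scope="session")
def mode_basis(seed_geom, connectivity):
    hess = kf.compute_hessian(
        lambda g: kf.total_energy(g, connectivity=connectivity), seed_geom
    )
    return kf.normal_mode_basis(hess, seed_geom.masses())


@pytest.fixture(scope="session")
def sample_set_2000(seed_geom, connectivity, alfs, mode_basis):
    """2000 accepted normal-mode samples with noise-free labels."""
    samples = kf.sample_geometries(
        seed_geom, mode_basis, kf.SamplingConfig(2000, seed=1), connectivity
    )
    rng = np.random.default_rng(2)
    examples = [
        kf.add_label_noise(
            kf.evaluate_components(g, connectivity=connectivity), g, 0.0, rng
        )
        for g in samples
    ]
    return assemble_sample_set(examples, alfs, use_noisy=False)


def _train_tables(tables, pso):
    return {key: train(x, y, pso) for key, (x, y) in tables.items()}


@pytest.fixture(scope="session")
def split_500(sample_set_2000):
    scrubbed = scrub(sample_set_2000, DESIGNS["500"].threshold_au)
    train_set, pool = split(scrubbed, 500, 3)
    test_set, _ = split(pool, 500, 4)
    return train_set, test_set


@pytest.fixture(scope="session")
def ff500(split_500, alfs):
    """Component-scheme force field, 500 noise-free training geometries."""
    train_set, _ = split_500
    pso = PSOConfig(swarm_size=20, iterations=60, seed=4)
    models = _train_tables(build_design(train_set, DESIGNS["500"]), pso)
    return ForceField(models, tuple(alfs), "component")


@pytest.fixture(scope="session")
def ff500_p2(split_500, alfs):
    """As ff500 but everywhere-smooth: p = 2, moderate fixed length scales,
    and a 1e-6 nugget, with weights fitted directly.

    Finite-difference force oracles need a C³ predicted surface with bounded
    third derivatives; freely trained exponents p < 2 (cusps) or very large
    θ (short length scales) blow up the oracle's truncation error without
    the analytic forces being wrong. Test MAE of this field is ≈ 0.02 kJ/mol.
    """
    train_set, _ = split_500
    hyp = Hyperparameters(np.array([30.0, 30.0, 10.0]), np.full(3, 2.0))
    models = {}
    for key, (x, y) in build_design(train_set, DESIGNS["500"]).items():
        mu, a = fit_weights(x, y, hyp, nugget=1e-6)
        models[key] = KrigingModel(mu, a, x, y, hyp, 1e-6)
    return ForceField(models, tuple(alfs), "component")


@pytest.fixture(scope="session")
def ff_total(sample_set_2000, alfs):
    """Total-scheme (single E_IQA^A per atom) force field, tight scrub."""
    scrubbed = scrub(sample_set_2000, DESIGNS["TE500"].threshold_au)
    train_set, _ = split(scrubbed, 500, 3)
    pso = PSOConfig(swarm_size=12, iterations=30, seed=6)
    models = _train_tables(build_design(train_set, DESIGNS["TE500"]), pso)
    return ForceField(models, tuple(alfs), "total")


@pytest.fixture(scope="session")
def ff_small(sample_set_2000, alfs):
    """Fast, lower-accuracy component force field for optimizer unit tests."""
    train_set, _ = split(sample_set_2000, 80, 7)
    design = kf.ModelDesign("small80", 80, 1e-3, "component")
    pso = PSOConfig(swarm_size=10, iterations=20, seed=8)
    models = _train_tables(build_design(train_set, design), pso)
    return ForceField(models, tuple(alfs), "component")


@pytest.fixture(scope="session")
def ff_fixed(sample_set_2000, alfs):
    """Component field with hand-fixed hyperparameters (θ = [20, 20, 5],
    p = 2) and directly fitted weights: deterministic, well-conditioned,
    and with correlation lengths short enough that far-out geometries
    genuinely mean-revert. Used for optimizer-behaviour tests."""
    train_set, _ = split(sample_set_2000, 80, 7)
    design = kf.ModelDesign("fixed80", 80, 1e-3, "component")
    hyp = Hyperparameters(np.array([20.0, 20.0, 5.0]), np.full(3, 2.0))
    models = {}
    for key, (x, y) in build_design(train_set, design).items():
        mu, a = fit_weights(x, y, hyp)
        models[key] = KrigingModel(mu, a, x, y, hyp, 1e-10)
    return ForceField(models, tuple(alfs), "component")


@pytest.fixture(scope="session")
def ff_small_p2(sample_set_2000, alfs):
    """Small everywhere-smooth field (p = 2, fixed θ) for FD force oracles."""
    train_set, _ = split(sample_set_2000, 80, 7)
    design = kf.ModelDesign("small80", 80, 1e-3, "component")
    hyp = Hyperparameters(np.array([30.0, 30.0, 10.0]), np.full(3, 2.0))
    models = {}
    for key, (x, y) in build_design(train_set, design).items():
        mu, a = fit_weights(x, y, hyp, nugget=1e-8)
        models[key] = KrigingModel(mu, a, x, y, hyp, 1e-8)
    return ForceField(models, tuple(alfs), "component")


@pytest.fixture(scope="session")
def test_mae_500(ff500, split_500):
    _, test_set = split_500
    preds = ff500.energies_batch(
        np.stack([g.coordinates for g in test_set.geometries])
    )
    return float(np.mean(np.abs(preds - test_set.molecular_energies())))
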