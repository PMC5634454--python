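"""End-to-end training pipeline: sample → label → scrub → train → validate
→ optimize, with stage-level resumability and a reproducibility manifest.

Every stochastic stage (sampling, label noise, train/test split, swarm
training) carries its own explicit seed in the run configuration; a config
missing any seed is rejected. Each stage writes its products to the run
directory and is skipped on re-entry if they already exist, so a run can be
resumed after deleting any intermediate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataset as ds
from . import kriging, validate
from .alf import build_all_alfs
from .forcefield import ForceField
from .geometry import detect_connectivity, read_xyz, read_xyz_frames, write_xyz, write_xyz_frames
from .optimize import PRESETS, optimize_cg, optimize_zero_kelvin
from .pes import DEFAULT_PARAMS, add_label_noise, evaluate_components, reference_minimum
from .sampling import SamplingConfig, compute_hessian, normal_mode_basis, sample_geometries
from .pes import total_energy

logger = logging.getLogger("krigforce")

__all__ = ["RunConfig", "ExperimentManifest", "run_pipeline", "load_forcefield"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, seeds included.

    The optimizer parameter presets ("set1"–"set4") are immutable module
    constants; the config merely selects which to run.
    """

    seed_sampling: int = 1
    seed_noise: int = 2
    seed_split: int = 3
    seed_pso: int = 4
    n_samples: int = 2000
    max_distortion: float = 0.20
    amplitude: float = 12.0
    noise_sigma: float = 0.05
    use_noisy_labels: bool = True
    designs: list[str] = field(default_factory=lambda: ["500", "TE500"])
    n_test: int = 500
    pso_swarm: int = 20
    pso_iterations: int = 50
    presets: list[str] = field(default_factory=lambda: ["set1"])
    sp_targets: list[float] = field(default_factory=lambda: [15.0, 50.0, 125.0])

    def validate(self) -> None:
        for name in ("seed_sampling", "seed_noise", "seed_split", "seed_pso"):
            value = getattr(self, name)
            if not isinstance(value, int):
                raise ValueError(f"stochastic stage seed '{name}' must be an integer")
        for d in self.designs:
            if d not in ds.DESIGNS:
                raise ValueError(f"unknown model design '{d}'")
        for p in self.presets:
            if p not in PRESETS:
                raise ValueError(f"unknown optimizer preset '{p}'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ExperimentManifest:
    """Config hash plus digests of every file the pipeline produced."""

    config_hash: str
    digests: dict[str, str]
    version: str = "0.1.0"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("sample")
def _stage_sample(cfg: RunConfig, run_dir: Path):
    seed_file = run_dir / "seed.xyz"
    samples_file = run_dir / "samples.xyz"
    if samples_file.exists() and seed_file.exists():
        return
    seed_geom, _ = reference_minimum()
    conn = detect_connectivity(seed_geom)
    hess = compute_hessian(lambda g: total_energy(g, connectivity=conn), seed_geom)
    basis = normal_mode_basis(hess, seed_geom.masses())
    samples = sample_geometries(
        seed_geom,
        basis,
        SamplingConfig(cfg.n_samples, cfg.max_distortion, cfg.amplitude,
                       cfg.seed_sampling),
        conn,
    )
    write_xyz(seed_file, seed_geom, "synthetic reference minimum")
    write_xyz_frames(samples_file, samples)


@_stage("label")
def _stage_label(cfg: RunConfig, run_dir: Path):
    out = run_dir / "dataset.csv"
    if out.exists():
        return
    seed_geom = read_xyz(run_dir / "seed.xyz")
    conn = detect_connectivity(seed_geom)
    alfs = build_all_alfs(seed_geom, conn)
    samples = read_xyz_frames(run_dir / "samples.xyz")
    rng = np.random.default_rng(cfg.seed_noise)
    examples = [
        add_label_noise(
            evaluate_components(g, DEFAULT_PARAMS, conn), g, cfg.noise_sigma, rng
        )
        for g in samples
    ]
    sset = ds.assemble_sample_set(examples, alfs, use_noisy=cfg.use_noisy_labels)
    sset.to_frame().to_csv(out, index=False)


def _load_sample_set(run_dir: Path) -> ds.SampleSet:
    import pandas as pd

    frame = pd.read_csv(run_dir / "dataset.csv")
    samples = read_xyz_frames(run_dir / "samples.xyz")
    seed_geom = read_xyz(run_dir / "seed.xyz")
    conn = detect_connectivity(seed_geom)
    alfs = build_all_alfs(seed_geom, conn)
    n_atoms = seed_geom.n_atoms
    d = 3 * n_atoms - 6
    by_atom = {a: frame[frame["atom"] == a + 1].reset_index(drop=True)
               for a in range(n_atoms)}
    features = {
        a: by_atom[a][[f"f{h + 1}" for h in range(d)]].to_numpy()
        for a in range(n_atoms)
    }
    outputs = {
        (a, name): by_atom[a][name].to_numpy()
        for a in range(n_atoms)
        for name in ds.COMPONENT_OUTPUTS + ("E_IQA",)
    }
    lomega = np.stack([by_atom[a]["lomega_au"].to_numpy() for a in range(n_atoms)],
                      axis=1)
    return ds.SampleSet(
        geometry_ids=by_atom[0]["geometry_id"].to_numpy(),
        geometries=tuple(samples),
        features=features,
        outputs=outputs,
        lomega=lomega,
        alfs=tuple(alfs),
    )


@_stage("train")
def _stage_train(cfg: RunConfig, run_dir: Path):
    sset = _load_sample_set(run_dir)
    pso = kriging.PSOConfig(
        swarm_size=cfg.pso_swarm, iterations=cfg.pso_iterations, seed=cfg.seed_pso
    )
    for name in cfg.designs:
        design = ds.DESIGNS[name]
        model_dir = run_dir / "models" / name
        if model_dir.exists():
            continue
        scrubbed = ds.scrub(sset, design.threshold_au)
        train_set, pool = ds.split(scrubbed, design.n_train, cfg.seed_split)
        test_set, _ = ds.split(pool, cfg.n_test, cfg.seed_split + 1)
        model_dir.mkdir(parents=True)
        (run_dir / f"split_{name}.json").write_text(
            json.dumps(
                {
                    "scrubbed_out": scrubbed.n_dropped_by_scrub,
                    "train_ids": [int(i) for i in train_set.geometry_ids],
                    "test_ids": [int(i) for i in test_set.geometry_ids],
                },
                indent=1,
            )
        )
        for (atom, output), (x, y) in ds.build_design(train_set, design).items():
            alf = train_set.alfs[atom]
            model = kriging.train(
                x, y, pso, metadata={
                    "design": name,
                    "atom": atom + 1,
                    "output": output,
                    "alf": [alf.origin_index, alf.x_axis_index, alf.xy_plane_index],
                    "angle_unit": "radian",
                    "phi_convention": "atan2(y, x) in the right-handed ALF",
                },
            )
            kriging.save_model(model, model_dir / f"atom{atom + 1}_{output}.json")


def load_forcefield(run_dir, design_name: str) -> ForceField:
    """Reassemble a trained force field from a run directory."""
    run_dir = Path(run_dir)
    design = ds.DESIGNS[design_name]
    seed_geom = read_xyz(run_dir / "seed.xyz")
    alfs = build_all_alfs(seed_geom, detect_connectivity(seed_geom))
    outputs = ds.COMPONENT_OUTPUTS if design.scheme == "component" else ("E_IQA",)
    models = {
        (a, out): kriging.load_model(
            run_dir / "models" / design_name / f"atom{a + 1}_{out}.json"
        )
        for a in range(seed_geom.n_atoms)
        for out in outputs
    }
    return ForceField(models, tuple(alfs), design.scheme)


@_stage("validate")
def _stage_validate(cfg: RunConfig, run_dir: Path):
    import pandas as pd

    sset = _load_sample_set(run_dir)
    rows = []
    for name in cfg.designs:
        out = run_dir / f"scurve_{name}.csv"
        if out.exists():
            continue
        design = ds.DESIGNS[name]
        split_info = json.loads((run_dir / f"split_{name}.json").read_text())
        id_pos = {int(g): i for i, g in enumerate(sset.geometry_ids)}
        train_idx = np.array([id_pos[i] for i in split_info["train_ids"]])
        test_idx = np.array([id_pos[i] for i in split_info["test_ids"]])
        train_set, test_set = sset.take(train_idx), sset.take(test_idx)
        ff = load_forcefield(run_dir, name)
        preds = ff.energies_batch(
            np.stack([g.coordinates for g in test_set.geometries])
        )
        truths = test_set.molecular_energies()
        curve = validate.s_curve(preds, truths)
        pd.DataFrame(
            {"abs_error_kjmol": curve.errors, "cumulative_pct": curve.cumulative_pct}
        ).to_csv(out, index=False)
        stats = validate.model_stats(preds, truths, train_set.molecular_energies())
        rows.append(
            {
                "model": name,
                "test_range": stats.test_range,
                "train_range": stats.train_range,
                "max_error": stats.max_error,
                "mae": stats.mae,
                "pct_error": stats.pct_error,
            }
        )
    if rows:
        pd.DataFrame(rows).to_csv(run_dir / "stats.csv", index=False)


@_stage("optimize")
def _stage_optimize(cfg: RunConfig, run_dir: Path):
    import pandas as pd

    sset = _load_sample_set(run_dir)
    _, e_min = reference_minimum()
    rel = sset.molecular_energies() - e_min
    sp_idx = [int(np.argmin(np.abs(rel - t))) for t in cfg.sp_targets]
    rows = []
    for name in cfg.designs:
        ff = load_forcefield(run_dir, name)
        for preset in cfg.presets:
            out = run_dir / f"opt_{name}_{preset}.csv"
            if out.exists():
                continue
            config = PRESETS[preset]
            for k, idx in enumerate(sp_idx, start=1):
                start = sset.geometries[idx]
                runner = (
                    optimize_zero_kelvin
                    if config.method == "zero_kelvin"
                    else optimize_cg
                )
                traj = runner(ff, start, config)
                sol = traj.solution
                write_xyz_frames(
                    run_dir / f"opt_{name}_{preset}_sp{k}.xyz",
                    [r.geometry for r in traj.records[:: max(1, len(traj.records) // 200)]],
                )
                rows.append(
                    {
                        "model": name,
                        "preset": preset,
                        "sp": k,
                        "start_delta_e": rel[idx],
                        "final_energy": sol.energy,
                        "delta_e_vs_min": sol.energy - e_min,
                        "steps": sol.step,
                        "termination": traj.termination_reason,
                        "converged": traj.converged,
                    }
                )
    if rows:
        pd.DataFrame(rows).to_csv(run_dir / "optimization.csv", index=False)


def run_pipeline(config: RunConfig, run_dir) -> ExperimentManifest:
    """Execute every stage in order and return the reproducibility manifest.

    Stages whose products already exist in ``run_dir`` are skipped, so the
    pipeline resumes from the first missing artifact.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    for stage in (_stage_sample, _stage_label, _stage_train, _stage_validate,
                  _stage_optimize):
        try:
            stage(config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    digests = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    config_hash = hashlib.sha256(
        yaml.safe_dump(asdict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest = ExperimentManifest(config_hash, digests)
    manifest.save(run_dir / "manifest.json")
    return manifest
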