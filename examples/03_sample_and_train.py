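"""Normal-mode sampling and kriging-model training at small scale.

Samples 400 distorted waters around the reference minimum (every bond and
valence angle within ±20% of the seed), labels them with the synthetic
surface, trains one kriging model per (atom, energy component) on 150
geometries, and prints test statistics — the per-model quality a model
builder would inspect before trusting an optimization.
"""

import numpy as np

import krigforce as kf
from krigforce.dataset import ModelDesign, assemble_sample_set, build_design, split
from krigforce.forcefield import ForceField
from krigforce.kriging import PSOConfig, train
from krigforce.validate import model_stats, s_curve

seed_geom, e_min = kf.reference_minimum()
conn = kf.detect_connectivity(seed_geom)
alfs = kf.build_all_alfs(seed_geom, conn)

hess = kf.compute_hessian(lambda g: kf.total_energy(g, connectivity=conn), seed_geom)
basis = kf.normal_mode_basis(hess, seed_geom.masses())
samples = kf.sample_geometries(seed_geom, basis, kf.SamplingConfig(400, seed=1), conn)
print(f"sampled {len(samples)} geometries inside the +/-20% box")

rng = np.random.default_rng(2)
examples = [
    kf.add_label_noise(kf.evaluate_components(g, connectivity=conn), g, 0.0, rng)
    for g in samples
]
sset = assemble_sample_set(examples, alfs, use_noisy=False)
print(f"molecular energy range: {np.ptp(sset.molecular_energies()):.1f} kJ/mol")

train_set, test_set = split(sset, 150, 3)
design = ModelDesign("demo150", 150, 1e-3, "component")
pso = PSOConfig(swarm_size=15, iterations=40, seed=4)
models = {
    key: train(x, y, pso) for key, (x, y) in build_design(train_set, design).items()
}
print(f"trained {len(models)} kriging models (3 atoms x 3 components)")

ff = ForceField(models, tuple(alfs), "component")
preds = ff.energies_batch(np.stack([g.coordinates for g in test_set.geometries]))
truths = test_set.molecular_energies()
stats = model_stats(preds, truths, train_set.molecular_energies())
curve = s_curve(preds, truths)
print(f"test MAE        = {stats.mae:.4f} kJ/mol")
print(f"max test error  = {stats.max_error:.4f} kJ/mol")
print(f"prediction %err = {stats.pct_error:.3f} %  (100*MAE / test range)")
print(f"median |error|  = {curve.quantile(0.5):.4f} kJ/mol "
      f"(S-curve increment {curve.increment_pct:.3f}% per test point)")
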