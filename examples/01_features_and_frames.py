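"""Atomic local frames and internal-coordinate features for water.

Builds a water molecule, installs one local frame per atom, and prints each
atom's 3N−6 = 3 features: two distances (Å) and one angle (rad). The
features are invariant under rigid motions, which is what lets one kriging
model per atom learn an energy from them.
"""

import numpy as np

import krigforce as kf

geom = kf.water_geometry(0.96, 1.02, np.radians(104.5))
conn = kf.detect_connectivity(geom)
print(f"bonds (0-based): {conn}")

for i, alf in enumerate(kf.build_all_alfs(geom, conn)):
    feats = kf.compute_features(geom, alf)
    print(
        f"atom {i + 1} ({geom.elements[i]}): x-axis atom {alf.x_axis_index + 1}, "
        f"xy-plane atom {alf.xy_plane_index + 1}, "
        f"features = [{feats[0]:.4f} A, {feats[1]:.4f} A, {feats[2]:.4f} rad]"
    )

# The analytic Jacobian ∂features/∂Cartesians annihilates rigid translations:
alf = kf.build_all_alfs(geom, conn)[0]
jac = kf.compute_feature_jacobian(geom, alf)
translation = np.tile([1.0, 0.0, 0.0], 3)
print(f"|J @ x-translation| = {np.abs(jac @ translation).max():.2e}  (exactly 0)")
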