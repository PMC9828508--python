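"""Atomic-local-frame features: invariance and the cyclic RBF kernel.

Each atom's 3N-6 features (two ALF distances, the valence angle, then
spherical polars of the remaining atoms) are unchanged by rigid motions of
the molecule; azimuthal features are compared on the circle.
"""

import numpy as np

from atomgpr import compute_alf, feature_count, featurize, get_system, kernel
from atomgpr.gpr import Hyperparameters
from atomgpr.molio import MolecularConfiguration

geom, _ = get_system("ammonia")
alf = compute_alf(geom)
fv = featurize(geom, alf, 0)
print(f"ammonia: {geom.natoms} atoms -> {feature_count(geom.natoms)} features")
print(f"nitrogen ALF triple (origin, x-axis, xy-plane): {alf[0]}")
print(f"features of N: {np.round(fv.values, 4)}")

# rotate + translate the molecule: features are identical
angle = 0.7
R = np.array([[np.cos(angle), -np.sin(angle), 0],
              [np.sin(angle), np.cos(angle), 0], [0, 0, 1.0]])
moved = MolecularConfiguration(geom.elements,
                               geom.coordinates @ R.T + [5.0, -3.0, 2.0])
drift = np.abs(featurize(moved, alf, 0).values - fv.values).max()
print(f"feature drift under rigid motion: {drift:.2e}  (invariant)")

# kernel similarity of the seed vs a slightly distorted copy
rng = np.random.default_rng(1)
distorted = MolecularConfiguration(
    geom.elements, geom.coordinates + 0.03 * rng.standard_normal((4, 3)))
theta = Hyperparameters(np.full(len(fv), 1.0))
k = kernel(fv.values, featurize(distorted, alf, 0).values, theta,
           fv.cyclic_mask)
print(f"kernel(seed, distorted) = {k:.4f}  (1 means identical environments)")
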