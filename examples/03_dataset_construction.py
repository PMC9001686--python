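"""From bath-parameter grids to machine-learning records.

Walks the dataset pipeline: the full parameter grid, the farthest-point
train/validation split, the vanishing-gradient horizon of one trajectory,
the region-wise time sampling, and the shape of a feature record
(site code, row label, normalised bath parameters, 100 logistic time
functions -> one density-matrix row).
"""

import numpy as np

from lindnet import build_fmo_hamiltonian, build_generator, site_excitation
from lindnet.dataset import (
    GridPoint,
    default_grid,
    enumerate_grid,
    farthest_point_split,
    feature_vector,
    find_t_M,
    sample_times,
)
from lindnet.lindblad import populations_on_grid

points = enumerate_grid(default_grid())
print(f"full grid: {len(points)} trajectories "
      f"({len(points) // 2} per initial site)")

split = farthest_point_split(points)  # 1000 / 200 / rest
print(f"farthest-point split: {len(split.train)} train, "
      f"{len(split.validation)} validation, {len(split.test)} test")

point = GridPoint(70.0, 175.0, 70.0, 1)
gen = build_generator(build_fmo_hamiltonian(), point.bath())
times, pops = populations_on_grid(gen, site_excitation(1), 1e6)
res = find_t_M((times, pops))
print(f"vanishing-gradient horizon at (lam=70, gamma=175, T=70): "
      f"t_M = {res.t_M / 1000:.2f} ps (converged: {res.converged})")

samples = sample_times(res.t_M)
print(f"training times sampled from this trajectory: {len(samples)} "
      f"(plus the t -> infinity token)")

x = feature_vector(point, n=3, t_fs=500.0)
print(f"feature record: length {len(x)}; head (m, n, gamma^, lam^, T^) = "
      f"{np.round(x[:5], 3)}")
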