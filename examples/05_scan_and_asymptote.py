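"""Non-recursive prediction: arbitrary times, shuffled grids, t = infinity.

Trains the miniature surrogate of example 04, then (i) shows that
predicting a shuffled time grid returns exactly the same states -- no
propagation, no error accumulation -- (ii) predicts the asymptotic state
directly from the all-ones time encoding and compares it with the exact
stationary state of the Lindblad generator, and (iii) scans the site-3
population at 0.5 ps over a small parameter box.
"""

import numpy as np

from lindnet import build_fmo_hamiltonian, build_generator, stationary_state
from lindnet.dataset import INFINITY
from lindnet.pipeline import (
    build_feature_arrays,
    generate_reference,
    run_config,
    split_points,
    train_from_arrays,
)
from lindnet.predictor import predict_trajectory, scan_site3

cfg = run_config("smoke", n_train=32, n_val=8, epochs=150,
                 seed_split=1, seed_train=1, seed_test=1)
split = split_points(cfg)
rec = generate_reference(split.train, cfg)
rec_val = generate_reference(split.validation, cfg)
Xt, Yt, _, meta = build_feature_arrays(rec)
Xv, Yv, _, _ = build_feature_arrays(rec_val)
model = train_from_arrays(Xt, Yt, Xv, Yv, cfg, feature_meta=meta)

# demonstrate on the held-out point closest to the grid centre
centre = np.array([160.0, 162.5, 170.0])
pt = min(split.test, key=lambda q: np.linalg.norm(
    (np.array([q.lam, q.gamma, q.temperature]) - centre) / [300.0, 275.0, 280.0]))
times = [0.0, 500.0, 1500.0, 2500.0, INFINITY]
fwd = predict_trajectory(model, pt, times)
perm = [4, 1, 3, 0, 2]
shuffled = predict_trajectory(model, pt, [times[i] for i in perm])
print("shuffled grid reproduces the same states exactly:",
      np.array_equal(shuffled.states, fwd.states[perm]))

rho_inf = stationary_state(build_generator(build_fmo_hamiltonian(), pt.bath()))
pred_inf = fwd.states[-1]
err = np.max(np.abs(np.diag(pred_inf - rho_inf).real))
print(f"asymptote: max |population error| vs exact stationary state = {err:.3f}")

res = scan_site3(model, [70.0, 190.0, 310.0], [50.0, 150.0, 250.0],
                 [50.0, 150.0, 250.0])
for site in (1, 6):
    row = res.argmax(site)
    print(f"site-{site} start: fastest transfer rho_33(0.5 ps) = "
          f"{row['rho33']:.3f} at lam={row['lam']:g}, gamma={row['gamma']:g}, "
          f"T={row['temperature']:g}")
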