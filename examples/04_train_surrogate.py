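"""Train a miniature surrogate end to end (2-3 minutes on one core).

Uses a small farthest-point selection of trajectories truncated at 2.5 ps,
a coarse time sampling, and a short training run -- enough to watch the
validation loss fall and to measure held-out population error.  The
full-scale configuration (``run_config("full")``) uses the same code path
with the complete grid, 1 ns horizons and 900 epochs.
"""

import numpy as np

from lindnet.pipeline import (
    build_feature_arrays,
    generate_reference,
    reference_records,
    run_config,
    split_points,
    train_from_arrays,
)
from lindnet.predictor import evaluate

cfg = run_config("smoke", n_train=32, n_val=8, n_test_eval=4, epochs=150,
                 seed_split=1, seed_train=1, seed_test=1)
split = split_points(cfg)
rec_train = generate_reference(split.train, cfg)
rec_val = generate_reference(split.validation, cfg)
Xt, Yt, _, meta = build_feature_arrays(rec_train)
Xv, Yv, _, _ = build_feature_arrays(rec_val)
print(f"{len(Xt)} training records from {len(split.train)} trajectories")

model = train_from_arrays(Xt, Yt, Xv, Yv, cfg, feature_meta=meta)
hist = model.history
print(f"validation MSE: epoch 1 {hist['val_mse'][0]:.2e} -> "
      f"best {min(hist['val_mse']):.2e}")

rng = np.random.default_rng(cfg.seed_test)
idx = rng.choice(len(split.test), size=cfg.n_test_eval, replace=False)
rec_test = generate_reference([split.test[i] for i in sorted(idx)], cfg)
report = evaluate(model, reference_records(rec_test))
print("held-out channel errors (MAE / RMSE):")
print(report.summary().round(5))
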