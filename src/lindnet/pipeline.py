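"""End-to-end pipeline: configuration, profiles, and the run steps.

A RunConfig names every knob and every seed; three scale profiles bundle
sensible values:

``full``
    The full-scale conditions: the complete 3960-trajectory grid,
    farthest-point split 1000/200/2760, vanishing-gradient horizons up to
    1 ns, the dense region-wise sampling schedule, 900 training epochs.
    Cluster-scale - provided for replication, not for desk runs.
``desk``
    A reduced run for a workstation: 200/40 split, horizons capped at
    50 ps, sampling steps x10, 300 epochs.
``smoke``
    Minutes on one CPU core: 100 training + 20 validation trajectories
    (farthest-point-selected from the full grid), horizons fixed at
    2.5 ps, sampling steps x100 (five times per trajectory plus the
    asymptote), 300 epochs.

Every step is a plain function usable from Python; the CLI wraps them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .dataset import (
    FeatureNorms,
    ParameterGrid,
    SamplingSchedule,
    TimeFeatureSet,
    TruncationConfig,
    default_grid,
    enumerate_grid,
    farthest_point_split,
    featurize_states,
    find_t_M,
    sample_times,
)
from .exciton import build_fmo_hamiltonian
from .lindblad import (
    build_generator,
    populations_on_grid,
    site_excitation,
    states_at_times,
    stationary_state,
)
from .surrogate import SurrogateCNN, SurrogateSpec, TrainedSurrogate, train

__all__ = ["RunConfig", "run_config", "generate_reference", "build_feature_arrays",
           "train_from_arrays", "reference_records", "make_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; every random choice traces to a seed."""

    profile: str = "smoke"
    n_train: int = 100
    n_val: int = 20
    n_test_eval: int = 12
    horizon_fs: float = 2500.0
    adaptive_horizon: bool = False
    schedule_factor: float = 100.0
    epochs: int = 300
    batch_size: int = 512
    learning_rate: float = 1e-3
    dt_fs: float = 5.0
    convention: str = "reference"
    seed_split: int = 1
    seed_train: int = 1
    seed_test: int = 1
    truncation: TruncationConfig = field(default_factory=TruncationConfig)

    def schedule(self) -> SamplingSchedule:
        return SamplingSchedule().coarsened(self.schedule_factor)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = run_config(raw.pop("profile", "smoke"))
        trunc = raw.pop("truncation", None)
        if trunc:
            raw["truncation"] = TruncationConfig(**trunc)
        return replace(base, **raw)


_PROFILES = {
    "full": dict(
        profile="full", n_train=1000, n_val=200, n_test_eval=600,
        horizon_fs=1e6, adaptive_horizon=True, schedule_factor=1.0, epochs=900,
    ),
    "desk": dict(
        profile="desk", n_train=200, n_val=40, n_test_eval=24,
        horizon_fs=5e4, adaptive_horizon=True, schedule_factor=10.0, epochs=300,
    ),
    "smoke": dict(
        profile="smoke", n_train=100, n_val=20, n_test_eval=12,
        horizon_fs=2500.0, adaptive_horizon=False, schedule_factor=100.0,
        epochs=300,
    ),
}


def run_config(profile: str = "smoke", **overrides) -> RunConfig:
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    cfg = dict(_PROFILES[profile])
    cfg.update(overrides)
    return RunConfig(**cfg)


# ---------------------------------------------------------------------------
# pipeline steps


def split_points(cfg: RunConfig, grid: ParameterGrid | None = None):
    """Farthest-point split of the (full, by default) parameter grid."""
    grid = grid or default_grid()
    points = enumerate_grid(grid)
    return farthest_point_split(
        points, n_train=cfg.n_train, n_val=cfg.n_val, seed=cfg.seed_split
    )


def generate_reference(points, cfg: RunConfig, *, progress=None):
    """Reference LTLME data for each grid point.

    Returns (point, times, states, rho_inf, t_M, meta) tuples: horizon from
    the vanishing-gradient rule (capped at cfg.horizon_fs) when
    ``cfg.adaptive_horizon``, else fixed at cfg.horizon_fs; states sampled
    at the region schedule; stationary state attached for the infinity
    target.
    """
    H = build_fmo_hamiltonian()
    schedule = cfg.schedule()
    out = []
    for point in points:
        gen = build_generator(H, point.bath(), convention=cfg.convention)
        rho0 = site_excitation(point.site)
        if cfg.adaptive_horizon:
            times, pops = populations_on_grid(gen, rho0, cfg.horizon_fs, cfg.dt_fs)
            res = find_t_M((times, pops), cfg.truncation)
            t_M = res.t_M
        else:
            t_M = cfg.horizon_fs
        t_samples = sample_times(t_M, schedule, grid_dt=cfg.dt_fs)
        states = states_at_times(gen, rho0, t_samples, cfg.dt_fs)
        rho_inf = stationary_state(gen)
        meta = {"dt": cfg.dt_fs, "convention": cfg.convention}
        out.append((point, t_samples, states, rho_inf, t_M, meta))
        if progress:
            progress(point, t_M)
    return out


def build_feature_arrays(records, *, norms: FeatureNorms = FeatureNorms(),
                         fset: TimeFeatureSet = TimeFeatureSet()):
    """Stack feature records (with the infinity sample) across trajectories."""
    Xs, Ys, provs = [], [], []
    for pid, (point, t_samples, states, rho_inf, t_M, meta) in enumerate(records):
        times = np.concatenate([t_samples, [np.inf]])
        allstates = np.concatenate([states, rho_inf[None]])
        X, Y, prov = featurize_states(point, times, allstates, fset=fset, norms=norms)
        Xs.append(X)
        Ys.append(Y)
        full = np.zeros(len(prov), dtype=[("point_id", "i4"), ("time_fs", "f8"),
                                          ("row", "i4")])
        full["point_id"] = pid
        full["time_fs"] = prov["time_fs"]
        full["row"] = prov["row"]
        provs.append(full)
    meta = {
        "norms": asdict(norms),
        "feature_order": "m,n,gamma_hat,lam_hat,T_hat,f0..f99",
        "target_order": "rho_nn,Re(offdiag ascending q),Im(offdiag ascending q)",
        "time_features": asdict(fset),
    }
    return (np.concatenate(Xs), np.concatenate(Ys), np.concatenate(provs), meta)


def train_from_arrays(X_train, Y_train, X_val, Y_val, cfg: RunConfig,
                      feature_meta: dict | None = None,
                      spec: SurrogateSpec | None = None,
                      verbose: bool = False) -> TrainedSurrogate:
    spec = spec or SurrogateSpec(
        epochs=cfg.epochs, batch_size=cfg.batch_size, learning_rate=cfg.learning_rate
    )
    model = SurrogateCNN(spec, seed=cfg.seed_train)
    return train(
        model, X_train, Y_train, X_val, Y_val,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=cfg.seed_train,
        feature_meta=feature_meta or {}, verbose=verbose,
    )


def reference_records(records):
    """Adapt generator output to the evaluator's (point, times, states) form."""
    out = []
    for point, t_samples, states, rho_inf, t_M, meta in records:
        times = np.concatenate([t_samples, [np.inf]])
        allstates = np.concatenate([states, rho_inf[None]])
        out.append((point, times, allstates))
    return out


# ---------------------------------------------------------------------------
# test fixtures


def make_fixtures(seed: int = 0, *, n_epochs: int = 1):
    """Deterministic micro-pipeline for the test suite.

    2 x 2 x 2 bath grid x both initial sites, 1 ps horizons, the smoke
    sampling schedule, and a micro-trained model (1 epoch by default).
    Everything derives from ``seed``; no files, no downloads.
    """
    grid = ParameterGrid(
        lam_values=(40.0, 280.0),
        gamma_values=(50.0, 250.0),
        temperature_values=(50.0, 290.0),
        initial_sites=(1, 6),
    )
    cfg = run_config(
        "smoke", n_train=10, n_val=4, n_test_eval=2, horizon_fs=1000.0,
        epochs=n_epochs, seed_split=seed, seed_train=seed, seed_test=seed,
    )
    points = enumerate_grid(grid)
    split = farthest_point_split(points, n_train=cfg.n_train, n_val=cfg.n_val,
                                 seed=cfg.seed_split)
    records = generate_reference(split.train + split.validation, cfg)
    X, Y, prov, meta = build_feature_arrays(records)
    n_train_rec = sum(
        (len(r[1]) + 1) * 7 for r in records[: len(split.train)]
    )
    model = train_from_arrays(
        X[:n_train_rec], Y[:n_train_rec], X[n_train_rec:], Y[n_train_rec:],
        cfg, feature_meta=meta,
    )
    return {
        "grid": grid, "config": cfg, "split": split, "records": records,
        "X": X, "Y": Y, "prov": prov, "meta": meta, "model": model,
    }
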