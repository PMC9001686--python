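"""Non-recursive trajectory reconstruction and evaluation.

A trained surrogate maps one feature record to one density-matrix row, so a
full state at time t is assembled from the seven row predictions; the
prediction at each time depends only on (parameters, site, t, model) - no
state is carried between times, which makes the reconstruction trivially
parallel over time points and free of error accumulation, and lets t be
the infinity token for a direct asymptote prediction.

Hermiticity is exact by construction (element nq averages the row-n value
with the conjugate row-q value).  No trace renormalisation or positivity
projection is applied by default: reported errors reflect the raw method.
An optional projection to the nearest density matrix (eigenvalue clipping)
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    N_SITES,
    FeatureNorms,
    GridPoint,
    TimeFeatureSet,
    assemble_from_rows,
    feature_vector,
)
from .surrogate import TrainedSurrogate

__all__ = [
    "PredictedTrajectory",
    "ErrorReport",
    "predict_state",
    "predict_trajectory",
    "evaluate",
    "scan_site3",
    "project_to_density_matrix",
]


@dataclass(frozen=True)
class PredictedTrajectory:
    """Surrogate states on a requested time grid (np.inf allowed)."""

    times: np.ndarray
    states: np.ndarray
    point: GridPoint
    trace_deviation: float = 0.0

    @property
    def populations(self) -> np.ndarray:
        return np.real(np.einsum("tii->ti", self.states))


def _feature_block(
    point: GridPoint, times_fs, fset: TimeFeatureSet, norms: FeatureNorms
) -> np.ndarray:
    rows = [
        feature_vector(point, n, t, fset, norms)
        for t in times_fs
        for n in range(1, N_SITES + 1)
    ]
    return np.asarray(rows)


def predict_state(
    model: TrainedSurrogate,
    point: GridPoint,
    t_fs: float,
    *,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
    project: bool = False,
) -> np.ndarray:
    """Predict the full 7x7 density matrix at one time (np.inf = asymptote)."""
    return predict_trajectory(
        model, point, [t_fs], fset=fset, norms=norms, project=project
    ).states[0]


def predict_trajectory(
    model: TrainedSurrogate,
    point: GridPoint,
    times_fs,
    *,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
    project: bool = False,
) -> PredictedTrajectory:
    """Predict states at each requested time, independently per time.

    The output is a pure function of (parameters, site, time, model):
    permuting the requested grid permutes the states identically.
    """
    times_fs = np.asarray(list(times_fs), dtype=float)
    if len(times_fs) == 0:
        return PredictedTrajectory(
            times=times_fs, states=np.empty((0, N_SITES, N_SITES), complex),
            point=point,
        )
    X = _feature_block(point, times_fs, fset, norms)
    rows = model.predict_rows(X).reshape(len(times_fs), N_SITES, -1)
    states = np.stack([assemble_from_rows(r.astype(float)) for r in rows])
    if project:
        states = np.stack([project_to_density_matrix(s) for s in states])
    dev = float(np.max(np.abs(np.einsum("tii->t", states).real - 1.0)))
    return PredictedTrajectory(
        times=times_fs, states=states, point=point, trace_deviation=dev
    )


def project_to_density_matrix(state: np.ndarray) -> np.ndarray:
    """Nearest density matrix: clip negative eigenvalues, renormalise trace."""
    w, v = np.linalg.eigh(state)
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("state has no positive weight to renormalise")
    w = w / w.sum()
    return (v * w) @ v.conj().T


# ---------------------------------------------------------------------------
# error metrics


@dataclass(frozen=True)
class ErrorReport:
    """MAE/RMSE per channel (populations, Re/Im coherences).

    ``per_trajectory`` holds one row per evaluated trajectory; the scalar
    attributes average those rows (mean of per-trajectory errors, the
    pooling convention recorded in ``convention``).  ``pooled`` is the
    alternative convention - every sample pooled before averaging.
    """

    per_trajectory: pd.DataFrame
    convention: str = "mean-of-trajectory-errors"
    pooled: dict = field(default_factory=dict)

    def __post_init__(self):
        for ch in ("pop", "re", "im"):
            if (self.per_trajectory[f"rmse_{ch}"] < self.per_trajectory[f"mae_{ch}"] - 1e-15).any():
                raise ValueError("RMSE must be >= MAE in every channel")

    @property
    def mae_populations(self) -> float:
        return float(self.per_trajectory["mae_pop"].mean())

    @property
    def mae_real_coherence(self) -> float:
        return float(self.per_trajectory["mae_re"].mean())

    @property
    def mae_imag_coherence(self) -> float:
        return float(self.per_trajectory["mae_im"].mean())

    @property
    def rmse_populations(self) -> float:
        return float(self.per_trajectory["rmse_pop"].mean())

    @property
    def rmse_real_coherence(self) -> float:
        return float(self.per_trajectory["rmse_re"].mean())

    @property
    def rmse_imag_coherence(self) -> float:
        return float(self.per_trajectory["rmse_im"].mean())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "populations": [self.mae_populations, self.rmse_populations],
                "re_coherence": [self.mae_real_coherence, self.rmse_real_coherence],
                "im_coherence": [self.mae_imag_coherence, self.rmse_imag_coherence],
            },
            index=["MAE", "RMSE"],
        )

    def to_csv(self, path) -> None:
        self.per_trajectory.to_csv(path, index=False)


def _channel_errors(pred: np.ndarray, ref: np.ndarray) -> dict:
    """Errors split into population / Re-coherence / Im-coherence channels."""
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    diag = np.eye(N_SITES, dtype=bool)
    d = pred - ref
    dpop = np.real(d[:, diag])
    off = d[:, ~diag]
    out = {}
    for ch, err in (("pop", dpop), ("re", off.real), ("im", off.imag)):
        out[f"mae_{ch}"] = float(np.mean(np.abs(err)))
        out[f"rmse_{ch}"] = float(np.sqrt(np.mean(err**2)))
    return out


def evaluate(
    model: TrainedSurrogate,
    references: list,
    *,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
) -> ErrorReport:
    """Channel errors of the surrogate against reference trajectories.

    ``references`` is a list of (point, times_fs, states) with states the
    reference density matrices at those times (np.inf rows carrying the
    stationary state).  Per trajectory, errors pool all evaluated times and
    matrix elements of a channel; the report then averages trajectories.
    """
    rows = []
    pooled = {ch: [] for ch in ("pop", "re", "im")}
    for point, times_fs, ref_states in references:
        pred = predict_trajectory(model, point, times_fs, fset=fset, norms=norms)
        ref_states = np.asarray(ref_states)
        if pred.states.shape != ref_states.shape:
            raise ValueError("reference and prediction time grids mismatch")
        errs = _channel_errors(pred.states, ref_states)
        rows.append({"lam": point.lam, "gamma": point.gamma,
                     "temperature": point.temperature, "site": point.site, **errs})
        d = pred.states - ref_states
        diag = np.eye(N_SITES, dtype=bool)
        pooled["pop"].append(np.real(d[:, diag]).ravel())
        pooled["re"].append(d[:, ~diag].real.ravel())
        pooled["im"].append(d[:, ~diag].imag.ravel())
    pooled_stats = {
        f"mae_{ch}": float(np.mean(np.abs(np.concatenate(v))))
        for ch, v in pooled.items()
    }
    pooled_stats.update(
        {
            f"rmse_{ch}": float(np.sqrt(np.mean(np.concatenate(v) ** 2)))
            for ch, v in pooled.items()
        }
    )
    return ErrorReport(per_trajectory=pd.DataFrame(rows), pooled=pooled_stats)


# ---------------------------------------------------------------------------
# parameter scans


@dataclass(frozen=True)
class ScanResult:
    """Site-3 population at a fixed time over a parameter grid."""

    table: pd.DataFrame
    t_fs: float

    def argmax(self, site: int) -> pd.Series:
        sub = self.table[self.table["site"] == site]
        return sub.loc[sub["rho33"].idxmax()]


def scan_site3(
    model: TrainedSurrogate,
    lam_values,
    gamma_values,
    temperature_values,
    sites=(1, 6),
    t_fs: float = 500.0,
    *,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
    chunk: int = 4096,
) -> ScanResult:
    """rho_33(t) for every (lam, gamma, T, site) combination.

    Every combination is an independent prediction (chunked batched
    inference); the output table is in deterministic lexicographic order
    (site, lam, gamma, T) and ``argmax`` gives the fastest-transfer
    parameters per initial site.
    """
    points = [
        GridPoint(lam, gam, tem, s)
        for s in sites
        for lam in lam_values
        for gam in gamma_values
        for tem in temperature_values
    ]
    # only row n=3 is needed for rho33
    X = np.asarray([feature_vector(pt, 3, t_fs, fset, norms) for pt in points])
    preds = []
    for lo in range(0, len(X), chunk):
        preds.append(model.predict_rows(X[lo : lo + chunk])[:, 0])
    rho33 = np.concatenate(preds) if preds else np.empty(0)
    table = pd.DataFrame(
        {
            "lam": [p.lam for p in points],
            "gamma": [p.gamma for p in points],
            "temperature": [p.temperature for p in points],
            "site": [p.site for p in points],
            "rho33": rho33.astype(float),
        }
    )
    return ScanResult(table=table, t_fs=t_fs)
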