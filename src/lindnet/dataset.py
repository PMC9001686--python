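"""Dataset construction: grids, splits, horizons, time sampling, features.

The surrogate learns the map

    (m, n, gamma_hat, lam_hat, T_hat, f_0(t)..f_99(t))  ->  row n of rho(t)

so this module turns reference trajectories into (X, Y) record arrays:

* parameter grids over (lam, gamma, T) x initial site, with the default
  grids of the training campaign (11 x 12 x 15 values, 1980 per site);
* a greedy farthest-point split of the grid into train / validation / test
  sets (max-min selection in the min-max-normalised parameter cube);
* the vanishing-gradient horizon t_M per trajectory: the earliest time at
  which the population gradient of every site has stayed below G_th for a
  fixed window of consecutive 5 fs steps;
* region-wise time sampling - dense near t = 0 where dynamics are coherent,
  progressively sparser towards t_M;
* the redundant logistic time encoding f_k(t) = 1/(1 + 15 exp(-(t + c_k))),
  c_k = 5k - 1 (t in ps), whose all-ones limit encodes t -> infinity, so the
  asymptotic state is an ordinary training target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .exciton import BathParameters
from .lindblad import DensityTrajectory

__all__ = [
    "GridPoint",
    "ParameterGrid",
    "SplitAssignment",
    "TruncationConfig",
    "TruncationResult",
    "SamplingSchedule",
    "TimeFeatureSet",
    "FeatureNorms",
    "INFINITY",
    "default_grid",
    "enumerate_grid",
    "farthest_point_split",
    "find_t_M",
    "sample_times",
    "time_features",
    "featurize_states",
    "row_target",
    "assemble_from_rows",
]

#: sentinel for the asymptotic-time sample
INFINITY = np.inf

N_SITES = 7


class GridPoint(NamedTuple):
    lam: float
    gamma: float
    temperature: float
    site: int

    def bath(self) -> BathParameters:
        return BathParameters(self.lam, self.gamma, self.temperature)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over bath parameters and initial excitation sites."""

    lam_values: tuple
    gamma_values: tuple
    temperature_values: tuple
    initial_sites: tuple = (1, 6)

    @property
    def n_per_site(self) -> int:
        return (
            len(self.lam_values)
            * len(self.gamma_values)
            * len(self.temperature_values)
        )


def default_grid(initial_sites=(1, 6)) -> ParameterGrid:
    """The full training grid: lam 10..310 (11), gamma 25..300 (12), T 30..310 (15)."""
    return ParameterGrid(
        lam_values=tuple(float(v) for v in range(10, 311, 30)),
        gamma_values=tuple(float(v) for v in range(25, 301, 25)),
        temperature_values=tuple(float(v) for v in range(30, 311, 20)),
        initial_sites=tuple(initial_sites),
    )


def enumerate_grid(grid: ParameterGrid) -> list[GridPoint]:
    """All grid points in deterministic lexicographic order (site, lam, gamma, T)."""
    if not (grid.lam_values and grid.gamma_values and grid.temperature_values):
        raise ValueError("grids must be nonempty")
    return [
        GridPoint(lam, gam, tem, site)
        for site in grid.initial_sites
        for lam in grid.lam_values
        for gam in grid.gamma_values
        for tem in grid.temperature_values
    ]


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test grid points plus the FPS pick order."""

    train: tuple
    validation: tuple
    test: tuple
    order: tuple = ()
    distances: tuple = ()

    def __post_init__(self):
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if total != len(set().union(*sets)):
            raise ValueError("train/validation/test sets must be disjoint")


def _normalise_params(points: Sequence[GridPoint]) -> np.ndarray:
    xyz = np.array([[p.lam, p.gamma, p.temperature] for p in points], dtype=float)
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (xyz - lo) / span


def _greedy_fps(xyz: np.ndarray, n_pick: int) -> tuple[list[int], list[float]]:
    """Greedy max-min selection; starts nearest the cube centre.

    Ties are broken by lowest index, making the selection fully
    deterministic for a fixed point ordering.
    """
    centre = np.full(xyz.shape[1], 0.5)
    start = int(np.argmin(np.linalg.norm(xyz - centre, axis=1)))
    picked = [start]
    dists = [float("inf")]
    mind = np.linalg.norm(xyz - xyz[start], axis=1)
    for _ in range(1, n_pick):
        nxt = int(np.argmax(mind))
        picked.append(nxt)
        dists.append(float(mind[nxt]))
        mind = np.minimum(mind, np.linalg.norm(xyz - xyz[nxt], axis=1))
    return picked, dists


def farthest_point_split(
    points: Sequence[GridPoint],
    n_train: int = 1000,
    n_val: int = 200,
    seed: int = 0,
    *,
    per_site: bool = True,
) -> SplitAssignment:
    """Greedy farthest-point train/validation/test split.

    Selection happens in the min-max-normalised (lam, gamma, T) cube.  With
    ``per_site`` (default) the budget is divided equally between the initial
    sites present and the greedy selection runs independently per site, so
    identically seeded site-1 and site-6 splits pick identical parameter
    combinations.  ``seed`` is recorded for provenance; the greedy pick
    itself is deterministic (index order breaks exact ties).
    """
    points = list(points)
    if len(set(points)) != len(points):
        raise ValueError("duplicate grid points make FPS distances degenerate")
    if n_train + n_val > len(points):
        raise ValueError("n_train + n_val exceeds the number of points")

    sites = sorted({p.site for p in points}) if per_site else [None]
    train, val, order, dists = [], [], [], []
    for s in sites:
        idx = [i for i, p in enumerate(points) if s is None or p.site == s]
        sub = [points[i] for i in idx]
        nt, nv = n_train // len(sites), n_val // len(sites)
        picked, d = _greedy_fps(_normalise_params(sub), nt + nv)
        chosen = [sub[i] for i in picked]
        train += chosen[:nt]
        val += chosen[nt:]
        order += chosen
        dists += d
    test = [p for p in points if p not in set(train) | set(val)]
    return SplitAssignment(
        train=tuple(train),
        validation=tuple(val),
        test=tuple(test),
        order=tuple(order),
        distances=tuple(dists),
    )


@dataclass(frozen=True)
class TruncationConfig:
    """Vanishing-gradient rule: |d rho_nn / dt| < g_th for `window` steps."""

    g_th: float = 1e-10
    window: int = 10

    def __post_init__(self):
        if self.g_th <= 0 or self.window < 1:
            raise ValueError("g_th must be > 0 and window >= 1")


@dataclass(frozen=True)
class TruncationResult:
    t_M: float
    per_site: np.ndarray
    converged: bool


def find_t_M(
    traj: DensityTrajectory | tuple[np.ndarray, np.ndarray],
    cfg: TruncationConfig = TruncationConfig(),
) -> TruncationResult:
    """Adaptive horizon: earliest plateau time per site, maximum over sites.

    The gradient is the forward difference of each site population between
    consecutive stored steps divided by the step in fs (units fs^-1).  A
    site plateaus at the end of the first window of `cfg.window` consecutive
    gradients all below ``cfg.g_th`` in magnitude.  If a site never
    plateaus, its horizon is the final stored time and ``converged`` is
    False.
    """
    if isinstance(traj, DensityTrajectory):
        times, pops = traj.times, traj.populations
    else:
        times, pops = traj
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    grad = np.abs(np.diff(pops, axis=0)) / dt  # (n_steps, n_sites), fs^-1
    below = grad < cfg.g_th
    w = cfg.window
    per_site = np.empty(pops.shape[1])
    converged = True
    for s in range(pops.shape[1]):
        run = 0
        hit = None
        for i in range(below.shape[0]):
            run = run + 1 if below[i, s] else 0
            if run >= w:
                hit = i + 1  # window ends at the state following gradient i
                break
        if hit is None:
            converged = False
            per_site[s] = times[-1]
        else:
            per_site[s] = times[hit]
    return TruncationResult(
        t_M=float(per_site.max()), per_site=per_site, converged=converged
    )


@dataclass(frozen=True)
class SamplingSchedule:
    """Region-wise training time steps.

    ``boundaries_ps`` are the left edges of the regions (the last region
    extends to t_M); ``steps_fs`` gives one sampling step per region.  The
    default is the full-scale schedule: 5 fs below 1 ps (i.e. 1000 fs)
    thinning to 1000 fs beyond 250 ps.
    """

    boundaries_ps: tuple = (0.0, 1.0, 1.5, 2.5, 5.0, 25.0, 50.0, 250.0)
    steps_fs: tuple = (5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

    def __post_init__(self):
        b = np.asarray(self.boundaries_ps)
        if len(self.boundaries_ps) != len(self.steps_fs):
            raise ValueError("one step per region required")
        if np.any(np.diff(b) <= 0):
            raise ValueError("region boundaries must be strictly increasing")

    def coarsened(self, factor: float) -> "SamplingSchedule":
        """Same regions with every step multiplied by ``factor`` (scaled profiles)."""
        return replace(self, steps_fs=tuple(s * factor for s in self.steps_fs))


def sample_times(
    t_M: float,
    schedule: SamplingSchedule = SamplingSchedule(),
    *,
    grid_dt: float = 5.0,
) -> np.ndarray:
    """Training sample times (fs) for a horizon t_M, without the infinity token.

    Regions are half-open [start, end); the horizon t_M itself is appended
    as the final sample.  Every returned time lies on the simulation grid.
    """
    if t_M < 0:
        raise ValueError("t_M must be nonnegative")
    edges_fs = [b * 1000.0 for b in schedule.boundaries_ps] + [np.inf]
    out = []
    for a, b, step in zip(edges_fs[:-1], edges_fs[1:], schedule.steps_fs):
        if a >= t_M:
            break
        b_eff = min(b, t_M)
        out.append(np.arange(a, b_eff - 1e-9, step))
    out.append([t_M])
    times = np.unique(np.concatenate(out))
    off = np.abs(np.round(times / grid_dt) * grid_dt - times)
    if np.max(off) > 1e-6:
        raise ValueError("sampling schedule produced off-grid times")
    return times


@dataclass(frozen=True)
class TimeFeatureSet:
    """Bank of shifted logistic time encodings, t in ps.

    f_k(t) = 1 / (1 + steepness * exp(-(t + c_k))), c_k = spacing*k + offset0;
    each function spans roughly one `spacing`-ps region, and every f_k -> 1
    as t -> infinity, so the all-ones vector encodes the asymptote.
    """

    count: int = 100
    steepness: float = 15.0
    spacing_ps: float = 5.0
    offset0_ps: float = -1.0

    @property
    def offsets(self) -> np.ndarray:
        return self.spacing_ps * np.arange(self.count) + self.offset0_ps


def time_features(t_fs: float, fset: TimeFeatureSet = TimeFeatureSet()) -> np.ndarray:
    """Evaluate the logistic bank at a time in fs (np.inf -> all ones)."""
    if np.isinf(t_fs):
        return np.ones(fset.count)
    if t_fs < 0:
        raise ValueError("time must be nonnegative")
    t_ps = t_fs / 1000.0
    return 1.0 / (1.0 + fset.steepness * np.exp(-(t_ps + fset.offsets)))


@dataclass(frozen=True)
class FeatureNorms:
    """Input normalisation constants: the maxima of the default grids."""

    lam_max: float = 310.0
    gamma_max: float = 300.0
    temperature_max: float = 310.0

    def normalise(self, point: GridPoint) -> tuple[float, float, float, bool]:
        lam_h = point.lam / self.lam_max
        gam_h = point.gamma / self.gamma_max
        tem_h = point.temperature / self.temperature_max
        extrapolating = max(lam_h, gam_h, tem_h) > 1.0
        return lam_h, gam_h, tem_h, extrapolating


#: m-feature encoding of the initial excitation site
SITE_CODES = {1: 0.0, 6: 1.0}

N_FEATURES = 105
N_TARGETS = 13


def row_target(state: np.ndarray, n: int) -> np.ndarray:
    """13-vector target for row ``n`` (1-based): [rho_nn, Re offdiag, Im offdiag].

    Off-diagonal elements rho_nq, q != n, are taken in ascending q; real
    parts first, then imaginary parts.
    """
    i = n - 1
    row = state[i]
    off = np.concatenate([row[:i], row[i + 1 :]])
    return np.concatenate([[row[i].real], off.real, off.imag])


def assemble_from_rows(rows: np.ndarray) -> np.ndarray:
    """Rebuild a Hermitian 7x7 matrix from seven 13-vector row predictions.

    Each element rho_nq averages the row-n prediction with the conjugate of
    the row-q prediction, so the result is Hermitian by construction.
    """
    if rows.shape != (N_SITES, N_TARGETS):
        raise ValueError(f"expected shape {(N_SITES, N_TARGETS)}")
    raw = np.zeros((N_SITES, N_SITES), dtype=complex)
    for n in range(N_SITES):
        off = np.delete(np.arange(N_SITES), n)
        raw[n, n] = rows[n, 0]
        raw[n, off] = rows[n, 1:7] + 1j * rows[n, 7:13]
    return (raw + raw.conj().T) / 2.0


def feature_vector(
    point: GridPoint,
    n: int,
    t_fs: float,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
) -> np.ndarray:
    """105-vector input (m, n/10, gamma_hat, lam_hat, T_hat, f_0..f_99)."""
    if point.site not in SITE_CODES:
        raise ValueError(f"initial site must be one of {sorted(SITE_CODES)}")
    lam_h, gam_h, tem_h, _ = norms.normalise(point)
    head = [SITE_CODES[point.site], n / 10.0, gam_h, lam_h, tem_h]
    return np.concatenate([head, time_features(t_fs, fset)])


def featurize_states(
    point: GridPoint,
    times_fs: np.ndarray,
    states: np.ndarray,
    *,
    fset: TimeFeatureSet = TimeFeatureSet(),
    norms: FeatureNorms = FeatureNorms(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Records for one trajectory: 7 (rows) per sampled time.

    ``times_fs`` may contain np.inf; ``states`` must align with it (the
    infinity entry carrying the stationary state).  Returns (X, Y, prov)
    with X (n, 105) float64, Y (n, 13) float64 and prov a structured array
    of (time_fs, row); the infinity token is stored as -1 in prov.
    """
    times_fs = np.asarray(times_fs, dtype=float)
    if len(times_fs) != len(states):
        raise ValueError("times and states must align")
    n_rec = len(times_fs) * N_SITES
    X = np.empty((n_rec, N_FEATURES))
    Y = np.empty((n_rec, N_TARGETS))
    prov = np.zeros(n_rec, dtype=[("time_fs", "f8"), ("row", "i4")])
    r = 0
    for t, state in zip(times_fs, states):
        for n in range(1, N_SITES + 1):
            X[r] = feature_vector(point, n, t, fset, norms)
            Y[r] = row_target(state, n)
            prov[r] = (-1.0 if np.isinf(t) else t, n)
            r += 1
    return X, Y, prov
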