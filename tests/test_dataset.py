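"""Grids, farthest-point split, horizons, time sampling, featurization."""

import numpy as np
import pytest

from lindnet import BathParameters, build_generator, site_excitation
from lindnet.dataset import (
    INFINITY,
    FeatureNorms,
    GridPoint,
    ParameterGrid,
    SamplingSchedule,
    TimeFeatureSet,
    TruncationConfig,
    assemble_from_rows,
    default_grid,
    enumerate_grid,
    farthest_point_split,
    feature_vector,
    featurize_states,
    find_t_M,
    row_target,
    sample_times,
    time_features,
)
from lindnet.lindblad import populations_on_grid


class TestGrid:
    def test_default_grid_values(self):
        g = default_grid()
        assert g.lam_values == tuple(float(v) for v in range(10, 311, 30))
        assert g.gamma_values == tuple(float(v) for v in range(25, 301, 25))
        assert g.temperature_values == tuple(float(v) for v in range(30, 311, 20))
        assert g.n_per_site == 1980

    def test_enumeration_counts(self):
        assert len(enumerate_grid(default_grid(initial_sites=(1,)))) == 1980
        assert len(enumerate_grid(default_grid())) == 3960
        tiny = ParameterGrid((10.0,), (25.0,), (30.0,), (1, 6))
        assert len(enumerate_grid(tiny)) == 2

    def test_enumeration_order_lexicographic(self):
        pts = enumerate_grid(default_grid())
        keys = [(p.site, p.lam, p.gamma, p.temperature) for p in pts]
        assert keys == sorted(keys)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(ParameterGrid((), (25.0,), (30.0,)))


def brute_force_greedy(xyz, n_pick):
    """Independent O(n^2) max-min selection with explicit distance matrix."""
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    centre = np.full(xyz.shape[1], 0.5)
    picked = [int(np.argmin(np.linalg.norm(xyz - centre, axis=1)))]
    while len(picked) < n_pick:
        best, best_d = None, -1.0
        for i in range(len(xyz)):
            if i in picked:
                continue
            di = min(d[i, j] for j in picked)
            if di > best_d:
                best, best_d = i, di
        picked.append(best)
    return picked


class TestFarthestPointSplit:
    def test_square_corners_pick_diagonal(self):
        pts = [GridPoint(0.0, 0.0, 1.0, 1), GridPoint(0.0, 1.0, 1.0, 1),
               GridPoint(1.0, 0.0, 1.0, 1), GridPoint(1.0, 1.0, 1.0, 1)]
        split = farthest_point_split(pts, n_train=2, n_val=0)
        a, b = split.train
        # max-min selection forces opposite corners
        assert a.lam != b.lam and a.gamma != b.gamma

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        xyz = rng.random((18, 3))
        pts = [GridPoint(*row, 1) for row in xyz]
        split = farthest_point_split(pts, n_train=7, n_val=3)
        from lindnet.dataset import _normalise_params

        expected = brute_force_greedy(_normalise_params(pts), 10)
        got = [pts.index(p) for p in split.order]
        assert got == expected

    def test_per_site_selections_identical(self):
        pts = enumerate_grid(default_grid())
        split = farthest_point_split(pts, n_train=40, n_val=10)
        combos = lambda seq, s: sorted(
            (p.lam, p.gamma, p.temperature) for p in seq if p.site == s
        )
        assert combos(split.train, 1) == combos(split.train, 6)

    def test_partition_is_disjoint_and_complete(self):
        pts = enumerate_grid(default_grid())
        split = farthest_point_split(pts, n_train=100, n_val=20)
        all_pts = set(split.train) | set(split.validation) | set(split.test)
        assert len(split.train) == 100 and len(split.validation) == 20
        assert len(all_pts) == 3960

    def test_duplicates_rejected(self):
        pts = [GridPoint(1.0, 1.0, 1.0, 1)] * 3
        with pytest.raises(ValueError, match="duplicate"):
            farthest_point_split(pts, n_train=1, n_val=0)


def sliding_window_scan(times, pops, g_th, window):
    """Direct oracle: scan every window of consecutive gradients per site."""
    dt = times[1] - times[0]
    grad = np.abs(np.diff(pops, axis=0)) / dt
    horizons = []
    for s in range(pops.shape[1]):
        t_site = times[-1]
        for i in range(len(grad) - window + 1):
            if np.all(grad[i : i + window, s] < g_th):
                t_site = times[i + window]
                break
        horizons.append(t_site)
    return max(horizons)


class TestVanishingGradientHorizon:
    def test_constant_trajectory_fires_at_tenth_step(self):
        times = np.arange(0.0, 500.0, 5.0)
        pops = np.full((len(times), 7), 1.0 / 7.0)
        res = find_t_M((times, pops))
        assert res.t_M == times[10]
        assert res.converged

    def test_linear_drift_never_fires(self):
        times = np.arange(0.0, 500.0, 5.0)
        pops = np.outer(times, np.full(7, 1e-5)) + 0.1
        res = find_t_M((times, pops))
        assert not res.converged
        assert res.t_M == times[-1]

    def test_matches_sliding_window_oracle(self, gen_factory):
        gen = gen_factory(70.0, 175.0, 70.0)
        times, pops = populations_on_grid(gen, site_excitation(1), 5e4)
        cfg = TruncationConfig()
        res = find_t_M((times, pops), cfg)
        assert res.t_M == sliding_window_scan(times, pops, cfg.g_th, cfg.window)

    def test_monotone_in_threshold(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        times, pops = populations_on_grid(gen, site_excitation(6), 5e4)
        horizons = [
            find_t_M((times, pops), TruncationConfig(g_th=g)).t_M
            for g in (1e-8, 1e-9, 1e-10)
        ]
        assert horizons == sorted(horizons)

    def test_coherent_corner_outlives_overdamped_corner(self, gen_factory):
        t_m = {}
        for tag, (lam, tem) in {"coherent": (10.0, 30.0),
                                "overdamped": (310.0, 310.0)}.items():
            gen = gen_factory(lam, 125.0, tem)
            times, pops = populations_on_grid(gen, site_excitation(1), 1e6)
            t_m[tag] = find_t_M((times, pops)).t_M
        assert t_m["coherent"] > t_m["overdamped"]


class TestSampleTimes:
    def test_single_region_horizon(self):
        times = sample_times(1000.0)
        assert len(times) == 201
        assert times[0] == 0.0 and times[-1] == 1000.0

    def test_three_region_horizon(self):
        times = sample_times(2500.0)
        assert len(times) == 291  # 200 + 50 + 40 + the horizon itself

    def test_zero_horizon(self):
        assert list(sample_times(0.0)) == [0.0]

    def test_all_on_simulation_grid(self):
        times = sample_times(1.0e6)
        assert np.all(np.abs(np.round(times / 5.0) * 5.0 - times) < 1e-9)

    def test_coarsened_schedule_scales_steps(self):
        sched = SamplingSchedule().coarsened(100.0)
        times = sample_times(2500.0, sched)
        assert list(times) == [0.0, 500.0, 1000.0, 1500.0, 2500.0]


class TestTimeFeatures:
    def test_infinity_is_all_ones(self):
        assert np.array_equal(time_features(INFINITY), np.ones(100))

    def test_one_picosecond_first_function(self):
        f = time_features(1000.0)
        assert f[0] == pytest.approx(1.0 / 16.0)

    def test_monotone_in_k_and_t(self):
        # nondecreasing in k at fixed t, bounded by (0, 1]; functions with
        # large offsets saturate to exactly 1.0 in double precision, which
        # is by design (the same limit encodes t -> infinity)
        f0 = time_features(0.0)
        assert np.all(np.diff(f0) >= 0)
        assert np.all((f0 > 0) & (f0 <= 1))
        assert f0[0] < 1.0 and f0[-1] == 1.0
        # strictly increasing in t over each function's active window
        for k in (0, 1):
            vals = [time_features(t)[k] for t in (0.0, 500.0, 1e3, 2e3, 4e3)]
            assert np.all(np.diff(vals) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            time_features(-5.0)


class TestFeaturization:
    point = GridPoint(310.0, 300.0, 310.0, 1)

    def test_normalised_maxima(self):
        x = feature_vector(self.point, 1, 0.0)
        m, n, gam, lam, tem = x[:5]
        assert (m, n) == (0.0, 0.1)
        assert (gam, lam, tem) == (1.0, 1.0, 1.0)

    def test_initial_state_target(self):
        state = np.zeros((7, 7), dtype=complex)
        state[0, 0] = 1.0
        t = row_target(state, 1)
        assert t[0] == 1.0 and np.all(t[1:] == 0.0)

    def test_record_shapes_and_counts(self):
        times = np.array([0.0, 5.0, INFINITY])
        states = np.stack([np.eye(7, dtype=complex) / 7] * 3)
        X, Y, prov = featurize_states(self.point, times, states)
        assert X.shape == (21, 105) and Y.shape == (21, 13)
        assert prov["time_fs"][-1] == -1.0  # infinity token
        # independent record counter: 7 per sampled time
        assert len(X) == 7 * len(times)

    def test_row_round_trip_is_exact(self):
        rng = np.random.default_rng(3)
        a = rng.random((7, 7)) + 1j * rng.random((7, 7))
        state = (a + a.conj().T) / 2
        rows = np.stack([row_target(state, n) for n in range(1, 8)])
        assert np.array_equal(assemble_from_rows(rows), state)

    def test_extrapolation_flagged(self):
        norms = FeatureNorms()
        beyond = GridPoint(340.0, 200.0, 200.0, 6)
        *_, extrapolating = norms.normalise(beyond)
        assert extrapolating
        *_, inside = norms.normalise(GridPoint(310.0, 300.0, 310.0, 6))
        assert not inside

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            feature_vector(GridPoint(10.0, 25.0, 30.0, 3), 1, 0.0)
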