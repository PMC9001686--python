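"""Non-recursive reconstruction, error metrics, and parameter scans."""

import numpy as np
import pandas as pd
import pytest

from lindnet import BathParameters, build_generator, propagate, site_excitation
from lindnet.dataset import INFINITY, GridPoint
from lindnet.predictor import (
    ErrorReport,
    evaluate,
    predict_state,
    predict_trajectory,
    project_to_density_matrix,
    scan_site3,
)

from conftest import ZeroModel

POINT = GridPoint(100.0, 75.0, 130.0, 6)


class TestReconstruction:
    def test_states_exactly_hermitian(self, micro):
        model = micro["model"]
        pred = predict_trajectory(model, POINT, [0.0, 250.0, INFINITY])
        for s in pred.states:
            assert np.array_equal(s, s.conj().T)

    def test_time_grid_permutation_invariance(self, micro):
        model = micro["model"]
        times = [0.0, 100.0, 500.0, 1000.0, INFINITY]
        fwd = predict_trajectory(model, POINT, times).states
        perm = [3, 0, 4, 2, 1]
        shuffled = predict_trajectory(model, POINT, [times[i] for i in perm]).states
        assert np.array_equal(shuffled, fwd[perm])

    def test_empty_grid_gives_empty_trajectory(self, micro):
        pred = predict_trajectory(micro["model"], POINT, [])
        assert pred.states.shape == (0, 7, 7)

    def test_trace_deviation_reported_not_repaired(self, micro):
        pred = predict_trajectory(micro["model"], POINT, [0.0, 500.0])
        traces = np.einsum("tii->t", pred.states).real
        assert pred.trace_deviation == pytest.approx(np.max(np.abs(traces - 1.0)))

    def test_projection_yields_density_matrix(self, micro):
        raw = predict_state(micro["model"], POINT, 250.0)
        proj = project_to_density_matrix(raw)
        w = np.linalg.eigvalsh(proj)
        assert np.all(w >= -1e-12)
        assert np.trace(proj).real == pytest.approx(1.0, abs=1e-12)


def double_loop_errors(preds, refs):
    """Naive per-trajectory channel errors with explicit element loops."""
    rows = []
    for pred, ref in zip(preds, refs):
        pop, re, im = [], [], []
        for t in range(len(pred)):
            for a in range(7):
                for b in range(7):
                    d = pred[t][a, b] - ref[t][a, b]
                    if a == b:
                        pop.append(abs(d.real))
                    else:
                        re.append(abs(d.real))
                        im.append(abs(d.imag))
        rows.append(
            dict(
                mae_pop=np.mean(pop), rmse_pop=np.sqrt(np.mean(np.square(pop))),
                mae_re=np.mean(re), rmse_re=np.sqrt(np.mean(np.square(re))),
                mae_im=np.mean(im), rmse_im=np.sqrt(np.mean(np.square(im))),
            )
        )
    return pd.DataFrame(rows)


class TestErrorMetrics:
    def _references(self, n_traj=3, n_t=4, seed=0):
        rng = np.random.default_rng(seed)
        refs = []
        for i in range(n_traj):
            a = rng.random((n_t, 7, 7)) + 1j * rng.random((n_t, 7, 7))
            states = (a + np.conj(np.swapaxes(a, 1, 2))) / 2
            point = GridPoint(10.0 + i, 25.0, 30.0, 1)
            times = np.arange(n_t) * 5.0
            refs.append((point, times, states))
        return refs

    def test_zero_model_matches_double_loop_oracle(self):
        refs = self._references()
        report = evaluate(ZeroModel(), refs)
        oracle = double_loop_errors(
            [np.zeros_like(r[2]) for r in refs], [r[2] for r in refs]
        )
        for col in oracle.columns:
            assert np.max(np.abs(report.per_trajectory[col] - oracle[col])) < 1e-12

    def test_zero_model_population_mae_is_mean_abs_population(self):
        refs = self._references(n_traj=1)
        report = evaluate(ZeroModel(), refs)
        direct = np.mean(np.abs([refs[0][2][t][i, i].real
                                 for t in range(len(refs[0][2]))
                                 for i in range(7)]))
        assert report.mae_populations == pytest.approx(direct, abs=1e-12)

    def test_rmse_never_below_mae(self):
        report = evaluate(ZeroModel(), self._references(n_traj=5, seed=3))
        for ch in ("pop", "re", "im"):
            assert (report.per_trajectory[f"rmse_{ch}"]
                    >= report.per_trajectory[f"mae_{ch}"]).all()

    def test_pooled_convention_also_reported(self):
        report = evaluate(ZeroModel(), self._references())
        assert set(report.pooled) == {
            "mae_pop", "mae_re", "mae_im", "rmse_pop", "rmse_re", "rmse_im"
        }

    def test_mismatched_grids_rejected(self, micro):
        point = GridPoint(40.0, 50.0, 50.0, 1)
        refs = [(point, np.array([0.0, 5.0]), np.zeros((3, 7, 7), complex))]
        with pytest.raises(ValueError):
            evaluate(micro["model"], refs)


class TestScan:
    def test_table_order_and_shape(self, micro):
        res = scan_site3(micro["model"], [10.0, 40.0], [25.0], [30.0, 50.0],
                         sites=(1, 6), t_fs=500.0)
        assert len(res.table) == 8
        keys = list(
            zip(res.table["site"], res.table["lam"], res.table["gamma"],
                res.table["temperature"])
        )
        assert keys == sorted(keys)

    def test_argmax_returns_row_per_site(self, micro):
        res = scan_site3(micro["model"], [10.0, 310.0], [25.0, 300.0],
                         [30.0, 310.0])
        for site in (1, 6):
            row = res.argmax(site)
            assert row["site"] == site
            assert np.isfinite(row["rho33"])

    def test_reference_transfer_slows_with_gamma_at_room_temperature(self, fmo):
        """LTLME check of the stated trend: higher gamma, slower site-3 EET."""
        vals = []
        for gamma in (25.0, 100.0, 200.0, 300.0):
            gen = build_generator(fmo, BathParameters(100.0, gamma, 300.0))
            vals.append(
                propagate(gen, site_excitation(1), 500.0).populations[-1][2]
            )
        assert np.all(np.diff(vals) < 0)
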