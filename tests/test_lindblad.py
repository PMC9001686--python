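"""LTLME generator and propagation physics."""

import numpy as np
import pytest

from lindnet.exciton import BathParameters, SiteHamiltonian
from lindnet.lindblad import (
    build_generator,
    propagate,
    site_excitation,
    states_at_times,
    stationary_state,
    thermalising_rate,
)
from lindnet.units import thermal_energy_cm1

BATH = BathParameters(lam=100.0, gamma=75.0, temperature=130.0)


class TestGenerator:
    def test_rates_nonnegative(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        assert np.all(gen.rates_fs >= 0.0)

    @pytest.mark.parametrize("convention", ["reference", "literal"])
    @pytest.mark.parametrize("omega", [10.0, 55.3, 180.0, 421.7])
    def test_detailed_balance(self, omega, convention):
        up = thermalising_rate(-omega, BATH, convention)
        down = thermalising_rate(omega, BATH, convention)
        boltz = np.exp(-omega / thermal_energy_cm1(BATH.temperature))
        assert up == pytest.approx(down * boltz, rel=1e-10)

    def test_zero_frequency_rate_is_dephasing_limit(self):
        # limit of 2 J(w) n(w) as w -> 0 equals the w = 0 rate
        for convention in ("reference", "literal"):
            k0 = thermalising_rate(0.0, BATH, convention)
            k_small = thermalising_rate(-1e-4, BATH, convention)
            assert k_small == pytest.approx(k0, rel=1e-3)

    def test_frequency_count_bounded(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        assert len(np.unique(np.round(gen.frequencies_cm1, 6))) <= 7 * 6 + 1

    def test_diagonal_hamiltonian_freezes_populations(self):
        h = SiteHamiltonian(matrix=np.diag([12410.0, 12530, 12210, 12320,
                                            12480, 12630, 12440]))
        gen = build_generator(h, BATH)
        # all jump operators attach to the zero gap: pure dephasing only
        assert np.max(np.abs(gen.frequencies_cm1)) < 1e-6
        rho0 = np.full((7, 7), 1.0 / 7.0, dtype=complex)
        traj = propagate(gen, rho0, 500.0)
        assert np.max(np.abs(traj.populations - traj.populations[0])) < 1e-10
        # every diagonal state is then stationary: the fixed point is not
        # unique and the solver must refuse, reporting the dimension
        with pytest.raises(ArithmeticError, match="dimension 7"):
            stationary_state(gen)

    def test_temperature_zero_rejected(self):
        with pytest.raises(ValueError):
            BathParameters(lam=100.0, gamma=75.0, temperature=0.0)


class TestPropagation:
    def test_zero_horizon_returns_initial_state(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        rho0 = site_excitation(1)
        traj = propagate(gen, rho0, 0.0)
        assert traj.times.shape == (1,)
        assert np.array_equal(traj.states[0], rho0)

    def test_reference_convention_worked_examples(self, gen_factory):
        """Site-3 population at 0.5 ps for the fastest-transfer parameters."""
        gen = gen_factory(310.0, 30.0, 25.0)
        p6 = propagate(gen, site_excitation(6), 500.0).populations[-1][2]
        p1 = propagate(gen, site_excitation(1), 500.0).populations[-1][2]
        assert p6 == pytest.approx(0.761, abs=0.02)
        assert p1 == pytest.approx(0.626, abs=0.02)

    def test_invariants_to_10ps(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        traj = propagate(gen, site_excitation(6), 1e4, initial_site=6)
        traj.validate(trace_tol=1e-8, herm_tol=1e-10, eig_tol=1e-8)

    def test_ode_matches_matrix_exponential(self, gen_factory):
        gen = gen_factory(70.0, 175.0, 70.0)
        te = propagate(gen, site_excitation(1), 1000.0, method="expm")
        to = propagate(gen, site_excitation(1), 1000.0, method="ode")
        assert np.max(np.abs(te.states - to.states)) < 1e-8

    def test_invalid_rho0_rejected(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        with pytest.raises(ValueError):
            propagate(gen, np.eye(7, dtype=complex), 100.0)  # trace 7
        bad = site_excitation(1)
        bad[0, 1] = 0.5  # not Hermitian
        with pytest.raises(ValueError):
            propagate(gen, bad, 100.0)

    def test_states_at_times_matches_full_propagation(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        rho0 = site_excitation(1)
        full = propagate(gen, rho0, 500.0)
        pick = np.array([0.0, 25.0, 250.0, 500.0])
        sparse = states_at_times(gen, rho0, pick)
        idx = (pick / 5).astype(int)
        assert np.max(np.abs(sparse - full.states[idx])) < 1e-12

    def test_off_grid_times_rejected(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        with pytest.raises(ValueError):
            states_at_times(gen, site_excitation(1), np.array([7.3]))


class TestStationaryState:
    def test_unique_fixed_point_annihilated(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        rho_inf = stationary_state(gen)
        assert np.trace(rho_inf).real == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(gen.superoperator @ rho_inf.reshape(-1))) < 1e-12

    def test_long_time_propagation_converges_to_fixed_point(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0)
        traj = propagate(gen, site_excitation(1), 1e6, store_stride=10000)
        assert np.max(np.abs(traj.states[-1] - stationary_state(gen))) < 1e-4

    def test_asymptote_independent_of_initial_site(self, gen_factory):
        gen = gen_factory(70.0, 175.0, 70.0)
        rho_inf = stationary_state(gen)
        for site in (1, 6):
            end = propagate(gen, site_excitation(site), 1e6,
                            store_stride=100000).states[-1]
            assert np.max(np.abs(end - rho_inf)) < 1e-6

    def test_metadata_records_convention(self, gen_factory):
        gen = gen_factory(100.0, 75.0, 130.0, convention="literal")
        traj = propagate(gen, site_excitation(1), 50.0)
        assert traj.metadata["convention"] == "literal"
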