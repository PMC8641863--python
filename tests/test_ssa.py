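"""Gillespie engine: exactness on linear oracles, reproducibility, conservation."""

import numpy as np
import pytest

from fflnoise import build_model, ensemble, simulate, stationary, unregulated_node_model
from fflnoise.crn import input_only_model
from fflnoise.input_signal import InputMechanism, InputProtocol


@pytest.fixture(scope="module")
def flat6():
    return InputProtocol(plateaus=(6.0, 6.0, 6.0), plateau_duration=20.0)


class TestReproducibility:
    def test_same_seed_same_trajectory(self, c1_or, protocol):
        t = np.linspace(0, 60, 121)
        a = simulate(c1_or, protocol, seed=42, sample_times=t)
        b = simulate(c1_or, protocol, seed=42, sample_times=t)
        assert np.array_equal(a.states, b.states)

    def test_different_seeds_differ(self, c1_or, protocol):
        t = np.linspace(0, 60, 121)
        a = simulate(c1_or, protocol, seed=1, sample_times=t)
        b = simulate(c1_or, protocol, seed=2, sample_times=t)
        assert not np.array_equal(a.states, b.states)


class TestConservation:
    def test_pools_exact_at_every_sample(self, protocol):
        crn = build_model("c1c1-minp-OR")
        traj = simulate(crn, protocol, seed=7, sample_times=np.linspace(0, 220, 441))
        names = crn.species_names
        for node in crn.protein_nodes:
            forms = [names.index(f) for f in crn.node_forms(node)]
            pools = traj.states[:, forms].sum(axis=1)
            assert (pools == 60).all()

    def test_bad_initial_state_rejected(self, c1_or, protocol):
        x0 = np.zeros(c1_or.n_species, dtype=int)  # violates the pool totals
        with pytest.raises(ValueError):
            simulate(c1_or, protocol, seed=1, x0=x0)


class TestLinearOracles:
    def test_pure_birth_death_is_poisson(self):
        # a=6, d=1 (no autocatalysis): stationary Poisson, Fano 1
        mech = InputMechanism(basal_rate=6.0, autocatalytic_rate=0.0, decay_rate=1.0)
        crn = input_only_model(mech)
        proto = InputProtocol(plateaus=(6.0, 6.0, 6.0), plateau_duration=20.0)
        stats = ensemble(crn, proto, n=300, base_seed=11)
        mean, var = stats.mean[-1, 0], stats.var[-1, 0]
        se = 3 * stats.se_mean[-1, 0]
        assert abs(mean - 6.0) < se
        fano = var / mean
        assert abs(fano - 1.0) < 3 * stats.se_var[-1, 0] / mean + 0.05

    def test_super_poissonian_input_fano(self, input_model, flat6):
        stats = ensemble(input_model, flat6, n=400, base_seed=3)
        mean, var = stats.mean[-1, 0], stats.var[-1, 0]
        assert abs(mean - 6.0) < 3 * stats.se_mean[-1, 0]
        assert abs(var - 1.83 * 6) < 3 * stats.se_var[-1, 0]

    def test_unregulated_node_binomial(self, flat6):
        crn = unregulated_node_model()
        stats = ensemble(crn, flat6, n=300, base_seed=17)
        ia = crn.species_index("N_a")
        assert abs(stats.mean[-1, ia] - 10.0) < 3 * stats.se_mean[-1, ia]
        assert abs(stats.var[-1, ia] - 60 * (1 / 6) * (5 / 6)) < 3 * stats.se_var[-1, ia]


class TestAgreementWithLNA:
    def test_c1_or_output_moments_close_to_lna(self, c1_or, flat6):
        stats = ensemble(c1_or, flat6, n=300, base_seed=29)
        mu, sigma = stationary(c1_or, 6.0)
        iz = c1_or.species_index("Z_a")
        # LNA is approximate for the nonlinear cascade: agree to a few percent
        assert stats.mean[-1, iz] == pytest.approx(mu[iz], rel=0.03)
        cv_ssa = np.sqrt(stats.var[-1, iz]) / stats.mean[-1, iz]
        cv_lna = np.sqrt(sigma[iz, iz]) / mu[iz]
        assert cv_ssa == pytest.approx(cv_lna, rel=0.15)


class TestEnsembleBookkeeping:
    def test_phases_and_levels(self, input_model, protocol):
        stats = ensemble(input_model, protocol, n=2, base_seed=1)
        assert list(stats.plateau_levels) == [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1]
        assert stats.plateau_phase[:6] == ["up"] * 6
        assert stats.plateau_phase[6:] == ["down"] * 5

    def test_single_replicate_rejected(self, input_model, protocol):
        with pytest.raises(ValueError):
            ensemble(input_model, protocol, n=1, base_seed=0)
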