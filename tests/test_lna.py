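"""LNA engine: drift/Jacobian/diffusion, stationary moments, integration."""

import numpy as np
import pytest

from fflnoise import build_model, integrate, staircase, stationary, unregulated_node_model
from fflnoise.lna import PSD_TOL, diffusion, drift, jacobian


@pytest.fixture(scope="module")
def input6():
    from fflnoise import calibrate_input
    from fflnoise.crn import input_only_model

    return input_only_model(calibrate_input(1.83, 6.0))


class TestLocalIngredients:
    def test_input_fixed_point_drift_vanishes(self, input6):
        f = drift(input6, np.array([6.0]))
        assert f[0] == pytest.approx(6.0 + 0.83 * 6 - 1.83 * 6)
        assert f[0] == pytest.approx(0.0, abs=1e-12)

    def test_input_diffusion_is_propensity_sum(self, input6):
        D = diffusion(input6, np.array([6.0]))
        assert D[0, 0] == pytest.approx(6.0 + (0.83 + 1.83) * 6.0)  # 21.96

    def test_input_jacobian_is_net_relaxation(self, input6):
        J = jacobian(input6, np.array([6.0]))
        assert J[0, 0] == pytest.approx(0.83 - 1.83)

    def test_jacobian_matches_finite_differences(self, c1_or, rng):
        x = rng.uniform(1.0, 40.0, size=c1_or.n_species)
        J = jacobian(c1_or, x)
        eps = 1e-6
        for i in range(c1_or.n_species):
            dx = np.zeros_like(x)
            dx[i] = eps
            fd = (drift(c1_or, x + dx) - drift(c1_or, x - dx)) / (2 * eps)
            assert np.allclose(J[:, i], fd, rtol=1e-6, atol=1e-6)


class TestStationary:
    def test_input_fano_exact_at_every_plateau(self, input_model):
        for level in (1, 2, 3, 4, 5, 6):
            mu, sigma = stationary(input_model, level)
            assert mu[0] == pytest.approx(level, rel=1e-9)
            assert sigma[0, 0] / mu[0] == pytest.approx(1.83, abs=1e-9)

    def test_unregulated_node_is_binomial(self):
        # independent switching: active count ~ binomial(60, 1/6)
        crn = unregulated_node_model()
        mu, sigma = stationary(crn, 1.0)
        ia = crn.species_index("N_a")
        assert mu[ia] == pytest.approx(10.0, rel=1e-9)
        assert sigma[ia, ia] == pytest.approx(60 * (1 / 6) * (5 / 6), rel=1e-6)

    def test_conserved_pool_has_zero_variance(self, c1_or):
        mu, sigma = stationary(c1_or, 6.0)
        names = c1_or.species_names
        v = np.zeros(len(names))
        v[names.index("X_i")] = v[names.index("X_a")] = 1.0
        assert v @ mu == pytest.approx(60.0, rel=1e-9)
        assert abs(v @ sigma @ v) < 1e-9

    def test_covariance_symmetric_psd(self, c1_or):
        _, sigma = stationary(c1_or, 6.0)
        assert np.allclose(sigma, sigma.T)
        eigs = np.linalg.eigvalsh(sigma)
        assert eigs.min() > -PSD_TOL


@pytest.fixture(scope="module")
def result(c1_or, protocol):
    return integrate(c1_or, protocol)


class TestIntegration:
    def test_grid_covers_protocol(self, result, protocol):
        assert result.times[0] == 0.0
        assert result.times[-1] == pytest.approx(protocol.total_time)
        assert (np.diff(result.times) >= 0).all()

    def test_end_of_plateau_matches_stationary(self, result, c1_or):
        # relaxation is fast relative to the plateau length
        for level, _, state in result.plateau_end_states():
            mu_s, sigma_s = stationary(c1_or, level)
            assert np.allclose(state.mu, mu_s, rtol=1e-3)
            assert np.allclose(
                np.diag(state.sigma), np.diag(sigma_s), rtol=1e-3, atol=1e-6
            )

    def test_up_down_plateaus_agree(self, result):
        by_level = {}
        iz = result.species_names.index("Z_a")
        for level, phase, state in result.plateau_end_states():
            by_level.setdefault(level, {})[phase] = state.mu[iz]
        for level, phases in by_level.items():
            if {"up", "down"} <= set(phases):
                assert phases["down"] == pytest.approx(phases["up"], rel=1e-2)

    def test_conserved_direction_stays_noiseless(self, result):
        names = result.species_names
        v = np.zeros(len(names))
        v[names.index("Z_i")] = v[names.index("Z_a")] = 1.0
        worst = max(abs(v @ s @ v) for s in result.sigma)
        assert worst < 1e-6

    def test_covariances_remain_psd(self, result):
        for k in range(0, len(result.times), 20):
            eigs = np.linalg.eigvalsh(result.sigma[k])
            assert eigs.min() > -1e-6

    def test_means_track_input_staircase(self, result):
        i_s = result.species_names.index("S")
        levels = [state.mu[i_s] for _, _, state in result.plateau_end_states()]
        assert levels == pytest.approx([1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1], rel=1e-3)


def test_stationary_matches_integration_on_coupled_model():
    crn = build_model("c1i4-mint-OR")
    result = integrate(crn, staircase())
    level, _, state = result.plateau_end_states()[5]
    assert level == 6.0
    mu_s, sigma_s = stationary(crn, 6.0)
    iz = crn.species_index("Z_a")
    assert state.mu[iz] == pytest.approx(mu_s[iz], rel=1e-3)
    assert state.sigma[iz, iz] == pytest.approx(sigma_s[iz, iz], rel=1e-3)
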