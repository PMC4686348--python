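import numpy as np
import pytest
from scipy import optimize

from neurosep import (
    StimulusParams,
    build_population,
    conditional_stats,
    entropy_plugin,
    estimate_connectivity,
    expected_energy,
    fit_recognition,
    free_energy,
    free_energy_trajectory,
    gamma_norm,
    generate_schedule,
    internal_energy,
)
from neurosep.population import EmptyGroupError, conditional_residual_covs
from neurosep.response import G1

LOG_2PI = np.log(2 * np.pi)


def random_series(rng, n_events=256, W=None, noise=0.3):
    if W is None:
        W = np.array([[2.0, 0.4], [0.3, 1.8]])
    s = rng.random((2, n_events))
    x = W @ s + noise * rng.standard_normal((2, n_events))
    return x, s, W


class TestBuildPopulation:
    def test_single_electrode_groups(self):
        u = np.zeros((2, 64), dtype=np.int8)
        u[0, ::2] = 1
        u[1, 1::2] = 1
        p = StimulusParams(n_events=64, n_trials=2)
        sch = generate_schedule(p, seed=5)
        counts = np.ones((64, 2, 64))
        counts[0][:, (sch.u[0] == 1)] = 5.0  # u1-preferring
        counts[16][:, (sch.u[1] == 1)] = 5.0  # u2-preferring
        stats = conditional_stats(counts, sch.u)
        if stats.label[0] == G1:
            pop = build_population(counts, stats, sch)
            assert np.allclose(pop.x[:, 0, :], counts[0])

    def test_empty_group_excluded(self, schedule):
        counts = np.full((64, 3, 256), 2.0)  # no preferences at all
        stats = conditional_stats(counts, schedule.u)
        with pytest.raises(EmptyGroupError):
            build_population(counts, stats, schedule)

    def test_saturated_inputs_give_unit_s_tilde(self, schedule):
        import dataclasses

        sch = dataclasses.replace(
            schedule, s=np.ones_like(schedule.s), u=np.ones_like(schedule.u)
        )
        assert (sch.s_tilde() == 1.0).all()


class TestConnectivity:
    def test_noiseless_exact_recovery(self, rng):
        x, s, W = random_series(rng, noise=0.0)
        est = estimate_connectivity(x, s)
        assert np.allclose(est.mu_W, W, atol=1e-12)
        assert np.allclose(est.sigma_xi, 0.0, atol=1e-20)

    def test_matches_least_squares_oracle(self, rng):
        """Closed form equals direct numerical minimization of the
        internal action sum ||x - W s||^2."""
        x, s, _ = random_series(rng, n_events=64)

        def action(w):
            W = w.reshape(2, 2)
            return np.sum((x - W @ s) ** 2)

        res = optimize.minimize(action, np.zeros(4), method="BFGS", tol=1e-12)
        est = estimate_connectivity(x, s)
        assert np.abs(est.mu_W - res.x.reshape(2, 2)).max() < 1e-6

    def test_gradient_zero_at_optimum(self, rng):
        """Central finite differences of the internal action vanish at the
        closed-form optimum (the action is quadratic, so central
        differences are exact up to rounding)."""
        x, s, _ = random_series(rng, n_events=64)
        est = estimate_connectivity(x, s)
        eps = 1e-6

        def action(W):
            return np.sum((x - W @ s) ** 2)

        for i in range(2):
            for j in range(2):
                dW = np.zeros((2, 2))
                dW[i, j] = eps
                grad = (action(est.mu_W + dW) - action(est.mu_W - dW)) / (2 * eps)
                assert abs(grad) < 1e-6

    def test_constant_input_is_singular(self):
        s = np.ones((2, 64))
        x = np.ones((2, 64))
        with pytest.raises(np.linalg.LinAlgError, match="singular|ill-conditioned"):
            estimate_connectivity(x, s, trial=7)


class TestEnergies:
    def test_internal_energy_zero_residual(self):
        val = internal_energy([0.0, 0.0], [0.0, 0.0], np.zeros((2, 2)), np.eye(2))
        assert np.isclose(val, LOG_2PI)

    def test_internal_energy_unit_residual(self):
        val = internal_energy([0.0, 0.0], [1.0, 0.0], np.zeros((2, 2)), np.eye(2))
        assert np.isclose(val, 0.5 + LOG_2PI)

    def test_internal_energy_quadratic_form_oracle(self, rng):
        S = np.array([[0.5, 0.2], [0.2, 0.8]])
        W = rng.standard_normal((2, 2))
        s_t = rng.random(2)
        x_t = rng.random(2)
        xi = x_t - W @ s_t
        a, b, c, d = S.ravel()
        inv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
        expect = 0.5 * xi @ inv @ xi + 0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(S))
        assert np.isclose(internal_energy(s_t, x_t, W, S), expect)

    def test_expected_energy_closed_forms(self):
        assert np.isclose(expected_energy(np.eye(2)), 1 + LOG_2PI)
        assert np.isclose(expected_energy(np.e**2 * np.eye(2)), 3 + LOG_2PI)

    def test_expected_energy_monte_carlo_oracle(self, rng):
        """Closed form matches the Monte-Carlo mean of the per-event energy
        over xi ~ N(0, Sigma) within 3 SE."""
        A = rng.standard_normal((2, 2))
        S = A @ A.T + 0.5 * np.eye(2)
        n = 100_000
        xi = rng.multivariate_normal(np.zeros(2), S, size=n)
        inv = np.linalg.inv(S)
        vals = 0.5 * np.einsum("ti,ij,tj->t", xi, inv, xi) + 0.5 * np.log(
            (2 * np.pi) ** 2 * np.linalg.det(S)
        )
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(expected_energy(S) - vals.mean()) < 3 * se

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            expected_energy(np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            internal_energy([0, 0], [0, 0], np.zeros((2, 2)), np.zeros((2, 2)))


class TestRecognition:
    U = np.zeros((2, 80), dtype=np.int8)
    U[0, 20:40] = 1
    U[1, 40:60] = 1
    U[0, 60:] = 1
    U[1, 60:] = 1

    def test_constant_per_state(self):
        x = np.zeros((2, 80))
        for k, (a, b) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
            m = (self.U[0] == a) & (self.U[1] == b)
            x[:, m] = k + 1.0
        gmm = fit_recognition(x, self.U)
        assert np.allclose(gmm.means, np.repeat([[1.0], [2.0], [3.0], [4.0]], 2, 1))
        assert np.allclose(gmm.covs, 0.0)
        assert gmm.means.shape[0] == 4  # component count fixed by design

    def test_moment_recovery(self, rng):
        means = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], dtype=float)
        n_per = 2000
        u = np.zeros((2, 4 * n_per), dtype=np.int8)
        x = np.empty((2, 4 * n_per))
        for k, (a, b) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
            sl = slice(k * n_per, (k + 1) * n_per)
            u[0, sl], u[1, sl] = a, b
            x[:, sl] = (means[k][:, None] + 0.5 * rng.standard_normal((2, n_per)))
        gmm = fit_recognition(x, u)
        assert np.abs(gmm.means - means).max() < 0.05
        assert np.abs(gmm.covs - 0.25 * np.eye(2)).max() < 0.03

    def test_sparse_state_flagged(self):
        u = np.zeros((2, 80), dtype=np.int8)
        u[0, 0] = 1  # state (1,0) has a single event
        u[1, 40:] = 1
        with pytest.raises(ValueError, match="flagged missing"):
            fit_recognition(np.random.default_rng(0).random((2, 80)), u)


class TestEntropy:
    def test_well_separated_mixture(self, rng):
        """Far-apart equal spherical components: H ~= log 4 + component
        Gaussian entropy."""
        sd = 0.1
        centers = np.array([[0, 0], [50, 0], [0, 50], [50, 50]], dtype=float)
        n_per = 500
        u = np.zeros((2, 4 * n_per), dtype=np.int8)
        x = np.empty((2, 4 * n_per))
        for k, (a, b) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
            sl = slice(k * n_per, (k + 1) * n_per)
            u[0, sl], u[1, sl] = a, b
            x[:, sl] = centers[k][:, None] + sd * rng.standard_normal((2, n_per))
        gmm = fit_recognition(x, u)
        H = entropy_plugin(x, gmm)
        comp_entropy = 0.5 * np.log((2 * np.pi * np.e) ** 2 * sd**4)
        assert abs(H - (np.log(4) + comp_entropy)) < 0.05

    def test_degenerate_mixture_is_single_gaussian(self, rng):
        x = 0.7 * rng.standard_normal((2, 4000))
        u = np.zeros((2, 4000), dtype=np.int8)
        u[0, 1000:2000] = 1
        u[1, 2000:3000] = 1
        u[:, 3000:] = 1
        gmm = fit_recognition(x, u)
        H = entropy_plugin(x, gmm)
        cov = np.cov(x, bias=True)
        expect = 0.5 * np.log((2 * np.pi * np.e) ** 2 * np.linalg.det(cov))
        assert abs(H - expect) < 0.05

    def test_widening_components_increases_entropy(self, rng):
        x = rng.standard_normal((2, 400))
        u = np.zeros((2, 400), dtype=np.int8)
        u[0, 100:200] = 1
        u[1, 200:300] = 1
        u[:, 300:] = 1
        gmm = fit_recognition(x, u)
        H1 = entropy_plugin(x, gmm)
        import dataclasses

        wider = dataclasses.replace(gmm, covs=gmm.covs * 4.0)
        assert entropy_plugin(x, wider) > H1


class TestFreeEnergy:
    def test_identity_exact(self, analyzed):
        fep = analyzed.fep
        assert np.allclose(fep["F"], fep["U"] - fep["H"], atol=0.0)

    def test_zero_when_terms_equal(self):
        dec = free_energy(1.234, 1.234)
        assert dec.F == 0.0

    def test_training_decreases_free_energy(self, analyzed):
        fep = analyzed.fep
        assert fep["F"].iloc[-1] < fep["F"].iloc[0]


class TestGammaNorm:
    def test_identity_matrix(self):
        assert np.isclose(gamma_norm(np.eye(2), 2.0), np.sqrt(2))
        assert np.isclose(gamma_norm(np.eye(2), 1.0), 2.0)

    def test_direct_evaluation(self, rng):
        W = rng.standard_normal((2, 2))
        direct = (np.abs(W) ** 4).sum() ** 0.25
        assert np.isclose(gamma_norm(W, 4.0), direct)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            gamma_norm(np.eye(2), 0.0)


def test_conditional_residual_covs_shapes(rng):
    x, s, W = random_series(rng, n_events=64)
    u = np.zeros((2, 64), dtype=np.int8)
    u[0, ::4] = 1
    u[1, 1::4] = 1
    u[:, 2::4] = 1
    covs = conditional_residual_covs(x, s, u, W)
    assert covs.shape == (4, 2, 2)
    assert np.allclose(covs, np.swapaxes(covs, 1, 2))


def test_trajectory_reports_gamma_norms(analyzed):
    """The per-trial table carries gamma-norms consistent with the
    connectivity entries they summarize."""
    fep = analyzed.fep
    row = fep.iloc[49]
    W = np.array([[row["W11"], row["W12"]], [row["W21"], row["W22"]]])
    for g in (1.0, 2.0, 4.0):
        assert np.isclose(row[f"gamma_norm_{g:g}"], gamma_norm(W, g))
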