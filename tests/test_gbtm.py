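"""Trajectory-model correctness: likelihood oracles, EM behaviour, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from jiatraj import (CohortTable, GbtmParameters, TrajectorySpec,
                     assign_groups, average_posterior_probability, bic,
                     fit_gbtm, generate_cohort, individual_log_likelihood,
                     posterior_probabilities, predicted_trajectories,
                     relative_entropy)
from jiatraj.gbtm import _canonical_order
from jiatraj.likelihoods import censnorm_log_density

from conftest import hand_params, one_group_config, oracle_gbtm_loglik, two_group_config


def _visits(rows):
    return pd.DataFrame(rows, columns=["time_years", "ajc", "pga_cm", "pge_cm"])


def match_groups(true_labels, assignment, k):
    """Map fitted group indices onto true ones by maximal overlap."""
    C = np.zeros((k, k))
    np.add.at(C, (true_labels, assignment), 1)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows
    return perm


class TestIndividualLikelihood:
    def test_matches_brute_force_enumeration(self):
        """Mixture likelihood equals group-by-group enumeration in plain
        probability space, for K up to 3 and up to 3 visits (incl. censored
        values and missing components)."""
        cases = [
            (1, _visits([(0.0, 2, 3.0, 2.5)])),
            (2, _visits([(0.0, 0, 0.0, 2.5), (1.0, 1, 4.0, np.nan)])),
            (3, _visits([(0.0, 5, 10.0, 2.5), (1.0, np.nan, 4.0, 0.0),
                         (3.0, 2, 3.3, 7.1)])),
        ]
        for k, visits in cases:
            params = hand_params(k=k, order=2)
            got = individual_log_likelihood(params, visits)
            want = oracle_gbtm_loglik(params, visits)
            assert got == pytest.approx(want, abs=1e-10)

    def test_single_group_is_plain_sum_of_densities(self):
        params = hand_params(k=1, order=1)
        visits = _visits([(0.0, 2, 3.0, 2.5), (2.0, 1, 2.0, 1.0)])
        total = 0.0
        for _, r in visits.iterrows():
            from jiatraj.likelihoods import polynomial_eta, zip_log_pmf
            lam = math.exp(polynomial_eta(params.beta["ajc"][0], r.time_years))
            total += zip_log_pmf(int(r.ajc), rate=lam, p_zero=params.p_zero[0])
            for j in ("pga_cm", "pge_cm"):
                mu = polynomial_eta(params.beta[j][0], r.time_years)
                total += censnorm_log_density(r[j], mu=mu, sigma=params.sigma[j])
        assert individual_log_likelihood(params, visits) == pytest.approx(total)

    def test_identical_groups_collapse_to_single_group_value(self):
        p1 = hand_params(k=1, order=1)
        p2 = GbtmParameters(
            pi=np.array([0.5, 0.5]),
            beta={j: np.vstack([b, b]) for j, b in p1.beta.items()},
            sigma=dict(p1.sigma), p_zero=np.repeat(p1.p_zero, 2))
        visits = _visits([(0.0, 3, 4.0, 2.0), (1.0, 0, 1.0, 0.0)])
        assert individual_log_likelihood(p2, visits) == pytest.approx(
            individual_log_likelihood(p1, visits), abs=1e-12)


class TestPosteriors:
    def _cohort(self):
        df = pd.DataFrame({
            "individual_id": ["a", "a", "b"], "time_years": [0.0, 1.0, 0.0],
            "ajc": [2.0, 1.0, 8.0], "pga_cm": [3.0, 2.0, 7.0],
            "pge_cm": [2.0, 2.0, 8.0]})
        return CohortTable(data=df)

    def test_identical_groups_give_uniform_rows(self):
        p1 = hand_params(k=1, order=1)
        p2 = GbtmParameters(
            pi=np.array([0.5, 0.5]),
            beta={j: np.vstack([b, b]) for j, b in p1.beta.items()},
            sigma=dict(p1.sigma), p_zero=np.repeat(p1.p_zero, 2))
        post = posterior_probabilities(p2, self._cohort())
        np.testing.assert_allclose(post, 0.5)

    def test_degenerate_prior_forces_first_column(self):
        p = hand_params(k=2, order=1)
        p.pi = np.array([1.0, 0.0])
        post = posterior_probabilities(p, self._cohort())
        np.testing.assert_allclose(post[:, 0], 1.0)

    def test_bayes_rule_hand_computation(self):
        params = hand_params(k=2, order=1)
        visits = _visits([(0.0, 1, 3.0, 2.0)])
        df = visits.assign(individual_id="x")
        post = posterior_probabilities(params, CohortTable(data=df))
        num = [math.exp(oracle_gbtm_loglik(
            GbtmParameters(pi=np.array([1.0]),
                           beta={j: b[[g]] for j, b in params.beta.items()},
                           sigma=params.sigma, p_zero=params.p_zero[[g]]),
            visits)) * params.pi[g] for g in (0, 1)]
        np.testing.assert_allclose(post[0], np.array(num) / sum(num), atol=1e-12)

    def test_rows_sum_to_one(self):
        post = posterior_probabilities(hand_params(k=3, order=1), self._cohort())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestDiagnostics:
    def test_assignment_argmax_and_ties(self):
        post = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])
        np.testing.assert_array_equal(assign_groups(post), [1, 0, 0])

    def test_bic_closed_form_and_monotonicity(self):
        assert bic(-100.0, 5, 100) == pytest.approx(200 + 5 * math.log(100))
        assert bic(-100.0, 0, 100) == pytest.approx(200.0)
        values = [bic(-100.0, k, 50) for k in range(6)]
        assert np.all(np.diff(values) > 0)

    def test_relative_entropy_closed_forms(self):
        one_hot = np.eye(3)[[0, 1, 2, 0]]
        assert relative_entropy(one_hot) == pytest.approx(1.0)
        uniform = np.full((5, 4), 0.25)
        assert relative_entropy(uniform) == pytest.approx(0.0, abs=1e-12)
        two = np.array([[0.9, 0.1], [0.5, 0.5]])
        expected = 1 - (-(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
                        + math.log(2)) / (2 * math.log(2))
        assert relative_entropy(two) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.2656, abs=1e-4)
        assert relative_entropy(np.ones((4, 1))) == 1.0

    def test_average_posterior_probability(self):
        post = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        assignment = np.array([0, 0, 1])
        app, overall = average_posterior_probability(post, assignment)
        assert app[0] == pytest.approx(0.7)
        assert app[1] == pytest.approx(0.9)
        assert overall == pytest.approx((0.8 + 0.6 + 0.9) / 3)

    def test_app_overall_is_size_weighted_group_mean(self):
        rng = np.random.default_rng(3)
        post = rng.dirichlet(np.ones(4), size=50)
        a = assign_groups(post)
        app, overall = average_posterior_probability(post, a)
        sizes = np.bincount(a, minlength=4)
        ok = sizes > 0
        assert overall == pytest.approx(
            np.sum(app[ok] * sizes[ok]) / sizes.sum())

    def test_app_flags_empty_group(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        app, _ = average_posterior_probability(post, np.array([0, 0]))
        assert np.isnan(app[1])


class TestPredictedTrajectories:
    def test_tiny_sigma_recovers_latent_mean(self):
        p = hand_params(k=1, order=0)
        p.beta = {"ajc": np.array([[0.0]]), "pga_cm": np.array([[5.0]]),
                  "pge_cm": np.array([[5.0]])}
        p.sigma = {"pga_cm": 1e-8, "pge_cm": 1e-8}
        curves = predicted_trajectories(p, [0.0, 1.0])
        np.testing.assert_allclose(curves["pga_cm"], 5.0, atol=1e-6)

    def test_total_inflation_zeroes_the_count_curve(self):
        p = hand_params(k=1, order=0)
        p.p_zero = np.array([1.0])
        curves = predicted_trajectories(p, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(curves["ajc"], 0.0)

    def test_censored_mean_matches_quadrature(self):
        p = hand_params(k=1, order=0)
        p.beta["pga_cm"] = np.array([[0.0]])
        p.sigma["pga_cm"] = 1.0
        curves = predicted_trajectories(p, [0.0])
        interior, _ = integrate.quad(
            lambda y: y * math.exp(censnorm_log_density(y, mu=0.0, sigma=1.0)),
            0.0, 10.0)
        want = interior + 10.0 * math.exp(censnorm_log_density(10.0, mu=0.0, sigma=1.0))
        assert curves["pga_cm"][0, 0] == pytest.approx(want, abs=1e-9)


class TestFitting:
    def test_single_group_fit_recovers_generating_curves(self):
        cfg = one_group_config(500, 2)
        cohort, _ = generate_cohort(cfg)
        fit = fit_gbtm(cohort, TrajectorySpec(1, 1), n_starts=1, seed=2)
        g = cfg.groups[0]
        # trajectory coefficients back within a generous Monte-Carlo band
        np.testing.assert_allclose(fit.params.beta["pga_cm"][0], g.pga_beta, atol=0.25)
        np.testing.assert_allclose(fit.params.beta["ajc"][0], g.ajc_beta, atol=0.3)
        assert fit.params.p_zero[0] == pytest.approx(g.ajc_p_zero, abs=0.1)
        assert fit.params.sigma["pga_cm"] == pytest.approx(cfg.sigma_pga, abs=0.1)

    def test_two_separated_groups_recovered_almost_perfectly(self):
        cfg = two_group_config(400, 3)
        cohort, truth = generate_cohort(cfg)
        fit = fit_gbtm(cohort, TrajectorySpec(2, 1), n_starts=2, seed=3)
        ids = pd.Series(truth.labels,
                        index=[f"id{i:05d}" for i in range(400)])
        tl = ids.loc[fit.individual_ids].to_numpy()
        assert adjusted_rand_score(tl, fit.assignment) > 0.95
        perm = match_groups(tl, fit.assignment, 2)
        pi_mapped = np.empty(2)
        for c in range(2):
            pi_mapped[perm[c]] = fit.params.pi[c]
        np.testing.assert_allclose(pi_mapped, [0.6, 0.4], atol=0.03)

    def test_em_loglik_is_monotone(self):
        cohort, _ = generate_cohort(two_group_config(150, 5))
        fit = fit_gbtm(cohort, TrajectorySpec(2, 1), n_starts=1, seed=5)
        diffs = np.diff(fit.loglik_history)
        assert np.all(diffs >= -1e-8 * (np.abs(fit.loglik) + 1))

    def test_posterior_rows_sum_to_one_and_entropy_in_range(self):
        cohort, _ = generate_cohort(two_group_config(150, 6))
        fit = fit_gbtm(cohort, TrajectorySpec(2, 1), n_starts=1, seed=6)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert 0.0 <= fit.entropy <= 1.0
        assert np.nanmin(fit.app) >= 1.0 / 2

    def test_canonical_relabelling_is_permutation_invariant(self):
        params = hand_params(k=3, order=1)
        base_order = _canonical_order(params)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(3)
            shuffled = params.permuted(perm)
            canon = shuffled.permuted(_canonical_order(shuffled))
            want = params.permuted(base_order)
            np.testing.assert_allclose(canon.pi, want.pi)
            np.testing.assert_allclose(canon.beta["ajc"], want.beta["ajc"])

    def test_parameter_json_round_trip(self):
        params = hand_params(k=2, order=2)
        again = GbtmParameters.from_dict(params.to_dict())
        np.testing.assert_allclose(again.pi, params.pi)
        for j in params.beta:
            np.testing.assert_allclose(again.beta[j], params.beta[j])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TrajectorySpec(0, 1)
        with pytest.raises(ValueError):
            TrajectorySpec(3, 4)
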