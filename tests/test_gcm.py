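"""GCM response model, sampler, scree analysis and resilience rerun."""

import numpy as np
import pytest

from kanocca import (
    DichotomizationScheme,
    GCMParameters,
    MCMCSettings,
    binary_matrix,
    fit_gcm,
    gcm_response_probability,
    generate_gcm_survey,
    posterior_predictive_check,
    resilience_rerun,
    scree_analysis,
    simulate_gcm,
)
from kanocca.synthetic import case_study_gcm_parameters

FAST = dict(chains=2, samples=1500, burnin=500, seed=7)


def _params(theta, g, delta, z):
    return GCMParameters(
        theta=np.atleast_1d(theta),
        g=np.atleast_1d(g),
        delta=np.atleast_1d(delta),
        z=np.atleast_1d(z),
    )


class TestResponseProbability:
    def test_perfect_competency_reproduces_truth(self):
        assert gcm_response_probability(1.0, 0.9, 0.5, 1) == 1.0
        assert gcm_response_probability(1.0, 0.9, 0.5, 0) == 0.0

    def test_zero_competency_is_pure_guessing(self):
        for z in (0, 1):
            assert gcm_response_probability(0.0, 0.3, 0.5, z) == pytest.approx(0.3)

    def test_hand_computed_value(self):
        # theta = delta = 0.5 -> D = 0.5; z=1, g=0.4 -> 0.5 + 0.5*0.4
        assert gcm_response_probability(0.5, 0.4, 0.5, 1) == pytest.approx(0.7)

    def test_degenerate_accuracy_defined_as_half(self):
        # theta=0, delta=0 makes D a 0/0 limit, defined as 0.5
        assert gcm_response_probability(0.0, 0.0, 0.0, 1) == pytest.approx(0.5)

    def test_monotone_in_theta_and_delta(self):
        thetas = np.linspace(0.01, 0.99, 25)
        p = gcm_response_probability(thetas, 0.3, 0.4, 1)
        assert np.all(np.diff(p) > 0)
        deltas = np.linspace(0.01, 0.99, 25)
        p = gcm_response_probability(0.6, 0.3, deltas, 1)
        assert np.all(np.diff(p) < 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            gcm_response_probability(1.2, 0.3, 0.5, 1)
        with pytest.raises(ValueError):
            gcm_response_probability(0.5, 0.3, 0.5, 2)


class TestSimulate:
    def test_same_seed_same_matrix(self):
        params = case_study_gcm_parameters(seed=0, n_respondents=20)
        assert np.array_equal(simulate_gcm(params, 42), simulate_gcm(params, 42))

    def test_perfect_competency_rows_equal_truth(self):
        z = np.array([1, 0, 1, 1, 0])
        params = _params(np.ones(10), np.full(10, 0.3), np.full(5, 0.5), z)
        Y = simulate_gcm(params, 1)
        assert np.array_equal(Y, np.tile(z, (10, 1)))

    def test_pure_guessing_cell_mean(self):
        params = _params(np.zeros(400), np.full(400, 0.3), np.full(50, 0.5), np.ones(50, int))
        Y = simulate_gcm(params, 2)
        assert Y.mean() == pytest.approx(0.3, abs=0.01)


class TestFit:
    def test_noiseless_limit_recovers_truth_exactly(self):
        z = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        params = _params(np.ones(30), np.full(30, 0.4), np.full(8, 0.5), z)
        Y = simulate_gcm(params, 3)
        post = fit_gcm(Y, **FAST)
        assert np.array_equal(post.binary_truth, z)
        assert np.allclose(post.item_truth, z, atol=0.01)

    def test_moderate_recovery_and_convergence(self, rng):
        """Competency and low-difficulty truths recover on an 80x10 design.

        Guessing bias is left unasserted here: with high competency and few
        items, knowers rarely guess and the bias is weakly informed.
        """
        params = _params(
            rng.uniform(0.5, 0.9, 80), rng.uniform(0.2, 0.5, 80),
            np.linspace(0.1, 0.9, 10), rng.integers(0, 2, 10),
        )
        Y = simulate_gcm(params, 4)
        post = fit_gcm(Y, chains=3, samples=3000, burnin=1500, seed=8)
        easy = params.delta <= 0.5
        assert np.array_equal(post.binary_truth[easy], params.z[easy])
        assert post.theta_mean == pytest.approx(params.theta.mean(), abs=0.08)
        assert post.max_rhat < 1.1
        # decisive truths are stable across chains
        for k in range(10):
            if post.item_truth[k] > 0.95 or post.item_truth[k] < 0.05:
                assert np.ptp(post.chain_item_truth[:, k]) < 0.05

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            fit_gcm(np.full((4, 4), 2.0), **FAST)

    def test_rejects_too_small(self):
        with pytest.raises(ValueError):
            fit_gcm(np.ones((1, 5)), **FAST)

    def test_warns_on_constant_rows(self):
        Y = np.array([[1, 1, 1], [0, 1, 0], [1, 0, 1], [0, 0, 1]])
        with pytest.warns(UserWarning, match="constant"):
            fit_gcm(Y, chains=1, samples=50, burnin=20, seed=0)

    def test_missing_cells_are_tolerated(self):
        params = _params(np.full(20, 0.9), np.full(20, 0.3), np.full(6, 0.5),
                         np.array([1, 0, 1, 0, 1, 0]))
        Y = simulate_gcm(params, 5).astype(float)
        Y[0, 0] = np.nan
        Y[3, 2] = np.nan
        post = fit_gcm(Y, **FAST)
        assert np.array_equal(post.binary_truth, params.z)


class TestScree:
    def test_single_culture_detected(self, rng):
        params = _params(
            rng.uniform(0.6, 0.9, 60), rng.uniform(0.2, 0.5, 60),
            np.full(14, 0.5), rng.integers(0, 2, 14),
        )
        res = scree_analysis(simulate_gcm(params, 6))
        assert res.n_cultures == 1
        assert res.ratio_first_second >= 1.75
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_opposed_cultures_flagged(self, rng):
        z = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        pa = _params(rng.uniform(0.6, 0.9, 50), np.full(50, 0.3), np.full(14, 0.5), z)
        pb = _params(rng.uniform(0.6, 0.9, 50), np.full(50, 0.3), np.full(14, 0.5), 1 - z)
        Y = np.vstack([simulate_gcm(pa, 7), simulate_gcm(pb, 8)])
        res = scree_analysis(Y)
        assert res.n_cultures == 2
        assert res.negative_loading_fraction > 0.25

    def test_zero_variance_respondents_omitted(self):
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 2, (20, 10))
        Y[:, 0] = 0
        Y[:, 1] = 1  # every respondent has variance by construction ...
        Y[3] = 1
        Y[11] = 0    # ... except these two
        res = scree_analysis(Y)
        assert res.n_omitted == 2
        assert res.eigenvalues.size == 18

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            scree_analysis(np.ones((5, 4)))


class TestPPC:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(3)
        params = _params(
            rng.uniform(0.5, 0.9, 60), rng.uniform(0.2, 0.5, 60),
            rng.uniform(0.3, 0.7, 10), rng.integers(0, 2, 10),
        )
        Y = simulate_gcm(params, 9)
        return Y, fit_gcm(Y, **FAST)

    def test_self_consistency(self, fitted):
        Y, post = fitted
        res = posterior_predictive_check(post, Y, n_replicates=100, seed=1)
        assert 2.5 < res["percentile"] < 97.5

    def test_rejects_zero_replicates(self, fitted):
        Y, post = fitted
        with pytest.raises(ValueError):
            posterior_predictive_check(post, Y, n_replicates=0)

    def test_detects_two_culture_misfit(self, rng):
        z = np.array([1, 0] * 5)
        pa = _params(rng.uniform(0.7, 0.95, 40), np.full(40, 0.3), np.full(10, 0.5), z)
        pb = _params(rng.uniform(0.7, 0.95, 40), np.full(40, 0.3), np.full(10, 0.5), 1 - z)
        Y = np.vstack([simulate_gcm(pa, 10), simulate_gcm(pb, 11)])
        post = fit_gcm(Y, **FAST)
        res = posterior_predictive_check(post, Y, n_replicates=100, seed=2)
        assert res["percentile"] > 95 or res["percentile"] < 5


class TestResilience:
    @pytest.fixture(scope="class")
    def survey(self):
        params = case_study_gcm_parameters(seed=11, n_respondents=60)
        return generate_gcm_survey(params, seed=12)[0]

    def test_empty_drop_list_matches_base(self, survey):
        settings = MCMCSettings(chains=1, samples=600, burnin=300, seed=5)
        base = resilience_rerun(survey, [], settings)
        again = resilience_rerun(survey, [], settings)
        assert not base.changed
        assert {a: str(r.cca) for a, r in base.classifications.items()} == {
            a: str(r.cca) for a, r in again.classifications.items()
        }

    def test_unknown_drop_id_rejected(self, survey):
        with pytest.raises(Exception, match="unknown"):
            survey.drop_attributes(["nope"])

    def test_dropping_almost_all_items_rejected(self, survey):
        ids = [a.id for a in survey.attributes]
        with pytest.raises(Exception, match="fewer than 2"):
            survey.drop_attributes(ids[:-1])

    def test_decisive_truths_survive_item_removal(self, rng):
        # mirror the robustness design: competent cohort, ten easy items
        # plus four near-0.5-difficulty items; dropping the ambiguous four
        # leaves the remaining consensus classifications unchanged
        params = _params(
            rng.uniform(0.55, 0.85, 80),
            np.full(80, 0.3),
            np.concatenate([np.linspace(0.15, 0.35, 10), np.full(4, 0.5)]),
            rng.integers(0, 2, 14),
        )
        survey, _ = generate_gcm_survey(params, seed=13)
        settings = MCMCSettings(chains=2, samples=1500, burnin=500, seed=6)
        base = resilience_rerun(survey, [], settings)
        res = resilience_rerun(
            survey,
            ["item11", "item12", "item13", "item14"],
            settings,
            base_classifications=base.classifications,
        )
        assert not res.changed
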