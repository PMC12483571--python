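"""Similarity kernel, assignment probabilities, KL fitting and LOO comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import socmap as sm
from socmap import bias_model
from socmap.exceptions import ConfigurationError, StructuralError


def random_instance(rng, n, active=3):
    D = rng.normal(size=(n, 3))
    C = np.zeros((n, n, 3))
    for k in range(3):
        M = np.triu(rng.integers(0, 2, size=(n, n)), 1)
        C[:, :, k] = M + M.T
    mask = np.array([True] * active + [False] * (3 - active))
    params = sm.BiasParams(
        beta=rng.uniform(0, 3, 3),
        beta_hat=rng.uniform(0, 3, 3),
        alpha=float(rng.uniform(0.1, 3)),
        active_mask=mask,
    )
    return D, C, params


def brute_force_probs(D, C, params):
    """Independent per-entry evaluation of the kernel and normalization."""
    n = len(D)
    P = np.zeros((n, n))
    for i in range(n):
        f = []
        for j in range(n):
            if i == j:
                f.append(params.alpha)
            else:
                v = 1.0
                for k in range(3):
                    if not params.active_mask[k]:
                        continue
                    rate = (
                        C[i, j, k] * params.beta[k]
                        + (1 - C[i, j, k]) * params.beta_hat[k]
                    )
                    v *= np.exp(-rate * (D[i, k] - D[j, k]) ** 2)
                f.append(v)
        P[i] = np.array(f) / sum(f)
    return P


class TestSimilarity:
    def test_self_similarity_is_alpha(self):
        p = sm.BiasParams(beta=np.ones(3), beta_hat=np.ones(3), alpha=0.37,
                          active_mask=np.ones(3, bool))
        assert sm.similarity_f(np.zeros(3), np.ones(3), np.ones(3), p, same=True) == 0.37

    def test_identical_attributes_give_one(self):
        p = sm.BiasParams(beta=np.array([5.0, 2, 1]), beta_hat=np.ones(3),
                          alpha=1.0, active_mask=np.ones(3, bool))
        d = np.array([0.3, -0.2, 1.0])
        assert sm.similarity_f(d, d, np.ones(3), p) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # unit difference on dim 1, shared condition, beta_1 = 0.5 -> e^-0.5
        p = sm.BiasParams(beta=np.array([0.5, 1, 1]), beta_hat=np.ones(3),
                          alpha=1.0, active_mask=np.ones(3, bool))
        f = sm.similarity_f(
            np.array([1.0, 0, 0]), np.zeros(3), np.array([1.0, 0, 0]), p
        )
        assert f == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        D, C, params = random_instance(rng, 5)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert sm.similarity_f(D[i], D[j], C[i, j], params) == pytest.approx(
                        sm.similarity_f(D[j], D[i], C[j, i], params)
                    )

    def test_negative_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            sm.BiasParams(beta=np.array([-1.0, 1, 1]), beta_hat=np.ones(3),
                          alpha=1.0, active_mask=np.ones(3, bool))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            sm.BiasParams(beta=np.ones(3), beta_hat=np.ones(3), alpha=0.0)


class TestAssignmentProbs:
    def test_uniform_case_n3(self):
        # all biases zero and alpha = 1: every entry (incl. diagonal) is 1/3
        D = np.arange(9.0).reshape(3, 3)
        C = np.zeros((3, 3, 3))
        p = sm.BiasParams(beta=np.zeros(3), beta_hat=np.zeros(3), alpha=1.0,
                          active_mask=np.ones(3, bool))
        P = sm.assignment_probs(D, C, p).P
        assert np.allclose(P, 1 / 3)

    def test_uniform_limit_closed_form(self):
        # beta -> 0: off-diagonal entries are 1/(N-1+alpha)
        rng = np.random.default_rng(1)
        D, C, _ = random_instance(rng, 6)
        p = sm.BiasParams(beta=np.zeros(3), beta_hat=np.zeros(3), alpha=0.7,
                          active_mask=np.ones(3, bool))
        P = sm.assignment_probs(D, C, p).P
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(P[off], 1 / (5 + 0.7))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            D, C, params = random_instance(rng, n)
            P = sm.assignment_probs(D, C, params).P
            assert np.abs(P - brute_force_probs(D, C, params)).max() < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 8),
        alpha=st.floats(0.01, 10),
    )
    def test_rows_sum_to_one(self, seed, n, alpha):
        rng = np.random.default_rng(seed)
        D, C, _ = random_instance(rng, n)
        params = sm.BiasParams(
            beta=rng.uniform(0, 5, 3), beta_hat=rng.uniform(0, 5, 3),
            alpha=alpha, active_mask=np.ones(3, bool),
        )
        P = sm.assignment_probs(D, C, params).P
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestEmpiricalProbs:
    def test_equilateral_triangle(self):
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        P = sm.empirical_probs(tri).P
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(P[off], 0.5)
        assert np.all(np.diag(P) == 0)

    def test_inverse_distance_ratio(self):
        # node at distance 2 gets half the unnormalized weight of distance 1
        coords = np.array([[0.0, 0], [1.0, 0], [-2.0, 0]])
        P = sm.empirical_probs(coords).P
        assert P[0, 1] / P[0, 2] == pytest.approx(2.0)

    def test_random_rows_stochastic(self):
        rng = np.random.default_rng(0)
        P = sm.empirical_probs(rng.uniform(size=(8, 2))).P
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(np.diag(P) == 0)

    def test_coincident_without_epsilon(self):
        coords = np.array([[0.0, 0], [0.0, 0], [1, 1]])
        with pytest.raises(StructuralError):
            sm.empirical_probs(coords, epsilon=0.0)


class TestKlRows:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(3)
        P = sm.empirical_probs(rng.uniform(size=(5, 2)))
        assert sm.kl_rows(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        emp = bias_model.ProbMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), "empirical")
        model = bias_model.ProbMatrix(np.array([[0.6, 0.4], [0.3, 0.7]]), "model")
        # closed form: 1*log(1/0.4) + 1*log(1/0.3)
        expected = np.log(1 / 0.4) + np.log(1 / 0.3)
        assert sm.kl_rows(emp, model) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_versus_offdiagonal_renormalized_model(self, seed):
        rng = np.random.default_rng(seed)
        emp = sm.empirical_probs(rng.uniform(size=(6, 2)))
        D, C, params = random_instance(rng, 6)
        model = sm.assignment_probs(D, C, params)
        # Gibbs: KL vs the model's off-diagonal rows renormalized is >= 0;
        # keeping the alpha mass in the denominator only adds to it
        assert sm.kl_rows(emp, model) >= 0


@pytest.fixture(scope="module")
def problem(ring_net):
    D = sm.attribute_matrix(ring_net)
    C = sm.condition_tensor(ring_net)
    gen = sm.BiasParams(beta=np.array([2.0, 0.5, 0]),
                        beta_hat=np.array([1.0, 0.25, 0]), alpha=1.0)
    pm = sm.simulate_placements(ring_net, gen, 1, noise_sd=0.0, seed=7)[0]
    return D, C, pm


class TestFit:

    def test_beats_random_parameter_draws(self, problem):
        D, C, pm = problem
        mask = np.array([True, True, False])
        fr = sm.fit(pm, D, C, "biased", active_mask=mask)
        emp = sm.empirical_probs(pm)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(500):
            params = sm.BiasParams(
                beta=rng.uniform(0, 4, 3), beta_hat=rng.uniform(0, 4, 3),
                alpha=float(rng.uniform(0.05, 4)), active_mask=mask,
            )
            draws.append(sm.kl_rows(emp, sm.assignment_probs(D, C, params)))
        assert fr.final_kl < np.quantile(draws, 0.05)

    def test_final_kl_never_exceeds_init(self, problem):
        D, C, pm = problem
        for variant in ("biased", "unbiased"):
            for seed in range(5):
                fr = sm.fit(pm, D, C, variant, seed=seed,
                            init=np.random.default_rng(seed).normal(size=5 if variant == "biased" else 2))
                assert fr.final_kl <= fr.init_kl + 1e-12

    def test_multistart_stability(self, problem):
        D, C, pm = problem
        kls = [
            sm.fit(pm, D, C, "biased", seed=s, n_starts=5).final_kl
            for s in range(3)
        ]
        assert max(kls) - min(kls) < 1e-6

    def test_parameter_counts(self):
        mask2 = np.array([True, True, False])
        mask3 = np.ones(3, bool)
        assert bias_model._n_free("unbiased", mask2) == 2
        assert bias_model._n_free("unbiased", mask3) == 2
        assert bias_model._n_free("biased", mask2) == 5
        assert bias_model._n_free("biased", mask3) == 7

    def test_matches_scipy_trust_region(self, problem):
        from scipy import optimize

        D, C, pm = problem
        mask = np.array([True, True, False])
        fr = sm.fit(pm, D, C, "biased", active_mask=mask)
        E = sm.empirical_probs(pm).P
        res = optimize.minimize(
            bias_model._kl_and_grad, np.zeros(5), args=(E, D, C, "biased", mask),
            jac=True, method="trust-constr", options={"maxiter": 500, "gtol": 1e-10},
        )
        assert fr.final_kl == pytest.approx(res.fun, abs=1e-4)


class TestLooCompare:
    def test_requires_enough_students_and_participants(self, ring_net):
        D = sm.attribute_matrix(ring_net)
        C = sm.condition_tensor(ring_net)
        with pytest.raises(ConfigurationError):
            sm.loo_compare([np.zeros((8, 2))], D, C)
        with pytest.raises(ConfigurationError):
            sm.loo_compare([np.zeros((2, 2))] * 3, D[:2], C[:2, :2])

    def test_heldout_row_not_used_in_fitting(self, ring_net, monkeypatch):
        # every fit during LOO must see the (N-1)-student sub-problem
        D = sm.attribute_matrix(ring_net)
        C = sm.condition_tensor(ring_net)
        gen = sm.BiasParams(beta=np.array([2.0, 0.5, 0]),
                            beta_hat=np.array([1.0, 0.25, 0]), alpha=1.0)
        pms = sm.simulate_placements(ring_net, gen, 2, noise_sd=0.05, seed=1)
        seen = []
        orig = bias_model.fit

        def spy(pm, D_, C_, *a, **kw):
            seen.append(D_.shape[0])
            return orig(pm, D_, C_, *a, **kw)

        monkeypatch.setattr(bias_model, "fit", spy)
        sm.loo_compare(pms, D, C, max_iter=20)
        assert seen and all(n == 7 for n in seen)
        assert len(seen) == 2 * 8 * 2  # participants x students x variants

    def test_unbiased_generator_gives_no_advantage(self, ring_net):
        D = sm.attribute_matrix(ring_net)
        C = sm.condition_tensor(ring_net)
        gen = sm.BiasParams(beta=np.full(3, 0.8), beta_hat=np.full(3, 0.8), alpha=1.0)
        pms = sm.simulate_placements(ring_net, gen, 6, noise_sd=0.05, seed=3)
        r = sm.loo_compare(pms, D, C, max_iter=40)
        assert r.p_value > 0.05

    def test_biased_generator_detected(self, ring_net):
        D = sm.attribute_matrix(ring_net)
        C = sm.condition_tensor(ring_net)
        gen = sm.BiasParams(beta=np.array([2.0, 0.5, 0]),
                            beta_hat=np.array([1.0, 0.25, 0]), alpha=1.0)
        pms = sm.simulate_placements(ring_net, gen, 6, noise_sd=0.05, seed=3)
        r = sm.loo_compare(pms, D, C, max_iter=40)
        assert r.delta_kl.mean() > 0 and r.t_stat > 0 and r.p_value < 0.05


class TestBiasRecallRegression:
    def test_planted_negative_correlation(self):
        rng = np.random.default_rng(0)
        bias = rng.normal(size=80)
        acc = 0.5 - 0.05 * bias + rng.normal(scale=0.02, size=80)
        rep = sm.bias_recall_regression(bias, acc)
        assert rep.pearson_r < -0.5 and rep.p_values["bias"] < 0.001

    def test_median_split_subgroups(self):
        rng = np.random.default_rng(1)
        bias = rng.normal(size=60)
        mod = rng.normal(size=60)
        acc = 0.5 - 0.05 * bias * (mod < 0) + rng.normal(scale=0.02, size=60)
        rep = sm.bias_recall_regression(bias, acc, moderator=mod)
        assert set(rep.subgroup_r) == {"low", "high"}
        assert rep.subgroup_r["low"] < rep.subgroup_r["high"]

    def test_degenerate_flagged(self):
        rep = sm.bias_recall_regression(np.ones(10), np.linspace(0, 1, 10))
        assert rep.flagged

    def test_null_effect_small_r(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(200):
            rep = sm.bias_recall_regression(
                rng.normal(size=50), rng.normal(size=50)
            )
            rs.append(rep.pearson_r)
        assert abs(np.mean(rs)) < 0.05
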