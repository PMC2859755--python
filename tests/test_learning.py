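import numpy as np
import pytest
from scipy.optimize import minimize

from seqmrf.learning import (
    Classifier,
    TrainingConfig,
    decision_scores,
    map_closed_form,
    map_objective,
    msp_objective,
    posterior_matrix,
    train,
)
from seqmrf.models import (
    LambdaParameters,
    lambda_to_theta,
    lambda_zeros,
    sample_sequences,
    theta_to_lambda,
)
from seqmrf.priors import bdeu_hyperparameters
from seqmrf.seqdata import LabeledDataset, count_statistics
from seqmrf.structures import (
    make_markov_structure,
    make_pairwise_mrf_structure,
    make_pwm_structure,
)

from conftest import random_anchored_lambda


def make_data(structures, rng, n=100, scale=0.8):
    lam = random_anchored_lambda(structures, rng=rng, scale=scale)
    return lam, sample_sequences(lam, n, seed=int(rng.integers(2 ** 31)))


def finite_diff(fun, x0, h=1e-6):
    g = np.zeros_like(x0)
    for j in range(len(x0)):
        up, dn = x0.copy(), x0.copy()
        up[j] += h
        dn[j] -= h
        g[j] = (fun(up) - fun(dn)) / (2 * h)
    return g


class TestMapObjective:
    def test_zero_data_uniform_pseudo_fixed_point(self):
        """With no data, the all-zero lambda is a stationary point of the
        BDeu-uniform posterior."""
        st = make_markov_structure(3, 1, 4)
        structures = (st, st)
        hyper = bdeu_hyperparameters(structures, [4.0, 4.0])
        empty = LabeledDataset([], np.zeros(0, dtype=np.intp))
        counts = count_statistics(empty, structures)
        lam = lambda_zeros(structures)
        _, grad = map_objective(lam, counts, hyper)
        assert np.max(np.abs(grad)) < 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        st = make_markov_structure(3, 1, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=60)
        counts = count_statistics(data, structures)
        hyper = bdeu_hyperparameters(structures, [4.0, 8.0])
        x0 = rng.normal(scale=0.3, size=len(lambda_zeros(structures).to_free_vector()))

        def value(v):
            return map_objective(LambdaParameters.from_free_vector(structures, 2, v),
                                 counts, hyper)[0]

        _, grad = map_objective(LambdaParameters.from_free_vector(structures, 2, x0),
                                counts, hyper)
        assert np.max(np.abs(grad - finite_diff(value, x0))) < 1e-6

    def test_ascent_along_gradient(self, rng):
        st = make_pwm_structure(4, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=50)
        counts = count_statistics(data, structures)
        hyper = bdeu_hyperparameters(structures, [4.0, 4.0])
        x0 = rng.normal(scale=0.3, size=len(lambda_zeros(structures).to_free_vector()))
        v0, g = map_objective(LambdaParameters.from_free_vector(structures, 2, x0),
                              counts, hyper)
        v1, _ = map_objective(
            LambdaParameters.from_free_vector(structures, 2, x0 + 1e-4 * g), counts, hyper)
        assert v1 > v0


class TestMapClosedForm:
    def test_no_data_gives_uniform(self):
        st = make_pwm_structure(3, 4)
        structures = (st, st)
        hyper = bdeu_hyperparameters(structures, [4.0, 12.0])
        empty = LabeledDataset([], np.zeros(0, dtype=np.intp))
        theta = map_closed_form(count_statistics(empty, structures), hyper)
        assert np.allclose(theta.class_probs, [0.25, 0.75])
        assert all(np.allclose(v, 0.25) for v in theta.values)

    def test_smoothed_frequency_arithmetic(self):
        ds = LabeledDataset.from_strings(["A"] * 10, label=0, n_classes=1)
        st = make_pwm_structure(1, 4)
        hyper = bdeu_hyperparameters(st, 4.0, C=1)
        theta = map_closed_form(count_statistics(ds, st), hyper)
        assert np.allclose(theta.values[0], [11 / 14, 1 / 14, 1 / 14, 1 / 14])

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_matches_numerical_optimum(self, order, rng):
        st = make_markov_structure(3, order, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=80)
        counts = count_statistics(data, structures)
        hyper = bdeu_hyperparameters(structures, [4.0, 8.0])
        theta_cf = map_closed_form(counts, hyper)

        def neg(v):
            val, g = map_objective(
                LambdaParameters.from_free_vector(structures, 2, v), counts, hyper)
            return -val, -g

        n = len(lambda_zeros(structures).to_free_vector())
        res = minimize(neg, np.zeros(n), jac=True, method="L-BFGS-B",
                       options={"gtol": 1e-9, "ftol": 1e-15, "maxiter": 5000})
        theta_num = lambda_to_theta(
            LambdaParameters.from_free_vector(structures, 2, res.x))
        assert np.allclose(theta_num.class_probs, theta_cf.class_probs, atol=1e-5)
        for a, b in zip(theta_num.values, theta_cf.values):
            assert np.allclose(a, b, atol=1e-5)


class TestMspObjective:
    def test_gradient_matches_finite_differences(self, rng):
        st = make_markov_structure(3, 1, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=60)
        hyper = bdeu_hyperparameters(structures, [4.0, 8.0])
        x0 = rng.normal(scale=0.3, size=len(lambda_zeros(structures).to_free_vector()))

        def value(v):
            return msp_objective(LambdaParameters.from_free_vector(structures, 2, v),
                                 data, hyper)[0]

        _, grad = msp_objective(LambdaParameters.from_free_vector(structures, 2, x0),
                                data, hyper)
        assert np.max(np.abs(grad - finite_diff(value, x0))) < 1e-6

    def test_huge_ess_pulls_msp_to_map(self, rng):
        """With a dominating prior both principles converge to its mode."""
        st = make_pwm_structure(3, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=40)
        big = 1e6
        map_clf = train(TrainingConfig(principle="MAP", ess=[big, big]),
                        structures, data)
        msp_clf = train(TrainingConfig(principle="MSP", ess=[big, big]),
                        structures, data)
        for a, b in zip(map_clf.params.values, msp_clf.params.values):
            assert np.max(np.abs(a - b)) < 1e-2

    def test_no_spurious_anchoring_invariance(self, rng):
        """Shifting one group's free entries by a constant changes the value:
        the anchored parameterization has no redundant directions."""
        st = make_pwm_structure(3, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=40)
        hyper = bdeu_hyperparameters(structures, [4.0, 4.0])
        lam = random_anchored_lambda(structures, rng=rng)
        v0, _ = msp_objective(lam, data, hyper)
        shifted = lam.copy()
        shifted.values[0][0:3] += 0.7  # free entries of the first group
        v1, _ = msp_objective(shifted, data, hyper)
        assert abs(v1 - v0) > 1e-6


class TestTrain:
    def test_map_pwm_parameter_recovery_improves_with_n(self):
        st = make_pwm_structure(5, 4)
        rng = np.random.default_rng(0)
        lam_true = random_anchored_lambda((st,), rng=rng, scale=0.7)
        theta_true = lambda_to_theta(lam_true)
        errors = []
        for n in (100, 1000, 10_000):
            data = sample_sequences(lam_true, n, seed=n)
            data.n_classes = 1
            clf = train(TrainingConfig(principle="MAP", ess=[1.0]), (st,), data)
            theta_hat = lambda_to_theta(clf.params)
            errors.append(max(np.abs(a - b).max()
                              for a, b in zip(theta_hat.values, theta_true.values)))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.02

    def test_msp_conditional_likelihood_at_least_map(self, rng):
        st = make_markov_structure(4, 1, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=150)
        map_clf = train(TrainingConfig(principle="MAP", ess=[4.0, 4.0]),
                        structures, data)
        msp_clf = train(TrainingConfig(principle="MSP", ess=[4.0, 4.0]),
                        structures, data)

        def cll(clf):
            lp = posterior_matrix(clf.params, data)
            return lp[np.arange(len(data)), data.labels].sum()

        assert cll(msp_clf) >= cll(map_clf) - 1e-6

    def test_mixture_objective_nests_single_model(self, rng):
        """Best-restart 2-component objective >= the single-model objective
        evaluated inside the mixture family (data term + matched priors)."""
        st1 = make_pwm_structure(4, 4)
        st2 = make_pwm_structure(4, 4, components=2)
        # data from two distinct planted PWMs
        comps = [random_anchored_lambda((st1, st1), rng=rng, scale=1.2) for _ in range(2)]
        from seqmrf.models import MixtureParameters
        truth = MixtureParameters(comps, np.zeros((2, 2)), np.zeros(2))
        data = sample_sequences(truth, 300, seed=9)
        single = train(TrainingConfig(principle="MAP", ess=[4.0, 4.0]), st1, data)
        mix = train(TrainingConfig(principle="MAP", ess=[4.0, 4.0], seed=1,
                                   tolerance=1e-4), st2, data)
        lp_single = posterior_matrix(single.params, data)
        lp_mix = posterior_matrix(mix.params, data)
        from seqmrf.models import mixture_log_joint, log_joint
        joint_single = sum(log_joint(single.params, data.sequences[i], int(data.labels[i]))
                           for i in range(len(data)))
        joint_mix = sum(mixture_log_joint(mix.params, data.sequences[i], int(data.labels[i]))
                        for i in range(len(data)))
        assert joint_mix >= joint_single - 1.0  # mixture fits the data at least as well

    def test_determinism_bitwise(self, rng):
        st = make_pairwise_mrf_structure(4, 4)
        structures = (st, st)
        _, data = make_data(structures, rng, n=80, scale=0.5)
        cfg = TrainingConfig(principle="MSP", ess=[4.0, 4.0], seed=42, tolerance=1e-4)
        a = train(cfg, structures, data)
        b = train(cfg, structures, data)
        for x, y in zip(a.params.values, b.params.values):
            assert np.array_equal(x, y)

    def test_small_ess_approaches_relative_frequencies(self):
        """alpha -> 0 recovers maximum likelihood; with zero counts present
        the estimate goes to the boundary (why the prior exists)."""
        ds = LabeledDataset.from_strings(["AA", "AC"], label=0, n_classes=1)
        st = make_pwm_structure(2, 4)
        for ess, tol in ((1e-6, 1e-6),):
            hyper = bdeu_hyperparameters(st, ess, C=1)
            theta = map_closed_form(count_statistics(ds, st), hyper)
            assert theta.values[0][0] == pytest.approx(1.0, abs=1e-6)   # P(A at 1)
            assert theta.values[0][2] == pytest.approx(0.0, abs=1e-6)   # unseen G

    def test_decision_scores_are_posterior_log_odds(self, rng):
        st = make_pwm_structure(3, 4)
        structures = (st, st)
        lam, data = make_data(structures, rng, n=30)
        scores = decision_scores(lam, data)
        lp = posterior_matrix(lam, data)
        assert np.allclose(scores, lp[:, 0] - lp[:, 1], atol=1e-12)
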