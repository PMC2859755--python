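import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from seqmrf.models import (
    IntractableModelError,
    MixtureParameters,
    ThetaParameters,
    class_log_posterior,
    lambda_to_theta,
    lambda_zeros,
    log_joint,
    log_partition,
    log_score,
    mixture_log_joint,
    partition_stats,
    sample_sequences,
    theta_log_joint,
    theta_to_lambda,
)
from seqmrf.structures import (
    ModelStructure,
    make_markov_structure,
    make_pairwise_mrf_structure,
    make_pwm_structure,
)

from conftest import random_anchored_lambda


def enumerate_outcomes(L, S, C):
    for c in range(C):
        for x in itertools.product(range(S), repeat=L):
            yield np.array(x), c


class TestLogScore:
    def test_zero_lambda_scores_zero(self, rng):
        lam = lambda_zeros(make_pwm_structure(4, 4), 2)
        assert log_score(lam, rng.integers(0, 4, 4), 0) == 0.0

    def test_additive_by_explicit_loops(self, rng):
        """Independent oracle: accumulate lambda entries with explicit loops."""
        st = make_markov_structure(3, 1, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        fi = lam.feature_indices[0]
        for _ in range(10):
            x = rng.integers(0, 4, 3)
            for c in range(2):
                expected = lam.class_values[c]
                for ell in range(3):
                    a_code = 0
                    for p in st.parents[ell]:
                        a_code = a_code * 4 + x[p]
                    expected += lam.values[c][fi.pos_offsets[ell] + a_code * 4 + x[ell]]
                assert log_score(lam, x, c) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        lam = lambda_zeros(make_pwm_structure(4, 4), 2)
        with pytest.raises(ValueError):
            log_score(lam, np.zeros(3, dtype=int), 0)


class TestLogPartition:
    def test_uniform_model_closed_form(self):
        lam = lambda_zeros(make_pwm_structure(3, 4), 2)
        assert log_partition(lam) == pytest.approx(np.log(2 * 4 ** 3))

    def test_single_class_L1_direct_sum(self):
        st = make_pwm_structure(1, 4)
        lam = lambda_zeros(st, 1)
        lam.values[0] = np.array([1.0, 0.0, 0.0, 0.0])
        assert log_partition(lam) == pytest.approx(np.log(np.e + 3))

    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_chain_recursion_equals_enumeration(self, order, rng):
        st = make_markov_structure(6, order, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        brute = logsumexp([log_score(lam, x, c) for x, c in enumerate_outcomes(6, 4, 2)])
        assert log_partition(lam) == pytest.approx(brute, abs=1e-10)

    def test_pairwise_enumeration_guard(self):
        st = make_pairwise_mrf_structure(16, 4)
        lam = lambda_zeros(st, 2)
        with pytest.raises(IntractableModelError, match="guard"):
            log_partition(lam)

    def test_chain_expectations_match_enumeration(self, rng):
        st = make_markov_structure(5, 1, 4)
        lam = random_anchored_lambda(st, C=1, rng=rng)
        stats = partition_stats(lam, want_expectations=True)
        fi = lam.feature_indices[0]
        probs = np.zeros(fi.n_features)
        for x, c in enumerate_outcomes(5, 4, 1):
            p = np.exp(log_score(lam, x, 0) - lam.class_values[0] - stats.log_z_seq[0])
            probs[fi.active_features(x)] += p
        assert np.allclose(stats.expectations[0], probs, atol=1e-10)


class TestLogJoint:
    def test_uniform_value(self):
        lam = lambda_zeros(make_pwm_structure(3, 4), 2)
        for x, c in [(np.zeros(3, dtype=int), 0), (np.ones(3, dtype=int), 1)]:
            assert log_joint(lam, x, c) == pytest.approx(-np.log(2 * 4 ** 3))

    def test_normalization_sums_to_one(self, rng):
        st = make_markov_structure(4, 2, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        total = logsumexp([log_joint(lam, x, c) for x, c in enumerate_outcomes(4, 4, 2)])
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_matches_directed_factorization(self, rng):
        """Mapped parameters give identical joints in both parameterizations."""
        st = make_markov_structure(3, 1, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        theta = lambda_to_theta(lam)
        for x, c in enumerate_outcomes(3, 4, 2):
            assert theta_log_joint(theta, x, c) == pytest.approx(
                log_joint(lam, x, c), abs=1e-10)


class TestClassPosterior:
    def test_uniform_posterior(self, rng):
        lam = lambda_zeros(make_pwm_structure(4, 4), 3)
        lp = class_log_posterior(lam, rng.integers(0, 4, 4))
        assert np.allclose(lp, np.log(1 / 3))

    def test_two_class_logistic_closed_form(self, rng):
        st = make_pwm_structure(2, 4)
        lam = lambda_zeros(st, 2)
        lam.class_values = np.array([1.3, 0.0])
        lp = class_log_posterior(lam, rng.integers(0, 4, 2))
        d = 1.3
        assert lp[0] == pytest.approx(-np.log1p(np.exp(-d)))

    def test_equals_joint_based_oracle(self, rng):
        st = make_markov_structure(4, 1, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        for _ in range(5):
            x = rng.integers(0, 4, 4)
            joints = np.array([log_joint(lam, x, c) for c in range(2)])
            assert np.allclose(class_log_posterior(lam, x),
                               joints - logsumexp(joints), atol=1e-12)


class TestThetaLambdaBijection:
    def test_uniform_maps_to_zero(self):
        st = make_pwm_structure(2, 4)
        fi = st.feature_index()
        theta = ThetaParameters((st,) * 2, np.array([0.5, 0.5]),
                                [np.full(fi.n_features, 0.25)] * 2)
        lam = theta_to_lambda(theta)
        assert np.allclose(lam.class_values, 0)
        assert all(np.allclose(v, 0) for v in lam.values)

    def test_pwm_softmax_closed_form(self, rng):
        st = make_pwm_structure(3, 4)
        lam = random_anchored_lambda(st, C=1, rng=rng)
        theta = lambda_to_theta(lam)
        for ell in range(3):
            block = lam.values[0][ell * 4 : (ell + 1) * 4]
            assert np.allclose(theta.values[0][ell * 4 : (ell + 1) * 4],
                               np.exp(block) / np.exp(block).sum(), atol=1e-12)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_roundtrip_lambda_theta_lambda(self, order, rng):
        st = make_markov_structure(4, order, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        back = theta_to_lambda(lambda_to_theta(lam))
        assert np.allclose(back.class_values, lam.class_values, atol=1e-8)
        for a, b in zip(back.values, lam.values):
            assert np.allclose(a, b, atol=1e-8)

    def test_right_to_left_structure_roundtrip(self, rng):
        rl = ModelStructure(kind="moral_bn", L=2, S=4, parents=((1,), ()))
        lam = random_anchored_lambda(rl, C=1, rng=rng)
        theta = lambda_to_theta(lam)
        back = theta_to_lambda(theta)
        for x, c in enumerate_outcomes(2, 4, 1):
            assert theta_log_joint(theta, x, c) == pytest.approx(
                log_joint(lam, x, c), abs=1e-10)
        assert np.allclose(back.values[0], lam.values[0], atol=1e-8)

    def test_constructive_and_numerical_solve_agree(self, rng):
        st = make_markov_structure(2, 1, 2)
        lam = random_anchored_lambda(st, C=1, rng=rng, scale=0.5)
        theta = lambda_to_theta(lam)
        a = theta_to_lambda(theta, method="construct")
        b = theta_to_lambda(theta, method="solve")
        assert np.allclose(a.values[0], b.values[0], atol=1e-6)

    def test_boundary_theta_rejected(self):
        st = make_pwm_structure(1, 2)
        theta = ThetaParameters((st,), np.array([1.0]), [np.array([1.0, 0.0])])
        with pytest.raises(ValueError, match="positive"):
            theta_to_lambda(theta)


class TestPWMAsMRFEmbedding:
    def test_kronecker_feature_model_matches_moral_bn(self, rng):
        """A PWM written with per-position indicator features is the same
        distribution as the moral-BN PWM with equal parameter values."""
        L, S = 3, 4
        bn = make_pwm_structure(L, S)
        mrf = ModelStructure(kind="pairwise_mrf", L=L, S=S, pairs=(),
                             include_singletons=True)
        lam_bn = random_anchored_lambda(bn, C=2, rng=rng)
        lam_mrf = lambda_zeros(mrf, 2)
        lam_mrf.class_values = lam_bn.class_values.copy()
        for c in range(2):
            lam_mrf.values[c] = lam_bn.values[c].copy()  # identical flat layout
        for x, c in enumerate_outcomes(L, S, 2):
            assert log_joint(lam_bn, x, c) == pytest.approx(
                log_joint(lam_mrf, x, c), abs=1e-12)


class TestMixture:
    def test_single_component_collapse(self, rng):
        st = make_markov_structure(3, 1, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        mix = MixtureParameters.from_single(lam)
        for _ in range(5):
            x = rng.integers(0, 4, 3)
            for c in range(2):
                assert mixture_log_joint(mix, x, c) == pytest.approx(
                    log_joint(lam, x, c), abs=1e-10)

    def test_equal_identical_components_match_single(self, rng):
        st = make_pwm_structure(3, 4)
        lam = random_anchored_lambda(st, C=2, rng=rng)
        single = MixtureParameters.from_single(lam)
        double = MixtureParameters([lam.copy(), lam.copy()],
                                   np.zeros((2, 2)), single.class_logits)
        x = rng.integers(0, 4, 3)
        assert mixture_log_joint(double, x, 0) == pytest.approx(
            mixture_log_joint(single, x, 0), abs=1e-12)

    def test_matches_probability_domain_oracle(self, rng):
        """Exhaustive probability-domain mixture equals the log-domain value."""
        st = make_markov_structure(3, 1, 4)
        comps = [random_anchored_lambda(st, C=2, rng=rng) for _ in range(2)]
        mix = MixtureParameters(comps, rng.normal(size=(2, 2)), rng.normal(size=2))
        pc = np.exp(mix.class_log_probs())
        w = mix.weights()
        for _ in range(5):
            x = rng.integers(0, 4, 3)
            for c in range(2):
                total = 0.0
                for m in range(2):
                    comp = comps[m]
                    stats = partition_stats(comp)
                    px_c = np.exp(log_joint(comp, x, c) - stats.class_log_probs[c])
                    total += pc[c] * w[c, m] * px_c
                assert mixture_log_joint(mix, x, c) == pytest.approx(
                    np.log(total), abs=1e-10)

    def test_mixture_normalizes(self, rng):
        st = make_pwm_structure(2, 4)
        comps = [random_anchored_lambda(st, C=2, rng=rng) for _ in range(2)]
        mix = MixtureParameters(comps, rng.normal(size=(2, 2)), rng.normal(size=2))
        total = logsumexp([mixture_log_joint(mix, x, c)
                           for x, c in enumerate_outcomes(2, 4, 2)])
        assert total == pytest.approx(0.0, abs=1e-10)


class TestSampling:
    def test_uniform_frequencies_within_four_se(self):
        lam = lambda_zeros(make_pwm_structure(4, 4), 1)
        ds = sample_sequences(lam, 10_000, seed=11)
        X = ds.as_matrix()
        se = np.sqrt(0.25 * 0.75 / len(X))
        for ell in range(4):
            freq = np.bincount(X[:, ell], minlength=4) / len(X)
            assert np.all(np.abs(freq - 0.25) < 4 * se)

    def test_deterministic_theta_yields_identical_samples(self):
        st = make_pwm_structure(3, 4)
        fi = st.feature_index()
        vals = np.zeros(fi.n_features)
        vals[[0, 4 + 1, 8 + 2]] = 1.0  # A, C, G deterministic
        theta = ThetaParameters((st,), np.array([1.0]), [vals])
        ds = sample_sequences(theta, 50, seed=0)
        assert all(ds.alphabet.decode(s) == "ACG" for s in ds.sequences)

    def test_planted_chain_transition_recovery(self, rng):
        """Empirical transitions of sampled order-1 data match theta to 4 SE."""
        st = make_markov_structure(3, 1, 4)
        lam = random_anchored_lambda(st, C=1, rng=rng, scale=0.5)
        theta = lambda_to_theta(lam)
        ds = sample_sequences(theta, 10_000, seed=5)
        X = ds.as_matrix()
        fi = theta.feature_indices[0]
        off = fi.pos_offsets[1]
        for a in range(4):
            rows = X[X[:, 0] == a]
            if len(rows) < 200:
                continue
            freq = np.bincount(rows[:, 1], minlength=4) / len(rows)
            probs = theta.values[0][off + a * 4 : off + a * 4 + 4]
            se = np.sqrt(probs * (1 - probs) / len(rows))
            assert np.all(np.abs(freq - probs) < 4 * se + 1e-9)

    def test_seed_determinism(self):
        lam = lambda_zeros(make_pairwise_mrf_structure(4, 4), 2)
        a = sample_sequences(lam, 30, seed=7)
        b = sample_sequences(lam, 30, seed=7)
        assert np.array_equal(a.as_matrix(), b.as_matrix())
        assert np.array_equal(a.labels, b.labels)
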