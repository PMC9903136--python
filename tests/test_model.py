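"""Likelihood, networks, ELBO, and generative sampling."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp
from scipy.stats import dirichlet_multinomial as scipy_dm, multinomial

from scfactor.model import (CountMatrix, GenerativeNets, PriorConfig,
                            VariationalNets, conditional_prior, decode_usage,
                            dirichlet_multinomial_logpmf, elbo_labeled,
                            elbo_labeled_samples, elbo_unlabeled,
                            elbo_unlabeled_samples, sample_generative,
                            SIGMA_MIN, SIGMA_MAX)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood
# ---------------------------------------------------------------------------


class TestDirichletMultinomial:
    def test_single_category_is_certain(self):
        assert dirichlet_multinomial_logpmf([5], [3.7]) == pytest.approx(0.0)

    def test_zero_total_is_certain(self):
        assert dirichlet_multinomial_logpmf([0, 0, 0], [2.0, 3.0, 4.0]) == pytest.approx(0.0)

    def test_uniform_dirichlet_two_counts(self):
        # P(X=(2,0)) = int_0^1 eta^2 d eta = 1/3 under eta ~ Beta(1,1)
        integral, _ = quad(lambda e: multinomial.pmf([2, 0], 2, [e, 1 - e]), 0, 1)
        got = dirichlet_multinomial_logpmf([2, 0], [1.0, 1.0])
        assert got == pytest.approx(np.log(1 / 3), abs=1e-10)
        assert got == pytest.approx(np.log(integral), abs=1e-8)

    @pytest.mark.parametrize("G,n", [(2, 4), (3, 5), (3, 6), (2, 6)])
    def test_proper_pmf_over_compositions(self, G, n):
        rng = np.random.default_rng(G * 10 + n)
        alpha = rng.uniform(0.2, 5.0, size=G)
        logps = [dirichlet_multinomial_logpmf(c, alpha)
                 for c in itertools.product(range(n + 1), repeat=G)
                 if sum(c) == n]
        assert logsumexp(logps) == pytest.approx(0.0, abs=1e-8)

    def test_large_concentration_approaches_multinomial(self):
        p = np.array([0.2, 0.5, 0.3])
        x = [3, 4, 1]
        got = dirichlet_multinomial_logpmf(x, 1e6 * p)
        assert got == pytest.approx(multinomial.logpmf(x, 8, p), abs=1e-3)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = rng.integers(2, 6)
            alpha = rng.uniform(0.1, 8.0, size=G)
            x = rng.integers(0, 7, size=G)
            ref = scipy_dm.logpmf(x, alpha, int(x.sum()))
            assert dirichlet_multinomial_logpmf(x, alpha) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("counts,alpha", [
        ([1, 2], [1.0, -1.0]),
        ([1, 2], [1.0, np.inf]),
        ([1, 2], [1.0, np.nan]),
        ([-1, 2], [1.0, 1.0]),
        ([0.5, 2], [1.0, 1.0]),
    ])
    def test_invalid_inputs_raise(self, counts, alpha):
        with pytest.raises(ValueError):
            dirichlet_multinomial_logpmf(counts, alpha)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_nets():
    prior = PriorConfig(L=3, d=6, d1=2)
    gen = GenerativeNets(prior, 12, hidden=(16, 16), seed=0)
    var = VariationalNets(prior, 12, hidden=(16, 16), seed=1)
    return prior, gen, var


class TestConditionalPrior:
    def test_zero_initialized_network_baseline(self, tiny_nets):
        prior, _, _ = tiny_nets
        gen = GenerativeNets(prior, 12, hidden=(16, 16), seed=2)
        for p in gen.cond_prior_net.parameters():
            p.data[:] = 0.0
        mu, sigma = conditional_prior([1, 0, 0], [0.3, -0.2], gen)
        assert np.allclose(mu, 0.0)
        assert np.allclose(sigma, np.log1p(np.e**0 * 0 + 1))  # softplus(0)=log 2
        assert np.allclose(sigma, np.log(2.0))

    def test_deterministic(self, tiny_nets):
        _, gen, _ = tiny_nets
        a = conditional_prior([0, 1, 0], [1.0, 2.0], gen)
        b = conditional_prior([0, 1, 0], [1.0, 2.0], gen)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_sigma_within_clamp_bounds_over_random_inputs(self, tiny_nets):
        prior, gen, _ = tiny_nets
        rng = np.random.default_rng(0)
        y = np.eye(3)[rng.integers(0, 3, size=1000)]
        z1 = rng.normal(0, 5, size=(1000, 2))
        _, sigma = gen.cond_prior(y, z1)
        assert np.all(sigma.data >= SIGMA_MIN) and np.all(sigma.data <= SIGMA_MAX)

    def test_shape_and_onehot_validation(self, tiny_nets):
        _, gen, _ = tiny_nets
        with pytest.raises(ValueError):
            conditional_prior([1, 0], [0.0, 0.0], gen)
        with pytest.raises(ValueError):
            conditional_prior([0.5, 0.5, 0.0], [0.0, 0.0], gen)
        with pytest.raises(ValueError):
            conditional_prior([1, 0, 0], [0.0, np.nan], gen)


class TestDecodeUsage:
    def test_usage_is_simplex_and_alpha_positive(self, tiny_nets):
        _, gen, _ = tiny_nets
        rng = np.random.default_rng(1)
        alpha, usage = decode_usage(rng.normal(size=(50, 6)), gen)
        assert np.all(alpha > 0)
        assert np.allclose(usage.sum(axis=1), 1.0, atol=1e-6)

    def test_usage_equals_normalized_alpha(self, tiny_nets):
        _, gen, _ = tiny_nets
        rng = np.random.default_rng(2)
        for _ in range(100):
            alpha, usage = decode_usage(rng.normal(size=6), gen)
            assert np.allclose(usage, alpha / alpha.sum(), atol=1e-10)

    def test_constant_decoder_gives_dirichlet_mean(self):
        prior = PriorConfig(L=1, d=2, d1=0)
        gen = GenerativeNets(prior, 2, hidden=(4, 4), seed=0)
        # force decoder output to softplus(b) = (3, 1) regardless of zy
        last_w, last_b = gen.decoder_net.weights[-1], gen.decoder_net.biases[-1]
        last_w.data[:] = 0.0
        last_b.data[:] = np.log(np.expm1(np.array([3.0, 1.0])))
        _, usage = decode_usage([0.4, -1.2], gen)
        assert np.allclose(usage, [0.75, 0.25], atol=1e-12)

    def test_nonfinite_zy_raises(self, tiny_nets):
        _, gen, _ = tiny_nets
        with pytest.raises(ValueError):
            decode_usage([np.nan, 0, 0, 0, 0, 0], gen)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_1d():
    """L=1, d=1, d1=0, G=2 model small enough for quadrature."""
    prior = PriorConfig(L=1, d=1, d1=0)
    gen = GenerativeNets(prior, 2, hidden=(8, 8), seed=3)
    var = VariationalNets(prior, 2, hidden=(8, 8), seed=4)
    return prior, gen, var


def quadrature_log_evidence(gen, x, y_idx=0, n_nodes=200):
    """Gauss-Hermite log-evidence of counts x on a d=1, d1=0 model."""
    L = gen.prior.L
    y1h = np.zeros((1, L))
    y1h[0, y_idx] = 1.0
    mu_t, sig_t = gen.cond_prior(y1h, np.zeros((1, 0)))
    mu, sig = float(mu_t.data[0, 0]), float(sig_t.data[0, 0])
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    zy = mu + np.sqrt(2) * sig * nodes
    alpha = gen.decode_alpha(zy[:, None]).data
    ll = np.array([dirichlet_multinomial_logpmf(x, a) for a in alpha])
    return logsumexp(ll + np.log(weights)) - 0.5 * np.log(np.pi)


class TestElbo:
    def test_labeled_estimate_below_zero(self, tiny_nets):
        prior, gen, var = tiny_nets
        x = np.array([3, 0, 1, 2, 0, 0, 4, 1, 0, 0, 2, 1])
        s = elbo_labeled_samples(x, 1, gen, var, prior, 10_000, 0)
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert s.mean() <= 0 + 3 * se

    def test_labeled_bounded_by_quadrature_evidence(self, toy_1d):
        prior, gen, var = toy_1d
        x = np.array([7, 3])
        logZ = quadrature_log_evidence(gen, x)
        s = elbo_labeled_samples(x, 0, gen, var, prior, 10_000, 11)
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert s.mean() <= logZ + 3 * se

    def test_unlabeled_bounded_by_enumerated_evidence(self):
        prior = PriorConfig(L=2, d=1, d1=0)
        gen = GenerativeNets(prior, 2, hidden=(8, 8), seed=5)
        var = VariationalNets(prior, 2, hidden=(8, 8), seed=6)
        x = np.array([4, 6])
        logZ = logsumexp([np.log(0.5) + quadrature_log_evidence(gen, x, y_idx=k)
                          for k in range(2)])
        s = elbo_unlabeled_samples(x, gen, var, prior, 10_000, 12)
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert s.mean() <= logZ + 3 * se

    def test_single_class_unlabeled_collapses_to_labeled(self, toy_1d):
        prior, gen, var = toy_1d
        x = np.array([2, 5])
        a = elbo_unlabeled_samples(x, gen, var, prior, 50, 7)
        b = elbo_labeled_samples(x, 0, gen, var, prior, 50, 7)
        assert np.allclose(a, b, atol=1e-10)

    def test_deterministic_under_fixed_seed(self, tiny_nets):
        prior, gen, var = tiny_nets
        x = np.array([3, 0, 1, 2, 0, 0, 4, 1, 0, 0, 2, 1])
        assert elbo_labeled(x, 0, gen, var, prior, 32, 9) == \
            elbo_labeled(x, 0, gen, var, prior, 32, 9)
        assert elbo_unlabeled(x, gen, var, prior, 32, 9) == \
            elbo_unlabeled(x, gen, var, prior, 32, 9)

    def test_invalid_label_raises(self, tiny_nets):
        prior, gen, var = tiny_nets
        with pytest.raises(ValueError):
            elbo_labeled(np.zeros(12, dtype=int), 5, gen, var, prior, 1, 0)


# ---------------------------------------------------------------------------
# generative sampling
# ---------------------------------------------------------------------------


class TestSampleGenerative:
    def test_rows_sum_to_requested_totals(self, tiny_nets):
        prior, gen, _ = tiny_nets
        totals = np.arange(1, 21)
        cm, truth = sample_generative(gen, prior, 20, totals, rng_seed=0)
        assert np.array_equal(cm.toarray().sum(axis=1), totals)
        assert truth.eta.shape == (20, 12)

    def test_identical_seeds_identical_matrices(self, tiny_nets):
        prior, gen, _ = tiny_nets
        a, _ = sample_generative(gen, prior, 10, np.full(10, 30), rng_seed=5)
        b, _ = sample_generative(gen, prior, 10, np.full(10, 30), rng_seed=5)
        assert np.array_equal(a.toarray(), b.toarray())

    def test_type_frequencies_match_uniform_prior(self):
        prior = PriorConfig(L=3, d=4, d1=2)
        gen = GenerativeNets(prior, 8, hidden=(8, 8), seed=1)
        n = 100_000
        _, truth = sample_generative(gen, prior, n, np.full(n, 5), rng_seed=2)
        freqs = np.bincount(truth.y_hat, minlength=3) / n
        bound = 3 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(freqs - 1 / 3) < bound)

    def test_invalid_totals_raise(self, tiny_nets):
        prior, gen, _ = tiny_nets
        with pytest.raises(ValueError):
            sample_generative(gen, prior, 3, [1, 0, 2], rng_seed=0)


# ---------------------------------------------------------------------------
# domain-type validation
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_count_matrix_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            CountMatrix(np.array([[1.5, 0]]), ["c1"], ["g1", "g2"])
        with pytest.raises(ValueError):
            CountMatrix(np.array([[1, -2]]), ["c1"], ["g1", "g2"])
        with pytest.raises(ValueError):
            CountMatrix(np.array([[1, 2]]), ["c1"], ["g1", "g1"])
        with pytest.raises(ValueError):
            CountMatrix(np.array([[1, 2], [0, 1]]), ["c1", "c1"], ["g1", "g2"])

    def test_prior_defaults_match_declared_choices(self):
        p = PriorConfig(L=4)
        assert p.d == 50 and p.d1 == 10
        assert np.array_equal(p.alpha0, np.ones(4))
        assert np.array_equal(p.mu0, np.zeros(10))
        assert np.array_equal(p.sigma0, np.ones(10))

    def test_prior_rejects_nonpositive_hyperparameters(self):
        with pytest.raises(ValueError):
            PriorConfig(L=2, alpha0=np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            PriorConfig(L=2, sigma0=np.zeros(10))
        with pytest.raises(ValueError):
            PriorConfig(L=0)

    def test_classifier_rows_are_simplex(self, tiny_nets):
        _, _, var = tiny_nets
        rng = np.random.default_rng(3)
        logp = var.log_q_y(rng.normal(size=(40, 6))).data
        p = np.exp(logp)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
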