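"""Deep generative factor model of single-cell gene-expression counts.

The generative process per cell:

    y  ~ Categorical(alpha0)                 cell type
    z1 ~ Normal(mu0, Sigma0)                 nuisance (batch/technical) factor
    zy ~ Normal(mu_zy(y, z1), Sigma_zy(y, z1))   complete hidden cell state
    alpha = Decoder(zy)                      Dirichlet concentrations
    eta ~ Dirichlet(alpha)                   gene usage (relative abundance)
    X  ~ Multinomial(n, eta)                 observed counts

The usage variable eta is marginalized analytically, so the count likelihood
is Dirichlet-multinomial conditioned on the observed per-cell total.
Variational factorization: q(zy|X) q(y|zy) q(z1|y,zy), with amortized
diagonal-Gaussian encoders and a softmax classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .autodiff import Tensor, concat_cols, parameter

SIGMA_MIN, SIGMA_MAX = 1e-3, 10.0
ALPHA_MIN, ALPHA_MAX = 1e-6, 1e6
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer counts with string identifiers."""

    counts: object  # ndarray or scipy sparse, cells x genes
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match matrix dimensions")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        dense = self.toarray()
        if dense.size and (not np.all(np.isfinite(dense)) or np.any(dense < 0)
                           or np.any(dense != np.round(dense))):
            raise ValueError("counts must be finite nonnegative integers")

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_cells(self):
        return self.counts.shape[0]

    @property
    def n_genes(self):
        return self.counts.shape[1]

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)


@dataclass
class PriorConfig:
    """Prior hyperparameters of the factor model.

    L      : number of cell types
    d      : dimension of the complete hidden state zy (default 50)
    d1     : dimension of the nuisance factor z1 (default 10)
    alpha0 : Categorical concentration over types (default all ones)
    mu0    : prior mean of z1 (default zeros)
    sigma0 : prior standard deviations of z1 (default ones)
    """

    L: int
    d: int = 50
    d1: int = 10
    alpha0: Optional[np.ndarray] = None
    mu0: Optional[np.ndarray] = None
    sigma0: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.d < 1 or self.d1 < 0:
            raise ValueError("d must be >= 1 and d1 >= 0")
        self.alpha0 = (np.ones(self.L) if self.alpha0 is None
                       else np.asarray(self.alpha0, dtype=float))
        self.mu0 = (np.zeros(self.d1) if self.mu0 is None
                    else np.asarray(self.mu0, dtype=float))
        self.sigma0 = (np.ones(self.d1) if self.sigma0 is None
                       else np.asarray(self.sigma0, dtype=float))
        if self.alpha0.shape != (self.L,) or np.any(self.alpha0 <= 0):
            raise ValueError("alpha0 must be length-L and positive")
        if self.mu0.shape != (self.d1,) or self.sigma0.shape != (self.d1,):
            raise ValueError("mu0/sigma0 must be length-d1")
        if np.any(self.sigma0 <= 0):
            raise ValueError("sigma0 must be positive")

    @property
    def log_py(self) -> np.ndarray:
        return np.log(self.alpha0) - np.log(self.alpha0.sum())


class MLP:
    """Two-hidden-layer perceptron with tanh activations (width 128)."""

    def __init__(self, in_dim: int, out_dim: int, hidden=(128, 128), *,
                 rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        dims = [in_dim, *hidden, out_dim]
        self.weights, self.biases = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            scale = 1.0 / np.sqrt(max(a, 1))
            self.weights.append(parameter(rng.normal(0.0, scale, size=(a, b))))
            self.biases.append(parameter(np.zeros(b)))

    def __call__(self, x: Tensor) -> Tensor:
        h = Tensor._lift(x)
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = h.tanh()
        return h

    def parameters(self):
        return [*self.weights, *self.biases]


class GaussianHead:
    """MLP trunk emitting a diagonal Gaussian (mu, sigma) of width out_dim."""

    def __init__(self, in_dim: int, out_dim: int, hidden=(128, 128), *,
                 rng: np.random.Generator):
        self.out_dim = out_dim
        self.net = MLP(in_dim, 2 * out_dim, hidden, rng=rng)

    def __call__(self, x: Tensor):
        h = self.net(x)
        mu = h.cols(0, self.out_dim)
        sigma = h.cols(self.out_dim, 2 * self.out_dim).softplus().clip(SIGMA_MIN, SIGMA_MAX)
        return mu, sigma

    def parameters(self):
        return self.net.parameters()


class GenerativeNets:
    """Conditional prior p(zy|y,z1) and decoder zy -> Dirichlet alpha."""

    def __init__(self, prior: PriorConfig, n_genes: int, hidden=(128, 128), *,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.prior = prior
        self.n_genes = n_genes
        self.cond_prior_net = GaussianHead(prior.L + prior.d1, prior.d, hidden, rng=rng)
        self.decoder_net = MLP(prior.d, n_genes, hidden, rng=rng)

    def cond_prior(self, y_onehot, z1):
        x = concat_cols(Tensor._lift(y_onehot), Tensor._lift(z1))
        return self.cond_prior_net(x)

    def decode_alpha(self, zy) -> Tensor:
        return self.decoder_net(Tensor._lift(zy)).softplus().clip(ALPHA_MIN, ALPHA_MAX)

    def parameters(self):
        return self.cond_prior_net.parameters() + self.decoder_net.parameters()


class VariationalNets:
    """Amortized q(zy|X), classifier q(y|zy), and q(z1|y,zy)."""

    def __init__(self, prior: PriorConfig, n_genes: int, hidden=(128, 128), *,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.prior = prior
        self.n_genes = n_genes
        self.encoder_net = GaussianHead(n_genes, prior.d, hidden, rng=rng)
        self.classifier_net = MLP(prior.d, prior.L, hidden, rng=rng)
        self.nuisance_net = GaussianHead(prior.L + prior.d, prior.d1, hidden, rng=rng)

    def encode(self, x_norm):
        return self.encoder_net(Tensor._lift(x_norm))

    def classify_logits(self, zy) -> Tensor:
        return self.classifier_net(Tensor._lift(zy))

    def log_q_y(self, zy) -> Tensor:
        logits = self.classify_logits(zy)
        return logits - logits.logsumexp(axis=1, keepdims=True)

    def nuisance(self, y_onehot, zy):
        x = concat_cols(Tensor._lift(y_onehot), Tensor._lift(zy))
        return self.nuisance_net(x)

    def parameters(self):
        return (self.encoder_net.parameters() + self.classifier_net.parameters()
                + self.nuisance_net.parameters())


@dataclass
class LatentState:
    """Per-cell posterior summaries."""

    y_prob: np.ndarray   # cells x L
    y_hat: np.ndarray    # cells, int label index
    zy_mean: np.ndarray  # cells x d
    z1_mean: np.ndarray  # cells x d1
    eta: np.ndarray      # cells x G expected gene usage

    def __post_init__(self):
        if not np.allclose(self.y_prob.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("y_prob rows must sum to 1")
        if not np.allclose(self.eta.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("eta rows must sum to 1")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def dirichlet_multinomial_logpmf(counts_row, alpha) -> float:
    """Log-pmf of the compound Dirichlet-multinomial at the observed total.

    log P(X = x | alpha) for X ~ Multinomial(n, eta), eta ~ Dirichlet(alpha),
    conditioned on n = sum(x).
    """
    x = np.asarray(counts_row, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if x.shape != a.shape or x.ndim != 1:
        raise ValueError("counts_row and alpha must be 1-D of equal length")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("alpha must be finite and strictly positive")
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("counts must be nonnegative integers")
    n = x.sum()
    A = a.sum()
    return float(
        gammaln(n + 1.0) - gammaln(x + 1.0).sum()
        + gammaln(A) - gammaln(A + n)
        + (gammaln(a + x) - gammaln(a)).sum()
    )


def _dm_loglik(X: np.ndarray, alpha: Tensor) -> Tensor:
    """Batched Dirichlet-multinomial log-likelihood; X constant, alpha in graph."""
    n = X.sum(axis=1, keepdims=True)
    coef = gammaln(n + 1.0) - gammaln(X + 1.0).sum(axis=1, keepdims=True)
    A = alpha.sum(axis=1, keepdims=True)
    ll = (A.gammaln() - (A + n).gammaln()
          + ((alpha + X).gammaln() - alpha.gammaln()).sum(axis=1, keepdims=True)
          + coef)
    return ll.sum(axis=1)  # (B,)


def gaussian_logpdf(x, mu, sigma) -> Tensor:
    """Diagonal-Gaussian log density, summed over the feature axis."""
    x, mu, sigma = Tensor._lift(x), Tensor._lift(mu), Tensor._lift(sigma)
    z = (x - mu) / sigma
    return (z * z * (-0.5) - sigma.log() - 0.5 * _LOG2PI).sum(axis=1)


# ---------------------------------------------------------------------------
# public operations on the networks
# ---------------------------------------------------------------------------


def conditional_prior(y_onehot, z1, nets: GenerativeNets):
    """Parameters (mu_zy, sigma_zy) of p(zy | y, z1) for a single cell."""
    y = np.asarray(y_onehot, dtype=float)
    z = np.asarray(z1, dtype=float)
    L, d1 = nets.prior.L, nets.prior.d1
    if y.shape != (L,) or not (np.isclose(y.sum(), 1.0) and set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError(f"y_onehot must be a one-hot vector of length {L}")
    if z.shape != (d1,):
        raise ValueError(f"z1 must have length {d1}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z1 must be finite")
    mu, sigma = nets.cond_prior(y[None, :], z[None, :])
    return mu.data[0], sigma.data[0]


def decode_usage(zy, nets: GenerativeNets):
    """Decode zy to Dirichlet concentrations alpha and their mean usage."""
    z = np.atleast_2d(np.asarray(zy, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError("zy must be finite")
    alpha = nets.decode_alpha(z).data
    usage = alpha / alpha.sum(axis=1, keepdims=True)
    if np.asarray(zy).ndim == 1:
        return alpha[0], usage[0]
    return alpha, usage


def normalize_rows(counts: np.ndarray, target_lib: float) -> np.ndarray:
    """Encoder input transform: scale rows to a common library, then log1p."""
    counts = np.asarray(counts, dtype=float)
    rs = counts.sum(axis=1, keepdims=True)
    rs = np.where(rs > 0, rs, 1.0)
    return np.log1p(counts / rs * target_lib)


def _one_hot(idx: np.ndarray, L: int) -> np.ndarray:
    out = np.zeros((len(idx), L))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def elbo_parts_labeled(X: np.ndarray, Xnorm: np.ndarray, y_onehot: np.ndarray,
                       gen: GenerativeNets, var: VariationalNets,
                       prior: PriorConfig, eps_zy: np.ndarray,
                       eps_z1: np.ndarray):
    """Per-cell reconstruction and KL-side terms of the labeled ELBO.

    Returns (loglik, latent_terms, zy) as graph tensors; the per-cell ELBO is
    loglik + latent_terms.  Splitting the two lets training anneal the latent
    terms while reporting the unannealed bound.
    """
    mu_q, sig_q = var.encode(Xnorm)
    zy = mu_q + sig_q * eps_zy
    mu_q1, sig_q1 = var.nuisance(y_onehot, zy)
    z1 = mu_q1 + sig_q1 * eps_z1
    mu_p, sig_p = gen.cond_prior(y_onehot, z1)
    alpha = gen.decode_alpha(zy)

    ll = _dm_loglik(X, alpha)
    log_py = (y_onehot @ prior.log_py[:, None]).sum(axis=1)
    latent = (gaussian_logpdf(zy, mu_p, sig_p)
              + gaussian_logpdf(z1, prior.mu0[None, :], prior.sigma0[None, :])
              + log_py
              - gaussian_logpdf(zy, mu_q, sig_q)
              - gaussian_logpdf(z1, mu_q1, sig_q1))
    return ll, latent, zy


def elbo_parts_unlabeled(X: np.ndarray, Xnorm: np.ndarray,
                         gen: GenerativeNets, var: VariationalNets,
                         prior: PriorConfig, eps_zy: np.ndarray,
                         eps_z1: np.ndarray):
    """Unlabeled ELBO: y enumerated over L classes weighted by q(y|zy)."""
    B = X.shape[0]
    L = prior.L
    mu_q, sig_q = var.encode(Xnorm)
    zy = mu_q + sig_q * eps_zy
    alpha = gen.decode_alpha(zy)
    ll = _dm_loglik(X, alpha)

    log_pi = var.log_q_y(zy)           # (B, L)
    pi = log_pi.exp()
    entropy = (pi * log_pi * (-1.0)).sum(axis=1)

    latent = (gaussian_logpdf(zy, mu_q, sig_q) * 0.0)  # zero tensor in graph
    for k in range(L):
        y1h = np.zeros((B, L))
        y1h[:, k] = 1.0
        mu_q1, sig_q1 = var.nuisance(y1h, zy)
        z1 = mu_q1 + sig_q1 * eps_z1
        mu_p, sig_p = gen.cond_prior(y1h, z1)
        t_k = (gaussian_logpdf(zy, mu_p, sig_p)
               + gaussian_logpdf(z1, prior.mu0[None, :], prior.sigma0[None, :])
               + float(prior.log_py[k])
               - gaussian_logpdf(z1, mu_q1, sig_q1))
        latent = latent + pi.cols(k, k + 1).sum(axis=1) * t_k
    latent = latent - gaussian_logpdf(zy, mu_q, sig_q) + entropy
    return ll, latent, zy, log_pi


def _mc_eps(rng: np.random.Generator, n: int, d: int, d1: int):
    return rng.standard_normal((n, d)), rng.standard_normal((n, d1))


def elbo_labeled_samples(counts_row, y_label: int, gen: GenerativeNets,
                         var: VariationalNets, prior: PriorConfig,
                         n_mc: int, rng_seed: int) -> np.ndarray:
    """Vector of n_mc single-sample ELBO estimates for one labeled cell."""
    if not (0 <= y_label < prior.L):
        raise ValueError(f"y_label must be in [0, {prior.L})")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    x = np.asarray(counts_row, dtype=float)[None, :]
    X = np.repeat(x, n_mc, axis=0)
    Xnorm = normalize_rows(X, max(X.sum(), 1.0) / n_mc)
    y1h = _one_hot(np.full(n_mc, y_label), prior.L)
    rng = np.random.default_rng(rng_seed)
    eps_zy, eps_z1 = _mc_eps(rng, n_mc, prior.d, prior.d1)
    ll, latent, _ = elbo_parts_labeled(X, Xnorm, y1h, gen, var, prior, eps_zy, eps_z1)
    return ll.data + latent.data


def elbo_labeled(counts_row, y_label, gen, var, prior, n_mc: int,
                 rng_seed: int) -> float:
    """Monte-Carlo ELBO estimate for a labeled cell, reproducible by seed."""
    return float(elbo_labeled_samples(counts_row, y_label, gen, var, prior,
                                      n_mc, rng_seed).mean())


def elbo_unlabeled_samples(counts_row, gen, var, prior, n_mc: int,
                           rng_seed: int) -> np.ndarray:
    """Vector of n_mc single-sample ELBO estimates for an unlabeled cell."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    x = np.asarray(counts_row, dtype=float)[None, :]
    X = np.repeat(x, n_mc, axis=0)
    Xnorm = normalize_rows(X, max(X.sum(), 1.0) / n_mc)
    rng = np.random.default_rng(rng_seed)
    eps_zy, eps_z1 = _mc_eps(rng, n_mc, prior.d, prior.d1)
    ll, latent, _, _ = elbo_parts_unlabeled(X, Xnorm, gen, var, prior, eps_zy, eps_z1)
    return ll.data + latent.data


def elbo_unlabeled(counts_row, gen, var, prior, n_mc: int,
                   rng_seed: int) -> float:
    """Semi-supervised ELBO for an unlabeled cell (y marginalized)."""
    return float(elbo_unlabeled_samples(counts_row, gen, var, prior,
                                        n_mc, rng_seed).mean())


def sample_generative(gen: GenerativeNets, prior: PriorConfig, n_cells: int,
                      totals: Sequence[int], rng_seed: int):
    """Sample counts and latent truth from the generative process."""
    totals = np.asarray(totals, dtype=int)
    if totals.shape != (n_cells,) or np.any(totals < 1):
        raise ValueError("totals must be n_cells positive integers")
    rng = np.random.default_rng(rng_seed)
    L, d1, G = prior.L, prior.d1, gen.n_genes

    py = prior.alpha0 / prior.alpha0.sum()
    y = rng.choice(L, size=n_cells, p=py)
    z1 = prior.mu0 + prior.sigma0 * rng.standard_normal((n_cells, d1))
    y1h = _one_hot(y, L)
    mu_p, sig_p = gen.cond_prior(y1h, z1)
    zy = mu_p.data + sig_p.data * rng.standard_normal((n_cells, prior.d))
    alpha = gen.decode_alpha(zy).data
    gam = rng.gamma(alpha)  # Dirichlet via normalized gammas, vectorized
    eta = gam / gam.sum(axis=1, keepdims=True)
    counts = rng.multinomial(totals, eta)

    cm = CountMatrix(sp.csr_matrix(counts),
                     [f"cell{i}" for i in range(n_cells)],
                     [f"gene{j}" for j in range(G)])
    truth = LatentState(y_prob=y1h, y_hat=y, zy_mean=zy, z1_mean=z1, eta=eta)
    return cm, truth
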