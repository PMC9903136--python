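"""Stochastic variational inference for the semi-supervised factor model.

Labeled cells contribute the labeled ELBO plus a supervised classifier term
-w * log q(y = y_obs | zy); unlabeled cells contribute the marginal ELBO with
the discrete label enumerated.  Optimization is minibatch Adam on the
negative objective, with a linear KL warm-up to avoid posterior collapse.

Minibatches are drawn by permuting a canonical cell order (cells sorted by
cell_id), so fitting is exactly invariant to the order cells arrive in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam
from .model import (CountMatrix, GenerativeNets, PriorConfig, VariationalNets,
                    elbo_parts_labeled, elbo_parts_unlabeled, normalize_rows,
                    _one_hot)


@dataclass
class TrainConfig:
    epochs: int = 200
    minibatch_size: int = 128
    learning_rate: float = 1e-3
    mc_samples: int = 1
    kl_warmup_epochs: int = 50   # linear 0 -> 1 KL weight
    classifier_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.minibatch_size < 1 or self.mc_samples < 1:
            raise ValueError("epochs >= 0, minibatch_size and mc_samples >= 1")
        if self.learning_rate <= 0 or self.classifier_weight < 0:
            raise ValueError("learning_rate > 0 and classifier_weight >= 0")
        if self.kl_warmup_epochs > max(self.epochs, 1):
            raise ValueError("kl_warmup_epochs must be <= epochs")


@dataclass
class ModelState:
    """Everything needed to reuse a fitted model."""

    prior: PriorConfig
    gen: GenerativeNets
    var: VariationalNets
    label_vocabulary: list
    gene_ids: list
    target_library: float
    history: list = field(default_factory=list)  # per-epoch dicts

    def label_index(self, label: str) -> int:
        return self.label_vocabulary.index(label)

    # -- serialization: config JSON + flat named arrays -------------------

    def save(self, path):
        arrays, names = {}, []
        for group, net in (("gen", self.gen), ("var", self.var)):
            for i, p in enumerate(net.parameters()):
                key = f"{group}_{i}"
                arrays[key] = p.data
                names.append(key)
        config = {
            "L": self.prior.L, "d": self.prior.d, "d1": self.prior.d1,
            "alpha0": self.prior.alpha0.tolist(),
            "mu0": self.prior.mu0.tolist(), "sigma0": self.prior.sigma0.tolist(),
            "n_genes": self.gen.n_genes,
            "gene_ids": self.gene_ids,
            "label_vocabulary": self.label_vocabulary,
            "target_library": self.target_library,
            "history": self.history,
            "param_names": names,
        }
        np.savez(path, __config__=np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as z:
            config = json.loads(bytes(z["__config__"]).decode())
            prior = PriorConfig(L=config["L"], d=config["d"], d1=config["d1"],
                                alpha0=np.array(config["alpha0"]),
                                mu0=np.array(config["mu0"]),
                                sigma0=np.array(config["sigma0"]))
            gen = GenerativeNets(prior, config["n_genes"], seed=0)
            var = VariationalNets(prior, config["n_genes"], seed=0)
            params = gen.parameters() + var.parameters()
            for key, p in zip(config["param_names"], params):
                p.data = z[key].copy()
            return cls(prior=prior, gen=gen, var=var,
                       label_vocabulary=config["label_vocabulary"],
                       gene_ids=config["gene_ids"],
                       target_library=config["target_library"],
                       history=config["history"])


def build_vocabulary(labels: Sequence[Optional[str]]) -> list:
    """Sorted distinct label strings; the y index is the sorted position."""
    return sorted({str(l) for l in labels if l is not None})


def svi_fit(data: CountMatrix, labels: Optional[Sequence[Optional[str]]],
            prior: Optional[PriorConfig] = None,
            cfg: Optional[TrainConfig] = None,
            vocabulary: Optional[list] = None) -> ModelState:
    """Fit the factor model to a (partially) labeled count matrix.

    labels: per-cell label strings, None marking unlabeled cells; may be None
    entirely only if an explicit vocabulary (and prior) pin down L.
    """
    cfg = cfg or TrainConfig()
    n, G = data.shape
    if n == 0 or G == 0:
        raise ValueError("empty count matrix")
    if labels is None:
        labels = [None] * n
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels length must match cell count")

    vocab = vocabulary if vocabulary is not None else build_vocabulary(labels)
    if not vocab:
        raise ValueError("no labeled cells and no explicit vocabulary")
    unknown = {str(l) for l in labels if l is not None} - set(vocab)
    if unknown:
        raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")
    if prior is None:
        prior = PriorConfig(L=len(vocab))
    if prior.L != len(vocab):
        raise ValueError("prior.L must equal vocabulary size")

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    gen = GenerativeNets(prior, G, seed=init_seed)
    var = VariationalNets(prior, G, seed=init_seed + 1)

    X = data.toarray()
    libs = X.sum(axis=1)
    target_library = float(np.median(libs[libs > 0])) if np.any(libs > 0) else 1.0
    Xnorm = normalize_rows(X, target_library)

    state = ModelState(prior=prior, gen=gen, var=var, label_vocabulary=vocab,
                       gene_ids=list(data.gene_ids),
                       target_library=target_library, history=[])
    if cfg.epochs == 0:
        return state

    # canonical order: sorted by cell_id, so input ordering cannot matter
    canon = np.array(sorted(range(n), key=lambda i: data.cell_ids[i]))
    y_idx = np.array([vocab.index(str(l)) if l is not None else -1 for l in labels])

    opt = Adam(gen.parameters() + var.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seeds[1])

    for epoch in range(cfg.epochs):
        beta = min(1.0, (epoch + 1) / max(cfg.kl_warmup_epochs, 1))
        order = canon[rng.permutation(n)]
        ep_elbo, ep_cls, n_seen, n_lab_seen = 0.0, 0.0, 0, 0
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start:start + cfg.minibatch_size]
            loss = None
            batch_elbo = 0.0

            lab = idx[y_idx[idx] >= 0]
            unl = idx[y_idx[idx] < 0]
            for _ in range(cfg.mc_samples):
                if len(lab):
                    y1h = _one_hot(y_idx[lab], prior.L)
                    eps_zy = rng.standard_normal((len(lab), prior.d))
                    eps_z1 = rng.standard_normal((len(lab), prior.d1))
                    ll, latent, zy = elbo_parts_labeled(
                        X[lab], Xnorm[lab], y1h, gen, var, prior, eps_zy, eps_z1)
                    log_q_y = (var.log_q_y(zy) * y1h).sum(axis=1)
                    contrib = (ll + latent * beta
                               + log_q_y * cfg.classifier_weight).sum()
                    loss = -contrib if loss is None else loss - contrib
                    batch_elbo += float((ll.data + latent.data).sum())
                    ep_cls += float(-log_q_y.data.sum()) / cfg.mc_samples
                if len(unl):
                    eps_zy = rng.standard_normal((len(unl), prior.d))
                    eps_z1 = rng.standard_normal((len(unl), prior.d1))
                    ll, latent, _, _ = elbo_parts_unlabeled(
                        X[unl], Xnorm[unl], gen, var, prior, eps_zy, eps_z1)
                    contrib = (ll + latent * beta).sum()
                    loss = -contrib if loss is None else loss - contrib
                    batch_elbo += float((ll.data + latent.data).sum())

            loss = loss * (1.0 / (len(idx) * cfg.mc_samples))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()

            ep_elbo += batch_elbo / cfg.mc_samples
            n_seen += len(idx)
            n_lab_seen += len(lab)

        state.history.append({
            "epoch": epoch,
            "mean_elbo": ep_elbo / n_seen,
            "mean_classifier_loss": (ep_cls / n_lab_seen) if n_lab_seen else 0.0,
        })
    return state
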