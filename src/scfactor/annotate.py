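"""Post-training inference: embeddings, cell-type calls, batch-corrected
expression, and 2-D visualization coordinates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import softmax

from .model import CountMatrix, decode_usage, normalize_rows, _one_hot
from .train import ModelState


class GeneAlignmentError(ValueError):
    """Query gene set cannot be aligned to the model's training genes."""


@dataclass
class EmbeddingResult:
    zy_mean: np.ndarray
    umap2d: np.ndarray
    umap_seed: int


def _align_counts(data: CountMatrix, model: ModelState) -> np.ndarray:
    """Reorder query columns to the model's gene order.

    Model genes absent from the query are imputed as zero counts (with a
    warning); query genes unknown to the model are an error.
    """
    model_genes = model.gene_ids
    pos = {g: j for j, g in enumerate(data.gene_ids)}
    unknown = sorted(set(data.gene_ids) - set(model_genes))
    if unknown:
        raise GeneAlignmentError(f"query genes unknown to the model: {unknown[:5]}")
    dense = data.toarray()
    X = np.zeros((data.n_cells, len(model_genes)))
    missing = []
    for j, g in enumerate(model_genes):
        if g in pos:
            X[:, j] = dense[:, pos[g]]
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"{len(missing)} model genes missing from query; imputed as zero")
    return X


def embed(data: CountMatrix, model: ModelState) -> np.ndarray:
    """Posterior-mean embedding: row i = mean of q(zy | X_i)."""
    X = _align_counts(data, model)
    Xnorm = normalize_rows(X, model.target_library)
    mu, _ = model.var.encode(Xnorm)
    return mu.data.copy()


def classify(data: CountMatrix, model: ModelState):
    """Cell-type posterior q(y|zy) at the embedding mean, and argmax labels.

    Ties break to the lowest vocabulary index (numpy argmax convention).
    """
    zy = embed(data, model)
    logits = model.var.classify_logits(zy).data
    y_prob = softmax(logits, axis=1)
    y_hat_idx = np.argmax(y_prob, axis=1)
    y_hat = [model.label_vocabulary[i] for i in y_hat_idx]
    return y_prob, y_hat


def correct_expression(data: CountMatrix, model: ModelState) -> np.ndarray:
    """Batch-corrected expected gene usage per cell.

    Each cell is re-decoded at reference nuisance conditions: zy* is the
    conditional-prior mean at (y = predicted type, z1 = prior mean mu0), so
    all nuisance variation is removed and rows are simplex points.
    """
    y_prob, y_hat = classify(data, model)
    prior = model.prior
    # one decode per class, then gather
    y1h = np.eye(prior.L)
    z1 = np.repeat(prior.mu0[None, :], prior.L, axis=0)
    mu_p, _ = model.gen.cond_prior(y1h, z1)
    _, usage_by_class = decode_usage(mu_p.data, model.gen)
    idx = np.array([model.label_vocabulary.index(l) for l in y_hat])
    return usage_by_class[idx]


def umap2d(embeddings: np.ndarray, seed: int, n_neighbors: int = 15,
           min_dist: float = 0.1) -> np.ndarray:
    """Seeded UMAP to 2-D (Euclidean metric)."""
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 3:
        raise ValueError("umap2d needs at least 3 cells")
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors shrunk from {n_neighbors} to {n - 1}")
        n_neighbors = n - 1
    import umap  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, metric="euclidean",
                            random_state=seed)
        coords = reducer.fit_transform(embeddings)
    return np.asarray(coords, dtype=float)
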