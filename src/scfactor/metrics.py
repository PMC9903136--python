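"""Evaluation statistics for annotation and integration quality."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from sklearn.neighbors import NearestNeighbors


@dataclass
class EvalReport:
    accuracy: float
    ari: float
    batch_entropy: float
    n_cells: int
    k_neighbors: int


def accuracy(pred, truth) -> float:
    """Fraction of exact label matches."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    if not pred:
        raise ValueError("empty label vectors")
    return float(np.mean([p == t for p, t in zip(pred, truth)]))


def adjusted_rand(pred, truth) -> float:
    """Adjusted Rand index from the pair-counting contingency table.

    ARI = (Index - Expected) / (MaxIndex - Expected), where Index is the
    number of agreeing pairs, Expected its value under random partitions
    with the same marginals, MaxIndex the average of the marginal pair sums.
    """
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 items")
    pcats = {c: i for i, c in enumerate(dict.fromkeys(pred))}
    tcats = {c: i for i, c in enumerate(dict.fromkeys(truth))}
    cont = np.zeros((len(pcats), len(tcats)), dtype=np.int64)
    for p, t in zip(pred, truth):
        cont[pcats[p], tcats[t]] += 1
    sum_ij = comb(cont, 2).sum()
    a = comb(cont.sum(axis=1), 2).sum()
    b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a * b / total
    max_index = 0.5 * (a + b)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def batch_mixing_entropy(coords, batches, k: int = 15) -> float:
    """Mean per-cell Shannon entropy of batch labels among k nearest neighbors.

    Entropy base is the number of batches, so the score lies in [0, 1]:
    1 = every neighborhood reflects the global batch mix, 0 = batches fully
    separated in the embedding.  The cell itself is excluded.
    """
    coords = np.asarray(coords, dtype=float)
    batches = np.asarray(batches)
    if coords.shape[0] != len(batches):
        raise ValueError("coords and batches must have equal length")
    cats = np.unique(batches)
    if len(cats) < 2:
        raise ValueError("batch mixing entropy needs at least 2 batches")
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    codes = np.searchsorted(cats, batches)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = codes[idx[:, 1:]]  # drop self
    ent = np.empty(n)
    for i in range(n):
        counts = np.bincount(neigh[i], minlength=len(cats))
        p = counts / counts.sum()
        p = p[p > 0]
        ent[i] = -(p * np.log(p)).sum() / np.log(len(cats))
    return float(ent.mean())
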