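"""Standard synthetic benchmarks used to validate the fitted model.

Two experiments, both fully seeded:

* label/integration benchmark — the default 3-type, 2-batch, 600-cell
  dataset (80% labeled); measures held-out classification accuracy of the
  fitted model and compares the batch-mixing entropy of its zy embedding
  against a 50-component truncated-SVD baseline on log-normalized counts.
* usage-recovery benchmark — 2000 cells from the same generator; measures
  the per-type Pearson correlation between the fitted mean gene usage and
  the true mean usage of the simulated cells.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr
from sklearn.decomposition import TruncatedSVD

from .annotate import classify, embed
from .metrics import accuracy, batch_mixing_entropy
from .model import decode_usage, normalize_rows
from .simulate import simulate_dataset
from .train import TrainConfig, svi_fit


def label_integration_benchmark(seed: int = 0, n_cells: int = 600):
    """Fit the default benchmark; return accuracy and mixing entropies."""
    cm, truth, labels = simulate_dataset(n_cells=n_cells, seed=seed)
    state = svi_fit(cm, labels, cfg=TrainConfig(seed=seed))
    _, y_hat = classify(cm, state)

    held = [i for i, l in enumerate(labels) if l is None]
    acc = accuracy([y_hat[i] for i in held],
                   [f"type{truth.true_labels[i]}" for i in held])

    zy = embed(cm, state)
    ent_model = batch_mixing_entropy(zy, truth.true_batches)
    Xn = normalize_rows(cm.toarray(), state.target_library)
    svd = TruncatedSVD(n_components=min(50, cm.n_genes - 1),
                       random_state=seed).fit_transform(Xn)
    ent_svd = batch_mixing_entropy(svd, truth.true_batches)

    return {
        "heldout_accuracy": acc,
        "n_heldout": len(held),
        "n_cells": n_cells,
        "batch_entropy_model": ent_model,
        "batch_entropy_svd": ent_svd,
        "state": state,
    }


def usage_recovery_benchmark(seed: int = 0, n_cells: int = 2000):
    """Fit at larger n; correlate fitted vs true per-type mean gene usage."""
    cm, truth, labels = simulate_dataset(n_cells=n_cells, seed=seed)
    state = svi_fit(cm, labels, cfg=TrainConfig(seed=seed))
    zy = embed(cm, state)
    _, eta_hat = decode_usage(zy, state.gen)

    per_type = {}
    for l in range(truth.profiles.shape[0]):
        idx = truth.true_labels == l
        r = pearsonr(eta_hat[idx].mean(axis=0),
                     truth.per_cell_eta[idx].mean(axis=0)).statistic
        per_type[f"type{l}"] = float(r)
    return {
        "per_type_pearson_r": per_type,
        "min_pearson_r": min(per_type.values()),
        "n_cells": n_cells,
        "state": state,
    }
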