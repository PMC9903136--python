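"""Dirichlet-process mixture subclustering of 2-D cell coordinates.

A truncated stick-breaking variational DP Gaussian mixture (full covariances)
is fitted to the UMAP coordinates; the number of subpopulations is read off
as the number of components that both carry non-negligible weight and have
at least one cell assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import BayesianGaussianMixture


@dataclass
class SubclusterResult:
    labels: np.ndarray        # per-cell component index
    K_effective: int          # occupied components
    weights: np.ndarray       # mixing proportions (length max_components)
    max_components: int
    seed: int


def dp_cluster(coords, max_components: int = 20, weight_floor: float = 0.01,
               seed: int = 0) -> SubclusterResult:
    """Cluster 2-D coordinates with automatic component-count estimation.

    K_effective counts components with weight >= weight_floor AND at least
    one assigned cell.  Degenerate all-identical inputs return K=1 with a
    warning rather than raising.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("coords must be 2-D with at least 2 rows")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")

    if np.allclose(coords, coords[0], atol=1e-12):
        warnings.warn("all coordinates identical; returning a single cluster")
        weights = np.zeros(max_components)
        weights[0] = 1.0
        return SubclusterResult(labels=np.zeros(len(coords), dtype=int),
                                K_effective=1, weights=weights,
                                max_components=max_components, seed=seed)

    gmm = BayesianGaussianMixture(
        n_components=max_components,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / max_components,
        mean_precision_prior=10.0,  # discourages splitting one mode in two
        max_iter=1000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = gmm.fit_predict(coords)
    weights = gmm.weights_
    occupied = np.unique(labels)
    k_eff = int(sum(1 for k in occupied if weights[k] >= weight_floor))
    k_eff = max(k_eff, 1)
    return SubclusterResult(labels=labels, K_effective=k_eff, weights=weights,
                            max_components=max_components, seed=seed)
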