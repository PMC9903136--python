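"""Seeded multi-batch scRNA-seq benchmark generator, plus the packaged
sample-bookkeeping manifest of the six source cohorts.

The simulator mirrors the model's own generative assumptions: each cell type
has a gene-usage profile on the simplex; each batch perturbs profiles
multiplicatively (lognormal factors, renormalized); per-cell usage is drawn
from a Dirichlet around the perturbed profile (overdispersion); counts are
multinomial at a lognormal library size.  Defaults define the standard
benchmark: 3 types, 2 batches, 600 cells, 200 genes, 80% labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .model import CountMatrix


@dataclass
class SyntheticTruth:
    profiles: np.ndarray       # L x G per-type gene-usage simplex rows
    batch_effects: np.ndarray  # B x G positive multiplicative factors
    true_labels: np.ndarray    # per-cell type index
    true_batches: np.ndarray   # per-cell batch index
    library_sizes: np.ndarray
    per_cell_eta: np.ndarray   # cells x G usage actually drawn
    seed: int

    def __post_init__(self):
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("profile rows must sum to 1")
        if np.any(self.batch_effects <= 0):
            raise ValueError("batch effects must be positive")
        n = len(self.true_labels)
        if not (len(self.true_batches) == len(self.library_sizes)
                == self.per_cell_eta.shape[0] == n):
            raise ValueError("per-cell arrays must have equal length")

    def expected_usage(self, type_idx: int, batch_idx: int) -> np.ndarray:
        """Batch-perturbed profile: the mean usage of a (type, batch) cell."""
        u = self.profiles[type_idx] * self.batch_effects[batch_idx]
        return u / u.sum()


def make_profiles(L: int, G: int, sparsity: float = 0.5, seed: int = 0) -> np.ndarray:
    """Distinct per-type gene-usage profiles on the G-simplex.

    sparsity is the fraction of genes per type forced to near-zero usage;
    disjoint-ish sparsity patterns across types control separation.
    """
    if L < 1 or G < 2:
        raise ValueError("need L >= 1 and G >= 2")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    profiles = rng.gamma(shape=1.0, scale=1.0, size=(L, G)) + 1e-12
    n_off = int(round(sparsity * G))
    for l in range(L):
        off = rng.choice(G, size=n_off, replace=False)
        profiles[l, off] *= 1e-4
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles


def simulate_dataset(L: int = 3, G: int = 200, B: int = 2, n_cells: int = 600,
                     batch_strength: float = 1.0, dirichlet_conc: float = 50.0,
                     mean_library: int = 2000, labeled_fraction: float = 0.8,
                     seed: int = 0, sparsity: float = 0.5):
    """Simulate a labeled multi-batch count matrix.

    Returns (CountMatrix, SyntheticTruth, labels) where labels is a per-cell
    list of type strings with None for the unlabeled hold-out.
    """
    if min(L, G, B, n_cells, mean_library) < 1 or dirichlet_conc <= 0:
        raise ValueError("all size/concentration parameters must be positive")
    if batch_strength < 0:
        raise ValueError("batch_strength must be >= 0")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    profiles = make_profiles(L, G, sparsity=sparsity, seed=seed)
    batch_effects = np.exp(rng.normal(0.0, batch_strength, size=(B, G)))

    y = rng.integers(0, L, size=n_cells)
    b = rng.integers(0, B, size=n_cells)
    libs = np.maximum(1, np.round(
        np.exp(rng.normal(np.log(mean_library), 0.3, size=n_cells)))).astype(int)

    pert = profiles[None, :, :] * batch_effects[:, None, :]  # B x L x G
    pert /= pert.sum(axis=2, keepdims=True)

    conc = dirichlet_conc * pert[b, y] + 1e-12  # cells x G
    gam = rng.gamma(conc)  # Dirichlet draw via normalized gammas
    eta = gam / gam.sum(axis=1, keepdims=True)
    counts = rng.multinomial(libs, eta)

    n_lab = int(round(labeled_fraction * n_cells))
    labeled_idx = rng.choice(n_cells, size=n_lab, replace=False)
    labels: list = [None] * n_cells
    for i in labeled_idx:
        labels[i] = f"type{y[i]}"

    cm = CountMatrix(sp.csr_matrix(counts),
                     [f"cell{i:05d}" for i in range(n_cells)],
                     [f"gene{j:04d}" for j in range(G)])
    truth = SyntheticTruth(profiles=profiles, batch_effects=batch_effects,
                           true_labels=y, true_batches=b, library_sizes=libs,
                           per_cell_eta=eta, seed=seed)
    return cm, truth, labels


# ---------------------------------------------------------------------------
# source-cohort bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class GroupRecord:
    group: int
    total_cells: int
    adult_cells: Optional[int]
    aged_cells: Optional[int]
    adult_patients: Optional[int]
    aged_patients: Optional[int]


@dataclass
class DatasetManifest:
    groups: list  # of GroupRecord

    def __post_init__(self):
        for g in self.groups:
            for v in (g.total_cells, g.adult_cells, g.aged_cells,
                      g.adult_patients, g.aged_patients):
                if v is not None and (v < 0 or int(v) != v):
                    raise ValueError("manifest entries must be nonnegative integers")


def table1_manifest() -> DatasetManifest:
    """Per-cohort cell and patient counts of the six integrated GBM datasets.

    Cohort 6 has no adult/aged split in the source bookkeeping; its entries
    are absent (None), never zero.
    """
    rows = [
        # group, total, adult cells, aged cells, adult pts, aged pts
        (1, 1901, 1645, 256, 3, 1),
        (2, 11786, 0, 11786, 0, 6),
        (3, 84969, 71053, 13916, 5, 2),
        (4, 15935, 12259, 3676, 1, 4),
        (5, 415, 415, 0, 1, 0),
        (6, 17982, None, None, None, None),
    ]
    return DatasetManifest(groups=[GroupRecord(*r) for r in rows])


def dataset_summary(m: DatasetManifest):
    """Column sums: (total_cells, adult_cells, aged_cells, total_patients).

    Absent values are skipped in the age-split sums; every group counts
    toward the grand total.
    """
    total_cells = sum(g.total_cells for g in m.groups)
    adult_cells = sum(g.adult_cells for g in m.groups if g.adult_cells is not None)
    aged_cells = sum(g.aged_cells for g in m.groups if g.aged_cells is not None)
    total_patients = sum((g.adult_patients or 0) + (g.aged_patients or 0)
                         for g in m.groups)
    return total_cells, adult_cells, aged_cells, total_patients
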