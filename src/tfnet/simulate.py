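"""Ground-truth generator for the benchmark simulation study.

Emulates the conditions the model targets: a sparse loading matrix with
Bernoulli support and Gaussian slab coefficients, clustered non-negative TF
activities (rectified Gaussians around per-cluster, per-TF centers), additive
white Gaussian noise, and an imperfect prior database obtained by corrupting
the true edge set at a stated precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .distributions import cut
from .model import ExpressionMatrix

__all__ = [
    "SyntheticSystem",
    "simulate_network",
    "simulate_factors",
    "simulate_expression",
    "corrupt_database",
    "benchmark_scenario",
    "NOISE_PRESETS",
]

#: Additive noise presets (variances): noise SD 0.1 ("low") and 1.0 ("high").
NOISE_PRESETS = {"low": 0.01, "high": 1.0}


@dataclass
class SyntheticSystem:
    """A complete simulated regulatory system with its ground truth."""

    A_true: np.ndarray
    X_true: np.ndarray
    labels_true: np.ndarray
    c_true: np.ndarray
    noise_var: float
    Y: ExpressionMatrix
    true_edges: set[tuple[str, str]]
    database_edges: set[tuple[str, str]]

    @property
    def gene_labels(self) -> list[str]:
        return self.Y.gene_labels

    @property
    def tf_labels(self) -> list[str]:
        L = self.X_true.shape[0]
        return [f"TF{j:02d}" for j in range(L)]


def _gene_names(G: int) -> list[str]:
    return [f"G{i:04d}" for i in range(G)]


def _tf_names(L: int) -> list[str]:
    return [f"TF{j:02d}" for j in range(L)]


def simulate_network(
    G: int,
    L: int,
    sparsity: float,
    rng: np.random.Generator,
    slab_sd: float = 1.0,
) -> tuple[np.ndarray, set[tuple[str, str]]]:
    """Sparse loading matrix: each pair regulated independently with
    probability ``sparsity``; coefficients are zero-mean Gaussian so both up-
    and down-regulation occur."""
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    support = rng.random((G, L)) < sparsity
    A = np.where(support, rng.normal(0.0, slab_sd, size=(G, L)), 0.0)
    genes, tfs = _gene_names(G), _tf_names(L)
    edges = {(genes[g], tfs[l]) for g, l in zip(*np.nonzero(support))}
    return A, edges


def simulate_factors(
    L: int,
    N: int,
    K: int,
    rng: np.random.Generator,
    separation: float = 1.0,
    within_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Clustered non-negative activities.

    ``K`` cluster centers per TF are drawn as a standardized Gaussian set of
    spread ``separation`` (the realized center set of every TF has mean 0 and
    standard deviation ``separation``), samples are assigned to clusters in
    (near-)balanced fashion, and each activity is
    ``cut(Normal(center, within_sd^2))`` — a rectified Gaussian, so fully
    suppressed TF states occur naturally.  Standardizing the center set keeps
    the mean activity comparable across TFs, matching the premise of the
    centralized model that every TF's sample-mean activity sits at the shared
    prior factor mean.
    """
    if K > N:
        raise ValueError("cannot form more clusters than samples")
    centers = rng.normal(0.0, 1.0, size=(L, K))
    if K > 1:
        centers = (
            (centers - centers.mean(axis=1, keepdims=True))
            / centers.std(axis=1, keepdims=True)
            * separation
        )
    else:
        centers = np.zeros((L, K))
    labels = np.arange(N) % K
    rng.shuffle(labels)
    X = cut(centers[:, labels] + rng.normal(0.0, within_sd, size=(L, N)))
    return X, labels


def simulate_expression(
    A_true: np.ndarray,
    X_true: np.ndarray,
    c_true: np.ndarray,
    noise_var: float,
    rng: np.random.Generator,
    gene_labels=None,
    sample_labels=None,
) -> ExpressionMatrix:
    """Observed matrix ``Y = A X + c 1' + E`` with white Gaussian noise."""
    if not noise_var >= 0:
        raise ValueError("noise_var must be non-negative")
    G, L = A_true.shape
    L2, N = X_true.shape
    if L != L2 or c_true.shape != (G,):
        raise ValueError("shape mismatch between loadings, factors and constant")
    noise = rng.normal(0.0, np.sqrt(noise_var), size=(G, N)) if noise_var > 0 else 0.0
    Y = A_true @ X_true + c_true[:, None] + noise
    return ExpressionMatrix(
        values=Y,
        gene_labels=list(gene_labels) if gene_labels is not None else _gene_names(G),
        sample_labels=(
            list(sample_labels) if sample_labels is not None else
            [f"S{n:03d}" for n in range(N)]
        ),
    )


def corrupt_database(
    true_edges: set[tuple[str, str]],
    precision: float,
    recall: float,
    universe,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Imperfect database: keep each true edge with probability ``recall`` and
    add false edges from the non-edge pool so expected precision is met.

    The number of false entries is ``|kept| * (1 - p) / p`` in expectation
    (stochastic rounding of the fractional part).
    """
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0 <= v <= 1 or precision <= 0:
            raise ValueError(f"{name} out of range: {v}")
    if recall == 0:
        warnings.warn("recall=0: database will contain no true edge")
    true_edges = set(true_edges)
    universe = set(tuple(e) for e in universe)
    kept = {e for e in sorted(true_edges) if rng.random() < recall}
    non_edges = sorted(universe - true_edges)
    n_false_exact = len(kept) * (1.0 - precision) / precision
    n_false = int(n_false_exact) + (rng.random() < (n_false_exact % 1.0))
    if n_false > len(non_edges):
        raise ValueError("not enough non-edges to reach the requested precision")
    false = (
        [non_edges[i] for i in rng.choice(len(non_edges), size=n_false, replace=False)]
        if n_false
        else []
    )
    return kept | set(false)


def benchmark_scenario(
    rng: np.random.Generator,
    G: int = 150,
    N: int = 40,
    K: int = 5,
    L: int = 10,
    sparsity: float = 0.1,
    precision: float = 0.9,
    recall: float = 0.9,
    noise_var: float = NOISE_PRESETS["low"],
    separation: float = 1.0,
    within_sd: float = 0.3,
) -> SyntheticSystem:
    """The benchmark simulated system: 150 genes, 40 samples in 5 clusters,
    10 TFs, 10% loading sparsity, database precision = recall = 0.9."""
    A, true_edges = simulate_network(G, L, sparsity, rng)
    X, labels = simulate_factors(L, N, K, rng, separation=separation, within_sd=within_sd)
    c = rng.normal(0.0, 1.0, size=G)
    Y = simulate_expression(A, X, c, noise_var, rng)
    genes, tfs = _gene_names(G), _tf_names(L)
    universe = {(g, t) for g in genes for t in tfs}
    db = corrupt_database(true_edges, precision, recall, universe, rng)
    return SyntheticSystem(
        A_true=A,
        X_true=X,
        labels_true=labels,
        c_true=c,
        noise_var=noise_var,
        Y=Y,
        true_edges=true_edges,
        database_edges=db,
    )
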