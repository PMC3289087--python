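"""Posterior summaries returned by a fitted model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NonnegativeFactorResults", "consensus_clustering"]


def consensus_clustering(cofreq: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Consensus labels from the posterior co-clustering frequency matrix.

    Average-linkage agglomeration on the dissimilarity ``1 - frequency``, cut
    where the average co-clustering frequency between groups drops below
    ``threshold``.  Returns integer labels starting at 0, ordered by first
    occurrence.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    cofreq = np.asarray(cofreq, dtype=float)
    n = cofreq.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    d = 1.0 - cofreq
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=1.0 - threshold, criterion="distance")
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        labels[i] = order[lab]
    return labels


@dataclass
class NonnegativeFactorResults:
    """Posterior summary of the sparse non-negative factor model.

    Attributes
    ----------
    edge_prob
        G x L posterior probabilities that each loading is nonzero, i.e. that
        TF l regulates gene g.
    A_mean
        G x L posterior-mean regulatory coefficients.
    X_mean
        L x N posterior-mean TF activities on the original (non-negative) scale.
    c_est
        Length-G estimate of the constant expression term, ``mu_y - A mu_x``.
    clustering
        Consensus sample labels derived from the co-clustering frequencies.
    cofreq
        N x N posterior co-clustering frequency matrix.
    """

    edge_prob: np.ndarray
    A_mean: np.ndarray
    X_mean: np.ndarray
    c_est: np.ndarray
    mu_x: np.ndarray
    mu_y: np.ndarray
    clustering: np.ndarray
    cofreq: np.ndarray
    n_samples_used: int
    gene_labels: list[str]
    tf_labels: list[str]
    sample_labels: list[str]
    config: object = None
    traces: dict = field(default_factory=dict)

    def predicted_edges(self, threshold: float | None = None) -> set[tuple[str, str]]:
        """(gene, tf) pairs with posterior probability >= threshold."""
        if threshold is None:
            threshold = getattr(self.config, "edge_threshold", 0.5)
        rows, cols = np.nonzero(self.edge_prob >= threshold)
        return {(self.gene_labels[g], self.tf_labels[l]) for g, l in zip(rows, cols)}

    def edge_table(self) -> pd.DataFrame:
        """Long-form table: gene, tf, posterior probability, mean coefficient."""
        g_idx, l_idx = np.meshgrid(
            np.arange(len(self.gene_labels)),
            np.arange(len(self.tf_labels)),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "gene": np.asarray(self.gene_labels)[g_idx.ravel()],
                "tf": np.asarray(self.tf_labels)[l_idx.ravel()],
                "posterior_prob": self.edge_prob.ravel(),
                "mean_coefficient": self.A_mean.ravel(),
            }
        )
        return df.sort_values("posterior_prob", ascending=False, ignore_index=True)

    def factor_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X_mean, index=self.tf_labels, columns=self.sample_labels
        )

    def clustering_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_labels, "consensus_label": self.clustering}
        )

    @property
    def n_clusters(self) -> int:
        return int(self.clustering.max()) + 1

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        thr = getattr(self.config, "edge_threshold", 0.5)
        n_edges = int((self.edge_prob >= thr).sum())
        sizes = np.bincount(self.clustering)
        lines = [
            "Bayesian non-negative factor model — posterior summary",
            "=" * 56,
            f"genes: {len(self.gene_labels)}   TFs: {len(self.tf_labels)}   "
            f"samples: {len(self.sample_labels)}",
            f"posterior draws used: {self.n_samples_used}",
            f"edges with P(regulation) >= {thr}: {n_edges}",
            f"consensus clusters: {self.n_clusters} "
            f"(sizes: {', '.join(map(str, sizes))})",
            f"prior factor mean mu_x: {self.mu_x[0]:.4f}",
            "",
            "top edges by posterior probability:",
        ]
        top = self.edge_table().head(10)
        for _, row in top.iterrows():
            lines.append(
                f"  {row.gene:>12s} <- {row.tf:<10s} "
                f"p={row.posterior_prob:0.3f}  coef={row.mean_coefficient:+0.3f}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------ plots

    def plot_edge_probability_hist(self, ax=None, bins: int = 40):
        """Histogram of all posterior regulation probabilities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.edge_prob.ravel(), bins=bins, color="steelblue")
        ax.set_xlabel("posterior probability of regulation")
        ax.set_ylabel("gene-TF pairs")
        return ax

    def plot_factors(self, ax=None):
        """Heatmap of posterior-mean TF activities, samples grouped by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.clustering, kind="stable")
        im = ax.imshow(self.X_mean[:, order], aspect="auto", cmap="viridis")
        ax.set_xlabel("samples (grouped by consensus cluster)")
        ax.set_ylabel("TF")
        ax.set_yticks(range(len(self.tf_labels)), self.tf_labels)
        ax.figure.colorbar(im, ax=ax, label="activity")
        return ax
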