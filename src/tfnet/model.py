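"""Model containers and the centralized-observation machinery.

The observed model is ``y_n = A x_n + c + e_n`` with non-negative factors
``x_n = cut(s_n)``.  Because the factor prior mean ``mu_x = E[cut(s)]`` is not
zero, removing the row means of the data does *not* remove the constant term:
the centralized model is ``yhat_n = A xhat_n + e_n`` with shifted factors
``xhat = cut(s) - mu_x``, and the constant term is recovered afterwards as
``c = mu_y - A mu_x``.

:class:`NonnegativeFactorModel` is the user-facing entry point: construct it
from an expression matrix plus a prior network, call :meth:`fit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import NIGParams, cut, student_t_predictive
from .priors import PriorNetwork, build_prior_network

__all__ = [
    "ExpressionMatrix",
    "ModelState",
    "centralize",
    "prior_factor_mean",
    "recover_factors",
    "estimate_constant",
    "NonnegativeFactorModel",
]


@dataclass
class ExpressionMatrix:
    """G x N matrix of log2 expression with gene and sample labels."""

    values: np.ndarray
    gene_labels: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        g, n = self.values.shape
        if len(self.gene_labels) != g or len(self.sample_labels) != n:
            raise ValueError("label counts do not match matrix dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_labels, columns=self.sample_labels
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_labels=[str(i) for i in df.index],
            sample_labels=[str(c) for c in df.columns],
        )


@dataclass
class ModelState:
    """One Gibbs state of the centralized model.

    ``Xc = cut(S) - mu_x`` elementwise at all times; ``gamma`` holds contiguous
    cluster labels starting at 0.
    """

    A: np.ndarray      # G x L loadings
    S: np.ndarray      # L x N pseudo-factors
    Xc: np.ndarray     # L x N centralized factors
    gamma: np.ndarray  # N cluster labels
    psi: np.ndarray    # G noise variances
    lam: np.ndarray    # L slab variances
    mu_x: np.ndarray   # L non-negative prior factor means

    def validate(self) -> None:
        if not np.allclose(cut(self.S) - self.mu_x[:, None], self.Xc, atol=1e-9):
            raise AssertionError("Xc inconsistent with cut(S) - mu_x")
        if np.any(self.psi <= 0) or np.any(self.lam <= 0):
            raise AssertionError("variances must stay positive")
        labels = np.unique(self.gamma)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise AssertionError("cluster labels not contiguous")


def centralize(Y: ExpressionMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove row (gene) means: returns ``(Yc, mu_y)`` with ``Yc = Y - mu_y``."""
    values = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    if values.shape[1] < 2:
        raise ValueError("at least two samples are required to centralize")
    mu_y = values.mean(axis=1)
    return values - mu_y[:, None], mu_y


def prior_factor_mean(
    hyper: NIGParams,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
    n_tfs: int = 1,
) -> np.ndarray:
    """Monte-Carlo estimate of ``mu_x = E[cut(s)]`` under the base prior.

    ``s`` follows the NIG-marginalized (Student-t) base predictive of the DPM;
    the DP concentration does not enter because all mixture components share
    the same base.  With shared hyperparameters the value is identical for
    every TF, so a constant vector of length ``n_tfs`` is returned.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10^4 for a stable estimate")
    if rng is None:
        rng = np.random.default_rng(0)
    df, loc, scale = student_t_predictive(np.empty(0), hyper)
    draws = loc + scale * rng.standard_t(df, size=n_mc)
    return np.full(n_tfs, float(cut(draws).mean()))


def recover_factors(Xc: np.ndarray, mu_x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Undo the centralization shift: ``X = Xc + mu_x``, clipped at 0.

    Entries below ``-mu_x`` by more than ``tol`` indicate an inconsistent
    state and raise.
    """
    Xc = np.asarray(Xc, float)
    mu_x = np.asarray(mu_x, float)
    X = Xc + mu_x[:, None]
    if np.any(X < -tol):
        raise ValueError("centralized factors fall below -mu_x beyond tolerance")
    return cut(X)


def estimate_constant(
    mu_y: np.ndarray, A_mean: np.ndarray, mu_x: np.ndarray
) -> np.ndarray:
    """Constant term ``c = mu_y - A mu_x`` (the removed row mean alone is biased)."""
    mu_y = np.asarray(mu_y, float)
    A_mean = np.asarray(A_mean, float)
    mu_x = np.asarray(mu_x, float)
    if A_mean.shape != (mu_y.size, mu_x.size):
        raise ValueError("shape mismatch between mu_y, A_mean and mu_x")
    return mu_y - A_mean @ mu_x


class NonnegativeFactorModel:
    """Bayesian non-negative factor model for TF-mediated regulation.

    Parameters
    ----------
    expression
        G x N log2 expression matrix (genes by samples).
    prior
        Per-(gene, TF) prior probabilities of regulation; build one with
        :func:`tfnet.priors.build_prior_network` or pass a dataframe-based
        constructor below.
    nig
        Normal-Inverse-Gamma base measure of the DP mixture over pseudo-factors.
    alpha_dp
        DP concentration; larger values favour more sample clusters.
    alpha_n, beta_n
        Inverse-Gamma hyperparameters of the per-gene noise variances.
    alpha_a, beta_a
        Inverse-Gamma hyperparameters of the per-TF slab variances.

    Examples
    --------
    >>> system = benchmark_scenario(rng=np.random.default_rng(0))  # doctest: +SKIP
    >>> model = NonnegativeFactorModel.from_arrays(system.Y, prior)  # doctest: +SKIP
    >>> res = model.fit(n_iter=2000, n_burnin=500, seed=1)  # doctest: +SKIP
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        prior: PriorNetwork,
        *,
        nig: NIGParams = NIGParams(),
        alpha_dp: float = 1.0,
        alpha_n: float = 1.0,
        beta_n: float = 0.1,
        alpha_a: float = 2.0,
        beta_a: float = 1.0,
    ) -> None:
        if list(prior.genes) != list(expression.gene_labels):
            raise ValueError("prior network gene labels must match expression rows")
        self.expression = expression
        self.prior = prior
        self.nig = nig
        self.alpha_dp = alpha_dp
        self.alpha_n = alpha_n
        self.beta_n = beta_n
        self.alpha_a = alpha_a
        self.beta_a = beta_a

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        edges,
        tfs=None,
        pi_recorded: float = 0.9,
        pi_unrecorded: float | None = None,
        **kwargs,
    ) -> "NonnegativeFactorModel":
        """Build from a genes-by-samples dataframe and a (gene, tf) edge list.

        ``tfs`` defaults to the sorted set of TF labels occurring in ``edges``;
        ``pi_unrecorded`` defaults to the genome-scale 500/20000 figure.
        """
        from .priors import DEFAULT_UNRECORDED_PI

        expr = ExpressionMatrix.from_frame(expression)
        edges = set(tuple(e) for e in edges)
        if tfs is None:
            tfs = sorted({t for _, t in edges})
        if pi_unrecorded is None:
            pi_unrecorded = DEFAULT_UNRECORDED_PI
        prior = build_prior_network(
            expr.gene_labels, tfs, edges, pi_recorded, pi_unrecorded
        )
        return cls(expr, prior, **kwargs)

    def fit(
        self,
        n_iter: int = 10_000,
        n_burnin: int = 2_000,
        thin: int = 1,
        seed: int = 0,
        edge_threshold: float = 0.5,
        progress: bool = False,
    ):
        """Run the Gibbs sampler and return a :class:`NonnegativeFactorResults`."""
        from .sampler import GibbsConfig, run_gibbs

        cfg = GibbsConfig(
            n_iter=n_iter,
            n_burnin=n_burnin,
            thin=thin,
            seed=seed,
            alpha_dp=self.alpha_dp,
            alpha_n=self.alpha_n,
            beta_n=self.beta_n,
            alpha_a=self.alpha_a,
            beta_a=self.beta_a,
            nig=self.nig,
            edge_threshold=edge_threshold,
        )
        return run_gibbs(self.expression, self.prior, cfg, progress=progress)
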