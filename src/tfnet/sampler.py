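"""Gibbs sampler for the sparse non-negative factor model.

One sweep updates, in order: slab variances ``lambda_l``, noise variances
``psi_g``, every loading ``a_{g,l}`` (spike-and-slab, column-blocked with
incremental residual updates), every cluster label ``gamma_n`` (collapsed
Chinese-restaurant update with Student-t predictives), then — after
instantiating the cluster means/variances from their Normal-Inverse-Gamma
posterior — every centralized factor ``xhat_{l,n}`` (mixture of the rectified
zero state and a lower-truncated Gaussian) and pseudo-factor ``s_{l,n}``.

Instantiating the cluster parameters once per sweep keeps every factor update
an exact conjugate draw; the parameters are discarded afterwards, so the chain
still targets the collapsed posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .distributions import (
    NIGParams,
    cut,
    student_t_logpdf,
    student_t_predictive,
    truncated_gaussian_sample,
)
from .model import (
    ExpressionMatrix,
    centralize,
    estimate_constant,
    prior_factor_mean,
)
from .priors import PriorNetwork

__all__ = [
    "GibbsConfig",
    "GibbsSampler",
    "run_gibbs",
    "psrf",
    "spike_slab_update",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler configuration and model hyperparameters."""

    n_iter: int = 10_000
    n_burnin: int = 2_000
    thin: int = 1
    seed: int = 0
    alpha_dp: float = 1.0       # DP concentration
    alpha_n: float = 1.0        # noise variance ~ InvGamma(alpha_n, beta_n)
    beta_n: float = 0.1
    alpha_a: float = 2.0        # slab variance ~ InvGamma(alpha_a, beta_a)
    beta_a: float = 1.0
    nig: NIGParams = field(default_factory=NIGParams)
    edge_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name in ("alpha_dp", "alpha_n", "beta_n", "alpha_a", "beta_a"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.edge_threshold < 1:
            raise ValueError("edge_threshold must be in (0, 1)")


def _norm_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _skew(x: np.ndarray) -> float:
    """Sample skewness (biased form is fine for an orientation decision)."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    m2 = float((d**2).mean())
    if m2 <= 0:
        return 0.0
    return float((d**3).mean() / m2**1.5)


def spike_slab_update(xtx, xty, psi, lam, pi):
    """Spike-and-slab conditional for one loading (vectorized over genes).

    Given the regressor energy ``xtx = x'x``, the residual projection
    ``xty = x'yhat`` (with the current loading's contribution added back),
    noise variance ``psi`` and slab variance ``lam``, the Bayes factor of the
    zero model against the slab model is

        BF01 = sqrt(1 + lam*xtx/psi) * exp(-lam*xty^2 / (2 psi (psi + lam*xtx)))

    and the loading is nonzero with posterior probability
    ``pi / (pi + (1 - pi) BF01)``.  Returns ``(p_nonzero, slab_mean, slab_var)``.
    Exact prior zeros/ones are honoured as hard constraints.
    """
    xtx = np.asarray(xtx, dtype=float)
    xty = np.asarray(xty, dtype=float)
    psi = np.asarray(psi, dtype=float)
    log_bf01 = 0.5 * np.log1p(lam * xtx / psi) - 0.5 * lam * xty**2 / (
        psi * (psi + lam * xtx)
    )
    pi_c = np.clip(pi, 1e-12, 1.0 - 1e-12)
    log_odds = np.log(pi_c) - np.log1p(-pi_c) - log_bf01
    p_nonzero = special.expit(log_odds)
    p_nonzero = np.where(np.asarray(pi) <= 0.0, 0.0, p_nonzero)
    p_nonzero = np.where(np.asarray(pi) >= 1.0, 1.0, p_nonzero)
    slab_var = 1.0 / (xtx / psi + 1.0 / lam)
    slab_mean = slab_var * xty / psi
    return p_nonzero, slab_mean, slab_var


class GibbsSampler:
    """Mutable sampler state over centralized data ``Yc = A Xc + E``.

    Built directly from arrays so that tiny instances (oracle tests,
    joint-distribution validation) can drive individual kernels; normal use
    goes through :func:`run_gibbs`.
    """

    def __init__(
        self,
        Yc: np.ndarray,
        pi: np.ndarray,
        cfg: GibbsConfig,
        mu_x: np.ndarray,
        rng: np.random.Generator,
    ) -> None:
        self.Yc = np.asarray(Yc, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.cfg = cfg
        self.rng = rng
        self.G, self.N = self.Yc.shape
        self.L = self.pi.shape[1]
        if self.pi.shape[0] != self.G:
            raise ValueError("pi and Yc disagree on the number of genes")
        self.mu_x = np.asarray(mu_x, dtype=float)
        if self.mu_x.shape != (self.L,):
            raise ValueError("mu_x must have one entry per TF")
        nig = cfg.nig
        self._df0, self._loc0, self._scale0 = student_t_predictive(np.empty(0), nig)
        self.init_state()

    # ------------------------------------------------------------------ setup

    def init_state(self) -> None:
        """Overdispersed initialization from the priors."""
        cfg, rng = self.cfg, self.rng
        self.lam = (cfg.beta_a / rng.gamma(cfg.alpha_a, size=self.L)).clip(1e-12)
        self.psi = (cfg.beta_n / rng.gamma(cfg.alpha_n, size=self.G)).clip(1e-12)
        support = rng.random((self.G, self.L)) < self.pi
        self.A = np.where(
            support, rng.normal(0.0, np.sqrt(self.lam), size=(self.G, self.L)), 0.0
        )
        t_draws = self._loc0 + self._scale0 * rng.standard_t(
            self._df0, size=(self.L, self.N)
        )
        self.S = t_draws
        self.Xc = cut(self.S) - self.mu_x[:, None]
        self.gamma = np.zeros(self.N, dtype=int)
        self.E = self.Yc - self.A @ self.Xc
        self._refresh_cluster_stats()

    def set_data(self, Yc: np.ndarray) -> None:
        """Replace the (centralized) data, keeping the latent state."""
        self.Yc = np.asarray(Yc, dtype=float)
        self.E = self.Yc - self.A @ self.Xc

    def oriented_init(self) -> None:
        """Data-driven factor initialization.

        Spike-and-slab factor models mix poorly from a diffuse start: a factor
        whose loadings collapse to the spike never picks up its signal, and a
        factor can settle into the sign-flipped image of the truth.  Each
        factor row is therefore initialized from the first principal component
        of the prior-recorded target genes' (centralized) expression, oriented
        by skewness — rectified activities have a long right tail — and scaled
        to respect the lower bound ``-mu_x``.  Loadings start at zero; the
        first sweep regresses them onto the oriented factors.
        """
        Yc = self.Yc
        Xc0 = np.empty((self.L, self.N))
        for l in range(self.L):
            targets = self.pi[:, l] >= 0.5
            rows = Yc[targets] if int(targets.sum()) >= 2 else Yc
            _, _, vt = np.linalg.svd(
                rows - rows.mean(axis=1, keepdims=True), full_matrices=False
            )
            score = vt[0]
            if _skew(score) < 0:
                score = -score
            sd = score.std()
            if sd > 0:
                score = score / sd * 0.7
            lo = score.min()
            bound = 0.9 * self.mu_x[l]
            if lo < -bound:
                score = score * (bound / -lo)
            Xc0[l] = score
        self.Xc = Xc0
        self.S = Xc0 + self.mu_x[:, None]
        self.A = np.zeros((self.G, self.L))
        self.E = self.Yc.copy()
        self.gamma = np.zeros(self.N, dtype=int)
        self._refresh_cluster_stats()

    def reorient(self, Xbar: np.ndarray) -> int:
        """Flip factor rows whose running-mean skewness is negative.

        A flipped row (together with its negated, rescaled loading column)
        leaves the likelihood unchanged, so this burn-in-only move just
        relocates the chain into the correctly oriented posterior basin.
        Returns the number of rows flipped.
        """
        n_flipped = 0
        for l in range(self.L):
            if _skew(Xbar[l]) < 0:
                cur = self.Xc[l]
                mxl = float(self.mu_x[l])
                top = cur.max()
                c = min(1.0, 0.95 * mxl / top) if top > 0 else 1.0
                self.A[:, l] *= -1.0 / c
                self.Xc[l] = -c * cur
                self.S[l] = self.Xc[l] + mxl
                n_flipped += 1
        if n_flipped:
            self.E = self.Yc - self.A @ self.Xc
            self._refresh_cluster_stats()
        return n_flipped

    def _refresh_cluster_stats(self) -> None:
        K = int(self.gamma.max()) + 1
        self.counts = np.bincount(self.gamma, minlength=K)
        self.sums = np.zeros((K, self.L))
        self.sumsqs = np.zeros((K, self.L))
        np.add.at(self.sums, self.gamma, self.S.T)
        np.add.at(self.sumsqs, self.gamma, self.S.T**2)

    # ---------------------------------------------------------- conditionals

    def update_slab_variances(self) -> None:
        """lambda_l ~ InvGamma(alpha_a + N_al/2, beta_a + sum a^2 / 2)."""
        cfg = self.cfg
        n_nz = (self.A != 0).sum(axis=0)
        ssq = (self.A**2).sum(axis=0)
        shape = cfg.alpha_a + 0.5 * n_nz
        scale = cfg.beta_a + 0.5 * ssq
        self.lam = (scale / self.rng.gamma(shape, size=self.L)).clip(1e-12)

    def update_noise_variances(self) -> None:
        """psi_g ~ InvGamma(alpha_n + N/2, beta_n + ||e_g||^2 / 2)."""
        cfg = self.cfg
        ssq = np.einsum("gn,gn->g", self.E, self.E)
        shape = cfg.alpha_n + 0.5 * self.N
        scale = cfg.beta_n + 0.5 * ssq
        self.psi = (scale / self.rng.gamma(shape, size=self.G)).clip(1e-300)

    def update_loading_column(self, l: int) -> None:
        """Block spike-and-slab update of column l (genes are conditionally
        independent given the factors, so the block draw is exact)."""
        x = self.Xc[l]
        xtx = float(x @ x)
        R = self.E + np.outer(self.A[:, l], x)
        xty = R @ x
        p_nz, m, v = spike_slab_update(xtx, xty, self.psi, self.lam[l], self.pi[:, l])
        nonzero = self.rng.random(self.G) < p_nz
        draws = m + np.sqrt(v) * self.rng.standard_normal(self.G)
        a_new = np.where(nonzero, draws, 0.0)
        self.A[:, l] = a_new
        self.E = R - np.outer(a_new, x)

    def update_loadings(self) -> None:
        for l in range(self.L):
            self.update_loading_column(l)

    def _cluster_predictive_params(self):
        """Student-t predictive (df, loc, scale) per (cluster, TF) from stats."""
        nig = self.cfg.nig
        counts = self.counts.astype(float)[:, None]
        kn = nig.k0 + counts
        mn = (nig.k0 * nig.m0 + self.sums) / kn
        an = nig.a0 + 0.5 * counts
        bn = nig.b0 + 0.5 * (self.sumsqs + nig.k0 * nig.m0**2 - kn * mn**2)
        bn = np.maximum(bn, 1e-300)
        df = 2.0 * an
        scale = np.sqrt(bn * (kn + 1.0) / (an * kn))
        return df, mn, scale, (kn, an, bn)

    def update_cluster_label(self, n: int) -> None:
        """Collapsed CRP draw of gamma_n given the pseudo-factors."""
        s_n = self.S[:, n]
        k_old = self.gamma[n]
        self.counts[k_old] -= 1
        self.sums[k_old] -= s_n
        self.sumsqs[k_old] -= s_n**2
        if self.counts[k_old] == 0:
            self.counts = np.delete(self.counts, k_old)
            self.sums = np.delete(self.sums, k_old, axis=0)
            self.sumsqs = np.delete(self.sumsqs, k_old, axis=0)
            self.gamma[self.gamma > k_old] -= 1
        df, mn, scale, _ = self._cluster_predictive_params()
        logp = student_t_logpdf(s_n[None, :], df, mn, scale).sum(axis=1)
        log_w = np.log(self.counts.astype(float)) + logp
        logp_new = float(
            student_t_logpdf(s_n, self._df0, self._loc0, self._scale0).sum()
        )
        log_w = np.append(log_w, math.log(self.cfg.alpha_dp) + logp_new)
        log_w -= log_w.max()
        w = np.exp(log_w)
        k_new = int(np.searchsorted(np.cumsum(w), self.rng.random() * w.sum()))
        k_new = min(k_new, len(self.counts))  # guard against roundoff overshoot
        if k_new == len(self.counts):
            self.counts = np.append(self.counts, 0)
            self.sums = np.vstack([self.sums, np.zeros(self.L)])
            self.sumsqs = np.vstack([self.sumsqs, np.zeros(self.L)])
        self.gamma[n] = k_new
        self.counts[k_new] += 1
        self.sums[k_new] += s_n
        self.sumsqs[k_new] += s_n**2

    def update_cluster_labels(self) -> None:
        for n in range(self.N):
            self.update_cluster_label(n)

    def draw_cluster_params(self):
        """Instantiate (mu, sigma^2) per (cluster, TF) from the NIG posterior."""
        _, mn, _, (kn, an, bn) = self._cluster_predictive_params()
        var = bn / self.rng.gamma(an)
        mu = mn + np.sqrt(var / kn) * self.rng.standard_normal(var.shape)
        return mu, var

    def _truncated_normal_lower(self, mean, var, lower):
        """Vectorized Normal(mean, var) draws conditioned on exceeding lower."""
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        var = np.atleast_1d(np.asarray(var, dtype=float))
        sd = np.sqrt(var)
        lower = np.broadcast_to(np.asarray(lower, dtype=float), mean.shape)
        alpha = (lower - mean) / sd
        out = np.empty_like(mean)
        easy = alpha < 4.0
        if np.any(easy):
            sf = special.ndtr(-alpha[easy])
            u = self.rng.random(int(easy.sum())) * sf
            z = -special.ndtri(np.maximum(u, 1e-300))
            out[easy] = mean[easy] + sd[easy] * z
        for i in np.flatnonzero(~easy):
            out[i] = truncated_gaussian_sample(
                float(mean[i]), float(var[i]), float(lower[i]), self.rng
            )
        return out

    def update_factor_row(self, l: int, mu_c: np.ndarray, var_c: np.ndarray) -> None:
        """Joint draw of (xhat_{l,n}, s_{l,n}) for all samples n.

        The conditional of the pseudo-factor is a two-part mixture: with the
        posterior zero-state weight, s is a <=0 truncated Gaussian and
        xhat = -mu_x (TF fully suppressed); otherwise xhat is a Gaussian
        truncated to (-mu_x, inf) combining the likelihood with the
        cluster-conditional prior, and s = xhat + mu_x.
        """
        rng = self.rng
        a_l = self.A[:, l]
        aw = a_l / self.psi
        prec = float(a_l @ aw)
        mxl = float(self.mu_x[l])
        g = mu_c[self.gamma, l]
        h = var_c[self.gamma, l]
        sd_h = np.sqrt(h)
        R = self.E + np.outer(a_l, self.Xc[l])
        if prec < 1e-300:
            # no information from the data: draw from the rectified prior
            p_zero = special.ndtr(-g / sd_h)
            zero = rng.random(self.N) < p_zero
            s_pos = self._truncated_normal_lower(g, h, 0.0)
            xc_new = np.where(zero, -mxl, s_pos - mxl)
        else:
            m_lik = (aw @ R) / prec
            v_lik = 1.0 / prec
            v_post = 1.0 / (prec + 1.0 / h)
            m_post = v_post * (m_lik * prec + (g - mxl) / h)
            log_w0 = special.log_ndtr(-g / sd_h) + _norm_logpdf(-mxl, m_lik, v_lik)
            log_wc = _norm_logpdf(m_lik, g - mxl, v_lik + h) + special.log_ndtr(
                (m_post + mxl) / np.sqrt(v_post)
            )
            p_zero = special.expit(log_w0 - log_wc)
            zero = rng.random(self.N) < p_zero
            trunc = self._truncated_normal_lower(m_post, v_post, -mxl)
            xc_new = np.where(zero, -mxl, trunc)
        # pseudo-factors: deterministic on the positive branch, truncated
        # Gaussian (<= 0) on the zero branch
        s_new = xc_new + mxl
        if np.any(zero):
            neg = -self._truncated_normal_lower(-g[zero], h[zero], 0.0)
            s_new[zero] = neg
        self.Xc[l] = xc_new
        self.S[l] = s_new
        self.E = R - np.outer(a_l, xc_new)

    def update_factors(self) -> None:
        mu_c, var_c = self.draw_cluster_params()
        for l in range(self.L):
            self.update_factor_row(l, mu_c, var_c)
        self._refresh_cluster_stats()

    def relabel_canonical(self) -> None:
        """Relabel clusters by first occurrence (labels are non-identifiable)."""
        order: dict[int, int] = {}
        for lab in self.gamma:
            if lab not in order:
                order[lab] = len(order)
        if all(k == v for k, v in order.items()):
            return
        perm = np.array([order[k] for k in range(len(self.counts))])
        self.gamma = perm[self.gamma]
        inv = np.argsort(perm)
        self.counts = self.counts[inv]
        self.sums = self.sums[inv]
        self.sumsqs = self.sumsqs[inv]

    def sweep(self) -> None:
        """One full Gibbs sweep over all conditionals."""
        self.update_slab_variances()
        self.update_noise_variances()
        self.update_loadings()
        self.update_cluster_labels()
        self.update_factors()
        self.relabel_canonical()


def run_gibbs(
    Y: ExpressionMatrix,
    prior: PriorNetwork,
    cfg: GibbsConfig,
    progress: bool = False,
):
    """Fit the model by Gibbs sampling and summarize the posterior.

    Returns a :class:`tfnet.results.NonnegativeFactorResults`.
    """
    from .results import NonnegativeFactorResults, consensus_clustering

    if Y.n_genes != len(prior.genes):
        raise ValueError("expression and prior disagree on the number of genes")
    Yc, mu_y = centralize(Y)
    ss = np.random.SeedSequence(cfg.seed)
    mu_x_seed, chain_seed = ss.spawn(2)
    L = len(prior.tfs)
    mu_x = prior_factor_mean(
        cfg.nig, n_mc=100_000, rng=np.random.default_rng(mu_x_seed), n_tfs=L
    )
    rng = np.random.default_rng(chain_seed)
    sampler = GibbsSampler(Yc, prior.pi, cfg, mu_x, rng)
    sampler.oriented_init()

    G, N = Yc.shape
    edge_count = np.zeros((G, L))
    A_sum = np.zeros((G, L))
    X_sum = np.zeros((L, N))
    coclust = np.zeros((N, N))
    n_used = 0
    trace_nclusters: list[int] = []
    trace_mean_psi: list[float] = []

    # burn-in-only reorientation checkpoints (see GibbsSampler.reorient)
    checkpoints = (
        {cfg.n_burnin // 4, cfg.n_burnin // 2, (3 * cfg.n_burnin) // 4}
        if cfg.n_burnin >= 8
        else set()
    )
    X_acc = np.zeros((L, N))
    n_acc = 0

    iterator = range(cfg.n_iter)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="gibbs")
        except ImportError:  # pragma: no cover
            pass
    for it in iterator:
        sampler.sweep()
        trace_nclusters.append(len(sampler.counts))
        trace_mean_psi.append(float(sampler.psi.mean()))
        if it < cfg.n_burnin:
            X_acc += sampler.Xc
            n_acc += 1
            if it in checkpoints:
                sampler.reorient(X_acc / n_acc)
                X_acc[:] = 0.0
                n_acc = 0
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            edge_count += sampler.A != 0
            A_sum += sampler.A
            X_sum += cut(sampler.S)
            same = sampler.gamma[:, None] == sampler.gamma[None, :]
            coclust += same
            n_used += 1

    edge_prob = edge_count / n_used
    A_mean = A_sum / n_used
    X_mean = X_sum / n_used
    cofreq = coclust / n_used
    labels = consensus_clustering(cofreq)
    c_est = estimate_constant(mu_y, A_mean, mu_x)
    return NonnegativeFactorResults(
        edge_prob=edge_prob,
        A_mean=A_mean,
        X_mean=X_mean,
        c_est=c_est,
        mu_x=mu_x,
        mu_y=mu_y,
        clustering=labels,
        cofreq=cofreq,
        n_samples_used=n_used,
        gene_labels=list(Y.gene_labels),
        tf_labels=list(prior.tfs),
        sample_labels=list(Y.sample_labels),
        config=cfg,
        traces={
            "n_clusters": np.asarray(trace_nclusters),
            "mean_psi": np.asarray(trace_mean_psi),
        },
    )


def psrf(chains) -> float:
    """Potential scale reduction factor over >= 2 equal-length scalar traces.

    Values near 1 indicate the chains are sampling the same distribution;
    values well above 1 indicate non-convergence.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValueError("psrf requires at least two chains")
    n = chains[0].size
    if n < 10 or any(c.size != n for c in chains):
        raise ValueError("chains must share a common length >= 10")
    means = np.array([c.mean() for c in chains])
    variances = np.array([c.var(ddof=1) for c in chains])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))
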