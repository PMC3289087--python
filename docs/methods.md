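# Methods

## Model

`tfnet` fits a sparse Bayesian factor model to a genes-by-samples log2
expression matrix `Y` (G × N):

```
y_n = A x_n + c + e_n,   e_n ~ N(0, diag(ψ_1 … ψ_G)),   ψ_g ~ InvGamma(α_n, β_n)
```

The latent factor `x_{l,n} ≥ 0` is the protein-level activity of TF `l` in
sample `n`, modeled as the rectification `x = cut(s) = max(s, 0)` of a Gaussian
pseudo-factor `s`. The rectified Gaussian keeps a point mass at zero — the
fully suppressed TF state — which a lower-truncated Gaussian cannot represent,
and it breaks the sign ambiguity of classical factor analysis: activities are
non-negative, and regulatory signs live exclusively in the loadings.

Samples are not independent: pseudo-factors follow a Dirichlet-process mixture
of Gaussians. Sample `n` carries a cluster label `γ_n` from a Chinese
restaurant process with concentration `α`; within cluster `k`, each TF
dimension has its own `(μ_{l,k}, σ²_{l,k})` with a conjugate
Normal-Inverse-Gamma base `NIG(m0, k0, a0, b0)` (`k0` is the prior-mean
precision scale, often written λ₀). The DPM clusters samples and selects the
number of clusters from the data.

Loadings are spike-and-slab:
`a_{g,l} ~ (1 − π_{g,l}) δ₀ + π_{g,l} N(0, λ_l)`, `λ_l ~ InvGamma(α_a, β_a)`.
The prior edge probability `π_{g,l}` carries database knowledge. If the
database is treated as an estimate of the true network with precision `p`,
recall `r`, and the network has sparsity `s`, confusion-matrix counting gives

```
π(recorded pair)   = p
π(unrecorded pair) = s (1 − r) / (1 − s r / p)
```

(validated in the tests against a brute-force counting oracle, since the
closed form follows from elementary counting). Without quality assumptions,
the genome-scale default for unrecorded pairs is 500/20000 = 0.025 (a typical
TF regulating ~500 of ~20000 genes); `π = 0.5` everywhere is the
noninformative baseline.

## Centralized (equivalent) model

Factor models are fitted to row-centered data to eliminate the constant term,
but here the factor mean is positive, so centering does not remove `c`
cleanly. With `μ_x = E[cut(s)]` under the DPM base predictive (a rectified
Student-t, computed once by Monte Carlo with 10⁵ draws and a derived seed),
the centered data obey

```
ŷ_n = A x̂_n + e_n,   x̂_n = cut(s_n) − μ_x  ∈ (−μ_x, ∞)^L
```

and the constant term is recovered afterwards as `c = μ_y − A μ_x`. The
centered factors are a per-TF constant shift of the originals, so the sample
clustering geometry is untouched. `μ_x` uses the base predictive only (the DP
concentration does not enter); with shared hyperparameters it is one number
repeated per TF. Per-TF hyperparameters are accepted by the configuration if a
user wants TF-specific means.

## Gibbs sampler

One sweep updates:

1. **Slab variances** `λ_l ~ InvGamma(α_a + N_l/2, β_a + Σ a²/2)` over the
   `N_l` currently nonzero loadings of TF `l` (prior draw if the column is
   empty).
2. **Noise variances** `ψ_g ~ InvGamma(α_n + N/2, β_n + ‖e_g‖²/2)`.
3. **Loadings**, column by column. For entry `(g, l)` with the entry's own
   contribution added back into the residual (`x = x̂_l`, `ŷ = e_g + a x`):

   ```
   BF01 = √(1 + λ_l xᵀx/ψ_g) · exp(− λ_l (xᵀŷ)² / (2 ψ_g (ψ_g + λ_l xᵀx)))
   P(a ≠ 0 | …) = π / (π + (1 − π) BF01)
   ```

   and a nonzero draw comes from the conjugate slab posterior with precision
   `xᵀx/ψ_g + 1/λ_l`. BF01 ≥ 1 when `xᵀŷ = 0`, so the zero model is favoured
   even at `π = 0.5` — the sampler is sparsity-seeking by construction (this
   is asserted on pure-noise data in the tests). Within a column the genes are
   conditionally independent, so the column is updated as one vectorized
   block; residuals are updated incrementally (O(GN) per column). Prior
   entries of exactly 0 or 1 act as hard constraints; interior values are used
   through their log-odds with a numerical clamp at 10⁻¹².
4. **Cluster labels**, sequentially, with cluster parameters collapsed:
   leave-one-out sufficient statistics per (cluster, TF) give Student-t
   predictives, and `γ_n` is drawn CRP-style with weights
   `N_{−n,k} · Π_l t(s_{l,n})` for existing clusters and `α · Π_l t₀(s_{l,n})`
   for a new one. Collapsing means the label draw is unaffected by the current
   factor values, which speeds mixing. Labels are compacted and re-canonicalized
   (first-occurrence order) every sweep; they are non-identifiable anyway and
   are summarized through the co-clustering matrix.
5. **Factors and pseudo-factors.** The cluster means/variances are then
   *instantiated* once from their NIG posterior given `(S, γ)`, which makes
   every factor update exact rather than predictive-approximate: given
   `(μ_{l,k}, σ²_{l,k})`, the conditional of `x̂_{l,n}` is a two-part mixture
   of the rectified zero state `x̂ = −μ_x` and a Gaussian truncated to
   `(−μ_x, ∞)` whose location blends the likelihood (via the column residual)
   with the cluster prior; the mixture weight comes from the closed-form
   normalizers of both branches. The pseudo-factor follows deterministically
   (`s = x̂ + μ_x`) on the positive branch and as a ≤ 0 truncated Gaussian
   draw on the zero branch. The instantiated parameters are discarded at the
   end of the sweep, so the chain still targets the collapsed posterior
   (standard auxiliary-parameter Gibbs). This choice — exact augmentation
   instead of a large-count Normal approximation to the Student-t predictive —
   is what lets the joint-distribution test below validate the kernel with no
   approximation slack.

Posterior summaries use all post-burn-in (optionally thinned) draws: edge
probabilities are the retained-sample frequency of `a_{g,l} ≠ 0`, loadings
and factors are posterior means (factors reported on the original scale
`cut(S)`), and the consensus clustering applies average-linkage agglomeration
to `1 −` co-clustering frequency, cut at frequency 0.5.

## Initialization and orientation

A single chain started from the prior has two failure basins it essentially
never leaves: a *dead* factor (all loadings in the spike; the factor decouples
from the data) and a *sign-flipped* factor (loading column negated, factor
reflected and rescaled inside the truncation bound — nearly
likelihood-equivalent, prior-penalized only through the loading scale).
`run_gibbs` therefore:

- initializes each factor row from the first principal component of the
  prior-recorded target genes' centered expression, oriented so its skewness
  is positive (rectified activities have a long right tail and an atom at the
  bottom) and scaled into the support, with loadings starting at zero; and
- at three checkpoints during burn-in, flips any factor row whose running-mean
  skewness is negative (negating and rescaling the loading column so the
  likelihood is exactly preserved).

Both devices act only before retained sampling begins, so the stationary
distribution is untouched; `GibbsSampler.init_state` retains the pure prior
initialization for kernel-level work.

## Validation strategy

- Every closed form (rectified-Gaussian mean, truncated-normal sampling,
  Student-t predictive, spike-and-slab posterior probability, CRP
  co-clustering probability, conjugate variance posteriors) is tested against
  an independent oracle: Monte Carlo, Kolmogorov–Smirnov against the analytic
  CDF, 2-D quadrature over (μ, σ²), 1-D evidence quadrature, or a grid
  posterior.
- The sampler as a whole passes a Geweke-style joint-distribution check at
  G=6, L=2, N=8: 10⁴ forward draws of (parameters, data) from the prior are
  compared with 10⁴ successive-conditional rounds (sweep, then regenerate the
  data from the current state) on seven tracked moments (loading support
  fraction and magnitude, log noise and slab variances, cluster count, mean
  pseudo-factor and centered factor), with batch-means standard errors; all
  |z| < 4. This exercises every conditional jointly.
- End-to-end recovery is checked on the benchmark generator (below).

A simple potential-scale-reduction diagnostic (`psrf`) over multiple scalar
traces is provided for convergence checking; routine use follows single-chain
practice with a fixed burn-in.

## Synthetic-data generator

`benchmark_scenario` reproduces the simulation conditions the method is
designed for: G=150 genes, N=40 samples in K=5 balanced clusters, L=10 TFs,
10% loading sparsity, and a corrupted database with precision = recall = 0.9.
Components:

- **Network**: each (gene, TF) pair regulated independently with probability
  0.1; nonzero coefficients `N(0, 1)`, so up- and down-regulation both occur.
  At this density a TF regulates ~15 genes and a gene is regulated by ~1 TF.
- **Activities**: per TF, K cluster centers drawn as a standardized Gaussian
  set with spread `separation` (default 1.0); activities are
  `cut(N(center, 0.3²))`. Standardizing the realized center set keeps the mean
  activity comparable across TFs, matching the model's premise that every
  TF's sample-mean activity sits at the shared prior factor mean; without it
  the pooled Pearson evaluation would measure generator/model mean mismatch
  rather than recovery quality.
- **Constant term** `c ~ N(0, 1)`; **noise** white Gaussian with presets
  `low` (SD 0.1) and `high` (SD 1.0).
- **Database**: each true edge kept with probability = recall; false edges
  added from the non-edge pool at the count that yields the target precision
  in expectation (stochastically rounded).

What the generator deliberately does **not** emulate: probe-level microarray
artifacts (background, saturation, normalization residue), heavy-tailed or
correlated noise, TF–TF interactions or combinatorial regulation, and context
dependence of edges beyond the stated precision/recall corruption. Passing
the recovery tests therefore demonstrates correctness of the inference under
the model's own generative assumptions plus database corruption — not
robustness to everything real expression data can contain.

## Defaults and problem sizes

| parameter | default | role |
|---|---|---|
| `m0, k0, a0, b0` | 0, 1, 2, 1 | NIG base; gives base predictive t(df=4, scale=√2) and `μ_x ≈ 0.50` |
| `α` (DP) | 1.0 | prior expected cluster count ~ log N; fixed, not resampled |
| `α_n, β_n` | 1.0, 0.1 | weak noise prior with mode 0.05, appropriate for log-scale residuals |
| `α_a, β_a` | 2.0, 1.0 | slab-variance prior, mean 1 |
| `edge threshold` | 0.5 | posterior cut-off for reporting regulations |
| iterations | 10000 / 2000 burn-in | default run length (single chain) |

The test suite and the acceptance script use scaled-down runs chosen to keep
Monte-Carlo error well below the margins being asserted: 2000 iterations with
500 burn-in for benchmark recovery (5 seeds in the tests), 800/200 for the
noise- and database-quality trend grids (2 seeds per cell; noise variances
0.01/1.0/4.0, quality 0.9/0.7/0.5), and 10⁴ rounds for the joint-distribution
check. The trend grid's top noise level exceeds the `high` preset because the
clustering error transition happens there: with 150 genes informing 10
factors, measurement noise is averaged down by roughly √(Σ_g a²_{g,l}/ψ), so
cluster structure survives noise that already degrades edge detection.

## Numerical choices

- Truncated-normal sampling switches from inverse-CDF (on the survival scale)
  to Robert's translated-exponential rejection when the standardized bound
  exceeds 4; far left bounds fall back to plain rejection.
- All mixture weights are computed in log space (`log_ndtr`, `log1p`,
  `expit`); Inverse-Gamma draws are floored at tiny positives to avoid exact
  zeros; the NIG scale update floors `b_n` against cancellation.
- A single `numpy.random.Generator` seeded from the run seed drives the chain;
  `μ_x` uses a sibling stream spawned from the same seed, so identical
  configurations are bit-reproducible.
- Ties at the edge threshold are included (`≥`).

## Limitations

- Only TFs present in the prior-knowledge edge list can be assigned targets;
  a regulator absent from the database is invisible to the model.
- The sampler is quadratic-ish in the data size per sweep and, like the
  underlying method, is not intended for genome-wide matrices; analyses should
  be restricted to a curated gene/TF set.
- The skewness-based orientation heuristic assumes activities with a
  suppressed (zero) state; a TF that is active in every sample has a weakly
  identified orientation in the first place.
- The DP concentration is fixed rather than resampled; cluster-count
  uncertainty is therefore understated when N is small.
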