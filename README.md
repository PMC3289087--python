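# tfnet

Transcription-factor regulatory-network inference from gene expression by
**Bayesian non-negative factor analysis**.

## The problem

Transcription factors (TFs) regulate when and how strongly their target genes
are transcribed, but the protein-level *activity* of a TF is rarely measurable
at scale — and a TF's own mRNA level is a poor proxy for it. `tfnet` treats TF
activities as latent factors behind the observed expression matrix and infers,
jointly:

- **which TF regulates which gene** (the sparse network, with posterior
  probabilities per edge),
- **the regulatory coefficients** (sign = up-/down-regulation, magnitude =
  strength),
- **the non-negative TF activity of every sample**, and
- **a clustering of the samples** (e.g. disease subtypes), discovered
  non-parametrically.

## The model

For a log2 expression matrix with columns `y_n` (G genes, N samples):

```
y_n = A x_n + c + e_n,          e_n ~ N(0, Ψ),  Ψ = diag(ψ_1 … ψ_G)
x_n = cut(s_n),                 cut(s) = max(s, 0) elementwise
s_n | γ_n = k ~ N(μ_k, Σ_k),    (μ_{l,k}, σ²_{l,k}) ~ NIG(m_0, λ_0, α_0, β_0)
γ_n ~ CRP(α)                    (Dirichlet-process mixture over samples)
a_{g,l} ~ (1 − π_{g,l}) δ_0 + π_{g,l} N(0, λ_l)
```

- Each TF activity is a **rectified Gaussian** — a point mass at zero (the
  suppressed state) plus a positive Gaussian branch — so activities are
  non-negative while loadings keep their sign. This also removes the sign
  ambiguity of ordinary factor analysis.
- The **spike-and-slab** prior on the loadings encodes database knowledge: a
  recorded TF→gene edge gets a high prior probability `π_{g,l}` (the assumed
  database precision), an unrecorded pair a small one derived from the
  database's precision `p`, recall `r` and the network sparsity `s`:

  ```
  π(recorded) = p,      π(unrecorded) = s(1 − r) / (1 − s·r/p)
  ```

- The **DP mixture** over pseudo-factors clusters samples without fixing the
  number of clusters.

Inference is a collapsed Gibbs sampler: Bayes-factor spike-and-slab updates
for every loading, Chinese-restaurant updates with Student-t predictives for
the cluster labels, truncated-Gaussian updates for the factors, and conjugate
Inverse-Gamma updates for all variances. Because the factor mean is positive,
data centralization is handled with the shifted ("equivalent") model and the
constant term is recovered as `c = μ_y − A μ_x`.

## Worked example

Simulate the benchmark system (150 genes, 40 samples in 5 clusters, 10 TFs,
10% loading sparsity, database precision = recall = 0.9), fit it, and score
the recovery:

```python
import numpy as np
from tfnet import (NonnegativeFactorModel, benchmark_scenario,
                   build_prior_network, pi_from_quality)
from tfnet.metrics import bcubed, pearson_recovery, target_prediction_eval

system = benchmark_scenario(np.random.default_rng(0))
pi_rec, pi_unrec = pi_from_quality(precision=0.9, recall=0.9, sparsity=0.1)
prior = build_prior_network(system.Y.gene_labels, system.tf_labels,
                            system.database_edges, pi_rec, pi_unrec)

model = NonnegativeFactorModel(system.Y, prior)
results = model.fit(n_iter=2000, n_burnin=500, seed=1)
print(results.summary())
```

```
Bayesian non-negative factor model — posterior summary
========================================================
genes: 150   TFs: 10   samples: 40
posterior draws used: 1500
edges with P(regulation) >= 0.5: 148
consensus clusters: 5 (sizes: 8, 8, 8, 8, 8)
prior factor mean mu_x: 0.4984

top edges by posterior probability:
         G0001 <- TF03       p=1.000  coef=+0.473
         G0002 <- TF00       p=1.000  coef=+0.515
         ...
```

The summary reports the number of retained posterior draws, how many gene–TF
pairs exceed the 0.5 posterior cut-off (148 predicted regulations vs. 139 true
edges here), and the consensus sample clustering (all five simulated subtypes
recovered, 8 samples each). Scoring against the generator's ground truth:

```python
print(pearson_recovery(results.A_mean, system.A_true))   # 0.998
print(pearson_recovery(results.X_mean, system.X_true))   # 0.996
ev = target_prediction_eval(results.edge_prob, system.true_edges, 0.5,
                            results.gene_labels, results.tf_labels)
print(ev.f)                                              # 0.98
print(bcubed(results.clustering, system.labels_true).f)  # 1.0
```

Loadings and factors correlate > 0.99 with the truth, the thresholded network
reaches a target-prediction F of 0.98, and the BCubed clustering F is 1.0.

The same pipeline is available from the shell:

```sh
tfnet all --outdir run1 --preset benchmark --seed 7 --iters 2000 --burnin 500
```

which writes the simulated system, the fit artifacts (`edges.tsv`,
`factors.tsv`, `clustering.tsv`, `posterior.json`) and `evaluation.json`. To
fit your own data, provide a genes-by-samples TSV and a two-column
(gene, tf) edge list:

```sh
tfnet fit --expression expr.tsv --edges transfac_edges.tsv \
          --precision 0.9 --recall 0.9 --sparsity 0.1 \
          --iters 10000 --burnin 2000 --outdir fit_out
```

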