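# nichelda

Sub-community analysis of **multi-niche microbiome data**: latent Dirichlet
allocation (LDA) on OTU count tables, Dirichlet-multinomial model-size
selection, between-niche association testing with the global test, and
niche-of-origin prediction from sub-community proportions.

Microbiome studies often sample several habitats ("niches") of the same
subjects — e.g. saliva, tongue and dental plaque within the mouth — yet most
analyses treat one niche at a time. `nichelda` is for researchers who want
to (i) describe the taxonomic structure of each niche as a small number of
bacterial *sub-communities*, (ii) test whether the composition of one niche
is associated with that of another, and (iii) check whether the
sub-communities really carry niche-specific signal by using them to predict
where each sample came from.

## The model

An OTU table is treated as a document–term matrix: a sample is a
"document", an OTU a "term".  With K sub-communities and V OTUs,

* θ_s ~ Dir_K(α) — sub-community proportions of sample *s*,
* φ_k ~ Dir_V(γ) — OTU composition of sub-community *k*,
* each read draws z ~ Mult(θ_s), then an OTU w ~ Mult(φ_z).

Fitting is by **collapsed Gibbs sampling** (θ, φ integrated out; a numba
kernel resamples every read's label with probability ∝
(n_sk+α)(n_kv+γ)/(n_k·+Vγ)), with posterior-mean estimates
θ̂_sk=(n_sk+α)/(N_s+Kα), φ̂_kv=(n_kv+γ)/(n_k·+Vγ).

Around the core model:

* **K selection** — Dirichlet-multinomial mixtures fitted by MAP-EM over a
  range of K; the K minimizing the Laplace approximation of the negative
  model evidence is chosen (`kselect.select_k`).  A simulation experiment
  (`kselect.k_vs_n_experiment`) shows this estimate inflates with the
  number of samples when the data come from the LDA process.
* **Association** — for an ordered niche pair (i, j), each of niche i's
  sub-community proportions is regressed on niche j's full arcsinh-transformed
  OTU matrix with the **global test**, a variance-component score test
  Q = (Y−μ)ᵀR(Y−μ)/μ₂ with R = XXᵀ/n that stays valid for p ≫ n; p-values
  are Bonferroni-corrected by K·m (`associate.associate_niches`).
* **Prediction** — multinomial logistic regression of niche on θ with
  leave-one-out evaluation and a full metric suite (accuracy, per-niche
  sensitivity, macro-F1, Cohen's κ, multiclass MCC, log loss, Hand–Till
  multiclass AUC) (`predict.loo_evaluate`).
* **Simulation** — `simulate.simulate_dataset` generates tables from the
  generative process with full ground truth, so every stage is testable
  without any data download.

## Worked example

```python
import numpy as np
from nichelda import (LdaHyperparams, blocked_phi, fit_lda, loo_evaluate,
                      match_subcommunities, simulate_dataset)

phi = blocked_phi(3, 60, seed=1, background=0.05)     # 3 separated communities
sim = simulate_dataset(K=3, V=60, S=120, depth=800, alpha=0.4, gamma=0.1,
                       seed=7, phi=phi)
fit = fit_lda(sim.table, 3, LdaHyperparams(n_iterations=300, burn_in=150,
                                           seed=2022))
perm = match_subcommunities(fit.phi, sim.true_phi)    # resolve label switching
print("mean |phi_hat - phi|  =", np.abs(fit.phi[perm] - sim.true_phi).mean())
print("mean |theta_hat - theta| =",
      np.abs(fit.theta[:, perm] - sim.true_theta).mean())

labels = np.array(["nicheA", "nicheB", "nicheC"])[sim.true_theta.argmax(1)]
report = loo_evaluate(fit.theta, labels)
print("LOO accuracy =", report.accuracy)
print(report.confusion)
```

prints

```
mean |phi_hat - phi|  = 0.0009
mean |theta_hat - theta| = 0.0262
LOO accuracy = 0.9916666666666667
        nicheA  nicheB  nicheC
nicheA      51       0       0
nicheB       1      29       0
nicheC       0       0      39
```

The estimated compositions match the generating ones to ~1e-3 per entry,
the mixing proportions to ~0.03, and the sub-community proportions alone
recover each sample's niche almost perfectly (rows of the confusion matrix
are the reference niches, columns the predictions).

A command-line interface mirrors the library:
`nichelda simulate | select-k | fit | predict | gtest | associate |
flow-a | flow-b` (flow-a: joint fit + signatures + prediction; flow-b:
per-niche fits + association matrix), driven by a YAML config and writing
TSV/JSON outputs plus a run manifest.

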