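# Methods

## Model and estimation

`nichelda` models an OTU count table (S samples × V OTUs) with latent
Dirichlet allocation.  Sample *s* mixes K sub-communities with proportions
θ_s ~ Dir_K(α·1); sub-community *k* emits OTUs with probabilities
φ_k ~ Dir_V(γ·1); each read draws a sub-community label z ~ Mult(θ_s) and
then an OTU w ~ Mult(φ_z).  Samples are exchangeable and reads within a
sample are conditionally iid — no spatial, phylogenetic or longitudinal
structure is modelled.

Estimation is collapsed Gibbs sampling over per-read labels; θ and φ are the
usual posterior means of the final state (`average_after_burn_in=True`
averages the post-burn-in sweeps instead, which stabilizes the estimates of
low-abundance composition entries at the cost of smoothing across residual
label drift).  The sampler is a numba kernel with its own RNG seeded once
per fit: a (data, K, seed) triple is bit-reproducible.  Sub-community
indices are arbitrary; every cross-run or truth comparison goes through
`simulate.match_subcommunities` (optimal assignment on cosine similarity).

Tunable parameters:

| parameter | meaning | default | why |
|---|---|---|---|
| α | Dirichlet weight on sub-communities per sample | 50/K | the convention of the standard collapsed-Gibbs implementations; configurable because mixing sparsity is data-dependent |
| γ | Dirichlet weight on OTUs per sub-community | 0.1 | standard sparse-topic default; use smaller values (e.g. 1e-3) when compositions are believed near-disjoint, larger for dense ones |
| n_iterations / burn_in | Gibbs sweeps | 2000 / 1000 | conservative for tables up to a few thousand samples; the trace of the collapsed log joint is exposed for stationarity checks |
| seed | master RNG seed | 2022 | replication default; flows derive per-stage seeds from it |

## Choosing K

`kselect` fits Dirichlet-multinomial (DM) mixtures by EM.  The E-step uses
exact component DM log-likelihoods (sparse: zero cells contribute nothing);
the M-step is one Minka fixed-point update per component — a
minorize-maximize step, so the objective never decreases.  Each Dirichlet
parameter carries a Gamma(η=0.1, ν=0.1) prior, handled exactly inside the
fixed-point update; without it the mixture likelihood is unbounded (a
component can collapse onto a few samples with infinite concentration) and
model-size selection degenerates.  Initialization is k-means on relative
abundances plus per-cluster moment estimates; `select_k` keeps the best of
`restarts` starts per K.

K is chosen to minimize the Laplace approximation of the negative log
evidence at the posterior mode, with d = K·V + (K−1) free parameters.  The
Hessian of the negative log posterior (log-parameter coordinates) is treated
as block-diagonal; each component block is diagonal-plus-rank-one,
diag(g_v·a_v² + η) − c·aaᵀ, so its determinant is closed form and no V×V
matrix is built.  The weight block contributes (K−1)·log S − Σ log π_k.
If the rank-one correction would make a block non-positive (a boundary
solution), its factor is floored at 1e-12.

Two caveats.  First, the criterion is only a model-selection device: a DM
mixture assigns each sample to one component, whereas the LDA model mixes
components within samples, so on LDA-type data the DM evidence is a
misspecified criterion and the selected K grows with the number of samples
— `k_vs_n_experiment` measures exactly this, and the acceptance run shows
the median K̂ rising from the true 5 at n=100 to the top of the search range
at n=1000.  Practical advice encoded in the API: treat K̂ as an upper bound
at large n, inspect per-K evidence (`SelectionResult.to_frame()`), and
override K explicitly where parsimony matters; the flow configs accept both.
Second, the human-in-the-loop adjustment of K after inspecting sub-community
composition is deliberately not automated — the package surfaces the per-K
diagnostics that make it possible.

For the K-vs-n simulation experiment the generator defaults are α = 1.0 and
γ = 0.1: the generative account of the data constrains α, γ to [0, 1], and
α = 1 (uniform prior over the mixing simplex) is the neutral choice in that
range; γ = 0.1 matches the fitting default.

## Association between niches

For each niche, LDA is fitted on *all* of that niche's samples; sample
intersection happens only at test time.  For an ordered pair (i → j):
restrict to subjects present in both niches, arcsinh-transform niche j's
rarefied counts (ln(x+√(x²+1)); variance-stabilizing, defined at zero;
`use_relative=True` switches to relative abundances — counts are the
default because rarefaction has already equalized depths), and run the
global test of each θ column of niche i against the whole matrix.

The global test is the variance-component score test: under
β_j ~ N(0, σ²), H₀: σ² = 0 is tested with Q = (Y−μ)ᵀR(Y−μ)/μ₂, R = XXᵀ/n,
with μ the response mean (identity link) and μ₂ its ML variance.  Columns
of X are centred (not scaled — covariates are weighted by their variance)
before forming R.  Inference is one-sided:

* The **permutation p-value** (default and authoritative) counts permuted
  statistics ≥ the observed one, with the +1 correction; `exhaustive=True`
  enumerates all n! permutations for tiny n.
* The **moment-based p-value** uses the exact permutation-null mean and
  variance of Q — closed forms in the entries of R and the centred
  response's power sums, derived from the sampling-without-replacement
  moments of index-coincidence patterns and verified against brute-force
  enumeration in the tests — referred to a gamma tail matched to those two
  moments.  A normal reference at the same moments was measurably
  anti-conservative mid-range (the null of a positive quadratic form is
  right-skewed), so the gamma reference is used; both p-values are reported.

Per-covariate diagnostics are the single-column score statistics,
standardized by their own permutation moments and signed by the direction
of association, ordered by `covariate_report` (aggregate to genus level
first with `tables_io.aggregate_taxa` for a readable display).

Raw p-values are multiplied by K_i·m (K_i sub-communities of the response
niche, m niches), capped at 1 — the correction the analysis design this
package reproduces prescribes, even though the literal count of tests per
pair is K_i; `strict_bonferroni=True` corrects by the total number of tests
instead.  A pair is significant when its minimum adjusted p ≤ α (0.05).
Within a pair all K_i responses share one permutation set (the RNG depends
only on the seed), which makes the compositional K=2 identity exact: with
θ₂ = 1−θ₁ and an affine-invariant statistic, both sub-communities give the
same p-value — the general tendency of sub-communities of a niche to stand
or fall together is the same phenomenon.

## Prediction

`predict.fit_multinomial` is maximum-likelihood softmax regression (lbfgs,
ridge 1e-8 for stability under near-separation).  `loo_evaluate` refits the
classifier with each sample held out; θ features are computed **once** on
the full table before the loop — replicating the evaluation design this
package reproduces, including its mild information leak (the held-out
sample influenced the sub-community definitions; a leak-free variant can be
composed from `lda.infer_theta`).  Argmax ties break toward the first class
in sorted label order.  Folds whose training set loses a singleton class
are flagged and still evaluated.  Metrics: accuracy, per-class sensitivity,
macro F1, Cohen's κ, the Gorodkin multiclass Matthews correlation, log loss
(probabilities clipped at 1e-15), and the Hand–Till multiclass AUC
(unweighted mean of pairwise AUCs with midrank ties) — each cross-checked
against an independent implementation in the tests.

## Data handling

Tables are TSV (header = OTU ids, first column = sample ids); taxonomy is
read from rank-prefixed lineages (`k__...;g__...`), either as a companion
file or embedded in the OTU ids.  Rarefaction draws each retained sample's
reads without replacement (multivariate hypergeometric) to exactly the
target depth; samples below depth are dropped (standard practice — keeping
partial samples would break depth comparability), as are emptied OTU
columns.  Contamination filtering excludes *subjects* — all their samples —
when a marker taxon strictly exceeds the threshold in any of their
oral-niche samples; the boundary case (exactly at threshold) is retained.
Visit filtering keeps each subject's minimum visit.  Aggregation to a rank
conserves per-sample totals, labelling OTUs not classified that far by
their lowest available higher rank.

## What the simulator does and does not emulate

`simulate_dataset` draws from the model itself (one multinomial draw per
sample from θ_sΦ — distributionally identical to per-read sampling and much
faster; per-read labels are reconstructed from their exact posterior on
request).  `blocked_phi` provides well-separated compositions: disjoint
dominant blocks, optionally plus a shared low-abundance tail, mimicking the
dominant-taxa-plus-rare-tail shape of real communities.
`simulate_linked_niches` couples two niches' θ through a shared per-subject
Gaussian score with logistic-normal noise of scale 1/effect — a test
fixture for the association pipeline, not a biological model of
between-niche transfer.

Consequently, passing tests demonstrate correctness of the algorithms under
the model's own assumptions.  They do not establish robustness to what real
16S data add: taxa shared across niches with phylogenetic correlation,
sequencing error and chimeras, compositional artefacts of library size, or
subject-level confounding.  The recovery study in particular uses
disjoint-support truth with a matched sparse prior (γ = 1e-3) — the regime
where rank-level recovery of compositions is information-theoretically
possible at depth 2000; with dense overlapping compositions the ranks of
OTUs below ~10 expected reads per sub-community are not recoverable and
rank-correlation targets should not be expected to transfer.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated data at
deliberately moderate sizes — recovery at S=300, V=300, depth 2000 with 400
Gibbs sweeps; calibration with 1000 null tests of n=50 against p=100 at 400
permutations; K-vs-n with 3 replicate datasets over n ∈ {100, 400, 1000};
association at S ≤ 80 niches-pairs with 500–1000 permutations — sizes at
which every result is stable across seeds while the whole suite stays in
the minutes range on one CPU.  EM convergence is relative tolerance 1e-6 on
the objective (cap 120 iterations, non-convergence flagged, not fatal);
Dirichlet parameters are floored at 1e-10; permutation p-values carry the
standard +1 correction and can never be 0.  Reproducibility: every stage
takes an explicit seed; the CLI derives per-stage seeds from a single
master seed via CRC mixing, recorded in the run manifest.

## Known limitations

* Single-chain Gibbs with fixed-length burn-in; no convergence diagnostics
  beyond the exposed log-likelihood trace.
* The DM evidence criterion inherits the sample-size sensitivity documented
  above; it bounds rather than pins K at large n.
* The global test here covers continuous responses with identity link only
  (no covariate adjustment, no logistic/survival variants).
* Leave-one-out evaluation inherits the design's information leak (θ fitted
  once); use `infer_theta` per fold when a strictly honest estimate matters.
* BIOM input is not supported; tables are TSV.
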