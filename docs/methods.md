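# Methods

## Model

`p2net` fits a dyad-independent exponential random graph model — the
undirected p2 model — to a simple graph over n nodes. Every unordered
pair {i, j} carries an independent Bernoulli edge indicator X_ij with

    logit P(X_ij = 1) = θ + α_i + α_j,

where θ is a global density parameter (the log-odds of an edge between
two baseline nodes) and α_i is the *sociality* of node i, its propensity
to form edges beyond the baseline. Socialities are regressed on nodal
covariates with a random effect:

    α_i = γ·x_i + a_i,      a_i ~ N(0, τ_a⁻¹).

Conditionally on the socialities the dyads are independent, which makes
the likelihood a product of pairwise Bernoulli terms with no intractable
normalizing constant; the degree sequence is the sufficient statistic for
the node effects. The directed p1 dyad law (mutual / asymmetric / null
cells with a reciprocity parameter φ) is provided as a closed-form
utility, but the inferential pipeline is undirected only.

Priors are hierarchical normal–gamma: θ ~ N(0, τ_θ⁻¹), each
γ_k ~ N(0, τ_γ⁻¹), and Gamma(a₀, b₀) hyperpriors on all three precisions
with a₀ = b₀ = 0.001, i.e. effectively noninformative. The hierarchical
specification for γ mirrors that of θ; this symmetry is a design choice
of the package.

Binary covariates such as intrinsic protein disorder enter as 0/1
columns; a continuous disorder probability is binarized at a threshold
(default 0.7, boundary inclusive: a value of exactly 0.7 counts as
disordered — the comparison direction is documented because the
convention is not universal).

## Posterior computation

The posterior over (θ, γ, a, τ_θ, τ_γ, τ_a) is sampled with
Metropolis-within-Gibbs:

* **Precisions** have conjugate gamma full conditionals,
  Gamma(a₀ + k/2, b₀ + Σv²/2), and are drawn exactly.
* **θ, each γ_k, each a_i** use scalar random-walk Metropolis steps.
  Because a scalar shift δ moves every affected linear predictor by a
  known amount (δ for θ; δ(x_ik + x_jk) for γ_k; δ on node i's incident
  pairs only for a_i), each acceptance ratio is a single vectorized
  softplus difference — O(n²) per sweep overall, O(n) per node update.
* **Adaptation.** Proposal scales are tuned during burn-in toward an
  acceptance rate of 0.44 per scalar block (batches of 50 sweeps,
  log-scale increments) and frozen afterwards, so the post-burn-in
  kernel is a fixed Markov kernel with the correct stationary law.

Default iteration counts follow the full-analysis profile (50 000
burn-in, 100 000 draws, thinning 10); the `desk` profile (2 000 / 8 000)
is the package's own choice of problem size for interactive fits and the
simulation studies shipped in the test-suite, where the posterior is
low-dimensional enough to mix well within a few thousand sweeps. Both
profiles are recorded in the run metadata. Thinning exists purely to
bound memory; all estimator contracts are stated on the retained draws.

Chains are started from overdispersed points (θ alternating between −4
and 0, a_i ~ N(0, 1) from each chain's own stream, γ = 0, precisions 1);
a single chain defaults to θ at the logit of the observed density with
a = 0. Chain seeds are spawned deterministically from the master seed;
identical (data, config, seed) reproduces output bit for bit.

No sum-to-zero constraint is imposed on the random effects: the
zero-mean prior anchors their level, at the cost of mild posterior
correlation between θ and mean(a). This matches the model as specified
and is visible as slower mixing of θ than of the a_i.

## Convergence monitoring

Geweke's z compares the first 10% of a chain with the last 50%, with
window variances from the spectral density at frequency zero (Bartlett
lag window, truncation at ⌊√n_window⌋ lags — fixed, not data-driven).
Gelman–Rubin's PSRF uses the classic between/within construction
√(((n−1)/n·W + B/n)/W) on ≥ 2 chains. Flags: |z| > 1.96, PSRF > 1.1.
The `fit` command refuses to pool chains whose worst PSRF is ≥ 1.1
unless `--force` is given. Raftery–Lewis is not implemented.

## Social-node calling

After pooling chains, socialities are reconstructed per draw as
α_i = γ·x_i + a_i and summarized (mean, sd, 2.5% and 97.5% quantiles,
linear interpolation between order statistics). A node is
*positive-mean* when mean(α_i) > 0 and *social* when the 2.5% quantile
of α_i is strictly greater than 0. Covariate effects are reported with
the same quantiles and a verdict string ("positive effect, credible"
iff q2.5 > 0, etc.).

## Goodness-of-fit

The degree distribution is checked posterior-predictively: for each of
100 (by default) posterior draws of (θ, α), a network is simulated on
the observed node set and its degree-fraction vector recorded; the
observed curve is compared with the per-degree 95% predictive envelope.
Simulating from posterior draws rather than a point estimate propagates
parameter uncertainty into the envelope; this is the package's choice
where a plug-in simulation would also have been defensible. The degree
axis runs from 0 to the largest degree seen in observed or simulated
networks, with explicit zeros.

## Clustering

Nodes are clustered by agglomerative complete linkage on the Euclidean
distances between posterior **mean** socialities (scalar summaries — the
quantity the fit ranks nodes by; clustering full posterior vectors was
the open alternative). The dendrogram is cut into k groups (default 5),
renumbered 1..k by descending mean sociality. The linkage itself is
delegated to `scipy.cluster.hierarchy`. Cluster reports give size and
degree range per cluster plus a flow matrix: the percentage of all edges
falling between each cluster pair (within-cluster on the diagonal), each
edge counted once, so the matrix totals 100.

## Synthetic data

`generate_synthetic_study` draws data exactly from the model's own law:
g_i ~ Bernoulli(prevalence), a_i ~ N(0, σ_a²), α_i = γ·g_i + a_i, edges
Bernoulli(expit(θ + α_i + α_j)). Defaults — n = 100, θ = −3, γ = 0.7,
σ_a = 0.8, prevalence 0.32 — describe a sparse, moderately heterogeneous
interaction network with roughly a third of nodes carrying the binary
attribute, the regime the pipeline is intended for. Because the
generator *is* the model, passing recovery and GOF tests demonstrates
the correctness of the inference machinery, not robustness to
misspecification: real interaction data bring sampling artefacts
(spoke-biased assays, false positives/negatives), transitivity and
community structure that the dyad-independent model does not represent.
One GOF test deliberately fits a misspecified (homogeneous) model to
heterogeneous data to confirm the check can fail.

## Numerical notes

* All densities are computed in log space; pairwise terms use
  `logaddexp(0, η)` for the softplus, so extreme parameters saturate
  smoothly instead of overflowing.
* Undirected edges are stored canonically (lexicographic endpoints);
  pair iteration is i < j in node-list order.
* Quantiles use linear interpolation between order statistics (NumPy's
  default), the same convention as the brute-force oracle in the tests.
* Complete-linkage ties are broken by SciPy's deterministic merge order;
  the test oracle compares merge heights, which are tie-invariant.
* Duplicate edge-list lines are deduplicated with a warning (error under
  `strict`); self-loops are always errors. Isolated nodes exist only
  when an explicit node-universe file is supplied.

## Limitations

* Dyad independence given α: no triangles, k-stars or community terms;
  transitive real networks will fail the degree GOF only insofar as
  degree heterogeneity is mis-modelled, and may pass it while being
  badly mis-modelled in clustering coefficient.
* Random-walk Metropolis mixes slowly for very large, very sparse
  graphs; the desk profile is sized for hundreds of nodes, not tens of
  thousands.
* The θ / mean(a) confounding noted above inflates the posterior sd of
  θ slightly relative to a sum-to-zero parameterization.
* The directed p2 model with correlated sender/receiver effects is out
  of scope; directed support stops at the closed-form p1 dyad law.
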