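# Methods

## The model

`gennet` infers a *genetic-and-epigenetic network* (GEN): the union of a
protein–protein interaction network (PPIN) and a gene regulatory
network (GRN) whose regulations are attenuated by DNA methylation.  Two
per-node stochastic models are fitted to expression data over L
samples.

**Protein interactive model.**  For protein i with candidate partners
N_i:

    y_i[n] = Σ_{j∈N_i} a_ij · y_i[n] · y_j[n] + h_i + v_i[n],   h_i ≥ 0

The product y_i·y_j represents the collision probability of the two
proteins; a_ij is the (signed) interaction ability and h_i ≥ 0 the
basal level.  mRNA abundance proxies protein abundance throughout —
genome-wide protein measurements are generally unavailable and mRNA
explains the majority of protein-abundance variance, so genes and
proteins share one identifier space.

**Gene regulatory model.**  For gene i with candidate TFs K_i and
candidate repressing miRNAs V_i:

    x_i[n] = Σ_{j∈K_i} b_ij · y_j[n] · M_i[n]
           − Σ_{v∈V_i} c_iv · x_i[n] · x_v^miR[n] · M_i[n]
           + M_i[n] · κ_i + ω_i[n],          κ_i ≥ 0, c_iv ≥ 0

**Methylation regulation.**  M_i[n] = 1 / (1 + (m_i[n]/0.5)²), where
m_i[n] ∈ [0,1] is the beta value.  M decreases strictly from 1
(unmethylated) to 0.2 (fully methylated): methylation weakens the
binding of TFs, miRNAs and RNA polymerase but never shuts it off.
Genes without probe coverage get M ≡ 1, the neutral element of the
model.  Expression matrices are fitted as given (no centering,
scaling, or log transform — the basal column absorbs offsets).

## Identification

Each node model is a linear regression with sign constraints: the
miRNA parameter is fitted as −c_iv ≤ 0 (so the reported repression
ability is always non-negative) and the basal term is bounded below by
zero; partner/TF abilities are free.  The bounded least-squares
problem is solved exactly when the ordinary solution is feasible
(it is then also the constrained optimum) and by a bounded-variable
solver otherwise.  σ̂² = RSS/L.

The *true system order* of a node — which candidate links are real —
is detected by minimizing

    AIC(Δ) = log σ̂² + 2Δ/L

with Δ = number of selected links + 1 (the basal term always counts
and is never removable).  Selection is stepwise: starting from the
basal-only model, add the single link that most decreases the AIC,
then sweep backward removing any link whose removal decreases it,
until no single move helps.  Ties break on the smallest column index,
making the procedure deterministic; moves that would make the selected
design rank-deficient are not taken (no regularization is applied).
Starting from the basal-only model (rather than the full model) keeps
the procedure well-defined when candidate sets exceed the sample count,
which routinely happens at realistic candidate densities and small
cohorts.

Every retained link gets a permutation p-value: the response vector is
permuted across samples B times (default 1000), the already-selected
model refit, and p = #{|θ̂_perm| ≥ |θ̂|}/B reported, floored at 1/B and
with ties counted as exceedances (conservative).  An analytic
t-statistic from the unconstrained normal equations is carried as
auxiliary output; pruning uses the AIC only and p-values are
annotation.  A σ̂² floor of 1e-12 inside the log keeps noiseless fits
finite.

## Principal network projection (PNP)

The identified abilities are assembled into the structure matrix H of
shape (2N+V) × N — protein rows â_ik, TF rows b̂_ij, miRNA rows −ĉ_iv,
absent links exactly zero.  With singular values s_1 ≥ … ≥ s_N, the
eigenexpression fractions are E_m = s_m²/Σs²; the minimal M with
cumulative fraction ≥ 0.85 defines the principal network structure.
Each row's dependent score is D(k) = ‖h_k · [r_1 … r_M]‖₂, the norm of
its projection on the top-M right singular subspace (invariant to
singular-vector sign flips; equal to the row norm when M = N).  The
core GEN is the top 5% of proteins by D(k) — ties at the cutoff are
included, which keeps the rule deterministic — plus every gene and
miRNA reachable from a selected protein through one retained edge,
with the induced retained edges.  Only the thin SVD (N right singular
vectors) is ever computed.

## Condition comparison

Differential expression and methylation use the pooled-variance
two-sample t-statistic with a two-sided label-permutation p-value
(floored at 1/B; the pooled sample is sorted before permuting so the
realized null does not depend on argument order).  Hyper/hypo
methylation calls follow the sign of the mean beta difference alone;
the p-value is carried as annotation, not used as a gate.  Basal-level
shifts Δκ_i = κ̂_i(B) − κ̂_i(A) proxy the methylation effect on
transcription.  Core networks are partitioned type-aware into common,
A-specific and B-specific edges and nodes.

## k-fold consistency

Samples are shuffled and split into k near-equal folds (sizes differ
by at most one, larger folds last — 62 samples at k = 10 give
6,6,6,6,6,6,6,6,7,7); repetition r identifies the GEN on the
complement of fold r (training on the fold itself is a config switch,
but complements are the default since identification on 2–3 samples is
meaningless).  Consistency = |edges selected in all k runs| / |edges
selected in ≥ 1 run|, reported separately for the PPIN and the GRN.
The union denominator is a declared convention.

## Synthetic data generator

The generator emulates the statistical structure the identification
assumes, so the whole pipeline is testable without external data.

* **Edge sampling.**  Bernoulli (Poisson-thinned uniform) draws give
  expected in-degrees equal to the requested means.  Defaults follow
  the candidate-network densities the method targets: 7.3 candidate
  TFs per gene, 15.9 candidate PPI partners per protein, and 11.8
  candidate miRNAs per gene (the ratio of candidate miRNA repressions
  to regulated genes).  The uniform draws are consumed in a documented
  order (TF matrix, PPI matrix, miRNA matrix) so the sampler can be
  reproduced independently.
* **Layering.**  Both models are implicit (the node's own profile
  appears on both sides), so profiles are solved in closed form from
  the exact linear rearrangement rather than by fixed-point iteration.
  A single layer of *sink* genes is chosen greedily, each assigned one
  generating mechanism (protein-interactive or gene-regulatory) with
  all of its regulators frozen as exogenous *sources*; a fully
  self-consistent joint equilibrium is never required.  Recovery
  benchmarks are therefore scored on sink nodes, where the generating
  mechanism defines the ground truth, and `truth_candidate()` exposes
  the *active* edges (those that shaped the data) — edges into source
  nodes carry no signal and are not identifiable even in principle.
* **Profiles.**  Sources and miRNAs draw lognormal(0, 0.5²) profiles —
  positive and right-skewed, an explicit stand-in since no marginal
  law of preprocessed expression is prescribed anywhere.  Methylation
  betas are Beta(2, 5) by default (hypomethylated-promoter-like, mean
  ≈ 0.29); condition-specific hyper/hypo genes are shifted by ±0.3 and
  clipped to [0,1].  Noise is Gaussian; benchmark scenarios set it to
  10% of the noiseless expression spread.
* **Abilities.**  b_ij ~ ±U(0.5, 1.5); h_i, κ_i ~ U(0.5, 1.5);
  |a_ij| ~ U(0.1, 0.4) and c_iv ~ U(0.3, 0.9), both scaled by
  1/√(in-degree of the modeled endpoint).  The √-scaling keeps the
  aggregate feedback — the PPIN denominator 1 − Σa_ij y_j and the
  miRNA repression load M·Σc_iv x_v — O(1) independent of degree
  while preserving a detectable per-link effect.  Without it the PPIN
  solve drifts into its singularity at realistic degrees, and the
  miRNA response saturates so strongly that a sparser-than-true model
  genuinely attains a lower AIC (the individual links become
  unidentifiable, not merely hard to find).
* **Degenerate-sample guard.**  Sample columns where any protein-model
  denominator satisfies |1 − Σ_j a_ij y_j| < 0.2 are rejected and the
  whole exogenous column redrawn; generation aborts with advice if
  more than half of all drawn columns are rejected (an ill-posed truth
  network).

What the generator does *not* emulate: platform artifacts (probe
effects, batch effects), count-distribution features of sequencing
data, spatial correlation of CpG probes, or feedback cycles between
modeled nodes.  Passing recovery benchmarks therefore demonstrate the
correctness and statistical behaviour of the identification machinery
under the model's own assumptions, not performance on any real cohort.

## Numerical choices and problem sizes

* Bounded LS: ordinary solution accepted when feasible, else
  `scipy.optimize.lsq_linear` (BVLS, falling back to TRF for
  rank-deficient fits) at tolerance 1e-12.
* AIC uses the natural log and a σ² floor of 1e-12; stepwise accepts a
  move only if it improves the AIC by more than 1e-12 (no cycling on
  ties).
* SVD via LAPACK through NumPy; eigenexpression fractions are exact
  ratios of squared singular values.
* Default study shapes: the bundled analysis uses 80 genes, 12 miRNAs
  and 60 samples per condition (identification in seconds); the
  recovery benchmark uses 200 genes, 30 miRNAs, L = 100, decoy ratio 1
  (identification in ~20 s).  The full-cohort shape (62/47/25/369
  samples) is available through `RunConfig`.
* All randomness flows through `numpy.random.default_rng`; every stage
  seed is derived deterministically from the master seed, and reruns
  of a pipeline configuration are bit-identical (checksummed in the
  run manifest).

## Known limitations

* AIC's fixed 2Δ/L penalty is liberal: a null candidate column enters
  with probability ≈ P(χ²₁ > 2) ≈ 0.16, so pruned networks carry a
  predictable false-positive load, and spurious retention is further
  inflated for PPIN models because the response appears inside every
  regressor (an endogeneity the model form itself dictates).
* Stepwise selection is a local search; on enumerable problems it
  matches exhaustive best-subset AIC in ≳90% of instances but can lock
  into a local minimum under strong collinearity.
* The permutation test permutes the response of an already-selected
  model; it quantifies the strength of a retained link, not the
  selection uncertainty.
* PPI abilities are reported per direction (one per endpoint model);
  the undirected pair is counted once in N_P regardless.
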