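# Methods

This note documents the models and procedures implemented in
`tfdyngrn`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical decisions made
where the design was genuinely open.

## 1. Preprocessing

**Gene filter.** A gene is retained if it has a count ≥ 2 in at least
two samples *and* is non-constant across samples. Both thresholds are
configurable (`min_count`, `min_count_samples`).

**Normalisation.** Median-of-ratios size factors: per sample, the
median over reference genes (genes with strictly positive counts in
every sample) of the log-ratio to the gene's geometric mean, then
exponentiated. Factors are rescaled to geometric mean 1. This
rescaling leaves all factor *ratios* identical to the classical
procedure (the test suite verifies agreement with an independent
implementation up to that constant) and buys an exact fixed point:
re-estimating factors on normalised data returns exactly 1 for every
sample. Genuine scale equivariance holds on ratios — multiplying one
sample's counts by c multiplies its factor *relative to every other
sample's* by exactly c; no per-dataset-reference method can scale the
absolute factor by c, since the reference itself moves.

**Contrast signatures.** Per gene, Welch's unequal-variance t-test
between two sample groups; two-sided p from the t distribution;
z = sign(t)·Φ⁻¹(1 − p/2). Welch is the robust default for two-replicate
groups. z is capped at |z| ≤ 8 because Φ⁻¹ overflows for the p ≈ 0
produced by zero within-group variance with a nonzero shift; genes
with zero variance in both groups and equal means get t = 0, p = 1,
z = 0.

**Per-sample signatures.** The source protocols do not pin down how a
*single-sample* signature (needed for per-time-point activity) should
be built; this package standardises each gene to mean 0 and unit
variance (ddof = 1) across all samples and uses a sample's column of
standardised values as its signature. Standardisation is idempotent and
zero-variance genes become all-zero rows.

## 2. TF activity

**Enrichment statistic.** NES = Σ_g w_g·m_g·z_g / √(Σ_g w_g²) over the
TF's measured targets (mode m ∈ {−1, +1}, confidence w ∈ (0, 1]). Under
independent standard-normal target z-scores the statistic is standard
normal. It is linear in the signature and exactly antisymmetric under
mode flips — properties the tests pin down. This is the weighted-sum
member of the enrichment family, not the two-tailed aREA statistic of
VIPER; it keeps the same contract (signed, normalised, permutable) in
an exactly testable form. TFs with fewer than `min_targets` (default 5)
measured targets are skipped and reported.

**Permutation null.** The null permutes *gene labels* of the signature
(equivalently: draws the TF's target set at random from the measured
genes). With two replicates per group, permuting samples admits only
six rearrangements, which cannot support a 1000-permutation null; gene
permutation is the documented choice. Two-sided p uses the add-one
rule, p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), so p is never 0; the
uniformity of p under a random regulon is verified by a KS test in the
suite. All TFs scored against one signature share a single set of
label permutations.

**Differential activity.** For each patient, condition, and pair of
consecutive design days, the signature is the later-vs-earlier
contrast; the stored score is the NES, zeroed whenever p > 0.05. A TF
is *differentially activated* (DA) if p < 0.05 in at least one
(patient, condition, interval); the selection records where each TF
fired. Intervals lacking two replicates on either day are skipped with
a warning.

## 3. Network inference

**Semi-parametric ODE + trees.** For target i, training pairs over all
(patient, replicate) series of one condition and consecutive days k:

    y = (x_i(t_{k+1}) − x_i(t_k)) / Δt + α·x_i(t_k),   features = x(t_k).

α is pooled as the median of per-TF decay estimates
α_i = ln(range_i + 1) / (t_last − t_first), where range_i is the TF's
observed dynamic range after shifting its minimum to 0 with offset
ε = 1 — a construction that stays defined on enrichment-score scales,
which can be negative. The ensemble is 1000 trees by default (300 in
the synthetic benchmark) with √p feature subsampling, built directly
from scikit-learn regression trees — bootstrap-aggregated CART for
`rf`, unbagged random-split trees for `et` — validating the design
matrix once per target rather than once per tree; importances agree
with `RandomForestRegressor` (cross-checked in the suite). The edge
weight of regulator j for target i is j's mean normalised impurity
importance with the self-importance removed and the remainder rescaled
to sum 1 (decay already models self-dependence, so self-edges are not
reported); targets with zero response variance contribute no edges.

**Stability and merging.** The fit is repeated n = 10 times with
distinct seeds; an edge survives iff w ≥ 0.01 in *every* run and takes
the mean weight. The two condition networks are merged by edge union
with the maximum weight (the combiner is not specified by the source
protocol; max preserves "exists in either condition" semantics) and
per-edge condition tags.

**Correlation network.** Per condition, each selected TF's profile is
its stored (zeroed) differential-activity scores over all
(patient, interval) cells in a fixed order; Pearson r over all TF
pairs; edge iff |r| ≥ 0.5 with sign(r); zero-variance profiles are
skipped. Profiles concatenate patients within a condition (computing
per patient and combining was the alternative reading). Condition
networks are unioned; a pair present in both keeps the entry with the
larger |r|, which also resolves conflicting signs (configurable).

**Consensus.** A directed edge i→j is kept iff the unordered pair
{i, j} is a correlation edge; direction and weight come from the
forest network, sign and correlation from the pair; both orientations
survive if both were inferred.

## 4. Topology statistics

All statistics use the simple undirected projection of the consensus
network (the sources do not state directedness or weighting for these
statistics). Betweenness is exact, unnormalised shortest-path
betweenness. Nominal assortativity is Newman's mixing-matrix
coefficient r = (Σe_ii − Σa_ib_i)/(1 − Σa_ib_i); with a single label
class the denominator vanishes and r is reported as undefined. Its
z-test shuffles node labels on the fixed topology (default 100
shuffles), z = (r_obs − mean_null)/sd_null, sd via ddof = 1; power and
size are verified on planted two-block graphs and random labels.
Multi-context nodes collapse to "both"/"shared"/"multiple" for the
standard annotation; a dominant-context labelling (argmax of summed
|score|) is provided for densely activated networks where the
collapsed labels degenerate to one class.

**Communities.** Edge clustering coefficient
ECC(u,v) = (#triangles on (u,v) + 1)/min(deg u − 1, deg v − 1), defined
as 0 when an endpoint has degree 1. Agglomeration proceeds over edges
in descending ECC (ties broken lexicographically on the sorted
endpoint pair, making the procedure deterministic), merging the two
endpoint clusters only while the smaller one is not yet a *module*,
where a cluster is a module once its internal edge count exceeds its
external edge count. This in/out-degree locking rule is the natural
reading of the fast agglomerative ECC family when the plugin's exact
stopping rule is unavailable, and it has the right limiting behaviour:
two 6-cliques joined by a bridge yield exactly two modules, because
each clique locks (15 internal > 1 external) before the bridge is
considered. A simpler "merge while the union's internal/external ratio
does not decrease" rule fails that case — the union of the two cliques
has no external edges, so the ratio is infinite and the bridge would
always merge them. Clusters below `module_min_size` (default 5) are
reported as unassigned. A greedy-modularity partition is available as
an independent cross-check.

## 5. ICA and variance projection

FastICA (delegated to scikit-learn, deflation-free parallel scheme,
`max_iter` 1000–2000; non-convergence raises) factorises the
gene-centred matrix as X ≈ M·A with independent metagenes M (unit-norm
columns, largest-|loading| entry positive) and metasamples A. Restart
stability is the mean absolute correlation of each component with its
best match (Hungarian assignment on |corr|) across seeded restarts —
a lightweight stand-in for consensus-clustering stability indices.
PVE of a component subset projects X onto the chosen columns of M with
the Moore–Penrose pseudoinverse, X̂ = M(MᵀM)⁻¹MᵀX, and reports
Σ_genes Var(X̂)/Σ_genes Var(X) with population variances (the
denominator convention cancels in the ratio). PVE depends only on the
column space: it is invariant to rescaling components and monotone in
the subset; it equals the aggregate least-squares R², which the suite
checks against an independent regression oracle at 1e-10.

**ORA.** Upper-tail hypergeometric p = P(X ≥ k) for overlap k between
a query and a set within a universe, verified against exhaustive
enumeration for every universe size ≤ 12; Benjamini–Hochberg step-up
for multiplicity.

## 6. Synthetic data: what it emulates, what it does not

The generator reproduces the study design — 3 patients × 2 conditions
× 2 replicates × days (1, 4, 8, 11, 14) — and the causal chain the
pipeline inverts: a known signed TF-TF network drives latent
activities, activities drive counts.

**Dynamics.** dx_i/dt = −α_i x_i + Σ_j s_ij w_ij tanh(x_j) + b_i +
u_{p,i} + v_{c,i} + g(t)·e_{c,p,i}, fixed-step Euler (step 0.05 day,
must be below the smallest day gap; trajectories beyond |x| = 1000
raise as blow-up). Defaults and why:

- `decay_range` (0.1, 0.35)/day — time constants of ~3–10 days, so
  relaxation is visible across the whole 13-day observation window
  rather than finishing before the second sample.
- `basal_sd`, `patient_effect_sd`, `condition_effect_sd` 0.3 and
  `init_sd` 1.0 — fixed points and excursions stay within |x| ≈ 1.5,
  the responsive range of tanh; with larger drives the regulation term
  saturates to a constant ±w and edges stop transmitting variation.
- a mid-culture environmental shift: a logistic gate centred on day 8
  (width 1.5 days) scales a per-TF input with sd 0.4, acting on a
  receptor-proximal subset of TFs (`frac_input_tfs` 0.4) with
  patient-specific coefficients. This mirrors the biology the design
  emulates — nurse-like cells establish themselves mid-culture and
  change the milieu, with strong inter-patient heterogeneity — and it
  matters statistically: with initial-state relaxation as the only
  temporal mode, every TF's interval profile is collinear within a
  patient and pairwise profile correlations carry almost no edge
  information.
- edge strengths U(0.5, 1.5), 20% repressive, 20% condition-specific
  (those contribute only in their condition); edges sampled
  independently per ordered pair (density 0.08 by default).
- observation noise sd 0.1 on the activities at the design days;
  replicates draw independent initial states (two wells seeded from
  the same patient material, drifting apart), optionally shared.

**Counts.** Target gene g of TF j with mode m:
μ = softplus(β0_g + m·λ·x_js)·libsize_s with λ = 1.5,
β0 ~ N(2, 1), libsize ~ U(8, 16); counts are negative binomial with
dispersion 0.1 (Var = μ + 0.1 μ²); each TF has 10 dedicated targets
(30% repressed) and 200 background genes have activity-independent
means. All draws flow from one seeded generator through named
substreams, so any artefact is reproducible from (config, seed).

**Not emulated:** contamination by non-tumour cells, viability loss,
ligand–receptor dynamics, batch effects, gene-length or GC biases,
shared targets between TFs, and TFs regulating their own targets'
transcripts only indirectly. Passing the recovery benchmark therefore
shows the pipeline inverts *this* generative family at realistic noise
— not that it resolves confounders the generator does not contain.

## 7. The recovery benchmark

`tfdyngrn.benchmark.run_benchmark` simulates one study, runs the full
pipeline in memory, and scores the consensus against the scoped
ground truth: AUPR over all ordered non-self TF pairs with a pair's
score equal to its consensus weight (0 if absent), referenced to the
density baseline (the precision of a random ranking); and sign
accuracy over true-positive edges. The benchmark uses 300 trees per
run (10 runs per condition) — about a minute per seed on one CPU;
the default analysis configuration for real data keeps 1000 trees.
Recovery depends on the realised network: across seeds the AUPR fold
over baseline is typically 2.3–4.8 (≥3 in most seeds) with sign
accuracy 0.8–1.0.

## 8. Known limitations

- The correlation filter (|r| ≥ 0.5 on 12-cell profiles) is weakly
  selective at small TF counts; it mainly contributes edge signs, and
  it can prune correct forest edges (the consensus AUPR is usually
  below the merged directed network's).
- Per-target importance normalisation makes weights comparable across
  targets but discards how well each target was predicted.
- The pooled decay rate mis-specifies TFs whose true decay differs
  from the median; the residual is partially absorbed by the
  (discarded) self-importance.
- Assortativity on collapsed tags is undefined when every node shares
  one tag; use dominant-context labels in that regime.
- The ECC community rule approximates the original plugin; only its
  limiting behaviour, not its exact output, is guaranteed to match.
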