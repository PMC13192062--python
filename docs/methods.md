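# Methods

This note documents the models, parameters and design choices behind
`boolimpl`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## StepMiner one-step fits

Per gene, values are sorted ascending (stable sort; ties keep input
order) and, for every step position k ∈ [1, n−1], the data are fitted by
two constants: the mean of the first k and of the last n−k values. The
selected k minimizes the residual SSE, computed with running sums
(left-SSE + right-SSE via cumulative sums of x and x²). With the model
dimension fixed, minimizing SSE orders candidate steps identically to
maximizing the F-statistic, which is reported as a diagnostic with
m = 3 degrees of freedom (two level means plus the step position); when
the residual SSE is 0, F = ∞ is reported. Ties in SSE (within 1e−12) are
resolved toward the smallest k for determinism. Only rising steps are
fitted. The gene's threshold is the midpoint (μ_lo + μ_hi)/2. Constant
genes have no step; they are flagged degenerate with t equal to the
constant and F = 0. Fits require n ≥ 4.

Numerical notes: the running-sum SSE can round to a tiny negative value
and is clamped at 0; on integer-valued inputs it is bit-identical to
recomputing the per-k sums from scratch (sums stay exact in double
precision), which the tests exploit.

## Discretization and the noise margin

States are ternary: LOW if value < t − margin, HIGH if value > t +
margin, INTERMEDIATE otherwise, with margin 0.5 — a two-fold change on
the log₂ scale. Boundary values (exactly t ± margin) are INTERMEDIATE.
Inputs are assumed already normalized to a log₂ scale (the I/O layer
offers `log2_tpm_transform` for raw TPM); no cross-dataset
harmonization is applied beyond the per-gene, per-dataset thresholds.

## BooleanNet quadrant statistics

Samples definite in both genes of a pair populate counts a₀₀, a₀₁, a₁₀,
a₁₁. For quadrant (i, j), the expected count under independence uses the
quadrant's own margins, n̂ = row_i · col_j / total — the standard
contingency-table expectation, which reduces to the low/low formula when
(i, j) = (0, 0) and makes all four asymmetric relationships computable.
Sparsity is S = (n̂ − n)/√n̂ and the error probability is the average of
the two conditional frequencies of landing in the quadrant given each
gene's margin. A quadrant is sparse when S > sThr (3) and p < pThr
(0.1). Tables with a zero margin (a gene observed in only one state)
have undefined statistics and yield no relationship.

The sparse-set → relationship map recognizes exactly six patterns:
{01,10} equivalent, {00,11} opposite, and the four singletons
({00} low⇒high, {01} low⇒low, {10} high⇒high, {11} high⇒low). Sparse
sets of size 3 or 4, or adjacent pairs sharing a margin, yield NONE —
adjacent pairs in fact force a zero margin, so they are unreachable.
Two algebraic laws are enforced by construction and verified
exhaustively in tests: transposing the table (reading the pair in the
other order) maps each relationship to its converse, and negating one
gene swaps equivalent↔opposite and low⇒low↔low⇒high etc.

The dynamic-range filter keeps genes with at least 5% of samples LOW
*and* at least 5% HIGH ("fewer than 5%" removed, so exactly 5% is
kept). The permutation FDR shuffles each gene's values independently
across samples — destroying all pairwise structure while preserving
marginals, hence thresholds and the filter — and reports the mean
significant-pair count over permutations divided by the observed count
(∞ when nothing is observed). The default is 3 permutations at desk
scale; the estimate is a ratio of large counts and stabilizes quickly.

## Clustered network

Equivalence edges form an undirected graph. Each edge's Jaccard
coefficient is computed on the open neighborhoods of its endpoints in
that graph. A minimum spanning forest with edge weight 1 − Jaccard
biases the retained tree toward well-embedded edges (the field's
procedure specifies an MST but no weight); tree edges with Jaccard
strictly below 0.5 are removed, and the surviving components — plus
singletons for filtered-in genes without equivalence edges — are the
clusters. Raising the threshold can only refine the partition.
Representatives are the top-3 members by within-cluster equivalence
degree (ties lexicographic). For each cluster pair, all 3 × 3
representative pairs are classified; an edge of the majority type is
added when at least half the pairs are informative (non-NONE) and at
least 67% of those agree — the "overwhelming majority" made concrete,
since no number is given in the source procedure. Edge colors follow
the fixed map (orange low⇒high, dark blue low⇒low, green high⇒high,
red high⇒low, light blue equivalent, black opposite) and round-trip
through the JSON and GraphML exports.

A log–log regression of cluster-size counts on size serves as the
scale-free diagnostic; it needs ≥ 3 distinct sizes and is reported, not
acted on.

## Composite scores, training, evaluation

Normalization is (expr − t − 0.5)/(3·SD) per gene, with SD the sample
standard deviation (n−1) over **all** samples of the dataset, cases and
controls pooled (the SD population is otherwise unspecified; pooling
keeps the transform label-blind). Zero-SD genes are dropped with a
warning. A composite score is the weighted sum of per-set means of
normalized values; missing signature genes are dropped (the mean
renormalizes over present genes), and a direction that is entirely
missing flags the evaluation as degraded rather than failing it. The
two-fold noise margin propagated through the normalization,
0.5/(3·SD) averaged over the genes used, is attached to the scores as
metadata (samples inside the band are listed as indeterminate); it
never alters the score, which must remain comparable across ROC
analyses.

Training: clusters are ranked by the mean over training cohorts of
|AUC − 0.5| of their cluster-average score (the selection criterion is
stated only as predictive ability; this makes it symmetric for up- and
down-regulated clusters), and the top 3 are kept by default. Candidate
genes come only from selected clusters; up candidates need per-gene
ROC-AUC > 0.6 in every cohort and down candidates < 0.3, both under the
fixed "higher expression ⇒ disease" orientation (no flipping — the
asymmetric cutoffs are intentional). Candidates are ranked by |Welch t|
on the designated primary cohort and capped at 20 per direction, with
weights +1/−1; the cap is a maximum, never padded. AUC is computed by
the rank-sum identity with midranks (ties count ½); Welch's t and its
Satterthwaite df come from `scipy.stats.ttest_ind(equal_var=False)`, and
Benjamini–Hochberg adjustment from `statsmodels.multipletests`. The
t-test (not Mann–Whitney) is used on composite scores because a
40-gene weighted mean is close to normal within a class (CLT); the test
suite checks this with a Shapiro test across seeds.

## Synthetic study conditions

The generator plants every structure the pipeline is meant to find;
defaults are the conditions all benchmarks run under.

* **Logic blocks** — six blocks (sizes 10, 8, 8, 6, 6, 5) of bimodal
  genes with modes μ_lo = 2, μ_hi = 6 and σ = 0.5, wired by one planted
  edge of each implication type (high⇒high, low⇒low, low⇒high,
  high⇒low, opposite) in a DAG. Root-block states are Bernoulli(0.5);
  a child copies the forced state where its parent constrains it and is
  free Bernoulli otherwise, then flips with violation rate ε (default 0).
* **Signature blocks** — 30 up and 30 down genes. The up block's latent
  state *is* the class label and the down block its complement (an
  extreme Bernoulli-rate shift between classes, softenable with
  `signature_flip`); signature genes use a mode gap equal to the class
  shift Δ = 1.0 = 2σ, so with no flips a case value is N(μ + Δ, σ²)
  against a control N(μ, σ²) and the per-gene ROC-AUC is exactly
  Φ(Δ/(σ√2)) = Φ(√2) ≈ 0.921 in closed form.
* **Co-regulation** — genes of one block share a fraction
  `noise_rho` = 0.5 of their noise variance through a latent per-sample
  block factor, as co-expressed genes do in real data. The split leaves
  per-gene marginals (and the closed-form AUC) unchanged but makes
  cross-mode excursions co-occur, so planted equivalences are detectable
  rather than sitting at the p ≈ pThr boundary. With independent noise
  the signature blocks — whose modes are only 2σ apart — fragment under
  Jaccard pruning; residual correlation is both realistic and what makes
  the planted clusters well-posed.
* **Background** — 60 unimodal genes, N(4, 0.25²). Their spread is small
  against the 0.5 margin, so the low/high tails cannot both reach 5% and
  the dynamic-range filter removes them; genes with σ comparable to the
  margin would (correctly) survive it.
* **Cohorts** — the training trio shares blocks and signature but has
  its own additive offset (0, +0.5, −0.4), noise multiplier (1.0, 1.2,
  0.9) and size (400, 300, 240 samples), mirroring the scale of typical
  bulk case/control brain cohorts; labels are Bernoulli(0.5). Held-out
  cohorts use a fresh seed, offset and noise multiplier.
* **Seeding** — one master seed flows through named `SeedSequence`
  streams (labels, states, flips, noise; one child per cohort), so
  identical configurations are bit-reproducible and single stages can
  be varied in isolation.

What the generator does **not** emulate: read counts and library-size
effects, probe-level artifacts, dropout, batch structure beyond a global
offset/scale, correlated violations, or signature genes entangled with
the logic DAG. Passing benchmarks therefore demonstrate correctness and
calibration of the inference machinery under its own model assumptions,
not performance on any real cohort.

## Benchmark sizes

The test suite and the reproduction script use: 1000 random vectors
(n ≤ 100) against the exhaustive step-position scan; 10,000 random count
tables for the converse/negation laws; 50 seeds × 200 independent pairs
at n = 200 for null calibration; the 300-sample planted network for
recovery and cluster agreement; and 20 independent trios for signature
recovery and held-out evaluation. These sizes give stable estimates
(binomial standard errors well below the asserted tolerances) while
keeping a full run on one CPU in the tens of seconds.

## Known limitations

* Only the rising one-step StepMiner variant is implemented; multi-step
  fits and time-series orderings are out of scope.
* The Jaccard coefficient is computed on all equivalence-graph edges but
  pruning applies to MST edges; pruning the full graph before the MST is
  a defensible alternative reading of the procedure.
* The permutation-FDR numerator/denominator convention (mean null count
  over observed count) is one of several reasonable definitions.
* Missing values are rejected, never imputed; transposed matrices are
  the caller's responsibility.
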