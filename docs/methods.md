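# Methods

This note documents the model, the algorithmic and numerical choices, and
what the synthetic-data generator does and does not emulate.

## Activity model

Expression of gene *gᵢ* under phenotype *k* ∈ {1, 2} is modelled as
Gaussian with mean μᵢ⁽ᵏ⁾ and standard deviation σᵢ⁽ᵏ⁾, estimated empirically
(sample mean; unbiased SD) from the phenotype-*k* training samples. The
per-observation log-likelihood ratio (natural log)

α(x) = log(σ⁽²⁾/σ⁽¹⁾) − (x − μ⁽¹⁾)²/(2σ⁽¹⁾²) + (x − μ⁽²⁾)²/(2σ⁽²⁾²)

is positive when the observation favours phenotype 1. Subnetwork activity is
the plain sum of member LLRs — no √n normalisation, since the downstream
*t* statistic is scale-invariant and normalisation would not change any
ranking. Discriminative power *R* of a gene set is the absolute two-sample
*t* of its activity; the absolute value matters because members may be
oppositely regulated (the LLR transform re-orients down-regulated genes, but
mixed sets can still yield negative *t*).

**σ flooring.** Class-conditional SDs are floored at
`sigma_floor_factor` (default 10⁻⁶) times the global SD of the expression
matrix, so the LLR stays finite for genes constant within a class. The floor
only matters for degenerate genes; any value orders of magnitude below
typical SDs gives identical results.

**t-statistic flavour.** Welch (unequal variances) is the default;
pooled-variance Student's *t* is available (`t_test="student"`). Welch is
the safer choice under the heteroscedasticity the two-Gaussian model itself
allows; the flavour only rescales scores slightly and does not change the
qualitative behaviour of any test in the suite.

## Path scoring

For a path λ of l genes with LLR correlation matrix P (Pearson, pooled over
both phenotypes — restricting to one class would discard the co-regulation
signal the score is meant to reward):

Σ′(λ) = (P + (θ − 1)I)/(l − 1 + θ) for l ≥ 2, Σ′ = [1] for l = 1;
s(λ) = |t_α|ᵀ Σ′ J; S(λ) = s(λ)/l.

This Σ′ is the simplest form with the three limits that pin the scheme down:
at θ = 0 each gene's effective weight is its average correlation with the
other members; as θ → ∞ (handled as an exact branch, not a large number)
Σ′ = I and S is the average |t|; at l = 1 the score is |t_α| for every θ,
matching the search initialisation. When all pairwise correlations are 1 the
row sums of Σ′ are identically 1, so S equals the average |t| at every θ —
fully coherent paths are scored exactly like the θ = ∞ limit.

Signed correlations are used (not |ρ|): anticorrelated LLRs genuinely reduce
the coherence of summed activity and should be penalised. Absolute t-scores
are used throughout, so up- and down-regulated genes mix freely in a path.

**Normalisation exponent.** The default S = s/l preserves the θ → ∞
average-|t| limit exactly; a stronger penalty S = s/l² is available via
`norm_exponent=2`. Note that at finite θ the normalised score of random
(uncorrelated) paths still drifts mildly downward with length — row sums of
Σ′ on null data are ≈ θ/(l − 1 + θ) — which is the intended penalty on
incoherent membership, not a normalisation artefact: length-neutrality is
exact in the θ = ∞ limit.

## Path search

A beam dynamic program stores, for every node v and length l ≤ L (lengths
count *nodes*; L defaults to 8, matching the admitted collection range
5 ≤ l ≤ 8), the top-M simple paths of length l ending at v, sorted by raw
score. Length-1 entries are the singletons with s = |t_α(v)|. For l ≥ 2,
candidates are all one-node extensions of the neighbours' (l − 1)-paths that
keep the path simple, and **every candidate is re-scored in full**: the
correlation coupling makes the score non-additive, so no exact score
recurrence exists and any additive update would be an approximation. The
per-(node, length) candidate pool is naturally bounded by M × degree.

Ties in raw score break lexicographically on the gene-id tuple, making the
whole search deterministic. With M at least the number of simple paths per
(node, length) the beam is lossless and the search provably exhaustive (the
test suite checks this against brute-force enumeration on small graphs).
Finished paths are pooled over the admitted length range, deduplicated as
orientation-free sequences (the score is reversal-invariant), and the top m
(default 100) by normalised score go to assembly.

Correlations are served from a precomputed gene × gene matrix when at most
3,000 genes are scoreable, and otherwise from standardized LLR rows batch by
batch; results are identical, only memory/time trade-offs differ.

## Greedy assembly and marker iteration

The top path seeds the subnetwork G_s. Remaining paths are scanned once in
rank order; a path sharing at least one gene with the *current* G_s is
tentatively unioned and kept iff R(union) > (1 + ε)·R(G_s), with ε = 0.01
guarding against overfitting-driven micro-improvements and the inequality
strict. Paths disjoint from G_s at their turn are skipped and (by default)
not revisited, even if a later merge would have created overlap; a
`multi_pass` option rescans until a full pass accepts nothing. The
accept/reject trace (with before/after R) is retained on every marker for
auditing.

After each marker, all edges incident to its members are removed
(`prune_network`) and the now-isolated members are dropped from the working
network, guaranteeing pairwise-disjoint markers; gene t-scores and the LLR
matrix are unchanged across iterations (only adjacency changes), and the DP
re-runs from scratch on the pruned network. If the path pool empties before
k markers are found, the run returns what it has with a warning rather than
failing — small networks exhaust quickly. No cap is placed on marker size
beyond the path-length limits.

Default parameters: θ = 8 (a mid-range trade-off that balances per-gene
power against coherence), M = 20, m = 100, lengths 5–8, ε = 0.01, k = 50.

## Cross-validation harness

Marker definitions are fixed before CV — discovery is not re-run per fold,
which mirrors the intended usage (markers from one study evaluated on
another) but means within-dataset AUCs carry a known optimistic bias from
discovery having seen all samples. Everything else is leakage-free and
fold-local: per repeat, a stratified ten-fold split is drawn (redrawn, with
a log note, if any fold is single-class); per test fold the nine training
folds are split 6/3 (seeded fold-level draw; the rotation is not prescribed
further) into a marker-ranking set and a feature-selection set. Gaussian LLR
parameters (or z-normalisation statistics for the mean-expression scheme)
are estimated on the nine training folds only. Markers are ranked by |t| of
their activity on the ranking set (pool capped at the top 50), the
classifier is an unpenalized logistic regression fitted on the ranking set
(behind a standardising scaler for optimizer stability; an L2 option exists
for tiny runs), and forward selection keeps a marker iff the selection-set
AUC *strictly* increases. The test fold contributes its AUC (rank-based,
ties ½, phenotype 1 positive) and its scores to a pooled error-vs-TPR curve,
where the error at a sensitivity level is the best misclassification rate
among thresholds achieving at least that TPR.

Every fold record retains the sample-index sets used for estimation,
ranking, selection and testing, so tests can assert the held-out fold never
enters any fitting step.

## Synthetic data generator

The generator produces the structure the method assumes and nothing more: an
Erdős–Rényi or Barabási–Albert network; disjoint connected modules grown by
seeded random walks (stalled growth adds a bridging edge, logged); planted
gene g in module q generated as x = s_g·((δ_q/2)·c + b_q·z) + N(0, σ²) with
c = ±1 the phenotype code, z a per-sample module-shared latent factor,
s_g ∈ {±1} a per-gene orientation (so modules mix up- and down-regulated
members), and background genes pure N(0, σ²). The latent construction keeps
generation O(genes × samples) and positive semidefinite by construction.

The loading b_q is calibrated so the *pooled-sample* correlation between two
members, class separation included and classes assumed balanced, hits
ρ_target: ρ = (δ²/4 + b²)/(δ²/4 + b² + σ²). Targets below the b = 0 bound
δ²/4/(δ²/4 + σ²) are infeasible and raise with that bound. Since the LLR is
approximately linear in x when class variances are similar, realized LLR
correlations track this target (within ±0.1 for n ≥ 100 samples; checked in
the suite).

Default study conditions — 300 nodes, three modules of six genes, δ = 2,
ρ_target = 0.5, 100 + 100 samples, σ = 1 — keep a full discovery + CV cycle
under ~10 s on one CPU while leaving the planted signal realistically noisy
(per-gene |t| ≈ 7, not separable by any single threshold). What the
generator does **not** emulate: microarray intensity distributions, probe
effects, missing values, batch structure, or hub-biased placement of disease
genes. Passing tests therefore demonstrate correctness and calibration of
the algorithms under the assumed model, not clinical performance on real
cohorts.

## Degenerate inputs and conventions

- Genes with zero LLR variance get correlation 0 to every other gene and 1
  on the diagonal; a zero-spread activity yields t = 0 with a warning.
- Phenotype codes are exactly {1, 2}; phenotype 1 is the positive class for
  AUC and the "plus" side of every t. Both classes need ≥ 2 samples.
- Duplicate expression rows for one gene are rejected, not averaged;
  collapsing multi-probe genes is the caller's responsibility upstream.
- Network parsing collapses duplicate/reversed edges and drops self-loops;
  the edge-list writer encodes isolated nodes as self-loop lines so
  round-trips preserve the node set.
- All randomness flows through explicit integer seeds; identical inputs and
  seeds reproduce marker GMT output byte-for-byte.

## Known limitations

- Exact re-scoring makes the search O(Σ_v deg(v) · M · L · l²·n_samples)
  per iteration; for genome-scale induced networks (~10⁴ nodes) a run at
  default settings is minutes-to-hours, not seconds.
- The greedy single-pass assembly is order-dependent by design; locally
  optimal merges are not revisited.
- Only two-phenotype designs are supported; no multi-class extension.
- Marker discovery outside the CV loop biases within-dataset AUCs upward;
  cross-dataset evaluation (markers from one dataset, CV on another) is the
  honest reproducibility measure and is supported directly.
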