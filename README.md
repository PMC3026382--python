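# subnetmarkers

Discovery of discriminative **subnetwork markers** in protein–protein
interaction (PPI) networks from two-phenotype gene-expression data.

Single-gene expression markers for clinical classification (e.g. predicting
breast-cancer metastasis) are notoriously unstable: small cohorts, noisy
measurements and redundant gene sets make marker lists poorly reproducible
across studies. Aggregating expression over *connected subnetworks* of a PPI
network yields markers that are both more discriminative and more
reproducible. This package implements a full pipeline for finding such
markers, together with baseline marker schemes and a leakage-free nested
cross-validation harness for comparing them, plus a seeded synthetic-data
generator that plants correlated, differentially expressed modules in a
random network for testing and calibration.

## The method

**Activity inference.** Each gene *gᵢ*'s expression is modelled per
phenotype *k* ∈ {1, 2} as Gaussian with parameters (μᵢ⁽ᵏ⁾, σᵢ⁽ᵏ⁾) estimated
on training samples. The log-likelihood ratio (LLR) of an observation *x* is

    α(x) = log σ⁽²⁾/σ⁽¹⁾ − (x − μ⁽¹⁾)²/2σ⁽¹⁾² + (x − μ⁽²⁾)²/2σ⁽²⁾²

and the activity of a gene set in a sample is the **sum of member LLRs**.
A marker's discriminative power *R* is the absolute two-sample *t* statistic
of its activity between the phenotypes.

**Path scoring.** A linear path λ = (g₁ … g_l) in the network is scored by a
correlation-weighted sum of its members' absolute LLR *t*-scores:

    s(λ) = |t_α|ᵀ Σ′ J,   Σ′ = (P + (θ−1)I)/(l−1+θ),   S(λ) = s(λ)/l

where *P* is the Pearson correlation matrix of the members' LLRs and *J* the
all-ones vector. The parameter θ trades off individual discriminative power
against inter-member coherence: at θ = 0 each gene is weighted by its average
correlation with the other members; as θ → ∞, Σ′ → I and *S* becomes the
plain average |t|.

**Search and assembly.** A beam dynamic program keeps, for every node and
every path length l ≤ L, the top-M highest-scoring simple paths ending there
(each candidate extension is re-scored exactly — the correlation coupling
admits no additive recurrence). The top-m finished paths within a length
range are merged greedily: a path overlapping the current subnetwork is
absorbed iff it multiplies *R* by more than (1 + ε). The accepted subnetwork
is pruned out of the network and the search repeats, producing *k* pairwise
**non-overlapping** markers.

**Evaluation.** Markers (fixed up front) are assessed by nested CV: per
random stratified ten-fold split, six folds rank markers and fit a logistic
regression, three folds drive forward feature selection by strict AUC
improvement, and the held-out fold provides the test AUC. Baselines include
top-|t| single genes, average-|t| gene-set ranking, and mean-expression
activity.

## Worked example

```python
import subnetmarkers as sm

# 300-node network, three planted 6-gene modules (effect size 2 SD,
# within-module correlation 0.5), 100 + 100 samples
network, truth, dataset = sm.planted_fixture(seed=42)

config = sm.RunConfig(theta=8.0, marker_count=3)
markers = sm.identify_markers(network, dataset, config).markers
for i, m in enumerate(markers, 1):
    print(f"marker_{i:03d}: {len(m.members):3d} genes  R = {m.R:6.2f}")

planted = truth.planted_genes
found = set().union(*[m.members for m in markers])
print(f"planted-gene recovery: {100 * len(planted & found) / len(planted):.0f}%")

defs = [(f"marker_{i:03d}", sorted(m.members)) for i, m in enumerate(markers, 1)]
cv = sm.nested_cv(dataset, defs, n_repeats=5, seed=0)
print(f"nested-CV mean test AUC: {cv.mean_auc:.3f}")
```

prints

```
marker_001:  12 genes  R =  49.85
marker_002:  10 genes  R =  34.35
marker_003:  38 genes  R =  13.99
planted-gene recovery: 100%
nested-CV mean test AUC: 1.000
```

The first two markers absorb the strongly correlated planted modules (their
activity separates the phenotypes at |t| ≈ 50 and 34); the third mops up the
remaining planted module plus correlated noise genes. All 18 planted genes
are recovered, and the cross-validated classifier built on the three marker
activities separates the phenotypes perfectly.

The same pipeline is available from the shell:

```bash
subnetmarkers simulate --out-dir sim --seed 42
subnetmarkers identify --expression sim/expression.tsv --labels sim/labels.tsv \
    --network sim/network.tsv --markers 3 --out-dir run
subnetmarkers score    --expression sim/expression.tsv --labels sim/labels.tsv \
    --markers run/markers.gmt --out-dir scores
subnetmarkers evaluate --expression sim/expression.tsv --labels sim/labels.tsv \
    --markers run/markers.gmt --repeats 5 --out-dir cv
```

For sklearn composition, `SubnetworkMarkerDiscovery` is a transformer
(`fit(X, y)` discovers markers, `transform(X)` yields a samples × markers
activity matrix) that slots into a `Pipeline` in front of any classifier.

## Input formats

- expression: TSV, genes × samples, header row of sample ids, first column
  gene ids (one shared namespace with the network; no probe mapping is done);
- labels: two-column TSV `sample_id <tab> phenotype` with phenotype ∈ {1, 2};
- network: two-column tab-separated edge list or SIF; undirected, self-loops
  dropped, duplicate edges collapsed;
- markers: GMT (name, description, member genes), written and read back.
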