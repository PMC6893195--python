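# Methods

This note documents the models and procedures `netprio` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer should know about.

## Functional network and features

The network is an undirected weighted gene graph with weights in [0, 1]
(posterior probabilities of shared function, as produced by Bayesian
integration pipelines such as FNTM). Input files are thresholded edge
dumps, so an absent edge is taken as weight 0 — the same semantics the
feature construction uses: a gene's feature vector against a module is its
row of the adjacency matrix restricted to the module's genes. A gene's
entry against itself is 0 (no self-edges), so known positives do not carry
a trivially identifying feature. Nodes are kept in lexicographic order;
every matrix assembled from the network is deterministic.

Coordinates are held 1-based and closed internally; BED input (0-based,
half-open) is converted on load. Genes present in gene sets or loci but
absent from the network are never silently dropped: they are carried
through reporting with a `not_in_network` flag and a functional score of 0.

## Module decomposition

Trait gene sets larger than `max_size` (default **400**; a 300-gene ceiling
over-fragments typical sets into sub-100-gene modules) are decomposed by
weighted fast-greedy modularity maximization (Clauset–Newman–Moore, via
python-igraph) on the subgraph the set induces in the network, cutting the
merge dendrogram at maximum modularity. Oversize communities are re-induced
and re-clustered recursively; a community the algorithm cannot split is
accepted as-is with a warning, which guarantees termination. Modules of any
size are kept; modules under 10 genes trigger a training-stability warning.
Edge weights enter the modularity (the network is intrinsically weighted).

## SVM ensembles and FPR calibration

Per module, `n_runs` (default **100**; tests and the acceptance script use
8–25 to stay inside time budgets — the estimator is unchanged, only its
ensemble size) linear SVMs are trained on module genes vs an equal-sized
fresh uniform draw from non-module universe genes. Classes are balanced by
construction, so no class weighting is used. The cost parameter is tuned
per run: mean stratified 10-fold CV accuracy on the geometric grid
1e−5…1e2 (8 points, factors of 10), then up to **5** re-grids of 8
geometric points spanning the best cost's neighbors, stopping when the best
accuracy improves by < 1e−3. Fold splits are seeded per run; the fold count
is capped at the smaller class size when necessary.

Decision values of all universe genes are averaged across runs without
per-run rescaling (all runs share the [0, 1] network-weight feature scale).
Known positives are scored by models that saw them in training; the
resulting optimism affects TP counts only, never a candidate gene's FPR,
because candidates are removed from training sets up front.

Per-gene FPR places the threshold at the gene's own (averaged) score,
inclusive: FPR = FP/(FP + TN) over **all** non-module universe genes (more
stable than the sampled training negatives), floored at 0.5/|negatives| so
−log10(FPR) stays finite. ROC curves sweep all unique score values
descending, anchored at (0,0) and (1,1); AUC is the trapezoidal area and
equals the Mann–Whitney probability with ties counted half (property-tested
to 1e−12).

## Mixed-model association

Kinship is pairwise-complete identity-by-state over SNPs outside the tested
locus (excluding the locus avoids absorbing the tested signal into the
covariance). The model `y = Xb + u + e`, cov(u) = σ_g²K, cov(e) = σ_e²I is
fitted by maximum likelihood: one eigendecomposition of K (symmetrized,
eigenvalues clipped at 0), then a 1-D profile over δ = σ_e²/σ_g² on 64
log-spaced points in [1e−5, 1e5] with bounded refinement between the best
grid point's neighbors; σ̂² is floored at 1e−12 so degenerate (constant)
phenotypes return a finite likelihood. Each SNP's LRT, 2(ll_full − ll_null)
with the intercept-only null under the same K, is referred to χ²(1).
Monomorphic SNPs and panels under 3 strains get p = 1 with a flag; SNPs
with missing calls among phenotyped strains are dropped with a logged
count (inbred panels have few). A binary phenotype is analyzed as a
quantitative 0/1 trait under the Gaussian model — the standard EMMA usage.

Calibration: with exchangeable (iid) null genotypes the empirical type-I
error at α = 0.05 is nominal (≈0.05 at n = 120, 1000 SNPs). With strongly
group-structured genotypes the scan is *conservative* (≈0.01 measured),
because group-tagged SNPs are partially explained by kinship — this is the
intended behavior of mixed-model association, not a defect.

p-values are floored at 1e−300 before −log10. The Bonferroni divisor
defaults to the number of SNPs actually scanned and is configurable
(`bonferroni_n`), since published analyses sometimes quote a divisor from a
different filtering stage.

## SNP→gene assignment and the combined score

Each SNP goes to the single gene minimizing distance to the gene *body*
(0 inside), provided the distance is ≤ 1 Mb; equidistant ties go to the
smaller start coordinate (logged). A gene's positional term is the max
−log10(p) over its SNPs; genes with no assigned SNP score 0 (p = 1) rather
than being excluded, so they still appear at the left edge of the score
plane. Normalization maxima are computed over positional candidates only.
S_cg = normalized positional + normalized functional ∈ [0, 2]; ranking ties
break lexicographically by gene id.

The Pareto front uses strict dominance: a gene is on the front iff no other
gene is ≥ in both normalized coordinates and > in at least one; duplicated
points can share the front. The front always contains the top-S_cg gene.
The gene × module output matrix reports, per module, the −log10(FPR) term,
a flag at FPR ≤ 0.2 (high-confidence functional association), and a
per-module combined score (positional term + that module's normalized
functional term) — both readings of "per-module score" are emitted because
published figures are ambiguous between them.

## Synthetic fixtures: what they do and do not establish

`synthetic_fixtures` generates the stated world the tests run in:

* **Network** — planted partition: module pairs fully connected with
  Beta-distributed weights (mean **0.8**, concentration 10), background
  edges subsampled to mean degree **50** (default; smaller in scaled-down
  tests) with weight mean **0.05**, mimicking a thresholded top-edges dump.
* **Gene sets** — one term per planted module plus 10% uniform noise genes;
  the causal gene's module is always covered.
* **Cohort** — **23** strains (the size of a typical inbred strain survey),
  mosaic haplotypes: SNPs in 25-SNP blocks, each strain copying one of 4
  ancestral prototypes per block with 5% per-SNP divergence. Linkage is
  therefore local (proxies of the causal SNP only inside its block) while
  shared ancestry induces non-trivial kinship. One causal SNP is placed in
  the causal gene's body, its alternate allele carried by half the
  haplotype groups; the binary phenotype is Bernoulli per strain with
  probability **0.9** (penetrance) on the alternate allele vs **0.05**
  background — a strong, near-Mendelian locus effect.

Everything is byte-reproducible from (config, seed), and generated files
pass every loader unchanged. The generator does **not** emulate ontology
structure, realistic mouse LD maps, gene-length variation, multi-allelic
sites, or genotyping error; a green recovery test establishes that the
pipeline's machinery recovers a strong planted signal at desk scale, not
that it would rank genes correctly under genome-scale noise, annotation
bias, or weak polygenic effects.

## Determinism

A single master seed derives per-module, per-run sub-seeds through
`numpy.random.SeedSequence([master, term_index, module_index])` spawning,
so adding a module never perturbs another module's randomness; two runs
with identical config produce byte-identical outputs (tested by checksum).

## Known limitations

* ML (not REML) variance components; with few strains σ_g² is biased
  downward, which slightly inflates LRT statistics — partially offset by
  the model's structural conservatism under population structure.
* The FPR calibration treats all non-module genes as negatives; true
  module members missing from the annotation deflate apparent FPRs.
* Cost-grid refinement bounds an under-specified search; accuracy plateaus
  make the selected cost arbitrary within the plateau (harmless for linear
  kernels, logged via the returned accuracy map).
* No ID-space conversion: network, gene sets, annotations and genotypes
  must already share one gene/strain vocabulary.
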