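# Methods

This note documents the models, parameter choices and numerical
conventions behind `stsig`, and what the synthetic benchmark does and does
not establish.

## Tag clustering (3′-end peak calling)

**Model.** Spot-resolved 3′-end capture produces molecules whose genomic
3′ ends pile up around transcription termination sites. Per (chromosome,
strand) the pooled 3′-end sites `(position p_i, count c_i)` are decomposed
by parametric density clustering. For a density penalty *d*
(molecules/bp) a segment scores `total_count − d·span`; a cluster is a
segment that is a maximal-scoring segment for some *d*. The recursion
finds, for segment `[i..j]`, the weakest boundary — the minimum over
prefix densities `Σc_{i..k−1}/(p_k − p_i)` and suffix densities
`Σc_{k+1..j}/(p_j − p_k)` — splits there, and assigns the segment the
density interval `[d_min, d_max]`, where `d_max` is the weakest-boundary
density and `d_min` is inherited from above. Ties go to the leftmost
boundary; the prefix side wins ties between sides. Single sites are leaves
with `d_max = +∞`; the root has `d_min = 0`.

Two non-obvious conventions, both validated against an exhaustive
density-sweep oracle (see `tests/oracles.py`):

* A segment whose split density lies *below* the density at which it came
  into existence (`d_max < d_min`) is *virtual*: it is never the maximal
  segment at any penalty. It is recursed through but not reportable, and
  its children inherit `max(d_min, d_max)` — not plainly `d_max` — as
  their floor. Without the `max` the children would claim density
  intervals in which they are never maximal.
* Reported clusters use `start = first site`, `end = last site + 1`
  (0-based half-open).

**Filtering.** Surviving clusters must satisfy `span ≤ max_span`
(default 200 bp — termination scatter is tens of bp wide) and
`total_count ≥ min_count` (default 2). A density-fold stability test
(`d_max ≥ min_fold · d_min`) is available but **off by default**
(`min_fold = 1`): the fold ≥ 2 convention from promoter (CAGE TSS) peak
calling assumes spiky profiles, whereas 3′-end termination peaks are
smooth; a smooth flat-topped peak has no interior segment whose density
doubles, so a fold filter shatters it into single-base leaves. Only the
outermost surviving cluster of each nested chain is emitted, so emitted
clusters are disjoint (`--keep-nested` exposes the rest; nothing
downstream uses it).

**Pooling.** Clustering always runs on the pooled reads of all input
sections, so every section shares one tag-cluster coordinate system —
required for cross-section training/testing.

**Gene association.** Each cluster's summit (highest-count site, leftmost
on ties) is matched against same-strand gene intervals extended
`downstream_slack` bp (default 500) past their 3′ end, to absorb
termination read-through. Among matches, the gene with the nearest 3′ end
wins; exact ties go to the smallest gene id. Clusters matching nothing
stay non-annotated — a real category, since termination signal exists
outside annotated models.

**MALAT1 removal.** Reads attributable to one configurable ultra-high
expressor (default MALAT1, a nuclear lncRNA notorious for internal priming
and overexpression in these libraries) are removed before clustering, by
gene tag or by 3′ position within the gene model.

## Filtering and normalization

Tag clusters detected in fewer than `min_tc_spots` spots (default 2) are
dropped, then spots with total counts < `min_spot_counts` (default 100) or
detected features < `min_spot_features` (default 100). The defaults assume
transcriptome-scale feature counts; scaled-down synthetic scenes use
proportionally scaled thresholds. Filtering is idempotent.

Size factors use the median-of-ratios estimator: reference profile =
per-feature geometric mean over spots, computed on the set *R* of features
nonzero in every spot; `s_j = median_{t∈R} k_jt / ref_t`. Spot-level data
is sparse enough that *R* is often tiny, so when `|R| < 50` the reference
falls back to geometric means over positive counts only (features with
≥ 2 positive spots) and each spot's median runs over its positive ratios.
Factors are not rescaled afterward — only their ratios matter downstream.
Normalized values are `log2(k/s + 1)`.

In *pooled* (unsupervised) analyses filtering and size factors are
computed once on the pooled matrix; in supervised train/test analyses each
section is filtered and normalized independently (test sections must be
processable without touching training data), with features aligned by id
and absent features imputed as zero.

## Differential-expression signature

Counts are modeled as NB with `Var = μ + αμ²`. For each pairwise contrast
(non-malignant vs DCIS, DCIS vs IDC, non-malignant vs IDC) and each tag
cluster:

* normalized counts `y = k/s`; group means `m_a`, `m_b`;
* `log2FC = log2((m_b+1)/(m_a+1))` — the pseudocount keeps zero-mean
  features finite, at the cost that a marker with baseline mean below
  ~0.75 molecules/spot can never reach |log2FC| > 2 even at an 8-fold true
  effect (`log2((8b+1)/(b+1)) > 2 ⇔ b > 0.75`). This is an intrinsic
  property of pseudocounted fold changes, not of the test;
* dispersion by method of moments on pooled within-group residuals,
  `α = max((s² − m̄)/m̄², 10⁻⁸)` with `s²` the pooled within-group variance
  and `m̄` the grand mean;
* Wald z from the delta-method standard error
  `SE = √(V_a/(m_a+1)² + V_b/(m_b+1)²)/ln 2`, `V_g = (m_g + αm_g²)/n_g`,
  two-sided p from the normal reference. Degenerate inputs (identical
  groups, all-zero features) give `log2FC = 0, p = 1`.

Under the null (NB μ=20, α=0.3, 30 vs 30 spots) the measured type-I error
at p < 0.05 is ≈ 0.055–0.06 — mildly liberal, as expected for a
moments-based Wald test, and immaterial at the FDR < 0.01 / |log2FC| > 2
operating point.

P-values are BH-adjusted within each contrast; selection is
`|log2FC| > 2 ∧ q < 0.01`; the signature is the union over the three
contrasts, ordered by matrix column order. BH per contrast (rather than
globally) keeps each volcano self-contained; with three contrasts the
difference at q < 0.01 is negligible.

## Supervised transfer

One-vs-rest linear SVM (squared hinge, C = 1 — the library default kept
deliberately, since the three classes are expected to be close to linearly
separable in log-expression space), trained on pooled labeled spots of the
training sections, features either the signature or all shared tag
clusters. Class probabilities are the temperature-1 softmax of the three
decision values: monotone in the margins, deterministic, and adequate for
argmax classification and soft visualization. Platt-style sigmoid
calibration (cross-validated) is available behind
`calibration="platt"` but off by default because its internal folds add
stochasticity. Ties in the argmax resolve in canonical class order
(non-malignant, DCIS, IDC).

Leave-one-dataset-out evaluation holds each section out in turn; in
signature mode the signature is re-derived from the training sections
only, so feature selection never sees the held-out section. Per-class
`F1 = 2TP/(2TP+FP+FN)` (0 when the denominator is 0) is tabulated per
held-out section with an arithmetic-mean row, displayed at 2 decimals
(round-half-even) with full precision kept in machine-readable output.
Spots labeled `unassigned` are excluded from training and from F1
denominators.

## Unsupervised grouping

PCA on the centered (not scaled — a feature's variance on log scale is
biologically meaningful) log-normalized matrix, top 2 components, each
loading vector signed so its largest-magnitude entry is positive (platform
reproducibility). Ward minimum-variance agglomeration (Ward.2 convention:
Euclidean coordinates, squared distances in the Lance–Williams update) on
the 2-D scores, cut at k = 3; group numbers are renumbered by first
appearance. Groups map to classes by majority vote among labeled members
(ties: canonical order; unlabeled groups map to `unassigned` with a
warning) and agreement is the fraction of labeled spots matching their
group's class.

## Synthetic scenes

The generator emulates the assumed data: `n_datasets = 4` serial sections
of a 33 × 35 barcoded array (1155 positions; the original slide design has
1007 active spots but its mask is not public, so a full grid is used);
3 spatially contiguous region classes per section (default `stripes`,
~60/20/20% of columns, mimicking the class imbalance of annotated tissue;
`blobs` grows two random-growth lesions on a non-malignant background);
300 genes placed non-overlapping on a toy chromosome with alternating
strands; per-(spot, gene) counts NB with dispersion α = 0.2 and mean
`base_g · 2^{effect·1[g marker of class(spot)]} · depth_j`, with
`log2FC = 3`, 20 markers per class, and `depth_j ~ LogNormal(0, 0.35)`.
Background baseline means are `2^U(−2.5, 1.5)` molecules/spot (≈ 560 k
molecules per section, typical of these libraries); marker genes draw from
`2^U(0, 2)` because a pseudocounted |log2FC| > 2 selection cannot, by the
arithmetic above, detect markers below ~0.75 molecules/spot — markers are
modeled as detectable, which is what marker genes are. One MALAT1-like
gene takes `malat1_fraction = 0.15` of all molecules. Each molecule
becomes a 48-bp BED read whose 3′ end is the gene's termination site plus
`round(N(0, 8 bp))`, clipped to the gene body ± 100 bp. Everything derives
from one seed; identical seeds give byte-identical files.

**What the synthetic benchmark shows — and not.** It exercises the full
chain (peak calling, accounting, normalization, selection, transfer,
unsupervised recovery) under the generator's assumptions: NB counts, clean
class geometry, markers expressed nowhere else, no batch effects between
sections, no mixed-population spots, no segmentation or doublet artifacts,
a transcriptome three orders of magnitude smaller than human. Perfect F1
on it demonstrates correctness of the machinery, not expected performance
on tissue; on real sections class boundaries blur (spots cover tens of
cells) and inter-section variation is larger.

**Scale.** Analyses run at the default scene (4 × 1155 spots, ~3.8 M
molecules, a few hundred tag clusters), which keeps the full recovery
experiment under a minute on one core while leaving count noise realistic;
the reduced scenes in the unit tests scale the filter thresholds
accordingly.

## Published benchmark tables

`stsig.refdata` bundles the printed per-section annotation counts and
cross-validation F1 grids of the four-section breast-cancer ST benchmark
this workflow re-implements (the underlying sequencing data has no bundled
accession). The package only recomputes their marginal sums and averages
as a consistency check. Note the published average rows are *truncated* to
2 decimals (a column mean of 0.975 appears as 0.97), and the published
overall percentages (97.7 / 98.3 / 93.7%) are means of those truncated
cells; `stsig` reports round-half-even averages instead and does not
replicate truncation.

## Known limitations

* The NB Wald test is a transparent stand-in for shrinkage-based DE
  estimators; per-feature agreement with those tools is out of scope, only
  the operating characteristics at the selection threshold are validated.
* Gene association uses the cluster summit only; overlap-fraction or
  multi-gene assignment is not modeled.
* No batch-effect correction across sections (the workflow pools them
  deliberately), no automatic choice of k, no image-based features.
* The paraclu-style decomposition is exact but the emitted set depends on
  the span/count/fold filters; stray low-count edge sites may surface as
  tiny separate clusters rather than joining a peak.
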