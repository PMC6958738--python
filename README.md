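# stsig — spatial transcriptomics tag-cluster signatures

`stsig` re-implements a complete spot-classification workflow for spatial
transcriptomics (ST) of tumor sections: from spatially barcoded 3′-end
sequencing reads to gene-model-independent expression features (*ST tag
clusters*), differential-expression signatures for histological region
classes — non-malignant, ductal carcinoma *in situ* (DCIS), and invasive
ductal carcinoma (IDC) — and transfer of those signatures to unseen tissue
sections with a linear multi-class support vector machine. An unsupervised
PCA + Ward alternative and a leave-one-dataset-out evaluation with
per-class F1 complete the workflow.

It is aimed at computational biologists who have ST-Pipeline-style BED
output (one row per UMI-collapsed molecule with genomic interval, strand
and array coordinates) plus per-spot region annotations, and who want
region signatures that generalize across serial sections.

## Method

1. **Tag clustering.** Each molecule is reduced to its 3′-end site
   (transcription termination side: `end − 1` on `+`, `start` on `−`).
   Per chromosome and strand, sites are grouped by parametric density
   clustering: a segment of sites is a cluster for every density penalty
   *d* at which it is the maximal-scoring segment of
   `score = total_count − d·span`. The recursive decomposition splits each
   segment at its weakest prefix/suffix boundary, giving every cluster a
   density interval `[d_min, d_max]`. Clusters are filtered by span and
   tag support, reads from a configurable ultra-high expressor (MALAT1 by
   default) are removed first, and clustering runs on the *pooled* reads
   of all sections so that every section shares one feature space.
2. **Normalization.** Spots × tag-cluster counts are filtered for
   low-expression spots/features, scaled by median-of-ratios size factors
   *s<sub>j</sub>* (geometric-mean pseudo-reference, with a positive-count
   fallback for sparse data), and transformed to
   `log2(k_ij / s_j + 1)`.
3. **Signature.** For each pairwise class contrast, every tag cluster gets
   a negative-binomial Wald test (`Var = μ + αμ²`, method-of-moments α,
   fold change `log2((m_b+1)/(m_a+1))`), Benjamini–Hochberg adjustment per
   contrast, and the signature is the union of tag clusters with
   `|log2FC| > 2` and `FDR < 0.01`.
4. **Transfer.** A one-vs-rest linear SVM (C = 1) is trained on the pooled
   labeled spots of the training sections — either on the signature
   features or on all tag clusters — and reports per-spot class
   probabilities (softmax over decision values). Leave-one-dataset-out
   rotation yields a sections × classes F1 grid with an average row
   (`F1 = 2TP / (2TP + FP + FN)`).
5. **Unsupervised alternative.** PCA (2 components, centered) + Ward
   agglomeration cut at k = 3, mapped to classes by majority vote against
   available annotations.

A first-class synthetic-data generator (`stsig.synthetic`) produces
multi-section scenes with known ground truth — negative-binomial counts,
spatially contiguous region classes, per-spot depth variation, one
MALAT1-like dominant gene, and Gaussian 3′-end scatter — so the whole
workflow is testable without any download.

## Worked example

Simulate a small four-section scene and run the full pipeline:

```sh
stsig simulate --config sim.yaml --out-dir scene
stsig tagcluster --bed scene/dataset_1.bed --bed scene/dataset_2.bed \
    --bed scene/dataset_3.bed --bed scene/dataset_4.bed \
    --gtf scene/genes.gtf --out-clusters tc.bed --out-matrix-dir matrices
stsig crossval --matrix matrices/dataset_1.matrix.tsv \
    --matrix matrices/dataset_2.matrix.tsv \
    --matrix matrices/dataset_3.matrix.tsv \
    --matrix matrices/dataset_4.matrix.tsv \
    --labels scene/labels.tsv --features signature \
    --min-spot-counts 40 --min-spot-features 30 --out f1.tsv
```

with `sim.yaml`:

```yaml
seed: 11
n_datasets: 4
grid_width: 16
grid_height: 14
n_genes: 120
n_signature_per_class: 10
```

The tag-cluster step prints its accounting (every input molecule is either
in the matrix, unclustered, or removed with the dominant gene):

```
131 tag clusters; matrix total 258607 (+104 unclustered, 46619 MALAT1 reads removed)
```

and the cross-validation prints the leave-one-section-out F1 grid — each
row is the section held out for testing while the other three train the
model, each column a region class:

```
           non-malignant  DCIS  IDC
dataset
dataset_1            1.0   1.0  1.0
dataset_2            1.0   1.0  1.0
dataset_3            1.0   1.0  1.0
dataset_4            1.0   1.0  1.0
Avg                  1.0   1.0  1.0
```

On this clearly separated synthetic scene the signature transfers
perfectly; `tc.bed` holds the clusters with their density intervals and
associated genes, e.g.

```
chrT  2972  3031  chrT:2972-3031:+  577  +  46  0.0962…  0.1111…  G0000  G0000
```

The same steps are available as library functions (`stsig.workflow`)
returning matrices, signature tables and report objects.

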