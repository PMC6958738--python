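"""End-to-end orchestration: reads -> clusters -> matrix -> signatures ->
supervised and unsupervised evaluation.

This is the programmatic equivalent of chaining the CLI subcommands; the
cross-validation and recovery analyses in ``scripts/acceptance.py`` and the
test suite run through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, preprocess, tagcluster, unsupervised
from .classify import EvaluationReport
from .signature import SignatureSet, derive_signature
from .synthetic import SimConfig, SimResult, simulate
from .types import SpotMatrix, RAW
from .unsupervised import ClusterAssignment

__all__ = ["PipelineResult", "reads_to_matrix", "run_unsupervised",
           "run_synthetic_pipeline", "signature_gene_recovery",
           "adjusted_rand_index"]


@dataclass
class PipelineResult:
    matrix: SpotMatrix                      # pooled raw spot x TC matrix
    clusters: list
    n_reads_in: int
    n_removed_gene: int
    n_discarded: int
    labels: pd.Series | None = None
    signature: SignatureSet | None = None
    reports: dict[str, EvaluationReport] = field(default_factory=dict)
    unsupervised: ClusterAssignment | None = None
    sim: SimResult | None = None


def reads_to_matrix(reads: pd.DataFrame, genes, remove_gene: str | None = "MALAT1",
                    min_fold: float = tagcluster.DEFAULT_MIN_FOLD,
                    max_span: int = tagcluster.DEFAULT_MAX_SPAN,
                    min_count: int = tagcluster.DEFAULT_MIN_COUNT,
                    downstream_slack: int = tagcluster.DEFAULT_DOWNSTREAM_SLACK,
                    ) -> PipelineResult:
    """Pooled tag clustering and matrix construction from a read table."""
    n_in = len(reads)
    if remove_gene:
        kept = tagcluster.remove_gene_reads(reads, genes, remove_gene)
    else:
        kept = reads
    n_removed = n_in - len(kept)
    sites = tagcluster.reads_to_sites(kept)
    clusters = tagcluster.call_clusters(sites, min_fold=min_fold,
                                        max_span=max_span, min_count=min_count)
    clusters = tagcluster.annotate_clusters(clusters, genes,
                                            downstream_slack=downstream_slack)
    matrix, discarded = tagcluster.build_matrix(kept, clusters)
    return PipelineResult(matrix=matrix, clusters=clusters, n_reads_in=n_in,
                          n_removed_gene=n_removed, n_discarded=discarded)


def run_unsupervised(matrix: SpotMatrix, labels: pd.Series | None = None,
                     k: int = 3, **filter_kwargs) -> ClusterAssignment:
    """Pooled filter + normalize + PCA + Ward, optionally scored vs labels."""
    filtered = preprocess.filter_matrix(matrix, **filter_kwargs)
    sf = preprocess.size_factors(filtered)
    log_m = preprocess.normalize_log(filtered, sf)
    emb = unsupervised.pca_embed(log_m, n_components=2)
    assignment = unsupervised.ward_cluster(emb, k=k)
    if labels is not None:
        assignment = unsupervised.map_groups_to_classes(assignment, labels)
    return assignment


def run_synthetic_pipeline(config: SimConfig | None = None,
                           feature_modes: tuple[str, ...] = ("signature", "all"),
                           with_unsupervised: bool = True,
                           filter_kwargs: dict | None = None) -> PipelineResult:
    """The headline recovery experiment on a simulated four-section scene.

    ``filter_kwargs`` override the low-expression filter thresholds (the
    defaults assume transcriptome-scale feature counts; scaled-down scenes
    need proportionally scaled thresholds).
    """
    config = config or SimConfig()
    filter_kwargs = filter_kwargs or {}
    sim = simulate(config)
    pooled_reads = pd.concat(sim.reads.values(), ignore_index=True)
    result = reads_to_matrix(pooled_reads, sim.genes)
    result.sim = sim
    result.labels = sim.labels_series

    per_dataset = {ds: result.matrix.for_dataset(ds) for ds in sim.reads}
    for mode in feature_modes:
        result.reports[mode] = classify.leave_one_dataset_out(
            per_dataset, result.labels, feature_mode=mode, **filter_kwargs)

    # global signature over all sections (per-dataset size factors)
    raw_parts, sf_parts = [], []
    for ds, m in per_dataset.items():
        filtered, sf, _ = classify.prepare_dataset(m, **filter_kwargs)
        keys = filtered.df.index.intersection(result.labels.index)
        raw_parts.append(SpotMatrix(filtered.df.loc[keys], RAW)
                         .reindex_tcs(result.matrix.tc_ids))
        sf_parts.append(sf.loc[keys])
    result.signature = derive_signature(
        SpotMatrix.concat(raw_parts), result.labels,
        size_factors_=pd.concat(sf_parts))

    if with_unsupervised:
        result.unsupervised = run_unsupervised(result.matrix, result.labels,
                                               **filter_kwargs)
    return result


def signature_gene_recovery(result: PipelineResult) -> tuple[float, float]:
    """(recall, precision) of the planted marker genes by the derived signature.

    Recall: fraction of planted signature genes with at least one selected
    tag cluster. Precision: fraction of selected tag clusters whose
    associated gene is a planted signature gene.
    """
    if result.sim is None or result.signature is None:
        raise ValueError("needs a synthetic pipeline result with a signature")
    planted = {g for genes in result.sim.truth.signature_genes.values()
               for g in genes}
    gene_of = {tc.id: tc.gene_id for tc in result.clusters}
    selected = result.signature.selected_tc_ids
    hit_genes = {gene_of.get(tc, "") for tc in selected}
    recall = np.mean([any(g in hit_genes for g in (gid,))
                      for gid in planted]) if planted else float("nan")
    precision = (np.mean([gene_of.get(tc, "") in planted for tc in selected])
                 if selected else float("nan"))
    return float(recall), float(precision)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement."""
    from sklearn.metrics import adjusted_rand_score

    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    if a.size != b.size:
        raise ValueError("partitions differ in length")
    return float(adjusted_rand_score(a, b))
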