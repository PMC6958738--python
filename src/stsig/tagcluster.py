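"""From spatial reads to tag clusters and the spot x tag-cluster matrix.

The capture chemistry is polyA-anchored 3'-end sequencing, so each molecule
is reduced to a single genomic site — its transcription termination side:
``end - 1`` on the ``+`` strand, ``start`` on the ``-`` strand. Per
(chromosome, strand), sites are decomposed by parametric density clustering:
a segment of sites is a cluster for all density thresholds d (molecules/bp)
at which it is the maximal-scoring segment of score
``total_count - d * span``. The decomposition is the classic recursive
split at the weakest prefix/suffix boundary; every cluster carries the
density interval ``[min_density, max_density]`` over which it is maximal,
and the ratio of the two is its stability.

Clustering is performed on the pooled reads of all input sections so that
every section shares one tag-cluster coordinate system (required for
cross-dataset training and testing downstream).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import ClusterNode, GeneModel, SpotMatrix, TagCluster, RAW

logger = logging.getLogger(__name__)

__all__ = [
    "remove_gene_reads",
    "reads_to_sites",
    "paraclu_decompose",
    "filter_clusters",
    "call_clusters",
    "associate_gene",
    "GeneIndex",
    "build_matrix",
]

# Density-rise (stability) filtering is off by default: sharp promoter-style
# peaks gain from requiring max_density >= 2 x min_density, but 3'-end
# termination peaks are smooth, and a smooth flat-topped peak has no interior
# segment whose density doubles — the filter would shatter it into
# single-base clusters. Pass min_fold=2 to restore the CAGE-style behavior.
DEFAULT_MIN_FOLD = 1.0
DEFAULT_MAX_SPAN = 200
DEFAULT_MIN_COUNT = 2
DEFAULT_DOWNSTREAM_SLACK = 500


def _three_prime(reads: pd.DataFrame) -> np.ndarray:
    pos = reads["start"].to_numpy().copy()
    plus = reads["strand"].to_numpy() == "+"
    pos[plus] = reads["end"].to_numpy()[plus] - 1
    return pos


def remove_gene_reads(reads: pd.DataFrame, genes: Sequence[GeneModel],
                      gene_name: str = "MALAT1") -> pd.DataFrame:
    """Drop reads attributable to one gene (ultra-high expressors).

    A read is removed when its 3'-end position falls inside a matching
    gene's interval on the same strand, or when its ``gene_tag`` equals the
    gene name (both case-insensitive). Absent gene: no-op with a warning.
    """
    name_lc = gene_name.lower()
    matches = [g for g in genes if g.gene_name.lower() == name_lc]
    tag_hit = reads["gene_tag"].str.lower().to_numpy() == name_lc
    pos_hit = np.zeros(len(reads), dtype=bool)
    pos = _three_prime(reads)
    for g in matches:
        pos_hit |= (
            (reads["chrom"].to_numpy() == g.chrom)
            & (reads["strand"].to_numpy() == g.strand)
            & (pos >= g.start)
            & (pos < g.end)
        )
    if not matches and not tag_hit.any():
        logger.warning("gene %r absent from annotation and tags; nothing removed",
                       gene_name)
        return reads
    keep = ~(tag_hit | pos_hit)
    return reads.loc[keep].reset_index(drop=True)


def reads_to_sites(reads: pd.DataFrame) -> pd.DataFrame:
    """Aggregate reads into 3'-end sites.

    Returns a DataFrame with columns ``chrom, strand, position, count``,
    sorted by (chrom, strand, position); the count sum equals the number of
    input reads.
    """
    if len(reads) == 0:
        raise ValueError("no reads to aggregate into sites")
    sites = (
        pd.DataFrame(
            {
                "chrom": reads["chrom"].to_numpy(),
                "strand": reads["strand"].to_numpy(),
                "position": _three_prime(reads),
            }
        )
        .groupby(["chrom", "strand", "position"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return sites


def paraclu_decompose(positions: np.ndarray, counts: np.ndarray,
                      chrom: str = "", strand: str = "+") -> ClusterNode:
    """Recursive maximal-segment decomposition of one chrom+strand's sites.

    ``positions`` must be strictly increasing and ``counts`` positive. The
    root gets ``min_density = 0``; each split happens at the weakest prefix
    or suffix boundary (leftmost on ties within a side; the prefix side wins
    ties between sides) and hands ``max(min_density, max_density)`` down as
    the children's ``min_density``. Single sites are leaves with
    ``max_density = +inf``. Nodes whose density interval is empty
    (``max < min``) are flagged unreportable but still recursed through:
    they are never the maximal segment at any density.
    """
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("paraclu_decompose needs at least one site")
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("site positions must be strictly increasing")
    if np.any(counts <= 0):
        raise ValueError("site counts must be positive")

    csum = np.concatenate([[0], np.cumsum(counts)])  # csum[k] = counts[:k].sum()

    def make_node(i: int, j: int, min_density: float) -> ClusterNode:
        total = int(csum[j + 1] - csum[i])
        return ClusterNode(
            chrom=chrom, strand=strand,
            start=int(positions[i]), end=int(positions[j]) + 1,
            n_sites=j - i + 1, total_count=total,
            min_density=min_density, max_density=np.inf,
            i=i, j=j,
        )

    root = make_node(0, positions.size - 1, 0.0)
    stack = [root]
    while stack:
        node = stack.pop()
        i, j = node.i, node.j
        if i == j:
            node.max_density = np.inf
            continue
        ks = np.arange(i + 1, j + 1)
        prefix_d = (csum[ks] - csum[i]) / (positions[ks] - positions[i])
        ks2 = np.arange(i, j)
        suffix_d = (csum[j + 1] - csum[ks2 + 1]) / (positions[j] - positions[ks2])
        bp = int(np.argmin(prefix_d))        # leftmost min: np.argmin is first
        bs = int(np.argmin(suffix_d))
        pref_min = float(prefix_d[bp])
        suff_min = float(suffix_d[bs])
        node.max_density = min(pref_min, suff_min)
        node.reportable = not (node.max_density < node.min_density)
        # an unreportable (virtual) node never becomes maximal, so its
        # children only take over once the *ancestor's* floor is exceeded
        child_min = max(node.min_density, node.max_density)
        if pref_min <= suff_min:             # prefix side wins ties
            k = i + 1 + bp
            left = make_node(i, k - 1, child_min)
            right = make_node(k, j, child_min)
        else:
            k = i + bs
            left = make_node(i, k, child_min)
            right = make_node(k + 1, j, child_min)
        node.children = [left, right]
        stack.append(right)
        stack.append(left)
    return root


def filter_clusters(root: ClusterNode, min_fold: float = DEFAULT_MIN_FOLD,
                    max_span: float = DEFAULT_MAX_SPAN,
                    min_count: int = DEFAULT_MIN_COUNT,
                    keep_nested: bool = False,
                    positions: np.ndarray | None = None,
                    counts: np.ndarray | None = None) -> list[TagCluster]:
    """Emit stable, compact, well-supported clusters from a decomposition.

    A node survives when ``max_density >= min_fold * min_density`` (leaves
    with ``+inf`` always pass), ``span <= max_span`` and
    ``total_count >= min_count``. By default only the outermost survivor of
    each nested chain is emitted, so emitted clusters are disjoint;
    ``keep_nested`` additionally emits surviving descendants.

    When the site arrays are supplied, each cluster records its summit: the
    position of its highest-count member site (leftmost on ties).
    """
    out: list[TagCluster] = []
    stack = [root]
    while stack:
        node = stack.pop()
        passes = (
            node.max_density >= min_fold * node.min_density
            and node.span <= max_span
            and node.total_count >= min_count
        )
        if passes:
            summit = -1
            if positions is not None and counts is not None:
                seg = slice(node.i, node.j + 1)
                summit = int(positions[seg][int(np.argmax(counts[seg]))])
            out.append(
                TagCluster(
                    chrom=node.chrom, strand=node.strand,
                    start=node.start, end=node.end,
                    n_sites=node.n_sites, total_count=node.total_count,
                    min_density=node.min_density, max_density=node.max_density,
                    summit=summit,
                )
            )
            if not keep_nested:
                continue
        stack.extend(reversed(node.children))
    out.sort(key=lambda tc: (tc.chrom, tc.start, tc.end, tc.strand))
    return out


def call_clusters(sites: pd.DataFrame, min_fold: float = DEFAULT_MIN_FOLD,
                  max_span: float = DEFAULT_MAX_SPAN,
                  min_count: int = DEFAULT_MIN_COUNT,
                  keep_nested: bool = False) -> list[TagCluster]:
    """Decompose and filter every (chrom, strand) of a site table."""
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in sites.groupby(["chrom", "strand"], sort=True):
        pos = grp["position"].to_numpy()
        cnt = grp["count"].to_numpy()
        root = paraclu_decompose(pos, cnt, chrom=chrom, strand=strand)
        clusters.extend(
            filter_clusters(root, min_fold=min_fold, max_span=max_span,
                            min_count=min_count, keep_nested=keep_nested,
                            positions=pos, counts=cnt)
        )
    return clusters


class GeneIndex:
    """Strand-aware interval lookup of gene models, extended downstream.

    Each gene's interval is extended by ``downstream_slack`` bp past its 3'
    end (rightward for ``+`` genes, leftward for ``-`` genes) to capture
    read-through termination signal.
    """

    def __init__(self, genes: Sequence[GeneModel],
                 downstream_slack: int = DEFAULT_DOWNSTREAM_SLACK):
        self.downstream_slack = downstream_slack
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            lo, hi = g.start, g.end
            if g.strand == "+":
                hi += downstream_slack
            else:
                lo -= downstream_slack
            self._trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g)

    def query(self, chrom: str, strand: str, position: int) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(position)]


def associate_gene(cluster: TagCluster, index: GeneIndex) -> tuple[str, str]:
    """Assign a cluster to the nearest-TTS same-strand gene at its summit.

    Among genes whose (slack-extended) interval contains the cluster summit,
    the gene whose 3' end is closest to the summit wins; exact ties go to
    the smallest gene_id. Returns ``("", "")`` when no gene matches.
    """
    if cluster.summit < 0:
        raise ValueError("cluster has no summit; call filter_clusters with sites")
    hits = index.query(cluster.chrom, cluster.strand, cluster.summit)
    if not hits:
        return "", ""
    best = min(hits, key=lambda g: (abs(g.tts - cluster.summit), g.gene_id))
    return best.gene_id, best.gene_name


def annotate_clusters(clusters: Iterable[TagCluster], genes: Sequence[GeneModel],
                      downstream_slack: int = DEFAULT_DOWNSTREAM_SLACK
                      ) -> list[TagCluster]:
    index = GeneIndex(genes, downstream_slack=downstream_slack)
    out = []
    for tc in clusters:
        tc.gene_id, tc.gene_name = associate_gene(tc, index)
        out.append(tc)
    return out


def build_matrix(reads: pd.DataFrame, clusters: Sequence[TagCluster]
                 ) -> tuple[SpotMatrix, int]:
    """Count, per spot, the molecules whose 3' site falls in each cluster.

    Reads assigned to no cluster are dropped and tallied; the matrix grand
    total plus the returned discard tally equals the number of input reads.
    Clusters must be disjoint within each (chrom, strand).
    """
    by_cs: dict[tuple[str, str], list[TagCluster]] = {}
    for tc in clusters:
        by_cs.setdefault((tc.chrom, tc.strand), []).append(tc)
    starts_by_cs, ends_by_cs, ids_by_cs = {}, {}, {}
    for key, tcs in by_cs.items():
        tcs.sort(key=lambda t: t.start)
        starts = np.array([t.start for t in tcs])
        ends = np.array([t.end for t in tcs])
        if np.any(ends[:-1] > starts[1:]):
            raise ValueError(f"overlapping clusters on {key[0]} strand {key[1]}")
        starts_by_cs[key] = starts
        ends_by_cs[key] = ends
        ids_by_cs[key] = np.array([t.id for t in tcs], dtype=object)

    pos = _three_prime(reads)
    assigned = np.full(len(reads), None, dtype=object)
    grouped = pd.DataFrame(
        {"chrom": reads["chrom"].to_numpy(), "strand": reads["strand"].to_numpy()}
    ).groupby(["chrom", "strand"], sort=False)
    for key, grp in grouped:
        arrs = starts_by_cs.get(key)
        if arrs is None:
            continue
        idx = grp.index.to_numpy()
        p = pos[idx]
        slot = np.searchsorted(arrs, p, side="right") - 1
        ok = (slot >= 0) & (p < ends_by_cs[key][np.clip(slot, 0, None)])
        assigned[idx[ok]] = ids_by_cs[key][slot[ok]]

    in_cluster = assigned != None  # noqa: E711 — elementwise on object array
    n_discarded = int((~in_cluster).sum())
    hit = pd.DataFrame(
        {
            "dataset": reads["dataset"].to_numpy()[in_cluster],
            "x": reads["x"].to_numpy()[in_cluster],
            "y": reads["y"].to_numpy()[in_cluster],
            "tc": assigned[in_cluster],
        }
    )
    counts = (
        hit.groupby(["dataset", "x", "y", "tc"], sort=True).size().rename("n")
    )
    wide = counts.unstack("tc", fill_value=0)
    all_ids = [tc.id for tc in sorted(clusters, key=lambda t: (t.chrom, t.start,
                                                               t.end, t.strand))]
    wide = wide.reindex(columns=all_ids, fill_value=0)
    return SpotMatrix(wide, RAW), n_discarded
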