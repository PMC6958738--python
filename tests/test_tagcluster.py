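"""Site aggregation, parametric density clustering, gene association and
matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stsig import tagcluster as tcm
from stsig.types import GeneModel, TagCluster
from .oracles import density_sweep_segments


def _reads(rows):
    """rows: (chrom, start, end, strand, tag, x, y)"""
    return pd.DataFrame(
        [dict(chrom=c, start=s, end=e, name=f"m{i}", score=0, strand=st_,
              gene_tag=t, x=x, y=y, dataset="d1")
         for i, (c, s, e, st_, t, x, y) in enumerate(rows)]
    )


MALAT1 = GeneModel("MALAT1", "MALAT1", "chr1", "+", 1000, 2000)


class TestRemoveGeneReads:
    def test_reads_inside_span_removed(self):
        rows = [("chr1", 1500, 1548, "+", "", 1, 1)] * 4 + \
               [("chr1", 3000, 3048, "+", "", 1, 1)] * 6
        out = tcm.remove_gene_reads(_reads(rows), [MALAT1], "MALAT1")
        assert len(out) == 6
        assert (out["start"] == 3000).all()

    def test_same_position_other_strand_kept(self):
        rows = [("chr1", 1500, 1548, "-", "", 1, 1)]
        out = tcm.remove_gene_reads(_reads(rows), [MALAT1], "MALAT1")
        assert len(out) == 1

    def test_absent_gene_is_noop(self, caplog):
        reads = _reads([("chr1", 10, 58, "+", "", 1, 1)])
        with caplog.at_level("WARNING"):
            out = tcm.remove_gene_reads(reads, [], "MALAT1")
        assert len(out) == 1
        assert "nothing removed" in caplog.text

    def test_tagged_reads_removed_even_outside_models(self):
        rows = [("chr2", 10, 58, "+", "MALAT1", 1, 1),
                ("chr2", 10, 58, "+", "G1", 1, 1)]
        out = tcm.remove_gene_reads(_reads(rows), [MALAT1], "MALAT1")
        assert list(out["gene_tag"]) == ["G1"]


class TestReadsToSites:
    def test_three_prime_conventions(self):
        sites = tcm.reads_to_sites(_reads([("chr1", 100, 148, "+", "", 1, 1)]))
        assert sites.iloc[0]["position"] == 147
        sites = tcm.reads_to_sites(_reads([("chr1", 100, 148, "-", "", 1, 1)]))
        assert sites.iloc[0]["position"] == 100

    def test_aggregation(self):
        sites = tcm.reads_to_sites(
            _reads([("chr1", 100 + i, 148, "+", "", 1, 1) for i in range(5)]))
        assert len(sites) == 1
        assert sites.iloc[0]["count"] == 5

    def test_count_conservation(self, small_scene):
        reads = small_scene.reads["dataset_1"]
        sites = tcm.reads_to_sites(reads)
        assert sites["count"].sum() == len(reads)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tcm.reads_to_sites(_reads([]))


class TestParacluDecompose:
    def test_single_site_leaf(self):
        root = tcm.paraclu_decompose([500], [7])
        assert root.min_density == 0.0
        assert root.max_density == np.inf
        assert root.children == []
        assert (root.start, root.end) == (500, 501)

    def test_two_equal_sites_hand_example(self):
        # prefix density at the only break: 4 / (20 - 10) = 0.4 = suffix
        root = tcm.paraclu_decompose([10, 20], [4, 4])
        assert root.max_density == pytest.approx(0.4)
        assert (root.start, root.end) == (10, 21)
        left, right = root.children
        for child in (left, right):
            assert child.min_density == pytest.approx(0.4)
            assert child.max_density == np.inf
            assert child.n_sites == 1

    def test_matches_density_sweep_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 26))
            pos = np.sort(rng.choice(np.arange(0, 250), size=n, replace=False))
            cnt = rng.integers(1, 15, size=n)
            root = tcm.paraclu_decompose(pos, cnt)
            mine = {(nd.start, nd.end) for nd in root.walk()
                    if nd.max_density > nd.min_density}
            assert mine == density_sweep_segments(pos, cnt)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 20)),
                    min_size=1, max_size=30, unique_by=lambda t: t[0]))
    def test_tree_invariants(self, site_list):
        site_list.sort()
        pos = np.array([p for p, _c in site_list])
        cnt = np.array([c for _p, c in site_list])
        root = tcm.paraclu_decompose(pos, cnt)
        total = 0
        for node in root.walk():
            if not node.children:
                total += node.total_count
            for child in node.children:
                # children take over above the parent's effective floor
                assert child.min_density == pytest.approx(
                    max(node.min_density, node.max_density))
                assert child.start >= node.start and child.end <= node.end
            if node.reportable and node is not root:
                assert node.max_density >= node.min_density
        assert total == cnt.sum()
        # laminarity of the full node set
        spans = [(n.start, n.end) for n in root.walk()]
        for a in spans:
            for b in spans:
                nested = (a[0] >= b[0] and a[1] <= b[1]) or \
                         (b[0] >= a[0] and b[1] <= a[1])
                disjoint = a[1] <= b[0] or b[1] <= a[0]
                assert nested or disjoint

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tcm.paraclu_decompose([], [])


class TestFilterClusters:
    def test_two_site_example_outermost_only(self):
        pos, cnt = np.array([10, 20]), np.array([4, 4])
        root = tcm.paraclu_decompose(pos, cnt, chrom="chr1", strand="+")
        out = tcm.filter_clusters(root, min_fold=2, max_span=1000, min_count=1,
                                  positions=pos, counts=cnt)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (10, 21)
        assert out[0].summit == 10      # leftmost of the tied sites

    def test_min_count_threshold(self):
        root = tcm.paraclu_decompose([10, 20], [4, 5])
        assert tcm.filter_clusters(root, min_fold=1, max_span=1000,
                                   min_count=10) == []

    def test_unrestricted_emission_covers_sites_once(self, rng):
        pos = np.sort(rng.choice(np.arange(0, 3000), size=30, replace=False))
        cnt = rng.integers(1, 15, size=30)
        root = tcm.paraclu_decompose(pos, cnt)
        out = tcm.filter_clusters(root, min_fold=1, max_span=np.inf, min_count=1)
        covered = sorted(p for tc in out for p in pos
                         if tc.start <= p < tc.end)
        assert covered == sorted(pos)
        assert sum(tc.total_count for tc in out) == cnt.sum()

    def test_keep_nested_emits_descendants(self):
        pos, cnt = np.array([10, 20]), np.array([4, 4])
        root = tcm.paraclu_decompose(pos, cnt)
        nested = tcm.filter_clusters(root, min_fold=1, max_span=1000,
                                     min_count=1, keep_nested=True,
                                     positions=pos, counts=cnt)
        assert len(nested) == 3


GENES = [
    GeneModel("G1", "GENE1", "chr1", "+", 1000, 2000),
    GeneModel("G2", "GENE2", "chr1", "+", 1800, 2600),
    GeneModel("G3", "GENE3", "chr1", "-", 5000, 6000),
]


def _cluster(summit, strand="+", chrom="chr1"):
    return TagCluster(chrom, strand, summit - 5, summit + 5, 3, 30, 0.0, 9.0,
                      summit=summit)


class TestAssociateGene:
    def test_summit_inside_single_gene(self):
        index = tcm.GeneIndex(GENES, downstream_slack=500)
        assert tcm.associate_gene(_cluster(1500), index) == ("G1", "GENE1")

    def test_downstream_slack(self):
        index = tcm.GeneIndex(GENES, downstream_slack=500)
        # 300 bp past GENE2's 3' end
        assert tcm.associate_gene(_cluster(2899), index)[0] == "G2"
        # on the minus strand, downstream extends leftward
        assert tcm.associate_gene(_cluster(4700, strand="-"), index)[0] == "G3"

    def test_intergenic_desert_unassociated(self):
        index = tcm.GeneIndex(GENES, downstream_slack=500)
        assert tcm.associate_gene(_cluster(9000), index) == ("", "")

    def test_nearest_tts_wins_in_overlap(self):
        index = tcm.GeneIndex(GENES, downstream_slack=500)
        # position 1950 sits in G1 and G2; G1's 3' end (1999) is nearer
        # than G2's (2599)
        assert tcm.associate_gene(_cluster(1950), index)[0] == "G1"


class TestBuildMatrix:
    def test_single_read_single_cluster(self):
        reads = _reads([("chr1", 100, 148, "+", "", 1, 1)])
        tc = TagCluster("chr1", "+", 140, 150, 2, 1, 0.0, 1.0)
        matrix, discarded = tcm.build_matrix(reads, [tc])
        assert matrix.values.tolist() == [[1]]
        assert discarded == 0

    def test_two_spots_two_clusters(self):
        rows = [("chr1", 100, 148, "+", "", 1, 1)] * 3 + \
               [("chr1", 500, 548, "+", "", 2, 2)] * 5
        tcs = [TagCluster("chr1", "+", 140, 150, 1, 3, 0.0, 1.0),
               TagCluster("chr1", "+", 540, 550, 1, 5, 0.0, 1.0)]
        matrix, _ = tcm.build_matrix(_reads(rows), tcs)
        assert matrix.values.tolist() == [[3, 0], [0, 5]]

    def test_overlapping_clusters_raise(self):
        tcs = [TagCluster("chr1", "+", 100, 150, 1, 3, 0.0, 1.0),
               TagCluster("chr1", "+", 140, 190, 1, 5, 0.0, 1.0)]
        with pytest.raises(ValueError, match="overlapping"):
            tcm.build_matrix(_reads([("chr1", 100, 148, "+", "", 1, 1)]), tcs)

    def test_column_sums_match_independent_tally(self, small_scene):
        reads = small_scene.reads["dataset_2"]
        sites = tcm.reads_to_sites(reads)
        clusters = tcm.call_clusters(sites)
        matrix, discarded = tcm.build_matrix(reads, clusters)
        assert matrix.total() + discarded == len(reads)
        # independent per-cluster tally over 3'-end positions
        pos = np.where(reads["strand"] == "+", reads["end"] - 1, reads["start"])
        for tc in clusters[:25]:
            expected = int(np.sum((reads["chrom"] == tc.chrom)
                                  & (reads["strand"] == tc.strand)
                                  & (pos >= tc.start) & (pos < tc.end)))
            assert matrix.df[tc.id].sum() == expected

    def test_deterministic_outputs(self, small_scene, tmp_path):
        from stsig import io as stio
        reads = small_scene.reads["dataset_1"]
        blobs = []
        for run in range(2):
            sites = tcm.reads_to_sites(reads)
            clusters = tcm.call_clusters(sites)
            matrix, _ = tcm.build_matrix(reads, clusters)
            stio.write_clusters_bed(clusters, tmp_path / f"tc{run}.bed")
            stio.write_matrix(matrix, tmp_path / f"m{run}.tsv")
            blobs.append(((tmp_path / f"tc{run}.bed").read_bytes(),
                          (tmp_path / f"m{run}.tsv").read_bytes()))
        assert blobs[0] == blobs[1]
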