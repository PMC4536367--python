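"""CLIP read collapsing, cluster calling, annotation, site prediction."""

import numpy as np
import pandas as pd
import pytest

from mirmeta.clip import (
    AlignedRead,
    Cluster,
    annotate_clusters,
    call_clusters,
    cluster_summit,
    collapse_duplicates,
    positional_seed_profile,
    predict_target_sites,
    top_expressed_mirnas,
)
from mirmeta.genes import GeneModel
from mirmeta.seedscan import revcomp


def read(start, end, chrom="c", strand="+", lib="l1"):
    return AlignedRead(chrom=chrom, start=start, end=end, strand=strand, library=lib)


def brute_force_components(reads, min_overlap=1):
    """Connected components of the pairwise interval-overlap graph."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if (a.chrom, a.strand) != (b.chrom, b.strand):
                continue
            if min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(reads[i])
    return list(comps.values())


class TestReadsAndCollapse:
    def test_min_length_enforced(self):
        with pytest.raises(ValueError):
            read(100, 124)  # 24 nt < minimum alignment length

    def test_identical_reads_collapse(self):
        reads = [read(100, 130)] * 5
        assert len(collapse_duplicates(reads)) == 1

    def test_distinct_starts_kept(self):
        reads = [read(100, 130), read(101, 130)]
        assert len(collapse_duplicates(reads)) == 2

    def test_pooled_libraries_collapse(self):
        reads = [read(100, 130, lib="l1"), read(100, 130, lib="l2")]
        assert len(collapse_duplicates(reads)) == 1


class TestCallClusters:
    def test_one_nt_overlap_merges(self):
        clusters = call_clusters([read(100, 130), read(129, 160)])
        assert len(clusters) == 1
        cl = clusters[0]
        assert (cl.start, cl.end, cl.n_reads) == (100, 160, 2)

    def test_abutting_reads_do_not_cluster(self):
        assert call_clusters([read(100, 130), read(130, 160)]) == []

    def test_single_read_no_cluster(self):
        assert call_clusters([read(100, 130)]) == []

    def test_min_overlap_parameter(self):
        pair = [read(100, 130), read(125, 155)]  # 5 nt overlap
        assert len(call_clusters(pair, min_overlap=5)) == 1
        assert call_clusters(pair, min_overlap=6) == []

    def test_strand_specific(self):
        assert call_clusters([read(100, 130, strand="+"), read(100, 130, strand="-")]) == []

    def test_matches_connected_components_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            reads = collapse_duplicates(
                read(int(s), int(s) + int(rng.integers(25, 60)),
                     strand="+-"[int(rng.integers(2))])
                for s in rng.integers(0, 400, size=n)
            )
            got = {
                (c.chrom, c.strand, c.start, c.end, c.n_reads)
                for c in call_clusters(reads)
            }
            want = set()
            for comp in brute_force_components(reads):
                if len(comp) >= 2:
                    want.add((comp[0].chrom, comp[0].strand,
                              min(r.start for r in comp), max(r.end for r in comp),
                              len(comp)))
            assert got == want


class TestSummit:
    def test_identical_spans_leftmost(self):
        reads = [read(100, 130, lib="a"), read(100, 130, lib="b")]
        assert cluster_summit((100, 130), reads) == 100

    def test_coverage_step(self):
        reads = [read(100, 130), read(110, 140)]
        assert cluster_summit((100, 140), reads) == 110

    def test_symmetric_stack_leftmost_of_plateau(self):
        reads = [read(100, 135), read(105, 140), read(110, 145)]
        # coverage is 3 on [110, 135); leftmost tie wins
        assert cluster_summit((100, 145), reads) == 110


class TestAnnotate:
    def models(self):
        plus = GeneModel(gene_id="gplus", chrom="c", start=1000, end=2200, strand="+",
                         cds_start=1200, cds_end=1900)
        minus = GeneModel(gene_id="gminus", chrom="c", start=20000, end=21500,
                          strand="-", cds_start=20400, cds_end=21300)
        nc = GeneModel(gene_id="nc1", chrom="c", start=40000, end=40400, strand="+",
                       cds_start=40000, cds_end=40000)
        spliced = GeneModel(gene_id="gsplice", chrom="c", start=60000, end=61000,
                            strand="+", cds_start=60100, cds_end=60900,
                            blocks=[(60000, 60300), (60700, 61000)])
        return [plus, minus, nc, spliced]

    def cluster(self, start, end, strand="+"):
        return Cluster(chrom="c", strand=strand, start=start, end=end, n_reads=2,
                       summit=start)

    def test_hierarchy_prefers_utr3(self):
        cl = self.cluster(1850, 1950)  # straddles CDS and 3'UTR
        annotate_clusters([cl], self.models())
        assert cl.annotation == "3'UTR" and cl.gene == "gplus"

    def test_extension_downstream(self):
        cl = self.cluster(5100, 5200)  # ~3 kb past the 3'UTR end
        annotate_clusters([cl], self.models())
        assert cl.annotation == "3'UTR" and cl.gene == "gplus"
        annotate_clusters([cl], self.models(), utr3_extension=1000)
        assert cl.annotation == "intergenic"

    def test_minus_strand_utr3_is_left_of_cds(self):
        cl = self.cluster(20100, 20200, strand="-")
        annotate_clusters([cl], self.models())
        assert cl.annotation == "3'UTR" and cl.gene == "gminus"

    def test_categories(self):
        cases = {
            (1050, 1100, "+"): "5'UTR",
            (1300, 1400, "+"): "CDS",
            (40100, 40200, "+"): "ncRNA",
            (60400, 60500, "+"): "intron",
            (90000, 90100, "+"): "intergenic",
        }
        for (s, e, strand), want in cases.items():
            cl = self.cluster(s, e, strand)
            annotate_clusters([cl], self.models())
            assert cl.annotation == want, (s, e, want, cl.annotation)

    def test_hierarchy_order_is_load_bearing(self):
        cl = self.cluster(1850, 1950)
        annotate_clusters([cl], self.models(),
                          hierarchy=("CDS", "3'UTR", "5'UTR", "ncRNA", "intron",
                                     "intergenic"))
        assert cl.annotation == "CDS"

    def test_strand_mismatch_ignored(self):
        cl = self.cluster(1850, 1950, strand="-")
        annotate_clusters([cl], self.models())
        assert cl.annotation == "intergenic"


class TestTopExpressed:
    def test_shares_example(self):
        s = pd.Series({"A": 0.5, "B": 0.3, "C": 0.15, "D": 0.05})
        assert top_expressed_mirnas(s) == ["A", "B", "C"]

    def test_single(self):
        assert top_expressed_mirnas(pd.Series({"only": 42.0})) == ["only"]

    def test_equal_shares_boundary(self):
        s = pd.Series({f"m{i}": 10.0 for i in range(10)})
        assert len(top_expressed_mirnas(s, 0.9)) == 9

    def test_all_zero(self):
        with pytest.raises(ValueError):
            top_expressed_mirnas(pd.Series({"a": 0.0}))

    def test_monotone_in_fraction(self, rng):
        s = pd.Series(rng.random(20), index=[f"m{i}" for i in range(20)])
        prev = set()
        for frac in (0.3, 0.5, 0.7, 0.9, 1.0):
            cur = set(top_expressed_mirnas(s, frac))
            assert prev <= cur
            prev = cur


class TestPredictSites:
    def setup_scene(self, mir203, motif_at=30, strand="+", annotation="3'UTR",
                    motif="ATTTCA"):
        seq = list("G" * 100)
        seq[motif_at : motif_at + len(motif)] = motif
        fwd = "".join(seq)
        genome = {"c": fwd if strand == "+" else revcomp(fwd)}
        cl = Cluster(chrom="c", strand=strand, start=0, end=100, n_reads=3, summit=10,
                     annotation=annotation, gene="gX")
        return cl, genome

    def test_6mer_site_found(self, mir203):
        cl, genome = self.setup_scene(mir203)
        sites = predict_target_sites([cl], [mir203], genome)
        assert len(sites) == 1
        row = sites.iloc[0]
        assert (row["mirna"], row["gene"], row["offset"], row["k_best"]) == (
            mir203.name, "gX", 30, 6)

    def test_minus_strand_site_found(self, mir203):
        cl, genome = self.setup_scene(mir203, strand="-")
        sites = predict_target_sites([cl], [mir203], genome)
        assert len(sites) == 1 and sites.iloc[0]["offset"] == 30

    def test_cds_cluster_skipped(self, mir203):
        cl, genome = self.setup_scene(mir203, annotation="CDS")
        assert predict_target_sites([cl], [mir203], genome).empty

    def test_two_occurrences_two_sites_one_gene(self, mir203):
        seq = list("G" * 100)
        seq[10:16] = "ATTTCA"
        seq[50:56] = "ATTTCA"
        genome = {"c": "".join(seq)}
        cl = Cluster(chrom="c", strand="+", start=0, end=100, n_reads=2, summit=5,
                     annotation="3'UTR", gene="gX")
        sites = predict_target_sites([cl], [mir203], genome)
        assert len(sites) == 2
        assert sites["gene"].nunique() == 1

    def test_k_best_upgrade(self, mir203):
        for motif, k in (("ACATTTCA", 8), ("TCATTTCA", 7), ("TTATTTCA", 6)):
            cl, genome = self.setup_scene(mir203, motif=motif)
            sites = predict_target_sites([cl], [mir203], genome)
            assert sites.iloc[0]["k_best"] == k, motif


class TestPositionalProfile:
    def make_cluster(self, seq_parts, genome_parts, summit, start):
        genome_parts.append("".join(seq_parts))
        return Cluster(chrom="c", strand="+", start=start,
                       end=start + len(seq_parts), n_reads=2, summit=summit,
                       annotation="3'UTR", gene="g")

    def test_motif_at_summit_all_mass_in_bin0(self, rng):
        bases = np.array(list("ACGT"))
        genome_parts = []
        clusters = []
        pos = 0
        for _ in range(30):
            seq = list("".join(bases[rng.integers(0, 4, 60)]).replace("ATTTCA", "GGGGGG"))
            seq[27:33] = "ATTTCA"  # motif start == summit offset
            clusters.append(self.make_cluster(seq, genome_parts, pos + 27, pos))
            pos += 60
        genome = {"c": "".join(genome_parts)}
        prof = positional_seed_profile(clusters, "ATTTCA", genome, [], 2,
                                       np.random.default_rng(0))
        mid = len(prof["observed"]) // 2
        assert prof["observed"][mid] == prof["observed"].sum() > 0

    def test_no_occurrences_flat_zero(self):
        genome = {"c": "G" * 200}
        cl = Cluster(chrom="c", strand="+", start=0, end=100, n_reads=2, summit=50,
                     annotation="3'UTR", gene="g")
        prof = positional_seed_profile([cl], "ATTTCA", genome, [], 1,
                                       np.random.default_rng(0))
        assert prof["observed"].sum() == 0

    def test_requires_shuffles(self):
        with pytest.raises(ValueError):
            positional_seed_profile([], "ATTTCA", {"c": ""}, [], 0,
                                    np.random.default_rng(0))
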