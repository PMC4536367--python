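"""Ago2 HITS-CLIP analysis: clusters, annotation, and seed-site prediction.

CLIP reads mark transcriptome positions bound by the miRNA-induced silencing
complex.  After PCR-duplicate collapsing, clusters are defined as >= 2 read
alignments overlapping by >= 1 nt (strand-specific, half-open intervals, so
abutting reads do not overlap).  Clusters are annotated hierarchically
(3'UTR with a 5 kbp downstream extension, then CDS, 5'UTR, ncRNA, intron,
intergenic), and 3'UTR cluster sequences are scanned for 6mer seed matches of
the miRNAs that account for 90% of the small-RNA pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .seedscan import MatureMiRNA, revcomp, scan_sites, seed_site_motif

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 25

ANNOTATION_HIERARCHY = ("3'UTR", "CDS", "5'UTR", "ncRNA", "intron", "intergenic")


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    start: int
    end: int
    strand: str
    library: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("negative read start")
        if self.end - self.start < MIN_READ_LENGTH:
            raise ValueError(
                f"read {self.chrom}:{self.start}-{self.end} shorter than "
                f"{MIN_READ_LENGTH} nt minimum alignment length"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class Cluster:
    chrom: str
    strand: str
    start: int
    end: int
    n_reads: int
    summit: int
    annotation: str | None = None
    gene: str | None = None
    seed_sites: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_reads < 2:
            raise ValueError("cluster needs >= 2 reads")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside cluster")


def collapse_duplicates(reads) -> list[AlignedRead]:
    """Collapse reads identical in (chrom, strand, start, end) to one.

    Libraries are pooled first, so identical alignments from different
    libraries also collapse; output is coordinate-sorted (order-independent).
    """
    unique = {}
    for r in reads:
        unique.setdefault((r.chrom, r.strand, r.start, r.end), r)
    return [
        AlignedRead(chrom=c, start=s, end=e, strand=st, library="pooled")
        for (c, st, s, e) in sorted(unique)
    ]


def cluster_summit(span: tuple[int, int], reads) -> int:
    """Position of maximal read coverage within ``span``; leftmost on ties."""
    start, end = span
    cov = np.zeros(end - start, dtype=int)
    for r in reads:
        lo, hi = max(r.start, start), min(r.end, end)
        if lo < hi:
            cov[lo - start : hi - start] += 1
    return start + int(np.argmax(cov))


def call_clusters(reads, min_reads: int = 2, min_overlap: int = 1) -> list[Cluster]:
    """Strand-specific read clusters with pairwise overlap >= min_overlap nt.

    Reads are grouped into connected components of the interval-overlap graph
    (intersection length >= min_overlap); components with >= min_reads reads
    become clusters spanning min start to max end, with a coverage summit.
    A sorted sweep tracking the running max end is exact here because the best
    overlap a new read can achieve within a component is against the read with
    the largest end.
    """
    clusters: list[Cluster] = []
    by_key: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.strand), []).append(r)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.start, r.end))
        component: list[AlignedRead] = []
        max_end = None
        for r in group:
            if component and min(max_end, r.end) - r.start >= min_overlap:
                component.append(r)
                max_end = max(max_end, r.end)
            else:
                _emit(clusters, chrom, strand, component, min_reads)
                component, max_end = [r], r.end
        _emit(clusters, chrom, strand, component, min_reads)
    return clusters


def _emit(clusters, chrom, strand, component, min_reads):
    if len(component) >= min_reads:
        span = (min(r.start for r in component), max(r.end for r in component))
        clusters.append(
            Cluster(
                chrom=chrom, strand=strand, start=span[0], end=span[1],
                n_reads=len(component), summit=cluster_summit(span, component),
            )
        )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _overlap(a0, a1, b0, b1) -> int:
    return min(a1, b1) - max(a0, b0)


def annotate_clusters(
    clusters, models, utr3_extension: int = 5000,
    hierarchy: tuple = ANNOTATION_HIERARCHY,
) -> list[Cluster]:
    """Assign each cluster the first matching category of the hierarchy.

    Overlap means >= 1 shared nt on the same strand.  For the 3'UTR category a
    direct 3'UTR overlap is preferred over one only via the downstream
    extension; within a category, the gene with the largest overlap wins (ties
    by gene id).  Returns the same cluster objects, annotated in place.
    """
    feats: dict[str, dict[tuple, list[tuple[int, int, str]]]] = {c: {} for c in hierarchy}

    def add(cat, m, iv, exonic=True):
        if iv is None or iv[0] >= iv[1] or cat not in feats:
            return
        pieces = (
            [(max(iv[0], bs), min(iv[1], be)) for bs, be in m.blocks] if exonic else [iv]
        )
        for s, e in pieces:
            if s < e:
                feats[cat].setdefault((m.chrom, m.strand), []).append((s, e, m.gene_id))

    for m in models:
        if m.coding:
            add("3'UTR", m, m.utr3())
            add("CDS", m, m.cds())
            add("5'UTR", m, m.utr5())
        else:
            add("ncRNA", m, (m.start, m.end))
        # introns: transcript span minus exon blocks
        prev = m.start
        for bs, be in m.blocks:
            add("intron", m, (prev, bs), exonic=False)
            prev = be
    # extended 3'UTRs kept separately so direct overlap is preferred
    extended: dict[tuple, list[tuple[int, int, str]]] = {}
    if utr3_extension > 0:
        for m in models:
            iv = m.utr3()
            if iv is None:
                continue
            if m.strand == "+":
                ext = (iv[1], iv[1] + utr3_extension)
            else:
                ext = (max(iv[0] - utr3_extension, 0), iv[0])
            extended.setdefault((m.chrom, m.strand), []).append((ext[0], ext[1], m.gene_id))

    def best_hit(table, cluster):
        hits = []
        for s, e, gid in table.get((cluster.chrom, cluster.strand), []):
            ov = _overlap(cluster.start, cluster.end, s, e)
            if ov >= 1:
                hits.append((-ov, gid))
        if not hits:
            return None
        hits.sort()
        return hits[0][1]

    for cl in clusters:
        cl.annotation, cl.gene = "intergenic", None
        for cat in hierarchy:
            if cat == "intergenic":
                continue
            gid = best_hit(feats[cat], cl)
            if gid is None and cat == "3'UTR":
                gid = best_hit(extended, cl)
            if gid is not None:
                cl.annotation, cl.gene = cat, gid
                break
    return clusters


# ---------------------------------------------------------------------------
# target-site prediction
# ---------------------------------------------------------------------------

def top_expressed_mirnas(mirna_rpm: pd.Series, cumulative_fraction: float = 0.90) -> list[str]:
    """Smallest descending-abundance prefix whose cumulative share reaches
    ``cumulative_fraction`` (boundary inclusive); ties ordered by name."""
    total = float(mirna_rpm.sum())
    if total <= 0:
        raise ValueError("all-zero miRNA abundances")
    ordered = mirna_rpm.sort_index().sort_values(ascending=False, kind="stable")
    cum = ordered.cumsum() / total
    # tiny tolerance so exact boundary shares (e.g. 10 x 10%) stay inclusive
    k = int(np.searchsorted(cum.to_numpy(), cumulative_fraction - 1e-12, side="left")) + 1
    return list(ordered.index[:k])


def cluster_sequence(cluster: Cluster, genome) -> str:
    """Genomic sequence of the cluster span, strand-corrected."""
    seq = genome[cluster.chrom][cluster.start : cluster.end]
    return seq if cluster.strand == "+" else revcomp(seq)


def predict_target_sites(clusters, mirnas, genome) -> pd.DataFrame:
    """6mer seed-site search in 3'UTR cluster sequences for each miRNA.

    Site existence uses the 6mer motif; each occurrence is additionally
    labelled with the longest motif present at that locus (k_best in
    {6, 7, 8}, an annotation only).  Offsets are in strand-corrected cluster
    coordinates.  Returns a table (mirna, gene, cluster_id, offset, k_best);
    the per-miRNA target gene set is the distinct genes with >= 1 site.
    """
    rows = []
    motifs = {}
    for m in mirnas:
        motifs[m.name] = {k: seed_site_motif(m, k).motif for k in (6, 7, 8)}
    for ci, cl in enumerate(clusters):
        if cl.annotation != "3'UTR":
            continue
        try:
            seq = cluster_sequence(cl, genome)
        except KeyError:
            logger.warning("no sequence for cluster %s:%d-%d; skipped",
                           cl.chrom, cl.start, cl.end)
            continue
        for name, mset in motifs.items():
            for off in scan_sites(seq, mset[6]):
                if off >= 2 and seq[off - 2 : off + 6] == mset[8]:
                    k_best = 8
                elif off >= 1 and seq[off - 1 : off + 6] == mset[7]:
                    k_best = 7
                else:
                    k_best = 6
                rows.append((name, cl.gene, ci, off, k_best))
    return pd.DataFrame(rows, columns=["mirna", "gene", "cluster_id", "offset", "k_best"])


# ---------------------------------------------------------------------------
# positional seed enrichment around summits
# ---------------------------------------------------------------------------

def _summit_in_seq(cl: Cluster) -> int:
    return cl.summit - cl.start if cl.strand == "+" else cl.end - 1 - cl.summit


def _bin_offsets(offsets, bin_width, half_span):
    n_bins = 2 * (half_span // bin_width) + 1
    hist = np.zeros(n_bins, dtype=float)
    mid = n_bins // 2
    for off in offsets:
        b = mid + int(np.floor((off + bin_width / 2) / bin_width))
        if 0 <= b < n_bins:
            hist[b] += 1
    return hist


def positional_seed_profile(
    clusters, motif, genome, utr_sequences, n_shuffles: int, rng,
    bin_width: int = 5, half_span: int = 50,
):
    """Histogram of motif offsets relative to cluster summits, with two nulls.

    Offsets are motif start minus summit, in transcript orientation, binned in
    ``bin_width``-nt bins over +/- ``half_span`` nt (bin 0 centred on the
    summit).  Backgrounds: (a) dinucleotide-shuffled cluster sequences scanned
    at the same summit positions (``n_shuffles`` rounds) and (b) length-matched
    windows drawn uniformly from the supplied 3'UTR sequences.  Per-bin
    enrichment is the observed frequency over the mean shuffled-background
    frequency (Laplace-smoothed so empty background bins stay finite).
    """
    from .seedscan import dinucleotide_shuffle, to_dna

    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pattern = motif.motif if hasattr(motif, "motif") else to_dna(motif)
    utr3_clusters = [c for c in clusters if c.annotation == "3'UTR"]
    seqs = [cluster_sequence(c, genome) for c in utr3_clusters]
    summits = [_summit_in_seq(c) for c in utr3_clusters]

    def offsets_for(seq, summit):
        return [h - summit for h in scan_sites(seq, pattern)]

    observed = np.zeros(2 * (half_span // bin_width) + 1)
    for seq, summit in zip(seqs, summits):
        observed += _bin_offsets(offsets_for(seq, summit), bin_width, half_span)

    shuffled = np.zeros_like(observed)
    for _ in range(n_shuffles):
        for seq, summit in zip(seqs, summits):
            if len(seq) >= 2:
                shuf = dinucleotide_shuffle(seq, rng)
                shuffled += _bin_offsets(offsets_for(shuf, summit), bin_width, half_span)
    shuffled_mean = shuffled / n_shuffles

    random_utr = np.zeros_like(observed)
    utr_list = [to_dna(s) for s in utr_sequences if len(s) > 0]
    if utr_list:
        for seq, summit in zip(seqs, summits):
            u = utr_list[rng.integers(len(utr_list))]
            if len(u) >= len(seq):
                w0 = rng.integers(len(u) - len(seq) + 1)
                window = u[w0 : w0 + len(seq)]
            else:
                window = u
            random_utr += _bin_offsets(offsets_for(window, summit), bin_width, half_span)

    def freq(hist):
        return (hist + 1.0) / (hist.sum() + len(hist))

    enrichment = freq(observed) / freq(shuffled_mean)
    centers = (np.arange(len(observed)) - len(observed) // 2) * bin_width
    return {
        "bin_centers": centers,
        "observed": observed,
        "shuffled": shuffled_mean,
        "random_utr": random_utr,
        "enrichment": enrichment,
        "n_clusters": len(utr3_clusters),
    }
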