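"""Quantification arithmetic for the expression assays.

Covers small-RNA miRNA counting (best contiguous match, >=18 nt), abundance
filters (minimum count in a minimum number of libraries), RPM normalisation,
pseudocounted log2 fold changes of mean RPM, 3'-end peak calling with an
internal-priming filter and 3'UTR-summed transcript counts, and translation
efficiency (ribosome-footprint RPM over mRNA RPM) with its KO/WT ratio.

Differential-expression modelling is deliberately absent: the downstream
meta-analysis consumes only the sign and rank of per-gene log2 fold changes,
so a dispersion model would add nothing it uses.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .seedscan import MatureMiRNA, revcomp, to_dna

logger = logging.getLogger(__name__)

UNASSIGNED = "*unassigned*"


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact contiguous match between two short strings."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def count_mirnas(reads, mirna_db, min_match: int = 18) -> tuple[pd.Series, int]:
    """Assign each read to the miRNA with the longest exact contiguous match.

    ``reads`` is an iterable of read sequences or a mapping sequence -> count
    (collapsed representation).  Matches shorter than ``min_match`` nt leave a
    read unassigned; ties on match length go to the lexicographically first
    miRNA name.  Returns (counts per miRNA, number of unassigned reads).
    """
    db = sorted(mirna_db, key=lambda m: m.name)
    if not db:
        raise ValueError("empty miRNA database")
    if isinstance(reads, Mapping):
        items = [(to_dna(s), int(c)) for s, c in reads.items()]
    else:
        collapsed: dict[str, int] = {}
        for s in reads:
            s = to_dna(s)
            collapsed[s] = collapsed.get(s, 0) + 1
        items = list(collapsed.items())
    counts = pd.Series(0, index=[m.name for m in db], dtype=int)
    unassigned = 0
    for seq, c in items:
        best_len, best_name = 0, None
        for m in db:
            # containment short-circuit covers the common exact/truncated case
            if seq in m.sequence or m.sequence in seq:
                match = min(len(seq), len(m.sequence))
            else:
                match = _longest_common_substring(seq, m.sequence)
            if match > best_len:
                best_len, best_name = match, m.name
        if best_len >= min_match:
            counts[best_name] += c
        else:
            unassigned += c
    return counts, unassigned


# ---------------------------------------------------------------------------
# filters and normalisation
# ---------------------------------------------------------------------------

def filter_min_reads(table: pd.DataFrame, min_count: int, min_libs: int) -> pd.DataFrame:
    """Keep features with count >= min_count in at least min_libs libraries."""
    if min_libs > table.shape[1]:
        raise ValueError("min_libs exceeds number of libraries")
    if table.empty:
        return table
    keep = (table >= min_count).sum(axis=1) >= min_libs
    return table.loc[keep]


def rpm(table: pd.DataFrame) -> pd.DataFrame:
    """Reads per million mapped reads, per library; columns each sum to 1e6."""
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total libraries: {bad}")
    return table / totals * 1e6


def log2fc(cond, ref, pseudocount: float = 1.0) -> pd.Series:
    """log2((mean RPM cond + pc) / (mean RPM ref + pc)); replicates averaged."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    mc = cond.mean(axis=1) if isinstance(cond, pd.DataFrame) else cond
    mr = ref.mean(axis=1) if isinstance(ref, pd.DataFrame) else ref
    return np.log2((mc + pseudocount) / (mr + pseudocount))


# ---------------------------------------------------------------------------
# 3'-end (3Seq) peaks
# ---------------------------------------------------------------------------

@dataclass
class PolyAPeak:
    """A cluster of mRNA 3'-end read sites (candidate cleavage/polyA site)."""

    chrom: str
    strand: str
    start: int
    end: int
    site: int                      # modal end position (leftmost on ties)
    read_count: int
    internal_priming: bool = False
    annotation: str | None = None
    gene: str | None = None
    lib_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.start <= self.site < self.end):
            raise ValueError("site outside peak span")
        if self.read_count < 1:
            raise ValueError("peak with no reads")


def call_3p_peaks(end_sites: pd.DataFrame, merge_distance: int = 10) -> list[PolyAPeak]:
    """Merge per-position 3'-end read counts into peaks.

    ``end_sites`` columns: chrom, strand, pos, count and optionally lib.
    Positions on the same chrom/strand closer than ``merge_distance`` are
    merged; the peak site is the modal position (leftmost on ties) and
    read_count is the sum.  Per-library counts are carried in ``lib_counts``
    when a lib column is present.
    """
    peaks: list[PolyAPeak] = []
    if end_sites.empty:
        return peaks
    has_lib = "lib" in end_sites.columns
    pooled = (
        end_sites.groupby(["chrom", "strand", "pos"], sort=True)["count"].sum().reset_index()
    )
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        positions = grp["pos"].to_numpy()
        counts = grp["count"].to_numpy()
        runs = []
        run_start = 0
        for i in range(1, len(positions)):
            if positions[i] - positions[i - 1] >= merge_distance:
                runs.append((run_start, i))
                run_start = i
        runs.append((run_start, len(positions)))
        for lo, hi in runs:
            pos_run, cnt_run = positions[lo:hi], counts[lo:hi]
            site = int(pos_run[int(np.argmax(cnt_run))])  # argmax -> leftmost tie
            peaks.append(
                PolyAPeak(
                    chrom=chrom, strand=strand,
                    start=int(pos_run[0]), end=int(pos_run[-1]) + 1,
                    site=site, read_count=int(cnt_run.sum()),
                )
            )
    if has_lib:
        for peak in peaks:
            sel = end_sites[
                (end_sites["chrom"] == peak.chrom)
                & (end_sites["strand"] == peak.strand)
                & (end_sites["pos"] >= peak.start)
                & (end_sites["pos"] < peak.end)
            ]
            peak.lib_counts = sel.groupby("lib")["count"].sum().to_dict()
    return peaks


def filter_internal_priming(
    peak: PolyAPeak, genome: Mapping[str, str],
    window: int = 10, max_a: int = 7, run_len: int = 6,
) -> bool:
    """True (remove) if the genomic window immediately 3' of the peak site is
    A-rich: >= ``max_a`` A in ``window`` nt, or the first ``run_len`` nt all A.

    Strand-aware; at a contig edge the available (possibly shorter) window is
    evaluated.
    """
    chrom_seq = genome[peak.chrom]
    if peak.strand == "+":
        downstream = chrom_seq[peak.site + 1 : peak.site + 1 + window]
    else:
        downstream = revcomp(chrom_seq[max(peak.site - window, 0) : peak.site])
    downstream = to_dna(downstream)
    if len(downstream) < window:
        logger.warning(
            "peak at %s:%d truncated downstream window (%d nt evaluated)",
            peak.chrom, peak.site, len(downstream),
        )
    if downstream.count("A") >= max_a:
        return True
    run = downstream[:run_len]
    return len(run) == run_len and run == "A" * run_len


def annotate_peaks_to_utr3(peaks, models) -> None:
    """Assign each peak to the gene whose 3'UTR contains its site (in place).

    Peaks whose site falls outside any same-strand 3'UTR get annotation
    'other'.  The cleavage site of a transcript is its 3' terminus, which lies
    inside the 3'UTR interval under half-open coordinates.
    """
    by_key: dict[tuple, list[tuple[int, int, str]]] = {}
    for m in models:
        iv = m.utr3()
        if iv is not None:
            by_key.setdefault((m.chrom, m.strand), []).append((iv[0], iv[1], m.gene_id))
    for key in by_key:
        by_key[key].sort()
    for peak in peaks:
        peak.annotation, peak.gene = "other", None
        for s, e, gid in by_key.get((peak.chrom, peak.strand), []):
            if s <= peak.site < e:
                peak.annotation, peak.gene = "3'UTR", gid
                break


def transcript_counts(peaks, models) -> pd.DataFrame:
    """Sum 3'UTR-localised, internal-priming-clean peak counts per transcript.

    Returns a table with one row per transcript; columns are libraries when
    peaks carry per-library counts, else a single 'count' column.  Transcripts
    with no qualifying peak get zero rows.
    """
    annotate_peaks_to_utr3(peaks, models)
    coding = [m.gene_id for m in models if m.coding]
    libs = sorted({lib for p in peaks for lib in p.lib_counts})
    cols = libs if libs else ["count"]
    table = pd.DataFrame(0, index=pd.Index(coding, name="gene_id"), columns=cols)
    for p in peaks:
        if p.internal_priming or p.annotation != "3'UTR" or p.gene is None:
            continue
        if libs:
            for lib, c in p.lib_counts.items():
                table.loc[p.gene, lib] += int(c)
        else:
            table.loc[p.gene, "count"] += p.read_count
    return table


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def translation_efficiency(
    mrna_rpm: pd.Series, ribo_cds_rpm: pd.Series, mode: str = "ribo_over_mrna"
) -> pd.Series:
    """Per-gene translation efficiency.

    Default ``ribo_over_mrna`` is the conventional footprint-density/mRNA
    ratio; ``mrna_over_ribo`` is the literal inverse.  Genes with a zero
    denominator are skipped with a warning.
    """
    if mode not in ("ribo_over_mrna", "mrna_over_ribo"):
        raise ValueError(f"unknown TE mode {mode!r}")
    common = mrna_rpm.index.intersection(ribo_cds_rpm.index)
    num, den = (ribo_cds_rpm, mrna_rpm) if mode == "ribo_over_mrna" else (mrna_rpm, ribo_cds_rpm)
    num, den = num.reindex(common), den.reindex(common)
    ok = den > 0
    if (~ok).any():
        logger.warning("translation_efficiency: skipping %d genes with zero denominator",
                       int((~ok).sum()))
    return (num[ok] / den[ok]).rename("te")


def delta_te(te_ko: pd.Series, te_wt: pd.Series) -> pd.Series:
    """KO/WT translation-efficiency ratio on the shared gene set."""
    common = te_ko.index.intersection(te_wt.index)
    return (te_ko.reindex(common) / te_wt.reindex(common)).rename("delta_te")
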