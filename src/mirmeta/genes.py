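"""Stranded transcript models (5'UTR / CDS / 3'UTR) on BED12 coordinates.

Coordinates are 0-based half-open and strand-aware throughout, matching BED.
A model with ``cds_start == cds_end`` is noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int
    cds_end: int
    blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not (self.start < self.end):
            raise ValueError(f"{self.gene_id}: empty span")
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript")
        if not self.blocks:
            self.blocks = [(self.start, self.end)]
        prev_end = -1
        for s, e in self.blocks:
            if s >= e or s < self.start or e > self.end or s < prev_end:
                raise ValueError(f"{self.gene_id}: invalid/unsorted blocks")
            prev_end = e

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    def utr3(self) -> tuple[int, int] | None:
        """Genomic interval of the 3'UTR, or None if noncoding/absent."""
        if not self.coding:
            return None
        iv = (self.cds_end, self.end) if self.strand == "+" else (self.start, self.cds_start)
        return iv if iv[0] < iv[1] else None

    def utr5(self) -> tuple[int, int] | None:
        if not self.coding:
            return None
        iv = (self.start, self.cds_start) if self.strand == "+" else (self.cds_end, self.end)
        return iv if iv[0] < iv[1] else None

    def cds(self) -> tuple[int, int] | None:
        return (self.cds_start, self.cds_end) if self.coding else None

    def utr3_end_site(self) -> int:
        """Genomic position of the transcript 3' terminus (cleavage site)."""
        return self.end - 1 if self.strand == "+" else self.start

    # -- BED12 ------------------------------------------------------------
    def to_bed12(self) -> str:
        sizes = ",".join(str(e - s) for s, e in self.blocks)
        starts = ",".join(str(s - self.start) for s, e in self.blocks)
        return "\t".join(
            str(x)
            for x in (
                self.chrom, self.start, self.end, self.gene_id, 0, self.strand,
                self.cds_start, self.cds_end, 0, len(self.blocks), sizes, starts,
            )
        )

    @classmethod
    def from_bed12(cls, line: str) -> "GeneModel":
        f = line.rstrip("\n").split("\t")
        start = int(f[1])
        n = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")[:n]]
        offs = [int(x) for x in f[11].rstrip(",").split(",")[:n]]
        blocks = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        return cls(
            gene_id=f[3], chrom=f[0], start=start, end=int(f[2]), strand=f[5],
            cds_start=int(f[6]), cds_end=int(f[7]), blocks=blocks,
        )
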