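"""miRNA seed-site motifs, 3'UTR scanning, and motif-enrichment machinery.

A miRNA represses an mRNA mainly through perfect Watson-Crick pairing between a
short site in the mRNA 3'UTR and the miRNA 5' "seed" region.  Throughout this
package the k-mer seed site (k in {6, 7, 8}) is defined as the reverse
complement of mature miRNA positions 2..k+1 (1-based).  For mmu-miR-203
(GUGAAAUGUUUAGGACCACUAG) this yields the 8mer site ACAUUUCA (DNA: ACATTTCA),
the reverse complement of positions 2-9.

.. note::
   This positional convention (2..k+1 for every k) differs from the TargetScan
   7mer-A1/8mer-A1 definitions, which anchor an A opposite miRNA position 1.
   Here the three site classes are nested suffix-extensions of one another:
   the 8mer is one base 5' of the 7mer, which is one base 5' of the 6mer, so a
   sequence containing the 8mer necessarily contains the 7mer and the 6mer.

All internal computation is in DNA space; U is mapped to T on input.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "MatureMiRNA",
    "SeedSiteMotif",
    "SEED_CLASSES",
    "revcomp",
    "to_dna",
    "seed_site_motif",
    "scan_sites",
    "classify_seed_class",
    "dinucleotide_shuffle",
    "motif_enrichment",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: seed classes from strongest to weakest site
SEED_CLASSES = ("8mer", "7mer", "6mer", "none")


def to_dna(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence (stored in DNA alphabet)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = to_dna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError(f"miRNA {self.name!r}: sequence shorter than 10 nt")
        if set(seq) - set("ACGT"):
            raise ValueError(f"miRNA {self.name!r}: non-ACGU/T characters in sequence")


@dataclass(frozen=True)
class SeedSiteMotif:
    """The 3'UTR site matched by a miRNA seed: revcomp of positions 2..k+1."""

    mirna: str
    k: int
    motif: str

    def __post_init__(self):
        if len(self.motif) != self.k:
            raise ValueError("motif length must equal k")


def seed_site_motif(mirna: MatureMiRNA, k: int) -> SeedSiteMotif:
    """Site motif for seed length ``k``: reverse complement of miRNA 2..k+1.

    Raises ``ValueError`` for k outside {6, 7, 8} or a too-short miRNA.
    """
    if k not in (6, 7, 8):
        raise ValueError(f"k must be 6, 7 or 8, got {k}")
    if len(mirna.sequence) < k + 1:
        raise ValueError(f"miRNA {mirna.name!r} too short for k={k}")
    # 1-based positions 2..k+1 == python slice [1:k+1]
    return SeedSiteMotif(mirna=mirna.name, k=k, motif=revcomp(mirna.sequence[1 : k + 1]))


def scan_sites(seq: str, motif) -> list[int]:
    """All 0-based start offsets of ``motif`` in ``seq``, overlapping included."""
    pattern = motif.motif if isinstance(motif, SeedSiteMotif) else to_dna(motif)
    seq = to_dna(seq)
    hits = []
    i = seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1)
    return hits


def classify_seed_class(utr_seq: str, mirna: MatureMiRNA) -> str:
    """Strongest site class present anywhere in the UTR (per-gene set logic).

    Returns the longest k in {8, 7, 6} whose motif occurs at least once, or
    ``"none"``.  For genes with multiple UTR isoforms the caller is expected
    to supply the longest UTR.
    """
    seq = to_dna(utr_seq)
    for k, label in ((8, "8mer"), (7, "7mer"), (6, "6mer")):
        if seed_site_motif(mirna, k).motif in seq:
            return label
    return "none"


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul-Erickson Euler-path construction)
# ---------------------------------------------------------------------------

def _reaches_sink(last_edge: dict, sink: str) -> bool:
    """True iff following each vertex's designated last edge reaches ``sink``."""
    for v in last_edge:
        seen = set()
        while v != sink:
            if v in seen or v not in last_edge:
                return False
            seen.add(v)
            v = last_edge[v]
    return True


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 10000) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide count vector.

    Uses the Euler-path construction: the sequence is a walk on the
    letter-transition multigraph; a uniform-ish random Eulerian walk with the
    same start and end vertex is produced by choosing a random last out-edge
    per vertex that forms an arborescence into the final letter, shuffling the
    remaining out-edges, and replaying the walk.  First and last base (and all
    mono- and dinucleotide counts) are invariant.
    """
    seq = to_dna(seq)
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle needs length >= 2")
    out = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        out[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = list(out)
    for _ in range(max_tries):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = out[v][rng.integers(len(out[v]))]
        if not _reaches_sink(last_edge, last):
            continue
        shuffled = {}
        for v, targets in out.items():
            rest = list(targets)
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            shuffled[v] = rest
        chars = [first]
        pos = defaultdict(int)
        v = first
        for _ in range(len(seq) - 1):
            nxt = shuffled[v][pos[v]]
            pos[v] += 1
            chars.append(nxt)
            v = nxt
        return "".join(chars)
    raise RuntimeError("no valid Eulerian arrangement found")  # pragma: no cover


# ---------------------------------------------------------------------------
# exhaustive k-mer enrichment (sequence-containment binomial)
# ---------------------------------------------------------------------------

def motif_enrichment(foreground, background, k: int) -> pd.DataFrame:
    """Rank k-mers by enrichment of sequence containment in fg vs bg.

    For each k-mer observed in the foreground, counts the number of foreground
    and background sequences containing it at least once and computes a
    one-sided Fisher (hypergeometric) tail on the containment 2x2 table:
    P(X >= fg_count) drawing n_fg sequences from the pooled n_fg + n_bg with
    fg_count + bg_count carriers.  A plug-in binomial with the background
    containment frequency as a known null rate is anti-conservative when that
    rate is itself estimated from a finite shuffle background — scanning
    thousands of k-mers then yields spurious Bonferroni-significant motifs on
    null data — so the exchangeability-based tail is used instead.  Sorted
    ascending by p, ties broken by descending fg_count then lexicographic
    motif.
    """
    if k > 10:
        raise ValueError("k must be <= 10")
    foreground = [to_dna(s) for s in foreground]
    background = [to_dna(s) for s in background]
    if not foreground:
        raise ValueError("empty foreground")
    if not background:
        raise ValueError("empty background")

    def containment(seqs):
        counts = defaultdict(int)
        for s in seqs:
            for m in {s[i : i + k] for i in range(len(s) - k + 1)}:
                counts[m] += 1
        return counts

    fg = containment(foreground)
    bg = containment(background)
    n_fg, n_bg = len(foreground), len(background)
    motifs = sorted(fg)
    c = np.array([fg[m] for m in motifs])
    b = np.array([bg.get(m, 0) for m in motifs])
    p = _stats.hypergeom.sf(c - 1, n_fg + n_bg, c + b, n_fg)
    table = pd.DataFrame(
        {"motif": motifs, "fg_count": c, "bg_count": b, "p": p}
    )
    table = table.sort_values(
        ["p", "fg_count", "motif"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table
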