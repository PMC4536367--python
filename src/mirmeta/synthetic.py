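"""Seeded synthetic study generator with known ground truth.

Emulates the data structure of a combined miRNA loss-/gain-of-function study
in mouse epidermis: a focal, highly expressed miRNA (miR-203); an expression
panel of 3 loss-of-function comparisons (total-epidermis microarray, ribosome
profiling, 3'-end mRNA sequencing) and 2 gain-of-function microarrays
(sorted-cell inductions); small-RNA libraries dominated by a few miRNAs; and
Ago2 CLIP read pileups at planted 3'UTR seed sites.  True-target genes carry
a seed site of a configured class (8mer/7mer/6mer) and anti-correlated
expression effects (up in every LOF, down in every GOF comparison); ribosome
footprints track mRNA levels so the planted translation-efficiency change is
exactly 1.

Everything is deterministic under ``SimConfig.rng_seed``: each emitter draws
from its own child generator, so stages can be regenerated independently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clip import AlignedRead
from .genes import GeneModel
from .io import read_fasta
from .meta import ExpressionDataset
from .seedscan import (
    MatureMiRNA,
    classify_seed_class,
    revcomp,
    scan_sites,
    seed_site_motif,
)

_STAGES = {"truth": 1, "sequences": 2, "panel": 3, "clip": 4}

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation or run configuration."""


def focal_mirna_record() -> MatureMiRNA:
    """The bundled mature mmu-miR-203-3p sequence (miRBase fixture)."""
    ref = importlib.resources.files("mirmeta.data") / "mmu_mir203.fa"
    with importlib.resources.as_file(ref) as path:
        seqs = read_fasta(path)
    name, seq = next(iter(seqs.items()))
    return MatureMiRNA(name=name, sequence=seq)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Effect sizes are log2 units; the overexpression (GOF) perturbation moves
    targets more than the knockout does (|gof| > |lof|), and site classes
    scale 8mer > 7mer > 6mer.
    """

    n_genes: int = 6000
    n_true_targets: int = 300
    seed_class_mix: dict = field(
        default_factory=lambda: {"8mer": 0.4, "7mer": 0.4, "6mer": 0.2}
    )
    utr_len_range: tuple = (500, 1500)
    gc_content: float = 0.45
    lof_effect_mean: float = 0.5
    gof_effect_mean: float = 1.0
    class_effect_scalars: dict = field(
        default_factory=lambda: {"8mer": 1.0, "7mer": 0.75, "6mer": 0.5}
    )
    noise_sd: float = 0.25
    n_lof_datasets: int = 3
    n_gof_datasets: int = 2
    clip_reads_per_site: int = 10
    clip_background_rate: float = 0.05   # reads per kb of genome
    library_depth: int = 5_000_000
    smallrna_depth: int = 100_000
    rng_seed: int = 0
    # secondary knobs
    sites_per_target: int = 1
    decoys: str = "ambient"              # or "none": reject chance sites everywhere
    utr5_len: int = 150
    cds_len: int = 900
    intergenic_gap: int = 500
    n_ncrna: int = 100
    ncrna_len: int = 400
    clip_read_length: int = 35
    clip_summit_jitter: int = 2
    n_companion_mirnas: int = 9
    focal_mirna_fraction: float = 0.3
    expression_ln_sd: float = 1.0
    te_ln_sd: float = 0.5

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_true_targets < 0:
            raise ConfigError("negative or zero gene counts")
        if self.n_true_targets > self.n_genes:
            raise ConfigError("n_true_targets exceeds n_genes")
        mix_total = sum(self.seed_class_mix.values())
        if abs(mix_total - 1.0) > 1e-9 or any(v < 0 for v in self.seed_class_mix.values()):
            raise ConfigError("seed_class_mix must be non-negative proportions summing to 1")
        if set(self.seed_class_mix) - {"8mer", "7mer", "6mer"}:
            raise ConfigError("seed_class_mix keys must be 8mer/7mer/6mer")
        if not 0 < self.gc_content < 1:
            raise ConfigError("gc_content must be in (0, 1)")
        if not 0 <= self.lof_effect_mean <= self.gof_effect_mean:
            raise ConfigError("need gof_effect_mean >= lof_effect_mean >= 0")
        if self.noise_sd < 0:
            raise ConfigError("negative noise_sd")
        if self.n_lof_datasets < 1 or self.n_gof_datasets < 1:
            raise ConfigError("need at least one LOF and one GOF dataset")
        lo, hi = self.utr_len_range
        if lo > hi or lo < 60:
            raise ConfigError("utr_len_range too short to host a seed site")
        if self.decoys not in ("ambient", "none"):
            raise ConfigError("decoys must be 'ambient' or 'none'")
        if self.clip_reads_per_site > 0:
            need = self.clip_reads_per_site + self.clip_summit_jitter + 5
            if self.clip_read_length < need:
                raise ConfigError("clip_read_length too short for reads-per-site + jitter")
            if self.clip_summit_jitter > self.clip_reads_per_site - 1:
                raise ConfigError("clip_summit_jitter too large for clip_reads_per_site")

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), _STAGES[stage]])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["utr_len_range"] = list(self.utr_len_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "utr_len_range" in d:
            d["utr_len_range"] = tuple(d["utr_len_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth: per-gene target status, seed class, sites, effects."""

    table: pd.DataFrame  # index gene_id; is_true_target, seed_class, utr_len,
                         # sites (list of UTR offsets), lof_effect, gof_effect

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def true_targets(self) -> set:
        return set(self.table.index[self.table["is_true_target"]])

    def targets_of_class(self, cls: str) -> set:
        sel = self.table["is_true_target"] & (self.table["seed_class"] == cls)
        return set(self.table.index[sel])

    def to_json_dict(self) -> dict:
        return {
            gid: {
                "is_true_target": bool(row.is_true_target),
                "seed_class": row.seed_class,
                "utr_len": int(row.utr_len),
                "sites": [int(x) for x in row.sites],
                "lof_effect": float(row.lof_effect),
                "gof_effect": float(row.gof_effect),
            }
            for gid, row in self.table.iterrows()
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimTruth":
        rows = []
        for gid, r in d.items():
            rows.append(
                (gid, r["is_true_target"], r["seed_class"], r["utr_len"],
                 list(r["sites"]), r["lof_effect"], r["gof_effect"])
            )
        table = pd.DataFrame(
            rows,
            columns=["gene_id", "is_true_target", "seed_class", "utr_len",
                     "sites", "lof_effect", "gof_effect"],
        ).set_index("gene_id")
        return cls(table=table)


def _class_counts(n_targets: int, mix: dict) -> dict:
    """Largest-remainder rounding of the class mix to integer counts."""
    classes = ["8mer", "7mer", "6mer"]
    raw = {c: n_targets * mix.get(c, 0.0) for c in classes}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_targets - sum(counts.values())
    for c in sorted(classes, key=lambda c: (counts[c] - raw[c], c))[:short]:
        counts[c] += 1
    return counts


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw target genes, their seed classes, site offsets and effect sizes."""
    rng = config.stage_rng("truth")
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.utr_len_range
    utr_lens = rng.integers(lo, hi + 1, size=config.n_genes)
    target_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_true_targets, replace=False)
    )
    counts = _class_counts(config.n_true_targets, config.seed_class_mix)
    class_labels = (
        ["8mer"] * counts["8mer"] + ["7mer"] * counts["7mer"] + ["6mer"] * counts["6mer"]
    )
    rng.shuffle(class_labels)

    seed_class = ["none"] * config.n_genes
    sites: list = [[] for _ in range(config.n_genes)]
    lof = np.zeros(config.n_genes)
    gof = np.zeros(config.n_genes)
    for idx, cls in zip(target_idx, class_labels):
        seed_class[idx] = cls
        k = int(cls[0])
        # keep sites clear of UTR edges so CLIP reads stay inside the 3'UTR
        span_lo, span_hi = 20, int(utr_lens[idx]) - 40
        offsets = []
        while len(offsets) < config.sites_per_target:
            o = int(rng.integers(span_lo, span_hi))
            if all(abs(o - p) >= k + 2 for p in offsets):
                offsets.append(o)
        sites[idx] = sorted(offsets)
        scalar = config.class_effect_scalars[cls]
        lof[idx] = config.lof_effect_mean * scalar
        gof[idx] = config.gof_effect_mean * scalar

    table = pd.DataFrame(
        {
            "is_true_target": [bool(s != "none") for s in seed_class],
            "seed_class": seed_class,
            "utr_len": utr_lens,
            "sites": sites,
            "lof_effect": lof,
            "gof_effect": gof,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimTruth(table=table)


# ---------------------------------------------------------------------------
# sequences and gene models
# ---------------------------------------------------------------------------

@dataclass
class SimSequences:
    utr3: dict            # gene_id -> 3'UTR sequence (transcript orientation)
    models: list          # GeneModel for coding + noncoding genes
    genome: dict          # chrom -> sequence
    mirna: MatureMiRNA    # focal miRNA

    def model_by_id(self) -> dict:
        return {m.gene_id: m for m in self.models}


def _random_seq(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _utr_with_sites(rng, length, cls, offsets, motifs, gc, max_tries=200) -> str:
    """Background UTR free of focal 6mer sites, with planted class motifs.

    The 5'-flanking base of a planted 7mer (6mer) site is forced away from the
    base that would upgrade it to an 8mer (7mer), and the finished sequence is
    re-scanned so the realised class and site count match the plan exactly.
    """
    motif = motifs[int(cls[0])] if cls != "none" else None
    six = motifs[6]
    for _ in range(max_tries):
        seq = _random_seq(rng, length, gc)
        if six in seq:
            continue
        if cls == "none":
            return seq
        chars = list(seq)
        for o in offsets:
            chars[o : o + len(motif)] = motif
            if cls == "7mer" and chars[o - 1] == motifs[8][0]:
                chars[o - 1] = "G" if motifs[8][0] != "G" else "T"
            if cls == "6mer" and chars[o - 1] == motifs[7][0]:
                chars[o - 1] = "G" if motifs[7][0] != "G" else "T"
        planted = "".join(chars)
        hits = [h for o in offsets for h in range(o + len(motif) - 6, o + len(motif) - 5)]
        if scan_sites(planted, six) != hits:
            continue
        k_present = max(
            (k for k in (6, 7, 8) if motifs[k] in planted), default=None
        )
        if k_present == int(cls[0]):
            return planted
    raise ConfigError(f"could not build a {cls} UTR of length {length}")


def emit_sequences(truth: SimTruth, config: SimConfig) -> SimSequences:
    """Emit 3'UTR FASTA content, BED12 gene models, and a genome-like FASTA.

    Genes are laid end-to-end on one chromosome, separated by random
    intergenic gaps, with random strand; each transcript is a single exon of
    5'UTR + CDS + 3'UTR.  Planted seed sites occupy exactly the configured
    UTR offsets; with ``decoys="none"`` non-target UTRs are rejection-sampled
    free of any focal 6mer-or-longer site (with the default ``"ambient"``
    policy chance sites are left in place, giving a realistic null).
    """
    rng = config.stage_rng("sequences")
    mirna = focal_mirna_record()
    motifs = {k: seed_site_motif(mirna, k).motif for k in (6, 7, 8)}

    utr3: dict[str, str] = {}
    models: list[GeneModel] = []
    genome_parts: list[str] = []
    cursor = 0
    chrom = "chr1"

    for gid, row in truth.table.iterrows():
        length = int(row.utr_len)
        cls = row.seed_class
        if cls == "none" and config.decoys == "ambient":
            utr = _random_seq(rng, length, config.gc_content)
        else:
            utr = _utr_with_sites(
                rng, length, cls, list(row.sites), motifs, config.gc_content
            )
        utr3[gid] = utr
        utr5 = _random_seq(rng, config.utr5_len, config.gc_content)
        cds = _random_seq(rng, config.cds_len, config.gc_content)
        transcript = utr5 + cds + utr
        strand = "+" if rng.integers(2) == 0 else "-"
        gap = int(config.intergenic_gap + rng.integers(config.intergenic_gap + 1))
        genome_parts.append(_random_seq(rng, gap, config.gc_content))
        cursor += gap
        start, end = cursor, cursor + len(transcript)
        if strand == "+":
            cds_start, cds_end = start + config.utr5_len, start + config.utr5_len + config.cds_len
            genome_parts.append(transcript)
        else:
            cds_start, cds_end = start + length, start + length + config.cds_len
            genome_parts.append(revcomp(transcript))
        cursor = end
        models.append(
            GeneModel(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                      cds_start=cds_start, cds_end=cds_end)
        )

    for i in range(config.n_ncrna):
        seq = _random_seq(rng, config.ncrna_len, config.gc_content)
        strand = "+" if rng.integers(2) == 0 else "-"
        gap = int(config.intergenic_gap + rng.integers(config.intergenic_gap + 1))
        genome_parts.append(_random_seq(rng, gap, config.gc_content))
        cursor += gap
        start, end = cursor, cursor + len(seq)
        genome_parts.append(seq if strand == "+" else revcomp(seq))
        cursor = end
        models.append(
            GeneModel(gene_id=f"nc{i:04d}", chrom=chrom, start=start, end=end,
                      strand=strand, cds_start=start, cds_end=start)
        )

    genome_parts.append(_random_seq(rng, config.intergenic_gap, config.gc_content))
    return SimSequences(
        utr3=utr3, models=models, genome={chrom: "".join(genome_parts)}, mirna=mirna
    )


def utr_site_genomic_interval(model: GeneModel, offset: int, length: int) -> tuple[int, int]:
    """Genomic interval of a 3'UTR site given its transcript-orientation offset."""
    iv = model.utr3()
    if iv is None:
        raise ValueError(f"{model.gene_id} has no 3'UTR")
    if model.strand == "+":
        return iv[0] + offset, iv[0] + offset + length
    return iv[1] - offset - length, iv[1] - offset


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

@dataclass
class PanelBundle:
    datasets: list                # ExpressionDataset x (n_lof + n_gof)
    counts_3seq: pd.DataFrame     # gene x [wt_1, wt_2, ko_1, ko_2]
    counts_ribo: pd.DataFrame
    smallrna: dict                # lib -> {read sequence: count}
    mirna_db: list                # MatureMiRNA
    focal: str

    def dataset(self, name: str) -> ExpressionDataset:
        return next(ds for ds in self.datasets if ds.name == name)


def _companion_mirnas(rng, focal: MatureMiRNA, n: int) -> list[MatureMiRNA]:
    """Random mature-miRNA-like 22-mers, distinct from the focal sequence."""
    out = []
    taken = {focal.sequence}
    while len(out) < n:
        seq = "".join(_BASES[rng.integers(0, 4, size=22)])
        if seq in taken:
            continue
        taken.add(seq)
        out.append(MatureMiRNA(name=f"sim-miR-{len(out) + 1:02d}", sequence=seq))
    return out


def _lof_dataset_names(n_lof: int) -> list[str]:
    if n_lof >= 3:
        return [f"lof_array_{i + 1}" for i in range(n_lof - 2)] + ["lof_3seq", "lof_ribo"]
    if n_lof == 2:
        return ["lof_array_1", "lof_3seq"]
    return ["lof_array_1"]


def _multinomial_counts(rng, weights: np.ndarray, depth: int, libs: list[str],
                        index) -> pd.DataFrame:
    p = weights / weights.sum()
    data = {lib: rng.multinomial(depth, p) for lib in libs}
    return pd.DataFrame(data, index=index)


def emit_expression_panel(truth: SimTruth, config: SimConfig) -> PanelBundle:
    """Emit the 5-dataset expression panel plus raw count tables.

    Every dataset's canonical log2 fold change is effect + N(0, noise_sd)
    (effect = +lof_effect in LOF, -gof_effect in GOF comparisons, 0 for
    non-targets).  The 3Seq and ribosome-profiling LOF datasets additionally
    come with per-library count tables: multinomial draws at ``library_depth``
    whose expected RPM ratios reproduce the dataset's realised log2FC, with
    ribosome counts tracking mRNA abundance times a gene-specific (genotype-
    independent) translation-efficiency factor, so the planted TE change is 1.
    Small-RNA libraries are multinomial over the miRNA pool, with the focal
    miRNA at ``focal_mirna_fraction`` in WT and absent in KO libraries.
    """
    rng = config.stage_rng("panel")
    genes = truth.gene_ids
    n = len(genes)
    lof_eff = truth.table["lof_effect"].to_numpy()
    gof_eff = truth.table["gof_effect"].to_numpy()

    def noisy(effect):
        noise = rng.standard_normal(n) * config.noise_sd if config.noise_sd > 0 else 0.0
        return pd.Series(effect + noise, index=genes)

    datasets = []
    lof_fc = {}
    for name in _lof_dataset_names(config.n_lof_datasets):
        fc = noisy(+lof_eff)
        lof_fc[name] = fc
        datasets.append(ExpressionDataset(name=name, direction="LOF", log2fc=fc))
    for i in range(config.n_gof_datasets):
        fc = noisy(-gof_eff)
        datasets.append(
            ExpressionDataset(name=f"gof_array_{i + 1}", direction="GOF", log2fc=fc)
        )

    base = rng.lognormal(mean=0.0, sigma=config.expression_ln_sd, size=n)
    fc_3seq = lof_fc.get("lof_3seq", pd.Series(0.0, index=genes)).to_numpy()
    counts_3seq = pd.concat(
        [
            _multinomial_counts(rng, base, config.library_depth, ["wt_1", "wt_2"], genes),
            _multinomial_counts(
                rng, base * np.exp2(fc_3seq), config.library_depth, ["ko_1", "ko_2"], genes
            ),
        ],
        axis=1,
    )
    te_factor = rng.lognormal(mean=0.0, sigma=config.te_ln_sd, size=n)
    fc_ribo = lof_fc.get("lof_ribo", pd.Series(0.0, index=genes)).to_numpy()
    counts_ribo = pd.concat(
        [
            _multinomial_counts(
                rng, base * te_factor, config.library_depth, ["wt_1", "wt_2"], genes
            ),
            _multinomial_counts(
                rng, base * np.exp2(fc_ribo) * te_factor, config.library_depth,
                ["ko_1", "ko_2"], genes,
            ),
        ],
        axis=1,
    )

    focal = focal_mirna_record()
    mirna_db = [focal] + _companion_mirnas(rng, focal, config.n_companion_mirnas)
    shares = np.array([config.focal_mirna_fraction] + [
        0.7 ** i for i in range(config.n_companion_mirnas)
    ])
    shares[1:] *= (1 - config.focal_mirna_fraction) / shares[1:].sum()
    ko_shares = shares.copy()
    ko_shares[0] = 0.0
    ko_shares /= ko_shares.sum()
    smallrna = {}
    frag_probs = np.array([0.7, 0.15, 0.10, 0.05])  # full, -1, -2, -3 nt 3' truncations
    for lib, p in (("wt_1", shares), ("wt_2", shares), ("ko_1", ko_shares), ("ko_2", ko_shares)):
        counts = rng.multinomial(config.smallrna_depth, p / p.sum())
        reads: dict[str, int] = {}
        for m, c in zip(mirna_db, counts):
            if c == 0:
                continue
            for trunc, sub in enumerate(rng.multinomial(c, frag_probs)):
                if sub > 0:
                    seq = m.sequence[: len(m.sequence) - trunc]
                    reads[seq] = reads.get(seq, 0) + int(sub)
        smallrna[lib] = reads

    return PanelBundle(
        datasets=datasets, counts_3seq=counts_3seq, counts_ribo=counts_ribo,
        smallrna=smallrna, mirna_db=mirna_db, focal=focal.name,
    )


def emit_3p_end_sites(seqs: SimSequences, counts_3seq: pd.DataFrame) -> pd.DataFrame:
    """Per-position 3'-end read counts implied by the 3Seq count table.

    Each gene's reads fall on its cleavage site, with ~20% on a minor site
    3 nt upstream (within the default peak-merge distance), so peak calling
    and 3'UTR-summed transcript counting reconstruct the per-library table.
    """
    by_id = seqs.model_by_id()
    rows = []
    for gid, row in counts_3seq.iterrows():
        m = by_id[gid]
        main = m.utr3_end_site()
        minor = main - 3 if m.strand == "+" else main + 3
        for lib, c in row.items():
            c = int(c)
            if c == 0:
                continue
            c_minor = c // 5
            if c - c_minor > 0:
                rows.append((m.chrom, m.strand, main, c - c_minor, lib))
            if c_minor > 0:
                rows.append((m.chrom, m.strand, minor, c_minor, lib))
    return pd.DataFrame(rows, columns=["chrom", "strand", "pos", "count", "lib"])


# ---------------------------------------------------------------------------
# CLIP reads
# ---------------------------------------------------------------------------

def emit_clip_reads(truth: SimTruth, config: SimConfig, seqs: SimSequences,
                    n_libraries: int = 4) -> list[AlignedRead]:
    """CLIP read alignments: pileups over planted sites plus uniform background.

    Each planted site receives exactly ``clip_reads_per_site`` reads of
    ``clip_read_length`` nt on the gene strand, all covering the site's 6mer
    core, staggered by 1 nt so the coverage summit falls on the core start
    (+/- ``clip_summit_jitter``).  Background reads are placed uniformly at
    ``clip_background_rate`` reads per kb of genome with random strand.
    """
    rng = config.stage_rng("clip")
    by_id = seqs.model_by_id()
    reads: list[AlignedRead] = []
    L = config.clip_read_length
    m_reads = config.clip_reads_per_site
    if m_reads > 0:
        for gid, row in truth.table[truth.table["is_true_target"]].iterrows():
            model = by_id[gid]
            k = int(row.seed_class[0])
            for off in row.sites:
                core_s, _core_e = utr_site_genomic_interval(model, off + (k - 6), 6)
                d = int(rng.integers(-config.clip_summit_jitter,
                                     config.clip_summit_jitter + 1))
                anchor = core_s - d
                for j in range(m_reads):
                    start = anchor - j
                    reads.append(
                        AlignedRead(chrom=model.chrom, start=start, end=start + L,
                                    strand=model.strand,
                                    library=f"clip_{j % n_libraries + 1}")
                    )
    genome_len = sum(len(s) for s in seqs.genome.values())
    n_bg = int(round(config.clip_background_rate * genome_len / 1000))
    chroms = sorted(seqs.genome)
    for i in range(n_bg):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, len(seqs.genome[chrom]) - L))
        strand = "+" if rng.integers(2) == 0 else "-"
        reads.append(
            AlignedRead(chrom=chrom, start=start, end=start + L, strand=strand,
                        library=f"clip_{i % n_libraries + 1}")
        )
    return reads
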