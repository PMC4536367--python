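# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `mirmeta`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Seed-site model

A k-mer seed site (k ∈ {6, 7, 8}) is the reverse complement of mature miRNA
positions 2..k+1 (1-based). For miR-203 this gives 8mer `ACAUUUCA`
(DNA `ACATTTCA`), 7mer `CAUUUCA`, 6mer `AUUUCA`. Under this convention the
classes nest: each longer site extends the shorter one by one base on the
site's 5′ side, so any sequence containing the 8mer contains the 7mer and
6mer. This is deliberately *not* the TargetScan 7mer-A1/8mer-A1 convention
(which anchors an A opposite miRNA position 1); the positions-2..9 reading is
the one consistent with the printed miR-203 8mer. The 6mer is taken as
positions 2–7, consistent with that same positional scheme. A gene's seed
class is the longest site present anywhere in its longest 3′UTR — a
set-membership definition, not weighted by site count.

All sequence computation is in DNA space; U maps to T at parse time.
Coordinates are 0-based, half-open, strand-aware (BED semantics) everywhere.

## Expression meta-analysis

Candidates must have log2FC strictly > 0 in every LOF dataset and strictly
< 0 in every GOF dataset. Strict inequalities mean an exact zero
disqualifies: zeros are measure-zero on microarray values but occur with
pseudocounted counts, and treating them as "moved" in either direction would
be arbitrary. The universe is the intersection of genes detected in all
datasets; genes missing anywhere are dropped, never imputed.

Seed enrichment among candidates uses the hypergeometric upper tail
(drawing |candidates| from the universe, with the universe's 7/8mer carriers
marked). Two negative controls are always computed: a size-matched uniform
random draw from the universe, and the anti-correlated set (down in all LOF,
up in all GOF), whose size is whatever the data yields. No multiple-testing
correction is applied across seed classes (raw K–S p-values are reported);
callers can correct downstream if needed.

The ranked correlation metric assigns rank 1 to the most upregulated gene in
each LOF dataset and to the most downregulated in each GOF dataset, sums the
per-dataset ranks, and ranks the sums (rank 1 = most consistently
anti-correlated). Ties get average ranks at both stages, making the metric
invariant under any strictly monotone transform of each dataset's values.

### One-sided Kolmogorov–Smirnov tests

The statistic is D = max_t [F_ref(t) − F_class(t)] in the direction implied
by the dataset (LOF: seed-class genes shifted up; GOF: shifted down). The
p-value is the asymptotic one-sided tail exp(−2D²nm/(n+m)); when
n·m ≤ 10,000 the exact distribution is used instead (scipy's path-counting
implementation). Classes with fewer than 5 genes report p = NaN. Tests
compare both D and p against brute-force CDF and permutation oracles.

## Quantification

* **Small RNA counting.** Each read is assigned to the miRNA with the
  longest exact contiguous match, requiring ≥18 nt; ties break to the
  lexicographically first miRNA name (documented, deterministic). Reads may
  be supplied collapsed (sequence → count). Detection filter: ≥50 reads in
  ≥2 libraries.
* **RPM.** count / library total × 10⁶. Filters are applied to raw counts;
  RPM is computed on the unfiltered library totals.
* **log2FC.** log2((mean RPM cond + 1)/(mean RPM ref + 1)), replicates
  averaged first. This replaces a dispersion-model DE fit on purpose: the
  meta-analysis consumes only signs and ranks, so DE p-values would be
  unused. The 1-RPM pseudocount shrinks low-expression genes toward zero.
* **3′-end peaks.** Per-position 3′-end counts on the same chrom/strand
  closer than 10 nt (configurable; no canonical value exists) merge into one
  peak; the peak site is the modal position (leftmost on ties), its count
  the sum. The internal-priming filter removes peaks whose downstream 10
  genomic nt (strand-aware) contain ≥7 A or start with 6 consecutive A —
  the field-standard heuristic, exposed in config. Transcript counts sum
  3′UTR-localised, filter-passing peaks; the 3Seq detection filter keeps
  transcripts with ≥10 reads in ≥2 libraries.
* **Translation efficiency.** Default TE = CDS ribosome-footprint RPM /
  mRNA RPM (the conventional direction); a `mrna_over_ribo` mode computes
  the literal inverse, which only flips labels in the symmetric downstream
  ratio ΔTE = TE_KO/TE_WT.

## CLIP analysis

Reads shorter than 25 nt are rejected at construction. Duplicate collapsing
keys on (chrom, strand, start, end) after pooling libraries. Clusters are
connected components of the interval-overlap graph with intersection ≥1 nt
(half-open intervals, so abutting reads do not overlap), kept when they
contain ≥2 reads — the literal reading of "two read alignments"; a sorted
sweep tracking the running maximum end is provably equivalent to the
component computation and is verified against it. The summit is the leftmost
position of maximal coverage (tie-break chosen; no canonical rule exists).

Annotation is hierarchical over exon-aware features: 3′UTR (direct overlap
preferred, then a 5 kb strand-aware downstream extension), CDS, 5′UTR,
ncRNA, intron, intergenic; within a category the gene with the largest
overlap wins. Target-site prediction scans the genomic sequence of each
3′UTR cluster (strand-corrected; not a read consensus) for 6mer sites of
every miRNA in the set accounting for 90% of the small-RNA pool (smallest
descending-abundance prefix reaching 90%, boundary inclusive, ties ordered
by name). Site existence uses the 6mer; each occurrence also reports the
longest motif present at that locus (k_best ∈ {6,7,8}) as an annotation.

The positional profile bins motif offsets relative to the summit (5-nt bins
over ±50 nt, transcript orientation) and compares against (a) dinucleotide-
shuffled cluster sequences scanned at the same summit positions and (b)
length-matched random 3′UTR windows. Per-bin enrichment is Laplace-smoothed
(add-one on counts) so empty background bins stay finite.

### Dinucleotide shuffle

The Altschul–Erickson Euler-path construction: sequences are walks on the
letter-transition multigraph; a random last out-edge per vertex forming an
arborescence into the final letter, plus shuffled remaining edges, replays
to a uniform-ish random Eulerian walk. The dinucleotide count vector (hence
mononucleotide counts and first/last base) is exactly preserved. Sequences
whose transition graph admits a single Eulerian arrangement (e.g. any
homopolymer, or `ACGTACGT`, whose single T→A edge forces the path) are fixed
points.

### Motif enrichment

Exhaustive k-mer enrichment counts, per k-mer, the number of foreground and
background sequences containing it at least once. The p-value is the
one-sided Fisher (hypergeometric) tail on that containment 2×2 table. An
earlier design used a binomial tail with the background containment
frequency as a known null rate; because that rate is itself estimated from a
finite shuffle background, the plug-in binomial is anti-conservative, and
scanning thousands of k-mers then produces spurious Bonferroni-significant
motifs on null data. The exchangeability-based Fisher tail keeps the null
clean (verified by seeded null runs in the test suite) while leaving planted
motifs at rank 1.

## Synthetic study generator

The generator emulates the structure of a combined miRNA LOF/GOF study in
mouse epidermis. Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes / n_true_targets | 6000 / 300 | detected transcriptome scale; planted target count |
| seed_class_mix | 0.4 / 0.4 / 0.2 | 8mer / 7mer / 6mer share of targets |
| lof_effect_mean, gof_effect_mean | 0.5, 1.0 log2 | knockout perturbs less than induction |
| class_effect_scalars | 1.0 / 0.75 / 0.5 | 8mer > 7mer > 6mer effect scaling |
| noise_sd | 0.25 log2 | per-dataset biological+technical noise |
| n_lof / n_gof datasets | 3 / 2 | microarray + 3Seq + Ribo-Seq; two GOF arrays |
| library_depth | 5×10⁶ | 3Seq/Ribo reads per library (2 per condition) |
| clip_reads_per_site / background | 10 / 0.05 per kb | planted pileup depth; uniform background |
| utr_len_range, gc_content | 500–1500 nt, 0.45 | 3′UTR length and composition |

Effect sizes per gene are deterministic (mean × class scalar), which keeps
the class-ordering and zero-noise contracts exact; dataset-level noise
supplies the variability. The noise level, depths, and CLIP parameters are
free parameters chosen to be realistic for this assay class — the original
study does not state its microarray noise model — and are *not* estimates of
any particular dataset.

Per gene, a background 3′UTR is drawn i.i.d. at the configured GC content;
for targets (and for everyone under `decoys="none"`) backgrounds are
rejection-sampled free of focal 6mer sites, then the class motif is written
at the planted offsets with a 5′-flank guard base preventing accidental
upgrade (7mer→8mer, 6mer→7mer), and the sequence is re-scanned to confirm
the realised class and site count. With the default `decoys="ambient"`
policy, non-target UTRs keep chance sites, giving a realistic enrichment
null. Genes are laid out single-exon (5′UTR + CDS + 3′UTR) on one
chromosome with random strands and random intergenic gaps.

Expression: each dataset's canonical log2FC is effect + N(0, noise_sd). The
3Seq and Ribo-Seq datasets additionally emit per-library multinomial count
tables whose expected RPM ratios reproduce the realised log2FC; ribosome
counts track mRNA weights times a gene-specific, genotype-independent TE
factor, so the planted TE change is exactly 1 (the pipeline's ΔTE then
deviates from 1 only through sampling and the two datasets' independent
noise draws). Small-RNA libraries are multinomial over a pool of the focal
miRNA (30% in WT, absent in KO) plus synthetic companion miRNAs with
geometric shares; reads are full-length or 1–3 nt 3′-truncated copies.

CLIP: each planted site receives exactly `clip_reads_per_site` reads, 1-nt
staggered so the coverage summit falls on the site's 6mer-core start
(± a jitter of 2 nt); background reads are uniform over the genome. Note a
geometric consequence of the leftmost-max-coverage summit rule: on minus-
strand genes the planted motif sits ~5 nt 5′ of the summit in transcript
coordinates, so planted positional mass spreads over bins 0/−1 rather than
bin 0 alone. Enrichment over shuffled backgrounds remains far above the
bin-0 threshold because background motif mass is two orders of magnitude
lower.

Determinism: every emitter draws from its own child generator keyed on
(rng_seed, stage), so stages regenerate independently and whole runs are
byte-identical under a fixed seed.

### What the generator does not emulate

No sequencing errors, adaptors, or raw FASTQ (alignment is out of scope;
reads are intervals); no alternative 3′UTR isoforms; no probe-level
microarray structure; no miRNA-family cross-targeting; no correlated noise
between datasets from shared samples; single-exon gene models (the
annotation code handles spliced models, but simulated genes are unspliced).
A passing pipeline on this generator demonstrates correctness of the
analysis logic and its statistical calibration — not performance on real
data, where effect-size distributions, UTR composition bias, and CLIP
background structure are all harder.

## Problem sizes used in validation

The default-scale validation run uses the full 6000-gene configuration; the
seed-class CDF analysis uses 4000 genes with 600 equal-mix targets so every
scanned class holds ≥200 genes; null-calibration series use 1200–1500 genes
at reduced depth over 100–200 seeded replicates. These sizes keep the whole
suite comfortably reproducible on a laptop while leaving all statistical
margins wide.

## Known limitations

* The per-gene assignment of extended-3′UTR clusters prefers direct overlap
  and then largest overlap; in dense gene neighbourhoods a downstream
  cluster can still annotate to a neighbour's extension, as with any
  extension-based scheme.
* `count_mirnas` uses longest-common-substring as the stand-in for a
  best-alignment criterion; it does not model mismatches or non-templated
  additions.
* The peak caller is a deliberate simplification (modal-site merge within a
  fixed distance); it does not model cleavage-site microheterogeneity
  beyond the merge window.
* The exact one-sided K–S p-value is delegated to scipy's path-counting
  method for small samples; for large samples the asymptotic tail is used,
  which is mildly conservative near D = 0.
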