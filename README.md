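# mirmeta

Multi-evidence identification of microRNA targets, built around the way
miR-203 targets were mapped in mouse epidermis: an expression meta-analysis
over loss-of-function (knockout vs wild-type) and gain-of-function (induced
overexpression vs uninduced) comparisons, combined with Ago2 HITS-CLIP
binding evidence and seed-site sequence analysis. The package is aimed at
computational biologists who want a tested, reusable implementation of this
class of analysis, exercised end-to-end on synthetic data with planted
targets so every statistic can be checked against known ground truth.

## The analysis

A gene directly repressed by a miRNA should satisfy three independent lines
of evidence:

1. **Anti-correlated expression.** With log2 fold changes `f_d(g)` in each
   dataset *d*, a candidate satisfies `f_d(g) > 0` in *every* LOF dataset and
   `f_d(g) < 0` in *every* GOF dataset (no fold-change or p-value cutoff —
   only signs). Candidates are drawn from the universe of genes detected in
   all datasets.
2. **A seed match.** The k-mer site (k ∈ {6,7,8}) is the reverse complement
   of mature miRNA positions 2..k+1; for miR-203
   (`GUGAAAUGUUUAGGACCACUAG`) the 8mer site is `ACAUUUCA`. Genes are
   classed by the longest site present in their (longest) 3′UTR. Candidate
   7/8mer enrichment is tested with a hypergeometric tail against the
   detected-transcript background, alongside two negative controls (a
   size-matched random set and the positively-correlated set).
3. **Physical Ago2 binding.** CLIP reads are duplicate-collapsed; clusters
   are ≥2 alignments overlapping by ≥1 nt; clusters are annotated
   hierarchically (3′UTR with a 5 kb downstream extension, CDS, 5′UTR,
   ncRNA, intron, intergenic); 3′UTR cluster sequences are scanned for 6mer
   sites of the miRNAs making up 90% of the small-RNA pool.

High-confidence targets are sign-consistent candidates with a 7/8mer 3′UTR
seed match whose 3′UTR carries a seed-containing Ago2 cluster. Supporting
analyses: a ranked correlation metric (rank of summed per-dataset ranks),
one-sided two-sample Kolmogorov–Smirnov CDF-shift tests per seed class
(p = exp(−2D²nm/(n+m)), exact for small samples), translation efficiency
(CDS ribosome-footprint RPM over 3′-end mRNA RPM) and its KO/WT ratio, 3′-end
peak calling with an internal-priming filter, best-match small-RNA counting
(≥18 nt), and exhaustive k-mer motif enrichment against dinucleotide-shuffled
backgrounds (Altschul–Erickson Euler-path shuffle).

The synthetic-data module generates a complete seeded study — sequences and
gene models, the 5-dataset expression panel (2 of the LOF datasets as raw
count tables), small-RNA libraries, CLIP reads — with planted effect sizes
and site classes, so precision/recall of the full pipeline are measurable.

## Worked example

```python
from mirmeta.pipeline import RunConfig, run_all
from mirmeta.synthetic import SimConfig

cfg = RunConfig(sim=SimConfig(n_genes=1000, n_true_targets=100,
                              library_depth=1_000_000,
                              smallrna_depth=20_000, rng_seed=42))
report = run_all(cfg, "demo_run")
```

This prints (via the report dictionary; abridged):

```
universe: 973 genes
up in all LOF: 150  down in all GOF: 329
sign-consistent candidates: 95
candidates with 7/8mer seed: 67
CLIP 3'UTR clusters: 101  focal target genes: 100
high-confidence targets: 65
seed enrichment: fold 4.83, p = 5.76e-41
precision 1.000  recall 0.650  CLIP site recovery 1.00
median target delta-TE (KO/WT): 1.007
```

Reading: of 1000 simulated genes (100 planted miR-203 targets), 95 moved
against miR-203 in all five comparisons; 67 of those carry a 7/8mer seed —
a 4.8-fold enrichment over the detected background, hypergeometric
p ≈ 6e-41. Intersecting with Ago2-bound, seed-containing 3′UTR clusters
leaves 65 high-confidence targets, all of them planted targets
(precision 1.0); recall is bounded by the planted 6mer-class targets, which
the 7/8mer filter deliberately excludes. The median KO/WT translation-
efficiency change of targets is ~1, as expected when planted effects are
purely mRNA-level. Every intermediate (FASTA/BED/TSV/JSON) is written to
`demo_run/`, and `mirmeta run --config cfg.yaml --seed 42 --out demo_run`
does the same from the shell.

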