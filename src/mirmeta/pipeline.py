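"""End-to-end orchestration: simulate -> quantify -> CLIP -> meta-analysis.

Each stage reads its inputs from and writes its outputs to a run directory in
plain-text formats (FASTA/BED/TSV/JSON), so any stage can be re-run in
isolation from persisted intermediates and reproduce the monolithic run.
All randomness flows from seeded child generators of the run seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clip as clipmod
from . import io
from . import meta as metamod
from . import quant
from .meta import ExpressionDataset, MetaPanel
from .seedscan import MatureMiRNA, classify_seed_class, seed_site_motif
from .synthetic import (
    ConfigError,
    SimConfig,
    SimTruth,
    emit_3p_end_sites,
    emit_clip_reads,
    emit_expression_panel,
    emit_sequences,
    simulate_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    smallrna_min_count: int = 50
    smallrna_min_libs: int = 2
    seq3_min_count: int = 10
    seq3_min_libs: int = 2
    ribo_min_count: int = 50
    ribo_min_libs: int = 2
    peak_merge_distance: int = 10
    pseudocount: float = 1.0
    te_mode: str = "ribo_over_mrna"
    clip_min_reads: int = 2
    clip_min_overlap: int = 1
    utr3_extension: int = 5000
    top_mirna_fraction: float = 0.90
    profile_shuffles: int = 20
    profile_bin: int = 5
    profile_half_span: int = 50

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        try:
            return cls(sim=SimConfig.from_dict(sim), **d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def meta_rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.sim.rng_seed), 5])


def _p(out_dir, name) -> Path:
    return Path(out_dir) / name


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config.sim)
    seqs = emit_sequences(truth, config.sim)
    panel = emit_expression_panel(truth, config.sim)
    end_sites = emit_3p_end_sites(seqs, panel.counts_3seq)
    reads = emit_clip_reads(truth, config.sim, seqs)

    io.write_json(_p(out_dir, "truth.json"), truth.to_json_dict())
    io.write_fasta(_p(out_dir, "utr3.fa"), seqs.utr3)
    io.write_fasta(_p(out_dir, "genome.fa"), seqs.genome)
    io.write_bed12(_p(out_dir, "models.bed12"), seqs.models)
    io.write_fasta(
        _p(out_dir, "mirna_db.fa"), {m.name: m.sequence for m in panel.mirna_db}
    )
    bed = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.library, 1, r.strand) for r in reads],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    io.write_bed6(_p(out_dir, "clip_reads.bed"), bed)
    end_sites.to_csv(_p(out_dir, "end_sites.tsv"), sep="\t", index=False)
    io.write_counts_tsv(_p(out_dir, "counts_3seq.tsv"), panel.counts_3seq)
    io.write_counts_tsv(_p(out_dir, "counts_ribo.tsv"), panel.counts_ribo)
    for lib, readmap in panel.smallrna.items():
        pd.Series(readmap, name="count").rename_axis("sequence").to_csv(
            _p(out_dir, f"smallrna_{lib}.tsv"), sep="\t"
        )
    manifest = []
    for ds in panel.datasets:
        io.write_log2fc_tsv(_p(out_dir, f"log2fc_{ds.name}.tsv"), ds.log2fc)
        manifest.append({"name": ds.name, "direction": ds.direction})
    io.write_json(
        _p(out_dir, "datasets.json"),
        {"datasets": manifest, "focal": panel.focal,
         "smallrna_libs": sorted(panel.smallrna)},
    )
    return {
        "n_genes": int(config.sim.n_genes),
        "n_true_targets": int(len(truth.true_targets)),
        "n_clip_reads": int(len(reads)),
        "n_end_site_records": int(len(end_sites)),
    }


# ---------------------------------------------------------------------------
# stage: quantification
# ---------------------------------------------------------------------------

def _load_mirna_db(out_dir) -> list[MatureMiRNA]:
    return [
        MatureMiRNA(name=n, sequence=s)
        for n, s in sorted(io.read_fasta(_p(out_dir, "mirna_db.fa")).items())
    ]


def _split_conditions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    ko = table[[c for c in table.columns if c.startswith("ko")]]
    wt = table[[c for c in table.columns if c.startswith("wt")]]
    return ko, wt


def stage_quant(config: RunConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    manifest = io.read_json(_p(out_dir, "datasets.json"))
    mirna_db = _load_mirna_db(out_dir)
    models = io.read_bed12(_p(out_dir, "models.bed12"))
    genome = io.read_fasta(_p(out_dir, "genome.fa"))

    # small RNA: best-match counting, >=50 reads in >=2 libraries, RPM
    lib_counts = {}
    for lib in manifest["smallrna_libs"]:
        df = pd.read_csv(_p(out_dir, f"smallrna_{lib}.tsv"), sep="\t", index_col=0)
        counts, unassigned = quant.count_mirnas(df["count"].to_dict(), mirna_db)
        lib_counts[lib] = counts
        logger.info("smallRNA %s: %d unassigned reads", lib, unassigned)
    mirna_counts = pd.DataFrame(lib_counts)
    kept = quant.filter_min_reads(
        mirna_counts, config.smallrna_min_count, config.smallrna_min_libs
    )
    mirna_rpm = quant.rpm(mirna_counts).loc[kept.index]
    io.write_counts_tsv(_p(out_dir, "mirna_counts.tsv"), mirna_counts)
    io.write_counts_tsv(_p(out_dir, "mirna_rpm.tsv"), mirna_rpm)

    # 3Seq: pooled peak calling, internal-priming filter, 3'UTR transcript counts
    end_sites = pd.read_csv(_p(out_dir, "end_sites.tsv"), sep="\t")
    peaks = quant.call_3p_peaks(end_sites, merge_distance=config.peak_merge_distance)
    n_flagged = 0
    for pk in peaks:
        pk.internal_priming = quant.filter_internal_priming(pk, genome)
        n_flagged += pk.internal_priming
    tx_counts = quant.transcript_counts(peaks, models)
    with open(_p(out_dir, "peaks.bed"), "w") as fh:
        for pk in peaks:
            flag = "IP" if pk.internal_priming else (pk.annotation or "NA")
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{flag}\t{pk.read_count}\t{pk.strand}\n"
            )
    kept3 = quant.filter_min_reads(tx_counts, config.seq3_min_count, config.seq3_min_libs)
    rpm3 = quant.rpm(tx_counts).loc[kept3.index]
    ko3, wt3 = _split_conditions(rpm3)
    fc3 = quant.log2fc(ko3, wt3, pseudocount=config.pseudocount)
    io.write_counts_tsv(_p(out_dir, "tx_counts_3seq.tsv"), tx_counts)
    io.write_log2fc_tsv(_p(out_dir, "quant_lof_3seq.tsv"), fc3)

    # ribosome profiling: CDS counts filter, RPM, log2FC, TE and delta-TE
    ribo = io.read_counts_tsv(_p(out_dir, "counts_ribo.tsv"))
    kept_r = quant.filter_min_reads(ribo, config.ribo_min_count, config.ribo_min_libs)
    rpm_r = quant.rpm(ribo).loc[kept_r.index]
    ko_r, wt_r = _split_conditions(rpm_r)
    fc_r = quant.log2fc(ko_r, wt_r, pseudocount=config.pseudocount)
    io.write_log2fc_tsv(_p(out_dir, "quant_lof_ribo.tsv"), fc_r)

    te_wt = quant.translation_efficiency(wt3.mean(axis=1), wt_r.mean(axis=1),
                                         mode=config.te_mode)
    te_ko = quant.translation_efficiency(ko3.mean(axis=1), ko_r.mean(axis=1),
                                         mode=config.te_mode)
    dte = quant.delta_te(te_ko, te_wt)
    te_table = pd.DataFrame({"te_wt": te_wt, "te_ko": te_ko, "delta_te": dte}).dropna()
    te_table.to_csv(_p(out_dir, "translation_efficiency.tsv"), sep="\t",
                    index_label="gene_id")

    return {
        "n_mirnas_detected": int(len(kept.index)),
        "n_peaks": int(len(peaks)),
        "n_peaks_internal_priming": int(n_flagged),
        "n_tx_quantified_3seq": int(len(kept3.index)),
        "n_tx_quantified_ribo": int(len(kept_r.index)),
        "n_te_genes": int(len(te_table)),
    }


# ---------------------------------------------------------------------------
# stage: CLIP
# ---------------------------------------------------------------------------

def stage_clip(config: RunConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    manifest = io.read_json(_p(out_dir, "datasets.json"))
    focal_name = manifest["focal"]
    models = io.read_bed12(_p(out_dir, "models.bed12"))
    genome = io.read_fasta(_p(out_dir, "genome.fa"))
    utr3 = io.read_fasta(_p(out_dir, "utr3.fa"))
    mirna_db = {m.name: m for m in _load_mirna_db(out_dir)}

    bed = io.read_bed6(_p(out_dir, "clip_reads.bed"))
    reads = [
        clipmod.AlignedRead(chrom=r.chrom, start=int(r.start), end=int(r.end),
                            strand=r.strand, library=r.name)
        for r in bed.itertuples()
    ]
    collapsed = clipmod.collapse_duplicates(reads)
    clusters = clipmod.call_clusters(
        collapsed, min_reads=config.clip_min_reads, min_overlap=config.clip_min_overlap
    )
    clipmod.annotate_clusters(clusters, models, utr3_extension=config.utr3_extension)
    with open(_p(out_dir, "clusters.bed"), "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.start}\t{cl.end}\t{cl.annotation}\t{cl.n_reads}\t{cl.strand}\n"
            )

    mirna_rpm = io.read_counts_tsv(_p(out_dir, "mirna_rpm.tsv"))
    wt_rpm = mirna_rpm[[c for c in mirna_rpm.columns if c.startswith("wt")]].mean(axis=1)
    top = clipmod.top_expressed_mirnas(wt_rpm, config.top_mirna_fraction)
    sites = clipmod.predict_target_sites(
        clusters, [mirna_db[n] for n in top if n in mirna_db], genome
    )
    sites.to_csv(_p(out_dir, "clip_sites.tsv"), sep="\t", index=False)
    focal_targets = sorted(
        set(sites.loc[sites["mirna"] == focal_name, "gene"].dropna())
    )
    Path(_p(out_dir, "clip_targets.txt")).write_text(
        "".join(g + "\n" for g in focal_targets)
    )

    rng = np.random.default_rng([int(config.sim.rng_seed), 6])
    focal = mirna_db[focal_name]
    profile = clipmod.positional_seed_profile(
        clusters, seed_site_motif(focal, 6), genome, list(utr3.values()),
        n_shuffles=config.profile_shuffles, rng=rng,
        bin_width=config.profile_bin, half_span=config.profile_half_span,
    )
    io.write_json(_p(out_dir, "positional_profile.json"), {
        k: profile[k] for k in
        ("bin_centers", "observed", "shuffled", "random_utr", "enrichment", "n_clusters")
    })

    ann = pd.Series([cl.annotation for cl in clusters]).value_counts().to_dict()
    mid = len(profile["enrichment"]) // 2
    return {
        "n_clip_reads": int(len(reads)),
        "n_unique_reads": int(len(collapsed)),
        "n_clusters": int(len(clusters)),
        "clusters_by_annotation": {k: int(v) for k, v in ann.items()},
        "n_top_mirnas": int(len(top)),
        "n_focal_sites": int((sites["mirna"] == focal_name).sum()) if len(sites) else 0,
        "n_focal_target_genes": int(len(focal_targets)),
        "summit_bin0_enrichment": float(profile["enrichment"][mid]),
    }


# ---------------------------------------------------------------------------
# stage: meta-analysis
# ---------------------------------------------------------------------------

def _load_panel(config: RunConfig, out_dir) -> MetaPanel:
    manifest = io.read_json(_p(out_dir, "datasets.json"))
    lof, gof = [], []
    for entry in manifest["datasets"]:
        name, direction = entry["name"], entry["direction"]
        # count-based LOF datasets come from the quantification stage so the
        # whole counting/filtering/RPM path is exercised end to end
        if name == "lof_3seq":
            fc = io.read_log2fc_tsv(_p(out_dir, "quant_lof_3seq.tsv"))
        elif name == "lof_ribo":
            fc = io.read_log2fc_tsv(_p(out_dir, "quant_lof_ribo.tsv"))
        else:
            fc = io.read_log2fc_tsv(_p(out_dir, f"log2fc_{name}.tsv"))
        ds = ExpressionDataset(name=name, direction=direction, log2fc=fc)
        (lof if direction == "LOF" else gof).append(ds)
    return MetaPanel(lof_datasets=lof, gof_datasets=gof)


def stage_meta(config: RunConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    manifest = io.read_json(_p(out_dir, "datasets.json"))
    panel = _load_panel(config, out_dir)
    utr3 = io.read_fasta(_p(out_dir, "utr3.fa"))
    mirna_db = {m.name: m for m in _load_mirna_db(out_dir)}
    focal = mirna_db[manifest["focal"]]

    seed_classes = pd.Series(
        {g: classify_seed_class(s, focal) for g, s in utr3.items()}, name="seed_class"
    )
    seed_classes.rename_axis("gene_id").to_frame().to_csv(
        _p(out_dir, "seed_classes.tsv"), sep="\t"
    )

    clip_path = _p(out_dir, "clip_targets.txt")
    clip_targets = (
        set(clip_path.read_text().split()) if clip_path.exists() else set()
    )
    result = metamod.meta_result(panel, seed_classes, clip_targets)
    result.to_csv(_p(out_dir, "meta_result.tsv"), sep="\t", index_label="gene_id")

    candidates = set(result.index[result["candidate"]])
    report = metamod.seed_enrichment(
        candidates, seed_classes, panel.universe, config.meta_rng(),
        control_sets={"anticorrelated": metamod.anticorrelated_set(panel)},
    )
    io.write_json(_p(out_dir, "enrichment.json"), {
        "observed": report.observed, "n_candidates": report.n_candidates,
        "background_rate": report.background_rate, "fold": report.fold,
        "p": report.p, "controls": report.controls,
    })

    ks_rows = []
    for ds in panel.all_datasets():
        tab = metamod.cdf_shift_tests(ds, seed_classes)
        for cls, row in tab.iterrows():
            ks_rows.append((ds.name, cls, int(row["n"]), row["D"], row["p"]))
    ks_table = pd.DataFrame(ks_rows, columns=["dataset", "seed_class", "n", "D", "p"])
    ks_table.to_csv(_p(out_dir, "ks_tests.tsv"), sep="\t", index=False)

    high_conf = metamod.high_confidence_targets(result)
    Path(_p(out_dir, "high_confidence_targets.txt")).write_text(
        "".join(g + "\n" for g in sorted(high_conf))
    )
    return {
        "n_universe": int(len(panel.universe)),
        "n_up_in_all_lof": int(result["up_in_all_lof"].sum()),
        "n_down_in_all_gof": int(result["down_in_all_gof"].sum()),
        "n_candidates": int(len(candidates)),
        "n_candidates_with_seed": int(
            (result["candidate"] & result["seed_class"].isin(metamod.SEED_OK)).sum()
        ),
        "n_high_confidence": int(len(high_conf)),
        "enrichment_p": float(report.p),
        "enrichment_fold": float(report.fold),
        "random_control_fold": float(report.controls["random"]["fold"]),
        "anticorrelated_control": report.controls["anticorrelated"],
    }


# ---------------------------------------------------------------------------
# evaluation and full run
# ---------------------------------------------------------------------------

def evaluate_against_truth(high_confidence, truth: SimTruth) -> dict:
    """Precision/recall of a predicted target set against the planted truth."""
    hc = set(high_confidence)
    true = truth.true_targets
    tp = hc & true
    precision = len(tp) / len(hc) if hc else float("nan")
    recall = len(tp) / len(true) if true else float("nan")
    per_class = {}
    for cls in ("8mer", "7mer", "6mer"):
        members = truth.targets_of_class(cls)
        per_class[cls] = len(hc & members) / len(members) if members else float("nan")
    return {
        "n_predicted": len(hc), "n_true": len(true), "n_correct": len(tp),
        "precision": precision, "recall": recall, "recall_by_class": per_class,
    }


def _clip_site_recovery(out_dir, truth: SimTruth, focal_name: str) -> float:
    """Fraction of planted sites recovered as focal-miRNA 3'UTR cluster sites."""
    sites = pd.read_csv(_p(out_dir, "clip_sites.tsv"), sep="\t")
    hit_genes = set(sites.loc[sites["mirna"] == focal_name, "gene"].dropna())
    planted = [
        (gid, off)
        for gid, row in truth.table[truth.table["is_true_target"]].iterrows()
        for off in row.sites
    ]
    if not planted:
        return float("nan")
    return sum(g in hit_genes for g, _ in planted) / len(planted)


def run_all(config: RunConfig, out_dir) -> dict:
    """Run every stage in order and assemble the machine-readable report."""
    out_dir = Path(out_dir)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    for name, fn in (
        ("simulate", stage_simulate), ("quant", stage_quant),
        ("clip", stage_clip), ("meta", stage_meta),
    ):
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)

    truth = SimTruth.from_json_dict(io.read_json(_p(out_dir, "truth.json")))
    manifest = io.read_json(_p(out_dir, "datasets.json"))
    hc = set(_p(out_dir, "high_confidence_targets.txt").read_text().split())
    report["evaluation"] = evaluate_against_truth(hc, truth)
    report["evaluation"]["clip_site_recovery"] = _clip_site_recovery(
        out_dir, truth, manifest["focal"]
    )
    te = pd.read_csv(_p(out_dir, "translation_efficiency.tsv"), sep="\t", index_col=0)
    targets_with_te = te.index.intersection(sorted(truth.true_targets))
    report["evaluation"]["median_delta_te_targets"] = (
        float(te.loc[targets_with_te, "delta_te"].median())
        if len(targets_with_te) else float("nan")
    )
    # internal consistency of the count chain
    m = report["stages"]["meta"]
    assert (
        m["n_high_confidence"] <= m["n_candidates_with_seed"]
        <= m["n_candidates"] <= m["n_universe"]
    )
    io.write_json(_p(out_dir, "report.json"), report)
    return report
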