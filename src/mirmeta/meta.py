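"""Gain/loss-of-function expression meta-analysis of miRNA targets.

A gene regulated by the miRNA should move against the miRNA in every
experiment: up in each knockout (loss-of-function, LOF) comparison and down in
each overexpression (gain-of-function, GOF) comparison.  This module builds
that sign-consistent candidate intersection over the universe of genes
detected in every dataset, quantifies 7/8mer seed-site enrichment among
candidates with a hypergeometric tail (plus the two negative controls: a
size-matched random gene set and the anti-correlated set), aggregates the
datasets into a ranked correlation metric, tests per-seed-class CDF shifts
with one-sided two-sample K-S tests, and intersects seed-filtered candidates
with CLIP-bound genes into the high-confidence target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import hypergeom_enrichment_p, ks_one_sided

SEED_OK = frozenset({"7mer", "8mer"})
MIN_CLASS_N = 5


@dataclass
class ExpressionDataset:
    """Per-gene log2 fold change for one comparison."""

    name: str
    direction: str  # LOF (KO vs WT), GOF (induced vs uninduced), or OTHER
    log2fc: pd.Series

    def __post_init__(self):
        if self.direction not in ("LOF", "GOF", "OTHER"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.log2fc.index.has_duplicates:
            raise ValueError(f"{self.name}: duplicate gene ids")
        if not np.isfinite(self.log2fc.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.name}: non-finite log2fc values")


@dataclass
class MetaPanel:
    lof_datasets: list
    gof_datasets: list
    universe: pd.Index = field(init=False)

    def __post_init__(self):
        if not self.lof_datasets or not self.gof_datasets:
            raise ValueError("need >= 1 LOF and >= 1 GOF dataset")
        idx = None
        for ds in self.lof_datasets + self.gof_datasets:
            idx = ds.log2fc.index if idx is None else idx.intersection(ds.log2fc.index)
        self.universe = idx.sort_values()

    def all_datasets(self):
        return list(self.lof_datasets) + list(self.gof_datasets)


@dataclass
class EnrichmentReport:
    observed: int
    n_candidates: int
    background_rate: float
    fold: float
    p: float
    controls: dict = field(default_factory=dict)


def sign_consistent_candidates(panel: MetaPanel) -> pd.DataFrame:
    """Candidate flags over the panel universe.

    A gene is a candidate iff log2fc > 0 in every LOF dataset and < 0 in every
    GOF dataset (strict inequalities; an exact zero anywhere disqualifies).
    Genes missing from any dataset are outside the universe, never imputed.
    """
    if len(panel.universe) == 0:
        raise ValueError("empty universe")
    up = pd.Series(True, index=panel.universe)
    for ds in panel.lof_datasets:
        up &= ds.log2fc.reindex(panel.universe) > 0
    down = pd.Series(True, index=panel.universe)
    for ds in panel.gof_datasets:
        down &= ds.log2fc.reindex(panel.universe) < 0
    return pd.DataFrame(
        {"up_in_all_lof": up, "down_in_all_gof": down, "candidate": up & down}
    )


def anticorrelated_set(panel: MetaPanel) -> set:
    """Genes positively correlated with the miRNA: down in all LOF, up in all GOF."""
    down = pd.Series(True, index=panel.universe)
    for ds in panel.lof_datasets:
        down &= ds.log2fc.reindex(panel.universe) < 0
    up = pd.Series(True, index=panel.universe)
    for ds in panel.gof_datasets:
        up &= ds.log2fc.reindex(panel.universe) > 0
    return set(panel.universe[down & up])


def seed_enrichment(
    candidates, seed_classes: pd.Series, universe, rng,
    control_sets: dict | None = None, seed_ok=SEED_OK,
) -> EnrichmentReport:
    """Hypergeometric 7/8mer seed enrichment among candidate genes.

    ``seed_classes`` maps every universe gene to its seed class.  The report
    always carries a size-matched random control drawn from the universe; any
    extra ``control_sets`` (e.g. the anti-correlated set) are evaluated the
    same way.
    """
    universe = pd.Index(universe)
    seeded = set(universe[seed_classes.reindex(universe).isin(seed_ok)])
    n_universe, k_seeded = len(universe), len(seeded)
    background_rate = k_seeded / n_universe if n_universe else 0.0

    def evaluate(genes):
        genes = set(genes) & set(universe)
        obs = len(genes & seeded)
        n = len(genes)
        if n == 0:
            return 0, 0, np.nan, 1.0
        fold = (obs / n) / background_rate if background_rate > 0 else np.nan
        return obs, n, fold, hypergeom_enrichment_p(obs, n_universe, k_seeded, n)

    obs, n, fold, p = evaluate(candidates)
    controls = {}
    random_set = rng.choice(universe.to_numpy(), size=min(n, n_universe), replace=False)
    for name, genes in {"random": set(random_set), **(control_sets or {})}.items():
        c_obs, c_n, c_fold, c_p = evaluate(genes)
        controls[name] = {"observed": c_obs, "n": c_n, "fold": c_fold, "p": c_p}
    return EnrichmentReport(
        observed=obs, n_candidates=n, background_rate=background_rate,
        fold=fold, p=p, controls=controls,
    )


def rank_correlation_metric(panel: MetaPanel) -> pd.Series:
    """Rank of summed per-dataset ranks; 1 = most consistently anti-correlated.

    In each LOF dataset the most upregulated gene gets rank 1; in each GOF
    dataset the most downregulated gets rank 1; the per-dataset ranks are
    summed and the sums ranked.  Ties receive average ranks at both stages.
    """
    ranks = []
    for ds in panel.lof_datasets:
        ranks.append(ds.log2fc.reindex(panel.universe).rank(ascending=False, method="average"))
    for ds in panel.gof_datasets:
        ranks.append(ds.log2fc.reindex(panel.universe).rank(ascending=True, method="average"))
    total = sum(ranks)
    return total.rank(ascending=True, method="average").rename("rank_metric")


def cdf_shift_tests(
    dataset: ExpressionDataset, seed_classes: pd.Series, alternative: str | None = None
) -> pd.DataFrame:
    """One-sided K-S of each seed class's log2fc against the no-match class.

    Direction follows the dataset: in a LOF comparison seed-match genes should
    sit right of (greater than) the no-match distribution, in a GOF comparison
    left of it.  Classes with fewer than 5 genes are reported with p = NaN.
    """
    if alternative is None:
        alternative = {"LOF": "greater", "GOF": "less"}.get(dataset.direction)
        if alternative is None:
            raise ValueError("direction OTHER requires an explicit alternative")
    values = dataset.log2fc
    classes = seed_classes.reindex(values.index).fillna("none")
    none_vals = values[classes == "none"].to_numpy()
    if len(none_vals) == 0:
        raise ValueError("no-match class is empty")
    rows = []
    for cls in ("8mer", "7mer", "6mer"):
        vals = values[classes == cls].to_numpy()
        if len(vals) < MIN_CLASS_N:
            rows.append((cls, len(vals), np.nan, np.nan))
            continue
        d, p = ks_one_sided(vals, none_vals, alternative=alternative)
        rows.append((cls, len(vals), d, p))
    return pd.DataFrame(rows, columns=["seed_class", "n", "D", "p"]).set_index("seed_class")


def meta_result(
    panel: MetaPanel, seed_classes: pd.Series, clip_targets=(), seed_ok=SEED_OK
) -> pd.DataFrame:
    """Per-gene MetaResult table over the panel universe."""
    df = sign_consistent_candidates(panel)
    df["seed_class"] = seed_classes.reindex(df.index).fillna("none")
    df["rank_metric"] = rank_correlation_metric(panel)
    df["in_clip"] = df.index.isin(set(clip_targets))
    df["high_confidence"] = df["candidate"] & df["seed_class"].isin(seed_ok) & df["in_clip"]
    return df


def high_confidence_targets(result: pd.DataFrame) -> set:
    """Candidates with 7/8mer seed sites that are also CLIP-bound."""
    return set(result.index[result["high_confidence"]])


def target_response(
    dataset: ExpressionDataset, targets, universe, alternative: str = "greater",
    top_k: int = 20,
) -> dict:
    """Response of a target set in an independent perturbation dataset.

    One-sided K-S of targets vs non-targets (default alternative: targets
    upregulated) plus the top-k targets ranked by log2fc.
    """
    universe = pd.Index(universe)
    targets = set(targets) & set(universe)
    if not targets:
        raise ValueError("empty target set")
    values = dataset.log2fc.reindex(universe)
    t_vals = values[values.index.isin(targets)].to_numpy()
    nt_vals = values[~values.index.isin(targets)].to_numpy()
    d, p = ks_one_sided(t_vals, nt_vals, alternative=alternative)
    ascending = alternative == "less"
    table = (
        values[values.index.isin(targets)]
        .sort_values(ascending=ascending)
        .head(top_k)
        .rename("log2fc")
        .to_frame()
    )
    return {"n_targets": len(t_vals), "n_other": len(nt_vals), "D": d, "p": p,
            "top_table": table}
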