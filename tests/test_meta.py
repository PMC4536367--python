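"""Sign-consistent candidates, enrichment, rank metric, K-S shift tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirmeta.meta import (
    ExpressionDataset,
    MetaPanel,
    anticorrelated_set,
    cdf_shift_tests,
    high_confidence_targets,
    meta_result,
    rank_correlation_metric,
    seed_enrichment,
    sign_consistent_candidates,
    target_response,
)
from mirmeta.stats import ks_one_sided


def make_panel(lof_values, gof_values, genes=None):
    """Panels from per-dataset value lists (one value per gene)."""
    genes = genes or [f"g{i}" for i in range(len(lof_values[0]))]
    lof = [
        ExpressionDataset(name=f"lof{i}", direction="LOF",
                          log2fc=pd.Series(v, index=genes, dtype=float))
        for i, v in enumerate(lof_values)
    ]
    gof = [
        ExpressionDataset(name=f"gof{i}", direction="GOF",
                          log2fc=pd.Series(v, index=genes, dtype=float))
        for i, v in enumerate(gof_values)
    ]
    return MetaPanel(lof_datasets=lof, gof_datasets=gof)


def brute_ks_one_sided(x, y):
    """Max one-sided CDF difference F_y - F_x over all data points."""
    d = 0.0
    for t in list(x) + list(y):
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        d = max(d, fy - fx)
    return d


class TestCandidates:
    def test_consistent_gene_is_candidate(self):
        panel = make_panel([[0.1], [0.5], [0.2]], [[-0.3], [-0.1]], genes=["g"])
        df = sign_consistent_candidates(panel)
        assert bool(df.loc["g", "candidate"])

    def test_two_of_three_lof_insufficient(self):
        panel = make_panel([[0.1], [0.5], [-0.2]], [[-0.3], [-0.1]], genes=["g"])
        assert not sign_consistent_candidates(panel).loc["g", "candidate"]

    def test_exact_zero_disqualifies(self):
        panel = make_panel([[0.0], [0.5], [0.2]], [[-0.3], [-0.1]], genes=["g"])
        df = sign_consistent_candidates(panel)
        assert not df.loc["g", "candidate"] and not df.loc["g", "up_in_all_lof"]

    def test_universe_is_dataset_intersection(self):
        lof = [ExpressionDataset("l", "LOF", pd.Series({"a": 1.0, "b": 1.0}))]
        gof = [ExpressionDataset("g", "GOF", pd.Series({"b": -1.0, "c": -1.0}))]
        panel = MetaPanel(lof_datasets=lof, gof_datasets=gof)
        assert list(panel.universe) == ["b"]

    def test_candidate_set_shrinks_with_more_datasets(self, rng):
        genes = [f"g{i}" for i in range(200)]
        vals = [rng.standard_normal(200) for _ in range(4)]
        small = make_panel([vals[0]], [vals[1]], genes=genes)
        big = make_panel([vals[0], vals[2]], [vals[1], vals[3]], genes=genes)
        c_small = set(small.universe[sign_consistent_candidates(small)["candidate"]])
        c_big = set(big.universe[sign_consistent_candidates(big)["candidate"]])
        assert c_big <= c_small

    def test_anticorrelated_set(self):
        panel = make_panel([[-0.1, 0.2], [-0.4, 0.1]], [[0.3, -0.2]], genes=["a", "b"])
        assert anticorrelated_set(panel) == {"a"}


class TestSeedEnrichment:
    def classes(self, genes, seeded):
        return pd.Series({g: ("7mer" if g in seeded else "none") for g in genes})

    def test_matches_exhaustive_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        seeded = set(genes[:5])
        classes = self.classes(genes, seeded)
        for cand in [set(genes[2:7]), set(genes[:3]), set(genes[8:])]:
            rep = seed_enrichment(cand, classes, genes, rng)
            obs = len(cand & seeded)
            hits = total = 0
            for combo in itertools.combinations(genes, len(cand)):
                total += 1
                hits += len(set(combo) & seeded) >= obs
            assert rep.p == pytest.approx(hits / total)

    def test_spec_worked_example(self, rng):
        # universe 20, K=5 seeded, 5 candidates of which 4 seeded
        genes = [f"g{i}" for i in range(20)]
        classes = self.classes(genes, set(genes[:5]))
        rep = seed_enrichment(set(genes[:4]) | {genes[10]}, classes, genes, rng)
        hits = total = 0
        for combo in itertools.combinations(range(20), 5):
            total += 1
            hits += len(set(combo) & set(range(5))) >= 4
        assert rep.p == pytest.approx(hits / total)
        assert rep.fold == pytest.approx((4 / 5) / (5 / 20))  # 3.2

    def test_all_universe_seeded(self, rng):
        genes = ["a", "b", "c"]
        classes = pd.Series({g: "8mer" for g in genes})
        rep = seed_enrichment({"a", "b"}, classes, genes, rng)
        assert rep.p == 1.0 and rep.fold == pytest.approx(1.0)

    def test_empty_candidates(self, rng):
        genes = ["a", "b"]
        rep = seed_enrichment(set(), self.classes(genes, {"a"}), genes, rng)
        assert rep.p == 1.0 and rep.observed == 0

    def test_controls_present(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rep = seed_enrichment(set(genes[:6]), self.classes(genes, set(genes[:10])),
                              genes, rng, control_sets={"anticorrelated": set(genes[20:])})
        assert set(rep.controls) == {"random", "anticorrelated"}
        assert rep.controls["random"]["n"] == 6


class TestRankMetric:
    def test_most_consistent_gene_ranks_first(self):
        panel = make_panel(
            [[3.0, 1.0, -1.0], [2.0, 0.5, -0.5], [1.0, 0.1, 0.0]],
            [[-3.0, -1.0, 1.0], [-2.0, 0.2, 0.4]],
        )
        metric = rank_correlation_metric(panel)
        assert metric["g0"] == 1.0

    def test_hand_computed_three_genes(self):
        panel = make_panel([[0.5, -0.2, 0.1]], [[-0.4, 0.3, -0.6]])
        # LOF ranks (desc): g0=1, g2=2, g1=3 ; GOF ranks (asc): g2=1, g0=2, g1=3
        # sums: g0=3, g1=6, g2=3 -> final ranks: g0=1.5, g2=1.5, g1=3
        metric = rank_correlation_metric(panel)
        assert metric.tolist() == [1.5, 3.0, 1.5]

    def test_tied_profiles_get_equal_metric(self):
        panel = make_panel([[0.5, 0.5, -1.0]], [[-0.5, -0.5, 1.0]])
        metric = rank_correlation_metric(panel)
        assert metric["g0"] == metric["g1"]

    def test_invariant_under_monotone_transforms(self, rng):
        genes = [f"g{i}" for i in range(50)]
        vals = [rng.standard_normal(50) for _ in range(5)]
        base = make_panel(vals[:3], vals[3:], genes=genes)
        warped = make_panel(
            [np.exp(v) for v in vals[:3]], [v ** 3 for v in vals[3:]], genes=genes
        )
        pd.testing.assert_series_equal(
            rank_correlation_metric(base), rank_correlation_metric(warped)
        )


class TestCdfShift:
    def dataset(self, values, classes, direction="GOF"):
        genes = [f"g{i}" for i in range(len(values))]
        ds = ExpressionDataset("d", direction, pd.Series(values, index=genes, dtype=float))
        return ds, pd.Series(classes, index=genes)

    def test_identical_distributions(self):
        ds, cls = self.dataset([0.0, 1.0, 2.0] * 4, ["8mer", "none"] * 6)
        # 8mer sample == none sample pointwise -> D = 0, p = 1
        tab = cdf_shift_tests(ds, cls)
        row = tab.loc["8mer"]
        assert row["D"] == 0.0 and row["p"] == 1.0

    def test_disjoint_supports_gof(self):
        values = [-1.0] * 6 + [0.0] * 6
        classes = ["8mer"] * 6 + ["none"] * 6
        ds, cls = self.dataset(values, classes, direction="GOF")
        assert cdf_shift_tests(ds, cls).loc["8mer", "D"] == 1.0

    def test_small_class_reported_na(self):
        ds, cls = self.dataset([0.1, 0.2, -0.1, 0.0, 0.3, 0.4],
                               ["8mer"] * 2 + ["none"] * 4)
        assert math.isnan(cdf_shift_tests(ds, cls).loc["8mer", "p"])

    def test_d_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n, m = int(rng.integers(2, 25)), int(rng.integers(2, 25))
            x = rng.standard_normal(n)
            y = rng.standard_normal(m) + rng.uniform(-1, 1)
            d, _ = ks_one_sided(x, y, alternative="greater")
            assert d == pytest.approx(brute_ks_one_sided(x, y))

    def test_p_matches_permutation_oracle_small(self):
        x, y = [-1.0, 0.0, 1.0], [0.0, 1.0, 2.0]
        d, p = ks_one_sided(x, y, alternative="greater")
        pool = x + y
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            a = [pool[i] for i in idx]
            b = [pool[i] for i in range(6) if i not in idx]
            total += 1
            hits += brute_ks_one_sided(a, b) >= d - 1e-12
        assert d == pytest.approx(brute_ks_one_sided(x, y))
        assert p == pytest.approx(hits / total)

    def test_asymptotic_formula_used_for_large_samples(self, rng):
        x = rng.standard_normal(150)
        y = rng.standard_normal(150) + 0.5
        d, p = ks_one_sided(y, x, alternative="greater")
        assert p == pytest.approx(math.exp(-2 * d * d * 150 * 150 / 300))


class TestHighConfidence:
    def test_set_logic(self):
        panel = make_panel(
            [[0.5, 0.4, 0.3, -0.1], [0.2, 0.1, 0.6, 0.3]],
            [[-0.5, -0.2, -0.1, -0.4]],
            genes=["a", "b", "c", "d"],
        )
        classes = pd.Series({"a": "8mer", "b": "none", "c": "7mer", "d": "8mer"})
        result = meta_result(panel, classes, clip_targets={"a", "b", "d"})
        # a: candidate + seed + clip; b: no seed; c: not in clip; d: not candidate
        assert high_confidence_targets(result) == {"a"}
        assert result.loc["c", "candidate"] and not result.loc["c", "high_confidence"]

    def test_intersection_examples(self):
        panel = make_panel([[1.0, 1.0, 1.0]], [[-1.0, -1.0, -1.0]],
                           genes=["a", "b", "c"])
        classes = pd.Series({"a": "7mer", "b": "7mer", "c": "7mer"})
        assert high_confidence_targets(meta_result(panel, classes, {"b", "c"})) == {"b", "c"}
        assert high_confidence_targets(meta_result(panel, classes, set())) == set()


class TestTargetResponse:
    def test_toy_table_sorted(self):
        ds = ExpressionDataset(
            "hras", "OTHER",
            pd.Series({"a": 2.0, "b": 0.5, "c": 1.0, "d": -1.0, "e": 0.0, "f": 0.1}),
        )
        out = target_response(ds, {"a", "b", "c"}, ds.log2fc.index, top_k=3)
        assert list(out["top_table"].index) == ["a", "c", "b"]

    def test_shifted_targets_significant(self, rng):
        genes = [f"g{i}" for i in range(120)]
        vals = rng.standard_normal(120)
        vals[:60] += 1.0
        ds = ExpressionDataset("d", "OTHER", pd.Series(vals, index=genes))
        out = target_response(ds, set(genes[:60]), genes)
        assert out["p"] < 0.01

    def test_null_calibration(self):
        """Under the null the one-sided K-S p rejects at ~ the nominal rate."""
        rejections = 0
        n_runs = 200
        for i in range(n_runs):
            r = np.random.default_rng(1000 + i)
            genes = [f"g{i}" for i in range(100)]
            ds = ExpressionDataset("d", "OTHER",
                                   pd.Series(r.standard_normal(100), index=genes))
            out = target_response(ds, set(genes[:50]), genes)
            rejections += out["p"] < 0.05
        assert 0.01 <= rejections / n_runs <= 0.10

    def test_empty_targets(self):
        ds = ExpressionDataset("d", "OTHER", pd.Series({"a": 1.0}))
        with pytest.raises(ValueError):
            target_response(ds, set(), ["a"])
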