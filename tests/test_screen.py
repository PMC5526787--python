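"""Depletion analysis: filtering, LFC, percentiles, tests and hit calls."""

import numpy as np
import pandas as pd
import pytest

from croatan import screen
from croatan import simulate as sim
from croatan.errors import EmptyResultError, ValidationError
from croatan.screen import (dual_construct_decomposition, filter_min_reference,
                            gene_hits, gene_percentile, group_tests,
                            log_fold_change)


def small_table(ref_counts, final_counts, replicate="rep1"):
    rows = []
    for i, (r, f) in enumerate(zip(ref_counts, final_counts)):
        rows.append({"construct": f"c{i}", "replicate": replicate,
                     "timepoint": "reference", "count": r})
        rows.append({"construct": f"c{i}", "replicate": replicate,
                     "timepoint": "final", "count": f})
    return pd.DataFrame(rows)


class TestFilter:
    def test_count_49_dropped(self):
        t = small_table([49, 100], [10, 10])
        out = filter_min_reference(t, threshold=50)
        assert set(out["construct"]) == {"c1"}

    def test_threshold_zero_identity(self):
        t = small_table([0, 5, 100], [1, 2, 3])
        out = filter_min_reference(t, threshold=0)
        assert len(out) == len(t)

    def test_per_replicate_filtering(self):
        t = pd.concat([small_table([49, 100], [1, 1], "rep1"),
                       small_table([100, 100], [1, 1], "rep2")])
        out = filter_min_reference(t, threshold=50)
        assert set(out[out["replicate"] == "rep1"]["construct"]) == {"c1"}
        assert set(out[out["replicate"] == "rep2"]["construct"]) == {"c0", "c1"}

    def test_all_filtered_is_error(self):
        with pytest.raises(EmptyResultError):
            filter_min_reference(small_table([1, 2], [1, 1]), threshold=50)

    def test_matches_comprehension_oracle(self):
        rng = np.random.default_rng(10)
        refs = rng.integers(0, 200, size=50)
        t = small_table(refs, rng.integers(0, 200, size=50))
        out = filter_min_reference(t, threshold=50)
        expected = {f"c{i}" for i, r in enumerate(refs) if r >= 50}
        assert set(out["construct"]) == expected


class TestLfc:
    def test_identical_counts_zero(self):
        t = small_table([100, 200, 300], [100, 200, 300])
        res = log_fold_change(t)
        assert np.allclose(res.mean_lfc, 0.0, atol=1e-9)

    def test_halving_gives_minus_one(self):
        # equal library sizes: add a balancing construct
        t = small_table([100, 300], [50, 350])
        res = log_fold_change(t, pseudocount=0)
        # totals equal (400/400) so cpm ratio for c0 is exactly 1/2
        assert res.mean_lfc["c0"] == pytest.approx(-1.0)

    def test_antisymmetric_under_timepoint_swap(self):
        t = small_table([100, 250, 30], [60, 90, 77])
        swapped = t.copy()
        swapped["timepoint"] = swapped["timepoint"].map(
            {"reference": "final", "final": "reference"})
        a = log_fold_change(t, pseudocount=0).mean_lfc
        b = log_fold_change(swapped, pseudocount=0).mean_lfc
        assert np.allclose(a, -b)

    def test_zscores_standardized_per_replicate(self):
        rng = np.random.default_rng(1)
        t = small_table(rng.integers(50, 500, 40), rng.integers(50, 500, 40))
        res = log_fold_change(t)
        z = res.per_replicate["zscore"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_missing_reference_rejected(self):
        t = small_table([100], [50])
        t = t[t["timepoint"] != "reference"]
        with pytest.raises(ValidationError):
            log_fold_change(t)

    def test_planted_depletion_recovered(self):
        lib = sim.make_single_guide_library()
        counts, truth = sim.make_screen(lib, sim.ScreenConfig(rng_seed=11))
        res = log_fold_change(filter_min_reference(counts))
        eg = lib.loc[lib["class"] == "EG", "construct"]
        mean_eg = res.mean_lfc[res.mean_lfc.index.isin(eg)].mean()
        assert mean_eg == pytest.approx(truth["eg_delta"], abs=0.2)


class TestGenePercentile:
    def test_distinct_lfcs_midpoint_convention(self):
        res = screen.DepletionResult(
            per_replicate=pd.DataFrame(),
            mean_lfc=pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0],
                               index=[f"c{i}" for i in range(5)]))
        out = gene_percentile(res, {f"c{i}": "g" for i in range(5)})
        got = out.sort_values("lfc")["depletion_percentile"].tolist()
        assert got == [90.0, 70.0, 50.0, 30.0, 10.0]

    def test_all_tied_is_50(self):
        res = screen.DepletionResult(
            per_replicate=pd.DataFrame(),
            mean_lfc=pd.Series([1.0] * 4, index=[f"c{i}" for i in range(4)]))
        out = gene_percentile(res, {f"c{i}": "g" for i in range(4)})
        assert (out["depletion_percentile"] == 50.0).all()

    def test_singleton_gene_excluded(self):
        res = screen.DepletionResult(
            per_replicate=pd.DataFrame(),
            mean_lfc=pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
        with pytest.warns(UserWarning):
            out = gene_percentile(res, {"a": "g1", "b": "g1", "c": "g2"})
        assert set(out["construct"]) == {"a", "b"}


class TestGroupTests:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        rep = group_tests({"a": x, "b": x})
        assert rep["test"] == "ranksum"
        assert rep["p_value"] > 0.9

    def test_monotone_relation_rho_one(self):
        rho, _ = screen.spearman_association([1, 2, 5, 9], [-1, 0, 2.5, 7])
        assert rho == pytest.approx(1.0)
        rep = group_tests({"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]})
        assert rep["spearman_rho"] > 0.9  # ties in group labels cap rho below 1

    def test_planted_shift_power(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            if group_tests({"a": a, "b": b})["p_value"] < 0.01:
                hits += 1
        assert hits >= 38  # >= 95% power at delta = 1 sigma

    def test_friedman_for_matched_groups(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        rep = group_tests({"t1": base, "t2": base + 1, "t3": base + 2},
                          matched=True)
        assert rep["test"] == "friedman"
        assert rep["p_value"] < 0.01

    def test_small_group_excluded(self):
        with pytest.warns(UserWarning):
            rep = group_tests({"a": [1.0], "b": [1, 2, 3], "c": [4, 5, 6]})
        assert set(rep["n"]) == {"b", "c"}


class TestDualDecomposition:
    def meta(self):
        return sim.make_dual_library(n_eg=2, n_neg=2, guides_per_gene=3)

    def test_simple_means(self):
        meta = pd.DataFrame([
            {"construct": "e|n1", "guide_h": "e", "guide_c": "n1",
             "gene_h": "EG0", "gene_c": "NEG0", "class_h": "EG", "class_c": "NEG"},
            {"construct": "e|n2", "guide_h": "e", "guide_c": "n2",
             "gene_h": "EG0", "gene_c": "NEG0", "class_h": "EG", "class_c": "NEG"},
            {"construct": "e|e2", "guide_h": "e", "guide_c": "e2",
             "gene_h": "EG0", "gene_c": "EG0", "class_h": "EG", "class_c": "EG"},
            {"construct": "e|e3", "guide_h": "e", "guide_c": "e3",
             "gene_h": "EG0", "gene_c": "EG0", "class_h": "EG", "class_c": "EG"},
        ])
        res = screen.DepletionResult(
            per_replicate=pd.DataFrame(),
            mean_lfc=pd.Series({"e|n1": -1.0, "e|n2": -1.0,
                                "e|e2": -2.0, "e|e3": -2.0}))
        out = dual_construct_decomposition(res, meta)
        row = out[out["guide"] == "e"].iloc[0]
        assert row["neg_partner_mean"] == -1.0
        assert row["same_gene_partner_mean"] == -2.0

    def test_planted_synergy_recovered(self):
        lib = sim.make_dual_library(n_eg=3, n_neg=3, guides_per_gene=4)
        counts, _ = sim.make_screen(lib, sim.ScreenConfig(rng_seed=13))
        res = log_fold_change(filter_min_reference(counts))
        out = dual_construct_decomposition(res, lib)
        assert len(out) > 0
        stronger = (out["same_gene_partner_mean"]
                    < out["neg_partner_mean"]).mean()
        assert stronger >= 0.9

    def test_no_dual_metadata_empty_report(self):
        res = screen.DepletionResult(per_replicate=pd.DataFrame(),
                                     mean_lfc=pd.Series(dtype=float))
        out = dual_construct_decomposition(res, self.meta())
        assert out.empty


class TestGeneHits:
    def test_single_depleted_construct_not_a_hit(self):
        lfc = pd.Series({"g1_a": -5.0, "g1_b": 1.0,
                         **{f"n{i}": 0.0 for i in range(20)}})
        res = screen.DepletionResult(per_replicate=pd.DataFrame(), mean_lfc=lfc)
        gmap = {"g1_a": "g1", "g1_b": "g1", **{f"n{i}": f"ng{i // 2}"
                                               for i in range(20)}}
        table = gene_hits(res, gmap, stringency_quantiles=(10,))
        assert not table[table["gene"] == "g1"]["hit"].any()

    def test_full_stringency_saturates(self):
        rng = np.random.default_rng(2)
        lfc = pd.Series(rng.normal(size=20), index=[f"c{i}" for i in range(20)])
        res = screen.DepletionResult(per_replicate=pd.DataFrame(), mean_lfc=lfc)
        gmap = {f"c{i}": f"g{i // 2}" for i in range(20)}
        table = gene_hits(res, gmap, stringency_quantiles=(100,))
        assert table["hit"].all()

    def test_hits_monotone_in_stringency(self):
        lib = sim.make_single_guide_library()
        counts, _ = sim.make_screen(lib, sim.ScreenConfig(rng_seed=14))
        res = log_fold_change(filter_min_reference(counts))
        gmap = dict(zip(lib["construct"], lib["gene"]))
        table = gene_hits(res, gmap)
        hit_sets = {q: set(sub[sub["hit"]]["gene"])
                    for q, sub in table.groupby("stringency_pct")}
        qs = sorted(hit_sets)
        for a, b in zip(qs, qs[1:]):
            assert hit_sets[a] <= hit_sets[b]

    def test_planted_screen_tpr_above_fpr(self):
        lib = sim.make_single_guide_library()
        counts, _ = sim.make_screen(lib, sim.ScreenConfig(rng_seed=14))
        res = log_fold_change(filter_min_reference(counts))
        gmap = dict(zip(lib["construct"], lib["gene"]))
        labels = dict(zip(lib["gene"], lib["class"]))
        rates = gene_hits(res, gmap, labels).attrs["rates"]
        assert (rates["tpr"] > rates["fpr"]).all()
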