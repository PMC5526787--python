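"""Microhomology enumeration, repair-likelihood fit, FSM assessment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from croatan import repair
from croatan import simulate as sim
from croatan.errors import FitError, ValidationError
from croatan.repair import (MicrohomologyPair, RepairModel, assess_fsm,
                            compute_hej_cutoff, enumerate_microhomologies,
                            fit_repair_model, predict_resolution)


def oracle_microhomologies(s, cut, min_len, window):
    """O(n^2 L) substring-comparison oracle: maximal flanking repeats."""
    out = set()
    lo, hi = max(0, cut - window), min(len(s), cut + window)
    for u in range(lo, cut):
        for d in range(cut, hi):
            max_len = min(cut - u, hi - d)
            L = 0
            while L < max_len and s[u + L] == s[d + L]:
                L += 1
            if L < min_len:
                continue
            if u > lo and d > cut and s[u - 1] == s[d - 1]:
                continue  # sub-repeat of a longer repeat at this locus pair
            out.add((s[u:u + L], cut - (u + L), d - cut))
    return out


class TestEnumeration:
    def test_planted_repeat(self):
        # AAGTC ends at the cut; second copy 4 nt downstream
        ctx = "TTTGGAAGTC" + "CGGT" + "AAGTCTTTGG"
        pairs = enumerate_microhomologies(ctx, 10, min_len=4, window=12)
        assert len(pairs) == 1
        (p,) = pairs
        assert p.homology_seq == "AAGTC"
        assert p.deletion_length == p.dist_upstream + p.dist_downstream + 5 == 9

    def test_min_len_above_longest_repeat(self):
        ctx = "ACGTACGTACGTACGTACGT"
        assert enumerate_microhomologies(ctx, 10, min_len=15, window=10) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        s = "".join(rng.choice(list("ACGT"), size=60))
        got = {(p.homology_seq, p.dist_upstream, p.dist_downstream)
               for p in enumerate_microhomologies(s, 30, 2, 30)}
        assert got == oracle_microhomologies(s, 30, 2, 30)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), size=40))
        cut = int(rng.integers(5, 35))
        got = {(p.homology_seq, p.dist_upstream, p.dist_downstream)
               for p in enumerate_microhomologies(s, cut, 2, 15)}
        assert got == oracle_microhomologies(s, cut, 2, 15)

    def test_deletion_length_invariant(self):
        p = MicrohomologyPair("ACG", 3, 2 / 3, dist_upstream=4, dist_downstream=7)
        assert p.deletion_length == 14

    def test_cut_outside_context_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_microhomologies("ACGT", 9)


class TestFit:
    def test_parameter_recovery_with_noise(self):
        table, truth = sim.make_resolution_table(
            sim.RepairTableConfig(rng_seed=5, n_rows=500, noise_sd=0.01))
        model = fit_repair_model(table)
        assert model.intercept == pytest.approx(truth["intercept"], rel=0.10)
        for k, v in truth["coefficients"].items():
            assert model.coefficients[k] == pytest.approx(v, rel=0.10)

    def test_zero_noise_exact(self):
        table, truth = sim.make_resolution_table(
            sim.RepairTableConfig(rng_seed=5, n_rows=200, noise_sd=0.0))
        model = fit_repair_model(table)
        assert model.intercept == pytest.approx(truth["intercept"], abs=1e-8)
        for k, v in truth["coefficients"].items():
            assert model.coefficients[k] == pytest.approx(v, abs=1e-8)

    def test_constant_column_rank_deficiency(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "length": [5] * 20,
            "gc_fraction": rng.uniform(0, 1, 20),
            "distance": rng.integers(0, 10, 20),
            "frequency": rng.uniform(0, 1, 20),
        })
        with pytest.raises(FitError, match="length"):
            fit_repair_model(table)

    def test_too_few_rows(self):
        table = pd.DataFrame({"length": [1, 2], "gc_fraction": [0, 1],
                              "distance": [1, 2], "frequency": [0.1, 0.2]})
        with pytest.raises(ValidationError):
            fit_repair_model(table)


def flat_model(intercept=0.0, length=0.0, gc=0.0, dist=0.0, cutoff=None):
    return RepairModel(intercept=intercept,
                       coefficients={"length": length, "gc_fraction": gc,
                                     "distance": dist},
                       hej_cutoff=cutoff)


class TestPredict:
    def test_zero_features_gives_intercept(self):
        m = flat_model(intercept=0.3, length=1, gc=1, dist=1)
        p = MicrohomologyPair("", 0, 0.0, 0, 0)
        assert predict_resolution(m, p) == pytest.approx(0.3)

    def test_constant_model(self):
        m = flat_model(intercept=0.2)
        for p in [MicrohomologyPair("ACG", 3, 1.0, 5, 9),
                  MicrohomologyPair("AT", 2, 0.0, 0, 2)]:
            assert predict_resolution(m, p) == pytest.approx(0.2)

    def test_matches_dot_product(self):
        rng = np.random.default_rng(6)
        m = flat_model(intercept=0.1, length=0.05, gc=0.3, dist=-0.01)
        for _ in range(30):
            L = int(rng.integers(2, 10))
            gc = float(rng.uniform())
            du, dd = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            p = MicrohomologyPair("A" * L, L, gc, du, dd)
            expect = max(0.0, 0.1 + 0.05 * L + 0.3 * gc - 0.01 * (du + dd))
            assert predict_resolution(m, p) == pytest.approx(expect)

    def test_negative_prediction_clamped(self):
        m = flat_model(intercept=-1.0)
        assert predict_resolution(m, MicrohomologyPair("AC", 2, 0.5, 1, 1)) == 0.0

    def test_min_distance_mode(self):
        m = flat_model(intercept=0.0, dist=1.0)
        m.distance_mode = "min"
        p = MicrohomologyPair("AC", 2, 0.5, 3, 7)
        assert predict_resolution(m, p) == pytest.approx(3.0)


class TestFsm:
    def test_single_frameshift_repeat(self):
        # one repeat, deletion length 9 -> in frame -> fsm 0
        ctx = "TTTGGAAGTC" + "CGGT" + "AAGTCTTTGG"
        m = flat_model(intercept=0.5)
        a = assess_fsm(m, ctx, 10, min_len=4, window=12)
        assert a.fsm_likelihood == 0.0
        assert not a.passes_fsm_test

    def test_single_inframe_vs_frameshift(self):
        m = flat_model(intercept=0.5)
        # deletion length 7: upstream copy ends 0 before cut, downstream 2 after
        s = "TGCAAGTC" + "GC" + "AAGTCTTTGGCA"
        a = assess_fsm(m, s, 8, min_len=5, window=10)
        assert a.fsm_likelihood == 1.0
        assert a.passes_fsm_test

    def test_threshold_is_strict(self):
        """A likelihood exactly at the threshold must fail the test."""
        rng = np.random.default_rng(21)
        m = flat_model(intercept=0.1, length=0.05)
        s = "".join(rng.choice(list("ACGT"), size=60))
        a = assess_fsm(m, s, 30, min_len=2, window=30)
        assert 0 < a.fsm_likelihood < 1
        at_boundary = assess_fsm(m, s, 30, fsm_threshold=a.fsm_likelihood,
                                 min_len=2, window=30)
        assert not at_boundary.passes_fsm_test
        below = assess_fsm(m, s, 30, fsm_threshold=a.fsm_likelihood - 1e-9,
                           min_len=2, window=30)
        assert below.passes_fsm_test

    def test_no_homology_fails(self):
        m = flat_model(intercept=0.0)
        a = assess_fsm(m, "ACGTACGTACGTACGT", 8, min_len=2, window=8)
        assert a.hej_sum == 0.0
        assert a.fsm_likelihood is None
        assert not a.passes_fsm_test

    def test_likelihood_partition_sums_to_one(self):
        rng = np.random.default_rng(11)
        m = flat_model(intercept=0.1, length=0.05)
        s = "".join(rng.choice(list("ACGT"), size=60))
        pairs = enumerate_microhomologies(s, 30, 2, 30)
        scores = np.array([predict_resolution(m, p) for p in pairs])
        total = scores.sum()
        fsm = scores[[p.is_frameshift for p in pairs]].sum()
        inframe = scores[[not p.is_frameshift for p in pairs]].sum()
        assert fsm / total + inframe / total == pytest.approx(1.0)
        a = assess_fsm(m, s, 30, min_len=2, window=30)
        assert a.fsm_likelihood == pytest.approx(fsm / total)

    def test_hej_cutoff_gates_pass(self):
        m = flat_model(intercept=0.5, cutoff=100.0)
        s = "TGCAAGTC" + "GC" + "AAGTCTTTGGCA"
        a = assess_fsm(m, s, 8, min_len=5, window=10)
        assert a.fsm_likelihood == 1.0 and not a.passes_fsm_test


class TestHejCutoff:
    def test_median_of_three(self):
        m = flat_model(intercept=0.5)
        # three backgrounds engineered to have different numbers of repeats
        rng = np.random.default_rng(6)
        bgs = [("".join(rng.choice(list("ACGT"), size=40)), 20)
               for _ in range(3)]
        sums = [repair.hej_sum(m, s, c) for s, c in bgs]
        assert compute_hej_cutoff(m, bgs) == pytest.approx(np.median(sums))
        assert m.hej_cutoff == pytest.approx(np.median(sums))

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            compute_hej_cutoff(flat_model(), [])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        m = flat_model(intercept=0.1, length=0.05, gc=0.3, dist=-0.01)
        bgs = [("".join(rng.choice(list("ACGT"), size=60)), 30)
               for _ in range(200)]
        cut = compute_hej_cutoff(m, bgs)
        sums = sorted(repair.hej_sum(m, s, c) for s, c in bgs)
        assert cut == pytest.approx((sums[99] + sums[100]) / 2)

    def test_roundtrip_json(self, tmp_path):
        m = flat_model(intercept=0.1, length=0.05, cutoff=0.7)
        p = tmp_path / "repair.json"
        m.to_json(p)
        m2 = RepairModel.from_json(p)
        assert m2.intercept == m.intercept
        assert m2.coefficients == m.coefficients
        assert m2.hej_cutoff == 0.7
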