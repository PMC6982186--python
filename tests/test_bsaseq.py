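"""SNP-index arithmetic, window statistics, null CIs and region calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsamap import bsaseq


def random_records(rng, n=100, chroms=("Chr1", "Chr2"), max_pos=2_000_000):
    pos = np.sort(rng.choice(np.arange(1, max_pos), size=n, replace=False))
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "L_ref": rng.integers(0, 40, n),
            "L_alt": rng.integers(0, 40, n),
            "S_ref": rng.integers(0, 40, n),
            "S_alt": rng.integers(0, 40, n),
        }
    )


class TestSnpIndex:
    @pytest.mark.parametrize(
        ("ref", "alt", "expected"),
        [(30, 0, 0.0), (0, 30, 1.0), (15, 15, 0.5), (12, 18, 0.6)],
    )
    def test_values(self, ref, alt, expected):
        assert bsaseq.snp_index(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert math.isnan(bsaseq.snp_index(0, 0))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bsaseq.snp_index(-1, 5)

    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_index_in_unit_interval(self, ref, alt):
        value = bsaseq.snp_index(ref, alt)
        assert math.isnan(value) or 0.0 <= value <= 1.0


class TestFilter:
    def test_low_depth_pool_removed_and_logged(self):
        records = pd.DataFrame(
            [
                ("Chr1", 100, "A", "T", 10, 10, 3, 2),  # S depth 5 < 7
                ("Chr1", 200, "A", "T", 10, 10, 5, 5),
            ],
            columns=["chrom", "pos", "ref", "alt", "L_ref", "L_alt", "S_ref", "S_alt"],
        )
        kept, report = bsaseq.filter_snps(records, 7, 0.0)
        assert len(kept) == 1 and kept["pos"].iloc[0] == 200
        assert report.n_removed_depth == 1 and report.n_removed_index == 0

    def test_zero_thresholds_are_identity(self):
        rng = np.random.default_rng(0)
        records = random_records(rng)
        kept, report = bsaseq.filter_snps(records, 0, 0.0)
        pd.testing.assert_frame_equal(kept, records.reset_index(drop=True))
        assert report.n_retained == len(records)

    def test_survivors_match_per_record_reevaluation(self):
        rng = np.random.default_rng(42)
        records = random_records(rng, n=100)
        kept, report = bsaseq.filter_snps(records, 7, 0.3)

        def survives(row):
            lt, s_t = row.L_ref + row.L_alt, row.S_ref + row.S_alt
            if lt < 7 or s_t < 7:
                return False
            idx = [row.L_alt / lt, row.S_alt / s_t]
            return max(idx) >= 0.3

        expected = sum(survives(r) for r in records.itertuples(index=False))
        assert len(kept) == expected == report.n_retained


class TestSlidingWindows:
    def test_window_count_for_2mb_chromosome(self):
        records = pd.DataFrame(
            [("Chr1", 5_000, "A", "T", 8, 2, 5, 5)],
            columns=["chrom", "pos", "ref", "alt", "L_ref", "L_alt", "S_ref", "S_alt"],
        )
        win = bsaseq.sliding_windows(records, 1_000_000, 10_000, {"Chr1": 2_000_000})
        assert len(win) == 101
        assert (win["start"] <= 2_000_000 - 1_000_000 + 1).all()
        assert win["start"].iloc[0] == 1 and win["start"].iloc[-1] == 1_000_001

    def test_mean_of_member_snps(self):
        records = pd.DataFrame(
            [
                ("Chr1", 5_000, "A", "T", 8, 2, 5, 5),   # L index 0.2
                ("Chr1", 15_000, "A", "T", 6, 4, 5, 5),  # L index 0.4
            ],
            columns=["chrom", "pos", "ref", "alt", "L_ref", "L_alt", "S_ref", "S_alt"],
        )
        win = bsaseq.sliding_windows(records, 1_000_000, 10_000, {"Chr1": 1_000_000})
        assert len(win) == 1
        assert win["mean_index_L"].iloc[0] == pytest.approx(0.3)
        assert win["delta"].iloc[0] == pytest.approx(0.3 - 0.5)

    def test_single_snp_window_equals_snp_index(self):
        records = pd.DataFrame(
            [("Chr1", 500, "A", "T", 3, 9, 6, 6)],
            columns=["chrom", "pos", "ref", "alt", "L_ref", "L_alt", "S_ref", "S_alt"],
        )
        win = bsaseq.sliding_windows(records, 1_000, 1_000, {"Chr1": 1_000})
        assert win["mean_index_L"].iloc[0] == pytest.approx(0.75)

    def test_window_means_match_bruteforce_grouping(self):
        rng = np.random.default_rng(7)
        records = random_records(rng, n=300)
        window, step = 100_000, 20_000
        lengths = {"Chr1": 2_000_000, "Chr2": 2_000_000}
        win = bsaseq.sliding_windows(records, window, step, lengths)

        indexed = bsaseq.add_indices(records).dropna(subset=["index_L", "index_S"])
        for row in win.sample(n=40, random_state=0).itertuples(index=False):
            members = indexed[
                (indexed["chrom"] == row.chrom)
                & (indexed["pos"] >= row.start)
                & (indexed["pos"] < row.start + window)
            ]
            assert row.n_snps == len(members)
            if len(members):
                assert row.mean_index_L == pytest.approx(members["index_L"].mean())
                assert row.mean_index_S == pytest.approx(members["index_S"].mean())
            else:
                assert math.isnan(row.delta)

    def test_all_outputs_in_valid_ranges(self, depth_records):
        win = bsaseq.sliding_windows(depth_records, 1_000_000, 100_000)
        nonempty = win[win["n_snps"] > 0]
        assert nonempty["mean_index_L"].between(0, 1).all()
        assert nonempty["mean_index_S"].between(0, 1).all()
        assert nonempty["delta"].between(-1, 1).all()


class TestNullCi:
    def test_bounds_widen_at_lower_depth(self):
        ci = bsaseq.simulate_null_ci([10, 100], bulk_size=30, reps=10_000, seed=1)
        lo10, hi10 = ci.lookup(10, 0.95)
        lo100, hi100 = ci.lookup(100, 0.95)
        assert lo10 < lo100 < 0 < hi100 < hi10

    def test_bounds_vanish_in_large_depth_and_bulk_limit(self):
        ci = bsaseq.simulate_null_ci([100_000], bulk_size=10_000, reps=2_000, seed=2)
        lo, hi = ci.lookup(100_000, 0.95)
        assert abs(lo) < 0.02 and abs(hi) < 0.02

    def test_bounds_match_independent_resimulation(self):
        """Oracle: same two-stage binomial null re-simulated with the legacy
        RandomState generator, 200k replicates."""
        depth, bulk = 30, 30
        ci = bsaseq.simulate_null_ci([depth], bulk, reps=200_000, seed=3)
        lo, hi = ci.lookup(depth, 0.95)

        rs = np.random.RandomState(99)
        k_l = rs.binomial(2 * bulk, 0.5, 200_000)
        k_s = rs.binomial(2 * bulk, 0.5, 200_000)
        deltas = (
            rs.binomial(depth, k_l / (2 * bulk)) / depth
            - rs.binomial(depth, k_s / (2 * bulk)) / depth
        )
        lo_o, hi_o = np.quantile(deltas, [0.025, 0.975])
        assert lo == pytest.approx(lo_o, abs=0.01)
        assert hi == pytest.approx(hi_o, abs=0.01)

    def test_deterministic_under_fixed_seed(self):
        a = bsaseq.simulate_null_ci([30], 30, reps=1_000, seed=5)
        b = bsaseq.simulate_null_ci([30], 30, reps=1_000, seed=5)
        assert a.lookup(30, 0.95) == b.lookup(30, 0.95)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bsaseq.simulate_null_ci([30], 30, reps=50)


class TestRegionCalling:
    def test_null_deltas_call_no_regions(self):
        win = pd.DataFrame(
            {
                "chrom": "Chr1",
                "start": 1 + 10_000 * np.arange(50),
                "end": 10_000 * np.arange(50) + 1_000_000,
                "n_snps": 10,
                "mean_index_L": 0.5,
                "mean_index_S": 0.5,
                "delta": 0.0,
                "eff_depth": 30.0,
            }
        )
        ci = bsaseq.simulate_null_ci([30], 30, reps=1_000, seed=1)
        _, regions = bsaseq.attach_ci_and_call_regions(win, ci)
        assert regions.empty

    def test_empty_window_list_gives_empty_regions(self):
        ci = bsaseq.simulate_null_ci([30], 30, reps=1_000, seed=1)
        flagged, regions = bsaseq.attach_ci_and_call_regions(
            pd.DataFrame(columns=list(bsaseq.WINDOW_COLUMNS)), ci
        )
        assert regions.empty and flagged.empty

    def test_planted_locus_recovered_single_seed(self, depth_records, causal):
        filtered, _ = bsaseq.filter_snps(depth_records)
        win = bsaseq.sliding_windows(filtered, 1_000_000, 100_000)
        depths = np.unique(np.round(win["eff_depth"].dropna()).astype(int))
        ci = bsaseq.simulate_null_ci(depths, bulk_size=30, reps=2_000, seed=8)
        win, regions = bsaseq.attach_ci_and_call_regions(win, ci)
        hits = regions[
            (regions["chrom"] == causal.chromosome)
            & (regions["start"] <= causal.position)
            & (regions["end"] >= causal.position)
        ]
        assert len(hits) == 1
        assert hits["peak_delta"].iloc[0] < -0.4  # strong negative excursion

    def test_ci_bounds_bracket_zero(self, depth_records):
        filtered, _ = bsaseq.filter_snps(depth_records)
        win = bsaseq.sliding_windows(filtered, 1_000_000, 100_000)
        ci = bsaseq.simulate_null_ci([30], bulk_size=30, reps=2_000, seed=8)
        win, _ = bsaseq.attach_ci_and_call_regions(win, ci)
        nonempty = win[win["n_snps"] > 0]
        assert (nonempty["ci_lower"] <= 0).all() and (nonempty["ci_upper"] >= 0).all()
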