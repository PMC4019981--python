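"""WD / WD^N scoring and the background-simulation threshold."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from apmskit import (
    DataError,
    Dataset,
    PipelineConfig,
    ProteinRecord,
    build_stats_table,
    simulate_threshold,
    wd_score,
    wdn_filter,
)
from apmskit.comppass import StatsTable, permuted_wd_scores, wd_matrix

from conftest import make_run
from oracles import exhaustive_null_quantile, sample_from_exhaustive_null


def make_table(xbar: dict, n: dict) -> StatsTable:
    """StatsTable from dicts {bait: {prey: value}}, with f and omega
    recomputed by plain loops (independent of the library's vectorization)."""
    xbar_df = pd.DataFrame(xbar).T.fillna(0.0).sort_index()
    n_df = pd.DataFrame(n).T.fillna(0).astype(int).reindex_like(xbar_df).fillna(0).astype(int)
    f = {}
    omega = {}
    for prey in xbar_df.columns:
        vals = [xbar_df.loc[b, prey] for b in xbar_df.index if n_df.loc[b, prey] > 0]
        f[prey] = len(vals)
        if len(vals) >= 2:
            m = sum(vals) / len(vals)
            s = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            omega[prey] = max(1.0, s / m)
        else:
            omega[prey] = 1.0
    return StatsTable(xbar=xbar_df, n=n_df, k=len(xbar_df),
                      f=pd.Series(f), omega=pd.Series(omega))


def dataset_from_nsaf(nsaf: pd.DataFrame, run_to_bait: dict) -> Dataset:
    proteins = {p: ProteinRecord(p, 100) for p in nsaf.columns}
    for b in set(run_to_bait.values()):
        proteins.setdefault(b, ProteinRecord(b, 100, True))
    runs = [make_run(rid, bait, {bait: 1}, replicate=i + 1)
            for i, (rid, bait) in enumerate(run_to_bait.items())]
    return Dataset(proteins=proteins, runs=runs)


class TestBuildStatsTable:
    def test_singleton_prey_has_unit_frequency_and_weight(self):
        nsaf = pd.DataFrame(
            {"A": [0.5, 0.6, 0.9, 0.8], "P": [0.5, 0.4, 0.0, 0.0],
             "B": [0.0, 0.0, 0.1, 0.2]},
            index=["r1", "r2", "r3", "r4"])
        ds = dataset_from_nsaf(nsaf, {"r1": "A", "r2": "A", "r3": "B", "r4": "B"})
        table = build_stats_table(nsaf, ds)
        assert table.k == 2
        assert table.f["P"] == 1
        assert table.omega["P"] == 1.0
        assert table.n.loc["A", "P"] == 2
        assert table.xbar.loc["A", "P"] == pytest.approx(0.45)

    def test_identical_xbar_across_baits_floors_omega(self):
        nsaf = pd.DataFrame({"P": [0.2, 0.2, 0.2], "A": [0.8, 0.0, 0.0],
                             "B": [0.0, 0.8, 0.0], "C": [0.0, 0.0, 0.8]},
                            index=["r1", "r2", "r3"])
        ds = dataset_from_nsaf(nsaf, {"r1": "A", "r2": "B", "r3": "C"})
        table = build_stats_table(nsaf, ds)
        assert table.f["P"] == 3
        assert table.omega["P"] == 1.0  # zero spread -> CV 0 -> floored

    def test_low_cv_floors_omega(self):
        # xbar {0.1, 0.3}: sample sd 0.1414, mean 0.2, CV ~0.707 < 1
        nsaf = pd.DataFrame({"P": [0.1, 0.3], "A": [0.9, 0.0], "B": [0.0, 0.7]},
                            index=["r1", "r2"])
        ds = dataset_from_nsaf(nsaf, {"r1": "A", "r2": "B"})
        table = build_stats_table(nsaf, ds)
        assert table.omega["P"] == 1.0

    def test_high_cv_exceeds_floor(self):
        nsaf = pd.DataFrame({"P": [0.001, 0.5], "A": [0.999, 0.0], "B": [0.0, 0.5]},
                            index=["r1", "r2"])
        ds = dataset_from_nsaf(nsaf, {"r1": "A", "r2": "B"})
        table = build_stats_table(nsaf, ds)
        expected_cv = np.std([0.001, 0.5], ddof=1) / np.mean([0.001, 0.5])
        assert table.omega["P"] == pytest.approx(expected_cv)
        assert table.omega["P"] > 1.0

    def test_bait_self_entry_excluded(self):
        nsaf = pd.DataFrame({"A": [0.6, 0.5], "B": [0.4, 0.5]}, index=["r1", "r2"])
        ds = dataset_from_nsaf(nsaf, {"r1": "A", "r2": "B"})
        table = build_stats_table(nsaf, ds)
        assert table.xbar.loc["A", "A"] == 0.0
        assert table.f["A"] == 1  # only bait B detects protein A


class TestWdScore:
    def test_hand_computed_value(self):
        table = make_table({"A": {"P": 0.04}, "B": {}, "C": {}},
                           {"A": {"P": 2}})
        # k=3, f=1, omega=1, n=2: sqrt(0.04 * 9) = 0.6
        assert wd_score(table, "A", "P") == pytest.approx(0.6)

    def test_ubiquitous_prey_reduces_to_sqrt_xbar(self):
        xbar = {b: {"P": 0.09} for b in "ABC"}
        n = {b: {"P": 1} for b in "ABC"}
        table = make_table(xbar, n)
        assert table.f["P"] == 3
        assert wd_score(table, "A", "P") == pytest.approx(math.sqrt(0.09))

    def test_zero_xbar_scores_zero(self):
        table = make_table({"A": {"P": 0.3}, "B": {"P": 0.0}}, {"A": {"P": 1}})
        assert wd_score(table, "B", "P") == 0.0

    def test_monotone_in_xbar_and_replication(self):
        scores_x = [wd_score(make_table({"A": {"P": x}, "B": {}}, {"A": {"P": 1}}),
                             "A", "P") for x in (0.01, 0.1, 0.5)]
        assert scores_x == sorted(scores_x) and len(set(scores_x)) == 3
        scores_n = [wd_score(make_table({"A": {"P": 0.1}, "B": {}}, {"A": {"P": n}}),
                             "A", "P") for n in (1, 2, 3)]
        assert scores_n == sorted(scores_n) and len(set(scores_n)) == 3

    def test_matrix_matches_scalar(self):
        table = make_table(
            {"A": {"P": 0.2, "Q": 0.05}, "B": {"Q": 0.1}},
            {"A": {"P": 2, "Q": 1}, "B": {"Q": 2}})
        mat = wd_matrix(table)
        for bait in table.baits:
            for prey in table.preys:
                assert mat.loc[bait, prey] == pytest.approx(wd_score(table, bait, prey))


class TestSimulateThreshold:
    def test_degenerate_table_gives_deterministic_threshold(self):
        # every prey in exactly one bait with the same xbar and n: every
        # simulated row is constant, omega = 1, f = k, so every simulated
        # WD equals sqrt(xbar) -- and every observed entry passes
        xbar = {b: {f"P{i}": 0.04} for i, b in enumerate("ABC")}
        n = {b: {f"P{i}": 2} for i, b in enumerate("ABC")}
        table = make_table(xbar, n)
        cfg = PipelineConfig(rng_seed=5, n_permutations=10)
        thr = simulate_threshold(table, cfg)
        assert thr == pytest.approx(0.2)
        res = wdn_filter(table, thr, cfg)
        assert res.passed_wdn.all()

    def test_threshold_scales_with_sqrt_of_global_rescaling(self):
        table = make_table(
            {"A": {"P": 0.2, "Q": 0.05}, "B": {"Q": 0.1, "R": 0.01}, "C": {"R": 0.02}},
            {"A": {"P": 2, "Q": 1}, "B": {"Q": 2, "R": 1}, "C": {"R": 2}})
        scaled = StatsTable(xbar=table.xbar * 4.0, n=table.n, k=table.k,
                            f=table.f, omega=table.omega)
        cfg = PipelineConfig(rng_seed=3, n_permutations=50)
        t1, t2 = simulate_threshold(table, cfg), simulate_threshold(scaled, cfg)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-9)
        wdn1 = wdn_filter(table, t1, cfg)
        wdn2 = wdn_filter(scaled, t2, cfg)
        assert wdn1.wdn.to_numpy() == pytest.approx(wdn2.wdn.to_numpy(), rel=1e-9)

    def test_planted_enriched_entry_passes_on_toy(self):
        # 3 baits x 4 preys; Q is background-like everywhere, the planted
        # entry is 10x enriched and unique to bait A
        xbar = {"A": {"PLANT": 0.4, "Q1": 0.04, "Q2": 0.05},
                "B": {"Q1": 0.05, "Q2": 0.04, "Q3": 0.05},
                "C": {"Q1": 0.04, "Q3": 0.04}}
        n = {"A": {"PLANT": 2, "Q1": 2, "Q2": 2},
             "B": {"Q1": 2, "Q2": 2, "Q3": 2},
             "C": {"Q1": 2, "Q3": 2}}
        table = make_table(xbar, n)
        cfg = PipelineConfig(rng_seed=11, n_permutations=400)
        thr = simulate_threshold(table, cfg)
        oracle = exhaustive_null_quantile(table.xbar, table.n, 0.95)
        assert thr == pytest.approx(oracle, rel=0.05)
        res = wdn_filter(table, thr, cfg)
        assert res[(res.bait == "A") & (res.prey == "PLANT")].iloc[0].wdn > 1.0

    def test_sampled_pool_matches_exhaustive_enumeration(self):
        xbar = {"A": {"P": 0.3, "Q": 0.02, "R": 0.05},
                "B": {"Q": 0.04, "R": 0.06, "S": 0.01},
                "C": {"Q": 0.03, "S": 0.02}}
        n = {"A": {"P": 2, "Q": 1, "R": 2}, "B": {"Q": 2, "R": 1, "S": 1},
             "C": {"Q": 2, "S": 2}}
        table = make_table(xbar, n)
        n_fail = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sampled = permuted_wd_scores(table, 300, rng)
            oracle = sample_from_exhaustive_null(
                table.xbar, table.n, 300, np.random.default_rng(1000 + seed))
            if ks_2samp(sampled, oracle).pvalue <= 0.01:
                n_fail += 1
        assert n_fail == 0

    def test_empty_table_rejected(self):
        table = make_table({"A": {"P": 0.0}, "B": {}}, {"A": {"P": 0}})
        with pytest.raises(DataError, match="non-zero"):
            simulate_threshold(table, PipelineConfig(rng_seed=1))


class TestWdnFilter:
    def test_boundary_is_inclusive(self):
        table = make_table({"A": {"P": 0.04}, "B": {}}, {"A": {"P": 1}})
        wd = wd_score(table, "A", "P")
        res = wdn_filter(table, wd, PipelineConfig(rng_seed=0))
        row = res.iloc[0]
        assert row.wdn == pytest.approx(1.0)
        assert row.passed_wdn

    def test_double_threshold_gives_wdn_two(self):
        table = make_table({"A": {"P": 0.04}, "B": {}}, {"A": {"P": 1}})
        wd = wd_score(table, "A", "P")
        res = wdn_filter(table, wd / 2.0, PipelineConfig(rng_seed=0))
        assert res.iloc[0].wdn == pytest.approx(2.0)

    def test_zero_score_never_passes(self):
        table = make_table({"A": {"P": 0.04}, "B": {"Q": 0.01}},
                           {"A": {"P": 1}, "B": {"Q": 1}})
        res = wdn_filter(table, 10.0, PipelineConfig(rng_seed=0))
        assert not res.passed_wdn.any()
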