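from math import sqrt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ihtseq import (
    ComparisonConfig,
    bh_adjust,
    call_degs,
    deg_summary,
    filter_low_counts,
    median_diff_p,
    median_null,
    run_comparison,
    simulate_null,
    stouffer_combine,
    ttest_per_gene,
)
from ihtseq.io_counts import write_deg_table
from ihtseq.simulate import SimConfig

from _oracles import bh_oracle, pooled_median_p_oracle


class TestTtest:
    def test_identical_groups_give_t0_p1(self, four_vs_four_design):
        row = np.tile([2.0, 2.0, 2.0, 2.0], 2)
        expr = pd.DataFrame([row], index=["g"], columns=list(four_vs_four_design.assignments))
        t, p = ttest_per_gene(expr, four_vs_four_design, "treated", "control")
        assert t[0] == 0.0 and p[0] == 1.0

    def test_symmetric_groups_give_p1(self, four_vs_four_design):
        row = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        expr = pd.DataFrame([row], index=["g"], columns=list(four_vs_four_design.assignments))
        _, p = ttest_per_gene(expr, four_vs_four_design, "treated", "control")
        assert p[0] == pytest.approx(1.0)

    def test_matches_pooled_sd_textbook_formula(self, four_vs_four_design):
        a = np.array([2.1, 2.3, 1.9, 2.2])
        b = np.array([1.1, 1.0, 1.3, 0.9])
        expr = pd.DataFrame(
            [np.concatenate([a, b])], index=["g"],
            columns=list(four_vs_four_design.assignments),
        )
        t, p = ttest_per_gene(expr, four_vs_four_design, "treated", "control")
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t_hand = (a.mean() - b.mean()) / sqrt(sp2 * (0.25 + 0.25))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=6)
        assert t[0] == pytest.approx(t_hand, rel=1e-12)
        assert p[0] == pytest.approx(p_hand, rel=1e-12)

    def test_missing_group_is_an_error(self, toy_log_expr, four_vs_four_design):
        with pytest.raises(ValueError, match="absent"):
            ttest_per_gene(toy_log_expr, four_vs_four_design, "ghost", "control")


class TestMedianNull:
    def test_four_vs_four_enumerates_70_splits(self, toy_log_expr, four_vs_four_design):
        cfg = ComparisonConfig(permutation_mode="exact", pooled_null=False)
        null = median_null(toy_log_expr, four_vs_four_design, "treated", "control", cfg)
        assert null.shape == (3, 70)

    def test_pooled_null_size_is_splits_times_genes(self, toy_log_expr, four_vs_four_design):
        cfg = ComparisonConfig(permutation_mode="exact")
        null = median_null(toy_log_expr, four_vs_four_design, "treated", "control", cfg)
        assert null.shape == (70 * 3,)
        assert np.all(np.diff(null) >= 0)

    def test_constant_gene_contributes_only_zeros(self, four_vs_four_design):
        expr = pd.DataFrame(
            [np.full(8, 3.5)], index=["flat"], columns=list(four_vs_four_design.assignments)
        )
        null = median_null(expr, four_vs_four_design, "treated", "control")
        np.testing.assert_array_equal(null, np.zeros(70))

    def test_p_matches_exhaustive_enumeration_oracle(self, toy_log_expr, four_vs_four_design):
        cfg = ComparisonConfig(permutation_mode="exact")
        null = median_null(toy_log_expr, four_vs_four_design, "treated", "control", cfg)
        obs, p = median_diff_p(toy_log_expr, four_vs_four_design, "treated", "control", null)
        obs_o, p_o, null_o = pooled_median_p_oracle(toy_log_expr.to_numpy(), 4)
        np.testing.assert_allclose(obs, obs_o, rtol=1e-12)
        np.testing.assert_allclose(p, p_o, rtol=1e-12)
        np.testing.assert_allclose(null, np.sort(null_o), rtol=1e-12)

    def test_observed_zero_gives_p_one(self, four_vs_four_design):
        row = [1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0]
        expr = pd.DataFrame([row], index=["g"], columns=list(four_vs_four_design.assignments))
        null = median_null(expr, four_vs_four_design, "treated", "control")
        _, p = median_diff_p(expr, four_vs_four_design, "treated", "control", null)
        assert p[0] == 1.0

    def test_observed_beyond_null_hits_smoothed_floor(self, four_vs_four_design):
        expr = pd.DataFrame(
            [np.arange(8.0)], index=["g"], columns=list(four_vs_four_design.assignments)
        )
        null = np.array([0.0, 0.1, 0.2])  # synthetic pooled null below the observation
        _, p = median_diff_p(expr, four_vs_four_design, "treated", "control", null)
        assert p[0] == pytest.approx(1.0 / (1 + 3))

    def test_exact_and_sampled_modes_agree(self, four_vs_four_design):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            rng.normal(size=(150, 8)), columns=list(four_vs_four_design.assignments)
        )
        exact_cfg = ComparisonConfig(permutation_mode="exact")
        sampled_cfg = ComparisonConfig(permutation_mode="sampled", n_perm=10_000, seed=3)
        null_e = median_null(expr, four_vs_four_design, "treated", "control", exact_cfg)
        null_s = median_null(expr, four_vs_four_design, "treated", "control", sampled_cfg)
        _, p_e = median_diff_p(expr, four_vs_four_design, "treated", "control", null_e)
        _, p_s = median_diff_p(expr, four_vs_four_design, "treated", "control", null_s)
        assert np.mean(np.abs(p_e - p_s)) < 0.01

    def test_sampled_mode_requires_enough_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            ComparisonConfig(permutation_mode="sampled", n_perm=10)


class TestStouffer:
    def test_uninformative_inputs_stay_uninformative(self):
        z, p = stouffer_combine([1.0], [1.0], [1.0], [1.0])
        assert z[0] == 0.0 and p[0] == 1.0

    def test_concordant_0p05_pair_closed_form(self):
        z, p = stouffer_combine([0.05], [0.05], [2.0], [0.5])
        assert z[0] == pytest.approx(2.771808, abs=1e-6)
        assert p[0] == pytest.approx(0.005574, abs=1e-6)

    def test_opposite_signs_cancel(self):
        z, p = stouffer_combine([0.01], [0.01], [1.0], [-1.0])
        assert z[0] == 0.0 and p[0] == 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p_t"):
            stouffer_combine([0.0], [0.5], [1.0], [1.0])
        with pytest.raises(ValueError, match="p_m"):
            stouffer_combine([0.5], [1.5], [1.0], [1.0])

    @given(
        p1=st.floats(1e-10, 1.0, exclude_min=False),
        p2=st.floats(1e-10, 1.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetric_in_its_two_components(self, p1, p2):
        _, pa = stouffer_combine([p1], [p2], [1.0], [1.0])
        _, pb = stouffer_combine([p2], [p1], [1.0], [1.0])
        assert pa[0] == pytest.approx(pb[0], rel=1e-9)

    @given(
        p1=st.floats(1e-8, 1.0),
        p2=st.floats(1e-8, 1.0),
        shrink=st.floats(0.1, 0.99),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_decreasing_a_p_never_raises_combined_p(self, p1, p2, shrink):
        _, p_base = stouffer_combine([p1], [p2], [1.0], [1.0])
        _, p_less = stouffer_combine([p1 * shrink], [p2], [1.0], [1.0])
        assert p_less[0] <= p_base[0] + 1e-12

    def test_uniform_on_independent_null_components(self):
        """Combining independent uniform two-sided p-values with random signs
        yields a uniform combined p — the combiner itself adds no bias."""
        rng = np.random.default_rng(99)
        n = 20_000
        p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
        s1, s2 = rng.choice([-1, 1], n), rng.choice([-1, 1], n)
        _, p = stouffer_combine(p1, p2, s1, s2)
        assert stats.kstest(p, "uniform").statistic < 0.02


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    def test_matches_quadratic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = int(rng.integers(1, 201))
            p = rng.uniform(np.finfo(float).tiny, 1.0, size=m)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=50))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_preserves_p_value_order(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


class TestDegCalls:
    @pytest.mark.parametrize(
        ("q", "lfc", "deg", "direction"),
        [
            (0.05, 0.58, True, "up"),     # both thresholds inclusive
            (0.05, -0.58, True, "down"),
            (0.051, 3.0, False, "none"),
            (0.01, -0.6, True, "down"),
            (0.01, 0.5, False, "none"),
        ],
    )
    def test_threshold_boundaries(self, q, lfc, deg, direction):
        table = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc], "q_fdr": [q]})
        out = call_degs(table, ComparisonConfig())
        assert bool(out["is_deg"][0]) is deg
        assert out["direction"][0] == direction


class TestRunComparison:
    def test_null_simulation_false_call_rate_bounded(self):
        cfg = SimConfig(
            n_genes=2000, groups={"control": 4, "treated": 4}, seed=21, de_fraction=0.0
        )
        counts, design, _ = simulate_null(cfg)
        table, summary = run_comparison(
            counts, design, "treated", "control", ComparisonConfig(seed=2)
        )
        assert summary["n_deg"] / summary["n_genes"] <= 0.05

    def test_spiked_genes_recovered(self):
        cfg = SimConfig(
            n_genes=800, groups={"control": 4, "treated": 4}, seed=31,
            de_fraction=0.1, lfc_floor=2.0, lfc_scale=1e-9,
        )
        from ihtseq import simulate_counts

        counts, design, truth = simulate_counts(cfg)
        table, _ = run_comparison(
            counts, design, "treated", "control", ComparisonConfig(seed=4)
        )
        table = table.set_index("gene_id")
        spiked = truth.is_de.index[truth.is_de["treated"]].intersection(table.index)
        assert table.loc[spiked, "is_deg"].mean() >= 0.8

    def test_same_seed_twice_is_byte_identical(self, tmp_path, small_sim):
        counts, design, _ = small_sim
        filtered = filter_low_counts(counts)
        paths = []
        for tag in ("a", "b"):
            table, _ = run_comparison(
                filtered, design, "KSO", "control", ComparisonConfig(seed=11)
            )
            path = tmp_path / f"{tag}.tsv"
            write_deg_table(table, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_summary_matches_table_recount(self, small_sim):
        counts, design, _ = small_sim
        table, summary = run_comparison(
            counts, design, "Fib", "control", ComparisonConfig(seed=1)
        )
        assert summary == deg_summary(table)
        assert summary["n_deg"] == summary["n_up"] + summary["n_down"]

    def test_component_pvalues_uniform_under_null(self):
        """Marginal p-values of both per-gene tests are calibrated on a pure
        null simulation (the combined p of two correlated components is not
        expected to be uniform and is not asserted here)."""
        cfg = SimConfig(
            n_genes=5000, groups={"control": 4, "treated": 4}, seed=55, de_fraction=0.0
        )
        counts, design, _ = simulate_null(cfg)
        from ihtseq import normalize

        filtered = filter_low_counts(counts)
        norm = normalize(filtered)
        expr = pd.DataFrame(norm.log_expr, index=filtered.gene_ids, columns=norm.sample_ids)
        _, p_t = ttest_per_gene(expr, design, "treated", "control")
        null = median_null(expr, design, "treated", "control", ComparisonConfig(seed=5))
        _, p_m = median_diff_p(expr, design, "treated", "control", null)
        assert stats.kstest(p_t, "uniform").statistic < 0.05
        assert stats.kstest(p_m, "uniform").statistic < 0.05
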