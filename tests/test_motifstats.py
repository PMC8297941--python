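"""Motif-level statistics: aggregation, tests, oracles and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synflow.infoflow import ConfigError
from synflow.motifstats import (
    _rm_anova_from_grid,
    baseline_and_permutation_comparison,
    bootstrap_ci,
    decile_significance_trend,
    motif_group,
    per_network_weight_regression,
    recurrent_vs_feedback_test,
    regress_out,
    rm_anova,
    spearman,
    summarize,
    synergy_share,
)


def make_triad_table(
    n_networks=10,
    per_cell=4,
    effect_rec=0.004,
    effect_fb=-0.002,
    noise=0.002,
    seed=0,
):
    """Synthetic triad table with additive recurrence/feedback effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for net in range(n_networks):
        tid = 0
        for r in range(3):
            for f in range(3):
                for _ in range(per_cell):
                    syn = 0.01 + effect_rec * r + effect_fb * f + rng.normal(0, noise)
                    rows.append(
                        dict(
                            network_id=net,
                            sender_a=tid,
                            sender_b=tid + 1000,
                            receiver=tid + 2000,
                            motif_id=1 + r * 3 + f,
                            recurrent_count=r,
                            feedback_count=f,
                            chirality="none",
                            synergy_norm=syn,
                            synergy=syn * 0.5,
                            redundancy=0.01,
                            mvte=0.05,
                            receiver_entropy=0.5,
                            sender_entropy=0.4,
                            ff_weight_mean=rng.uniform(0.01, 0.05),
                            recurrent_weight_mean=0.01 * r,
                            feedback_weight_mean=0.01 * f,
                        )
                    )
                    tid += 1
    return pd.DataFrame(rows)


class TestSummarize:
    def test_group_means(self):
        df = make_triad_table(n_networks=2, per_cell=2)
        s = summarize(df)
        one = df[(df.network_id == 0) & (df.motif_id == 5)]
        row = s[(s.network_id == 0) & (s.motif_id == 5)]
        assert row["synergy_norm"].iloc[0] == pytest.approx(one["synergy_norm"].mean())
        assert row["triad_count"].iloc[0] == 2

    def test_duplicate_triads_rejected(self):
        df = make_triad_table(n_networks=1, per_cell=1)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            summarize(dup)

    def test_matches_groupby_oracle(self):
        df = make_triad_table(n_networks=3, per_cell=3, seed=5)
        s = summarize(df)
        oracle = df.groupby(["network_id", "motif_id"])["synergy"].mean()
        for _, row in s.iterrows():
            assert row["synergy"] == pytest.approx(
                oracle.loc[(row["network_id"], row["motif_id"])]
            )


class TestGroupComparisons:
    def test_recurrent_exceeds_feedback_detected(self):
        s = summarize(make_triad_table(effect_rec=0.01, effect_fb=-0.01))
        res = recurrent_vs_feedback_test(s)
        assert res.direction == "greater"
        assert res.p_value < 0.01

    def test_identical_groups_degenerate(self):
        df = make_triad_table(effect_rec=0.0, effect_fb=0.0, noise=0.0)
        with pytest.raises(ValueError, match="zero|degenerate"):
            recurrent_vs_feedback_test(summarize(df))

    def test_baseline_and_permutation_detect_planted_ordering(self):
        df = make_triad_table(effect_rec=0.01, noise=0.001, seed=1)
        wil, perm = baseline_and_permutation_comparison(
            df, group="recurrent", n_perm=199, seed=2
        )
        assert wil.p_value < 0.01 and wil.direction == "greater"
        assert perm.p_value < 0.05 and perm.direction == "greater"

    def test_permutation_config_error(self):
        df = make_triad_table()
        with pytest.raises(ConfigError, match="n_perm"):
            baseline_and_permutation_comparison(df, n_perm=10, alpha=0.001)


class TestRMAnova:
    def test_constant_response_gives_zero_f(self):
        grid = np.ones((8, 3, 3))
        for res in _rm_anova_from_grid(grid):
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_matches_statsmodels_anova_rm(self):
        # independent oracle: statsmodels AnovaRM on the same long table
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        n = 12
        grid = rng.normal(size=(n, 3, 3)) + np.arange(3)[None, :, None] * 0.5
        ours = _rm_anova_from_grid(grid)
        long = pd.DataFrame(
            [
                {"subject": s, "a": a, "b": b, "y": grid[s, a, b]}
                for s in range(n)
                for a in range(3)
                for b in range(3)
            ]
        )
        sm = AnovaRM(long, "y", "subject", within=["a", "b"]).fit().anova_table
        for res, name in zip(ours, ["a", "b", "a:b"]):
            assert res.statistic == pytest.approx(sm.loc[name, "F Value"], abs=1e-9)
            assert res.p_value == pytest.approx(sm.loc[name, "Pr > F"], abs=1e-9)
            assert res.df == (sm.loc[name, "Num DF"], sm.loc[name, "Den DF"])

    def test_balanced_known_cells_sums_of_squares_oracle(self):
        # hand-computable: subjects identical, cells = r + 2f, no noise
        n = 5
        grid = np.tile(
            np.add.outer(np.arange(3), 2.0 * np.arange(3)), (n, 1, 1)
        )
        rec, fb, inter = _rm_anova_from_grid(grid)
        # zero error SS with nonzero effect SS -> infinite F, p = 0
        assert rec.statistic == np.inf and rec.p_value == 0.0
        assert fb.statistic == np.inf
        assert inter.statistic == 0.0  # additive construction

    def test_pipeline_surface_aggregates_chiralities(self):
        df = make_triad_table()
        # split the (1,1) cell into two chirality motifs
        mask = (df.recurrent_count == 1) & (df.feedback_count == 1)
        df.loc[mask, "chirality"] = np.where(
            np.arange(mask.sum()) % 2, "parallel", "cross"
        )
        res = rm_anova(summarize(df))
        assert len(res) == 3
        assert res[0].df == (2, 2 * (10 - 1))
        assert res[2].df == (4, 4 * (10 - 1))

    def test_insufficient_networks_rejected(self):
        df = make_triad_table(n_networks=2)
        with pytest.raises(ValueError, match="3"):
            rm_anova(summarize(df))


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5, 6, 7]
        y = [2, 1, 3, 3, 5, 4, 6, 5, 7, 9]
        ours = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert ours.statistic == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_small_sample_p_is_permutation_fraction(self):
        res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        # exact enumeration: of 5! rank permutations, 10 reach |rho| >= 0.9
        assert res.p_value == pytest.approx(10 / 120, abs=1e-12)


class TestRegressOut:
    def test_response_equal_covariate_gives_zero_residuals(self):
        x = np.arange(10.0)
        assert np.allclose(regress_out(x, x), 0.0, atol=1e-12)

    def test_orthogonal_covariate_leaves_centered_response(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        x = np.tile([1.0, -1.0], 50)
        y = y - (y @ x) / (x @ x) * x  # force orthogonality
        res = regress_out(y, x)
        assert np.allclose(res, y - y.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        res = regress_out(y, X)
        Xi = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert np.allclose(res, y - Xi @ beta, atol=1e-10)
        # residuals orthogonal to each covariate
        assert np.all(np.abs(res @ Xi) < 1e-8)

    def test_collinear_columns_named(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            regress_out(np.random.default_rng(0).normal(size=10), X)


class TestWeightRegression:
    def test_constructed_ff_dependence_detected(self):
        rng = np.random.default_rng(6)
        df = make_triad_table(n_networks=12, per_cell=3, noise=0.0, seed=7)
        df["synergy_norm"] = 2.0 * df["ff_weight_mean"] + rng.normal(
            0, 0.001, len(df)
        )
        betas, tests = per_network_weight_regression(df)
        assert tests["ff_weight_mean"].p_value < 0.01
        assert tests["ff_weight_mean"].direction == "greater"
        assert (betas["ff_weight_mean"] > 1.0).all()

    def test_small_networks_skipped(self):
        df = make_triad_table(n_networks=8, per_cell=1)  # 9 triads < 10
        betas, _ = per_network_weight_regression(df, min_triads=10)
        assert betas.empty


class TestBootstrap:
    def test_identical_values_zero_width(self):
        lo, hi = bootstrap_ci([2.5] * 12, "mean", n_boot=500, seed=0)
        assert lo == hi == 2.5

    def test_seed_reproducible(self):
        vals = np.random.default_rng(8).normal(size=30)
        assert bootstrap_ci(vals, "median", seed=3) == bootstrap_ci(
            vals, "median", seed=3
        )

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(9)
        cover = 0
        n_rep = 300
        for k in range(n_rep):
            sample = rng.normal(size=50)
            lo, hi = bootstrap_ci(sample, "mean", n_boot=400, seed=k)
            cover += lo <= 0.0 <= hi
        assert cover / n_rep == pytest.approx(0.95, abs=0.04)


class TestSynergyShare:
    def test_single_motif_ratio_one(self):
        df = make_triad_table(n_networks=3, per_cell=1)
        df = df[df.motif_id == 1]
        shares, _ = synergy_share(df)
        assert (shares["ratio"] == 1.0).all()
        assert (shares["synergy_share"] == 1.0).all()

    def test_two_to_one_synergy_ratio(self):
        rows = []
        for i, (mid, syn) in enumerate([(1, 0.2), (1, 0.2), (3, 0.1), (3, 0.1)]):
            rows.append(
                dict(network_id=0, sender_a=i, sender_b=i + 10, receiver=i + 20,
                     motif_id=mid, recurrent_count=1 if mid == 3 else 0,
                     feedback_count=0, synergy_norm=syn)
            )
        shares, _ = synergy_share(pd.DataFrame(rows))
        m1 = shares[shares.motif_id == 1].iloc[0]
        assert m1["synergy_share"] == pytest.approx(2 / 3)
        assert m1["triad_share"] == pytest.approx(0.5)

    def test_shares_sum_to_one_per_network(self):
        df = make_triad_table(n_networks=6, per_cell=3, seed=11)
        shares, _ = synergy_share(df)
        sums = shares.groupby("network_id")[["triad_share", "synergy_share"]].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestDecileTrend:
    def _edges(self, n_networks=10, n_edges=60, top_half_sig=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for net in range(n_networks):
            te = rng.random(n_edges)
            sig = te > np.median(te) if top_half_sig else rng.random(n_edges) < 0.3
            rows.append(pd.DataFrame(dict(network_id=net, te_raw=te, sig=sig)))
        return pd.concat(rows, ignore_index=True)

    def test_top_half_significant_gives_positive_trend(self):
        table, trend = decile_significance_trend(self._edges())
        assert trend.direction == "greater"
        assert trend.p_value < 0.01
        probs = table[table.network_id == 0].sort_values("decile")["p_significant"]
        assert (np.diff(probs) >= 0).all()

    def test_ten_edges_yield_binary_probabilities(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            dict(network_id=0, te_raw=rng.random(10), sig=rng.random(10) < 0.5)
        )
        probs, _ = decile_significance_trend(table)
        assert set(probs["p_significant"]) <= {0.0, 1.0}

    def test_all_significant_network_contributes_tie(self):
        table = pd.DataFrame(
            dict(network_id=0, te_raw=np.arange(20.0), sig=True)
        )
        _, trend = decile_significance_trend(table)
        assert trend.p_value == 1.0


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self):
        """Wilcoxon / permutation / RM-ANOVA rejection rates sit at the
        nominal level under matched simulated nulls."""
        from synflow.validation import null_pvalue_calibration

        out = null_pvalue_calibration(n_replicates=200, seed=0)
        for name, ps in out.items():
            rate = np.mean(ps < 0.05)
            # 200 replicates: binomial 99.7% interval around 0.05
            assert 0.05 - 3 * 0.0154 <= rate <= 0.05 + 3 * 0.0154, (name, rate)


def test_motif_group_labels():
    assert motif_group(2, 1) == "recurrent"
    assert motif_group(0, 1) == "feedback"
    assert motif_group(0, 0) == "default"
    assert motif_group(1, 1) == "balanced"
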