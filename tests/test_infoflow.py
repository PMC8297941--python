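"""Plug-in estimators: examples, brute-force oracle equivalence, identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synflow.infoflow import (
    ConfigError,
    JointDistribution,
    build_network,
    conditional_te,
    entropy,
    jitter_test,
    multivariate_te,
    mutual_information,
    transfer_entropy,
)
from synflow.raster import TS1, SpikeTrain, TimescaleSpec
from synflow.spikesim import SimConfig, generate_ground_truth, simulate


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the library's vectorized paths)
# ---------------------------------------------------------------------------


def brute_entropy(series):
    vals, counts = np.unique(series, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def brute_cmi(samples, x_idx, y_idx, z_idx):
    """I(X;Y|Z) by direct summation over an explicit sample table."""
    from collections import Counter

    def key(row, idx):
        return tuple(row[i] for i in idx)

    n = len(samples)
    cz = Counter(key(r, z_idx) for r in samples)
    cxz = Counter(key(r, x_idx + z_idx) for r in samples)
    cyz = Counter(key(r, y_idx + z_idx) for r in samples)
    cxyz = Counter(key(r, x_idx + y_idx + z_idx) for r in samples)
    total = 0.0
    for r in samples:
        pxyz = cxyz[key(r, x_idx + y_idx + z_idx)] / n
        pz = cz[key(r, z_idx)] / n
        pxz = cxz[key(r, x_idx + z_idx)] / n
        pyz = cyz[key(r, y_idx + z_idx)] / n
        total += np.log2(pxyz * pz / (pxz * pyz))
    return total / n


def brute_te(source, target, d):
    samples = [
        (target[t], source[t - d], target[t - d]) for t in range(d, len(target))
    ]
    return brute_cmi(samples, (0,), (1,), (2,))


class TestEntropy:
    def test_alternating_series_is_one_bit(self):
        assert entropy(np.tile([0, 1], 50)) == pytest.approx(1.0)

    def test_constant_series_is_zero(self):
        assert entropy(np.zeros(40, dtype=int)) == 0.0

    def test_quarter_probability(self):
        series = np.array([1, 0, 0, 0] * 25)
        assert entropy(series) == pytest.approx(0.8113, abs=1e-4)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            entropy(np.array([]))


class TestMutualInformation:
    def test_identical_series_normalized_to_one(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 500)
        assert mutual_information(a, a, normalize=True) == pytest.approx(1.0)

    def test_negated_series_normalized_to_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 500)
        assert mutual_information(a, 1 - a, normalize=True) == pytest.approx(1.0)

    def test_independent_series_mi_shrinks_with_length(self):
        rng = np.random.default_rng(2)
        mis = []
        for n in (200, 2000, 20000):
            vals = [
                mutual_information(rng.integers(0, 2, n), rng.integers(0, 2, n))
                for _ in range(20)
            ]
            mis.append(np.mean(vals))
        assert mis[0] > mis[1] > mis[2]
        assert mis[2] < 1e-4

    def test_zero_entropy_normalizer_returns_nan(self):
        a = np.zeros(50, dtype=int)
        b = np.tile([0, 1], 25)
        assert np.isnan(mutual_information(a, b, normalize=True))


class TestTransferEntropy:
    def test_delayed_copy_approaches_source_entropy(self):
        rng = np.random.default_rng(3)
        src = rng.integers(0, 2, 100_000)
        tgt = np.roll(src, 1)
        tgt[0] = 0
        assert transfer_entropy(src, tgt, 1) == pytest.approx(1.0, abs=0.01)

    def test_constant_source_gives_exactly_zero(self):
        rng = np.random.default_rng(4)
        tgt = rng.integers(0, 2, 500)
        assert transfer_entropy(np.zeros(500, dtype=int), tgt, 1) == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            transfer_entropy(np.array([0, 1]), np.array([1, 0]), 2)

    def test_plug_in_bias_shrinks_with_length(self):
        rng = np.random.default_rng(5)
        means = []
        for n in (500, 2000, 8000, 32000):
            vals = [
                transfer_entropy(
                    (rng.random(n) < 0.3).astype(int),
                    (rng.random(n) < 0.3).astype(int),
                    1,
                )
                for _ in range(30)
            ]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_short_series(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 20)
        src = rng.integers(0, 2, n)
        tgt = rng.integers(0, 2, n)
        d = int(rng.integers(1, min(3, n - 1) + 1))
        assert transfer_entropy(src, tgt, d) == pytest.approx(
            brute_te(src.tolist(), tgt.tolist(), d), abs=1e-12
        )


@pytest.fixture(scope="module")
def xor_series():
    rng = np.random.default_rng(6)
    n = 60_000
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    tgt = np.zeros(n, dtype=int)
    tgt[1:] = a[:-1] ^ b[:-1]
    return a, b, tgt


class TestMultivariateAndConditionalTE:
    def test_xor_target_mvte_one_bit_bivariate_zero(self, xor_series):
        a, b, tgt = xor_series
        assert multivariate_te(a, b, tgt, 1) == pytest.approx(1.0, abs=0.01)
        assert transfer_entropy(a, tgt, 1) == pytest.approx(0.0, abs=0.01)
        assert transfer_entropy(b, tgt, 1) == pytest.approx(0.0, abs=0.01)

    def test_xor_conditional_te_one_bit(self, xor_series):
        a, b, tgt = xor_series
        assert conditional_te(a, tgt, b, 1) == pytest.approx(1.0, abs=0.01)

    def test_constant_second_source_reduces_to_bivariate(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 400)
        tgt = rng.integers(0, 2, 400)
        const = np.zeros(400, dtype=int)
        assert multivariate_te(a, const, tgt, 1) == pytest.approx(
            transfer_entropy(a, tgt, 1), abs=1e-12
        )
        assert conditional_te(a, tgt, const, 1) == pytest.approx(
            transfer_entropy(a, tgt, 1), abs=1e-12
        )

    def test_independent_target_mvte_small(self):
        rng = np.random.default_rng(8)
        n = 50_000
        assert multivariate_te(
            rng.integers(0, 2, n), rng.integers(0, 2, n), rng.integers(0, 2, n), 1
        ) < 0.001

    def test_chain_rule_exact_identity(self):
        # mvTE = TE(A->I) + cTE(B->I | A) on the same empirical joint
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 300
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            tgt = rng.integers(0, 2, n)
            mv = multivariate_te(a, b, tgt, 1)
            assert mv == pytest.approx(
                transfer_entropy(a, tgt, 1) + conditional_te(b, tgt, a, 1),
                abs=1e-12,
            )

    def test_mvte_dominates_bivariate(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = 500
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            tgt = rng.integers(0, 2, n)
            mv = multivariate_te(a, b, tgt, 1)
            assert mv >= transfer_entropy(a, tgt, 1) - 1e-12
            assert mv >= transfer_entropy(b, tgt, 1) - 1e-12


class TestJointDistribution:
    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum"):
            JointDistribution(("a", "b"), np.full((2, 2), 0.3))

    def test_from_series_matches_lag_convention(self):
        src = np.array([1, 0, 0, 1, 0])
        tgt = np.array([0, 1, 0, 0, 1])
        jd = JointDistribution.from_series(tgt, [src], 1)
        # sample tuples (tgt_t, src_{t-1}, tgt_{t-1}) for t=1..4
        expected = [(1, 1, 0), (0, 0, 1), (0, 0, 0), (1, 1, 0)]
        for tup in expected:
            assert jd.probs[tup] > 0
        assert jd.probs.sum() == pytest.approx(1.0)


class TestJitterTest:
    def test_insufficient_jitters_for_alpha_rejected(self):
        t = SpikeTrain(0, np.array([1.0, 5.0]), 10.0)
        with pytest.raises(ConfigError, match="n_jitter"):
            jitter_test(t, t, TS1, n_jitter=100, alpha=0.001)

    def test_strong_planted_coupling_is_significant(self):
        graph = generate_ground_truth(2, 0.0, seed=2)
        graph.adjacency[0, 1] = 0.6
        cfg = SimConfig(
            duration_ms=300_000.0,
            baseline_rate_lognormal=(np.log(2.0), 0.0),
            coupling_delay_ms=1.0,
            burst_gain=1.0,
            seed=7,
        )
        src, tgt = simulate(graph, cfg)
        res = jitter_test(src, tgt, TS1, n_jitter=999, alpha=0.01, seed=3)
        assert res.significant
        assert res.p_value == pytest.approx(1 / 1000)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(11)
        a = SpikeTrain(0, np.sort(rng.uniform(0, 60_000, 100)), 60_000.0)
        b = SpikeTrain(1, np.sort(rng.uniform(0, 60_000, 100)), 60_000.0)
        r1 = jitter_test(a, b, TS1, n_jitter=199, alpha=0.01, seed=5)
        r2 = jitter_test(a, b, TS1, n_jitter=199, alpha=0.01, seed=5)
        assert r1 == r2


class TestBuildNetwork:
    def test_planted_triad_edges_recovered(self):
        graph = generate_ground_truth(3, 0.0, [(0, 0, None)], (0.5, 0.7), seed=1)
        cfg = SimConfig(
            duration_ms=600_000.0, coupling_delay_ms=1.0, seed=4
        )
        trains = simulate(graph, cfg)
        net = build_network(trains, TS1, n_jitter=199, alpha=0.01, seed=9)
        assert bool(net.sig_mask[0, 2]) and bool(net.sig_mask[1, 2])
        # normalized TE well-defined and bounded
        off = ~np.eye(3, dtype=bool)
        assert np.all((net.te_norm[off] >= 0) & (net.te_norm[off] <= 1))

    def test_zero_entropy_target_flagged_undefined(self):
        silent = SpikeTrain(0, np.array([]), 60_000.0)
        rng = np.random.default_rng(12)
        active = SpikeTrain(1, np.sort(rng.uniform(0, 60_000, 120)), 60_000.0)
        net = build_network([active, silent], TS1, n_jitter=199, alpha=0.01, seed=0)
        assert np.isnan(net.te_norm[0, 1])  # silent receiver
        assert not net.sig_mask[0, 1]

    def test_edge_list_round_trip_columns(self, tmp_path):
        rng = np.random.default_rng(13)
        trains = [
            SpikeTrain(i, np.sort(rng.uniform(0, 60_000, 100)), 60_000.0)
            for i in range(3)
        ]
        net = build_network(trains, TS1, n_jitter=199, alpha=0.01, seed=1)
        path = tmp_path / "net.tsv"
        net.write_edge_list(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        assert list(df.columns) == ["src", "dst", "te_raw", "te_norm", "pval", "sig"]
        assert len(df) == 6
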